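"""Synthetic alignment, variant and HSP tables with known ground truth.

Every input the pipeline consumes can be generated here at desk scale,
so each stage is testable without any sequence download.  The alignment
generator emulates the shape of a real draft-assembly-versus-reference
comparison: a bulk of top hits whose identities centre near the low 80s
percent with heavily right-skewed alignment lengths, plus two kinds of
planted outliers — "diverged" contigs whose only alignment is a 19-20 bp
perfect hit, and "conserved" contigs with very long (9,647-89,591 bp)
high-identity alignments.  Simulation happens at the alignment-summary
level; no sequences are emitted.

Planted rows are separable from the background by construction: a
19-20 bp perfect hit has composite value >= 1/20 = 0.05 while any
background row (length >= 25, identity <= 100) has composite <= 0.04.

Each table draws from its own pseudo-random stream derived from the
seed as ``default_rng([stream_code, seed])`` (alignment = 1,
variants = 2), so generating one table never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_align import BLAST_COLUMNS, write_blast_tab
from .qc import write_contig_meta

_ALIGN_STREAM = 1
_VARIANT_STREAM = 2

#: Alignment-length range (bp) of planted conserved outlier contigs.
CONSERVED_LENGTH_RANGE = (9_647, 89_591)
#: Contig-size range (bp) of planted diverged outlier contigs.
DIVERGED_CONTIG_RANGE = (300, 1_471)

_CHROMOSOMES = [f"chr{i}" for i in range(1, 29)] + ["chrZ"]


@dataclass(frozen=True)
class SyntheticAlignmentSpec:
    """Parameters of one synthetic comparative-alignment table.

    Background identities are Normal(identity_mean, identity_sd) clipped
    to [60, 100] percent; background alignment lengths are
    lognormal(al_log_mean, al_log_sd) clipped to >= 25 bp.  The defaults
    centre identity near 83% (the level observed for a quail-to-chicken
    comparison) with a median alignment length of ~700 bp and a heavy
    right tail.
    """

    n_background: int
    n_planted_diverged: int = 0
    n_planted_conserved: int = 0
    identity_mean: float = 83.0
    identity_sd: float = 5.0
    al_log_mean: float = 6.55
    al_log_sd: float = 0.70
    seed: int = 0

    def __post_init__(self):
        for name in ("n_background", "n_planted_diverged", "n_planted_conserved"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if not 0.0 < self.identity_mean <= 100.0:
            raise ValueError(
                f"identity_mean must be in (0, 100], got {self.identity_mean}"
            )
        if self.identity_sd < 0 or self.al_log_sd < 0:
            raise ValueError("identity_sd and al_log_sd must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_background + self.n_planted_diverged + self.n_planted_conserved


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels of the planted outlier contigs."""

    planted_diverged_ids: tuple
    planted_conserved_ids: tuple
    seed: int


def _bitscore(alignment_length: np.ndarray, identity: np.ndarray) -> np.ndarray:
    # rough bits-per-aligned-base model, enough to make scores rankable
    return np.round(1.9 * alignment_length * identity / 100.0, 1)


def _evalue(alignment_length: np.ndarray, bit_score: np.ndarray) -> np.ndarray:
    log_e = np.log(alignment_length * 1e6) - bit_score * np.log(2.0)
    with np.errstate(under="ignore"):
        return np.minimum(np.exp(log_e), 10.0)


def make_alignment_table(
    spec: SyntheticAlignmentSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one top HSP per contig plus contig metadata and truth labels.

    Returns ``(hits, meta, truth)``: an HSP table in the standard
    12-column layout (with a ``strand`` column, subject coordinates
    already normalized), contig metadata (contig_id, length >= alignment
    span, gc_fraction in [0.3, 0.6]) for every emitted id, and the
    planted-outlier id lists.  Identical spec and seed give byte-identical
    tables.
    """
    rng = np.random.default_rng([_ALIGN_STREAM, spec.seed])
    nb, nd, nc = spec.n_background, spec.n_planted_diverged, spec.n_planted_conserved
    n = spec.n_total

    ids = np.array([f"contig_{i:06d}" for i in range(1, n + 1)])
    # id blocks: background, then diverged, then conserved; row order is
    # shuffled at the end so planting position carries no signal
    bg_ids, div_ids, con_ids = ids[:nb], ids[nb : nb + nd], ids[nb + nd :]

    al = np.empty(n, dtype=np.int64)
    ident = np.empty(n, dtype=float)
    contig_len = np.empty(n, dtype=np.int64)

    al[:nb] = np.maximum(
        np.round(rng.lognormal(spec.al_log_mean, spec.al_log_sd, nb)), 25
    ).astype(np.int64)
    ident[:nb] = np.clip(rng.normal(spec.identity_mean, spec.identity_sd, nb), 60.0, 100.0)
    contig_len[:nb] = al[:nb] + rng.integers(0, np.maximum(al[:nb], 300) + 1)

    al[nb : nb + nd] = rng.integers(19, 21, nd)
    ident[nb : nb + nd] = 100.0
    contig_len[nb : nb + nd] = rng.integers(
        DIVERGED_CONTIG_RANGE[0], DIVERGED_CONTIG_RANGE[1] + 1, nd
    )

    al[nb + nd :] = rng.integers(
        CONSERVED_LENGTH_RANGE[0], CONSERVED_LENGTH_RANGE[1] + 1, nc
    )
    ident[nb + nd :] = rng.uniform(95.0, 100.0, nc)
    contig_len[nb + nd :] = al[nb + nd :] + rng.integers(
        0, np.maximum(al[nb + nd :] // 10, 1) + 1, nc
    )

    q_start = np.ones(n, dtype=np.int64)
    q_end = q_start + al - 1
    subject = rng.choice(_CHROMOSOMES, n)
    s_start = rng.integers(1, 150_000_000, n)
    s_end = s_start + al - 1
    strand = rng.choice(["+", "-"], n)
    mismatches = np.round(al * (1.0 - ident / 100.0)).astype(np.int64)
    gap_opens = rng.poisson(al / 2000.0)
    bit_score = _bitscore(al, ident)
    e_value = _evalue(al.astype(float), bit_score)

    hits = pd.DataFrame(
        {
            "query_id": ids,
            "subject_id": subject,
            "percent_identity": ident,
            "alignment_length": al,
            "mismatches": mismatches,
            "gap_opens": gap_opens,
            "q_start": q_start,
            "q_end": q_end,
            "s_start": s_start,
            "s_end": s_end,
            "e_value": e_value,
            "bit_score": bit_score,
            "strand": strand,
        }
    )
    hits = hits.iloc[rng.permutation(n)].reset_index(drop=True)

    meta = pd.DataFrame(
        {
            "contig_id": ids,
            "length": contig_len,
            "gc_fraction": np.round(rng.uniform(0.3, 0.6, n), 4),
        }
    )
    truth = SyntheticTruth(
        planted_diverged_ids=tuple(div_ids),
        planted_conserved_ids=tuple(con_ids),
        seed=spec.seed,
    )
    return hits, meta, truth


def make_variant_table(
    n: int,
    cov_mean: float = 77.0,
    cov_disp: float = 5.0,
    contig_len: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic heterozygous-variant table for one contig.

    Positions are uniform on [0, contig_len); coverage is
    negative-binomial with the given mean and dispersion (gamma shape),
    emulating the overdispersion of real short-read depth; call
    probabilities are uniform on [0.90, 1.0]; types are drawn
    SNP/insertion/deletion with proportions 0.93/0.035/0.035, mirroring
    a ~13:1 SNP:indel ratio.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if cov_mean <= 0:
        raise ValueError(f"cov_mean must be > 0, got {cov_mean}")
    if cov_disp <= 0:
        raise ValueError(f"cov_disp must be > 0, got {cov_disp}")
    rng = np.random.default_rng([_VARIANT_STREAM, seed])
    cols = ["contig_id", "position", "var_type", "coverage", "probability"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    p = cov_disp / (cov_disp + cov_mean)
    return pd.DataFrame(
        {
            "contig_id": "synthetic_contig",
            "position": rng.integers(0, contig_len, n),
            "var_type": rng.choice(
                ["SNP", "insertion", "deletion"], n, p=[0.93, 0.035, 0.035]
            ),
            "coverage": rng.negative_binomial(cov_disp, p, n),
            "probability": rng.uniform(0.90, 1.0, n),
        }
    )[cols]


def make_hsp_set(
    layout: Sequence[tuple[float, float, float, float]], contig_id: str
) -> pd.DataFrame:
    """Deterministic HSP table from an explicit (q_start, q_end, identity,
    bitscore) layout — a fixture builder for overlap and recomputation
    checks."""
    rows = []
    for i, (qs, qe, ident, bs) in enumerate(layout):
        if qs > qe:
            raise ValueError(f"layout row {i}: inverted interval ({qs}, {qe})")
        length = int(qe) - int(qs) + 1
        rows.append(
            {
                "query_id": contig_id,
                "subject_id": "chrS",
                "percent_identity": float(ident),
                "alignment_length": length,
                "mismatches": int(round(length * (1 - ident / 100.0))),
                "gap_opens": 0,
                "q_start": int(qs),
                "q_end": int(qe),
                "s_start": int(qs),
                "s_end": int(qe),
                "e_value": float(_evalue(np.array([length], float), np.array([bs]))[0]),
                "bit_score": float(bs),
                "strand": "+",
            }
        )
    return pd.DataFrame(rows, columns=BLAST_COLUMNS + ["strand"])


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write truth labels as a two-column TSV (contig_id, label)."""
    rows = [(cid, "diverged") for cid in truth.planted_diverged_ids] + [
        (cid, "conserved") for cid in truth.planted_conserved_ids
    ]
    pd.DataFrame(rows, columns=["contig_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_synthetic_dataset(spec: SyntheticAlignmentSpec, outdir: str | Path) -> dict:
    """Emit hits.tsv, contigs.tsv and truth.tsv for a spec; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hits, meta, truth = make_alignment_table(spec)
    paths = {
        "hits": outdir / "hits.tsv",
        "contigs": outdir / "contigs.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_blast_tab(hits, paths["hits"])
    write_contig_meta(meta, paths["contigs"])
    write_truth(truth, paths["truth"])
    return paths
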