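"""Variant filtering, heterozygosity density and genome summary computations.

Covers the per-assembly bookkeeping around the divergence analysis:
coverage/probability filtering of predicted heterozygous variants,
genome-wide variant density per Kbp, preparation of the binned diploid
input consumed by pairwise sequentially Markovian coalescent (PSMC)
inference, repeat-class and microsatellite summary totals, and the
C-value based genome-size estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VARIANT_TYPES = ("SNP", "insertion", "deletion")

#: Standard conversion from haploid nuclear DNA content to base pairs.
BP_PER_PICOGRAM = 0.978e9


@dataclass(frozen=True)
class CoverageFilterSpec:
    """Coverage window and probability floor for retaining variants.

    For diploid-consensus preparation the window is deliberately wide
    (e.g. 46-280x for a ~77x assembly) so that collapsed repeats and
    low-coverage artifacts are both excluded.
    """

    min_coverage: float
    max_coverage: float
    min_probability: float = 0.0

    def __post_init__(self):
        if not 0 <= self.min_coverage <= self.max_coverage:
            raise ValueError(
                f"require 0 <= min_coverage <= max_coverage, got "
                f"({self.min_coverage}, {self.max_coverage})"
            )


def filter_variants(variants: pd.DataFrame, spec: CoverageFilterSpec) -> pd.DataFrame:
    """Retain variants inside the coverage window with sufficient probability.

    Boundaries inclusive on both coverage ends; order preserved;
    idempotent.
    """
    keep = (
        (variants["coverage"] >= spec.min_coverage)
        & (variants["coverage"] <= spec.max_coverage)
        & (variants["probability"] >= spec.min_probability)
    )
    return variants[keep].reset_index(drop=True)


def variant_density_per_kb(n_variants: int, assembled_length: float) -> float:
    """Heterozygous variants per kilobase of assembled sequence.

    Returns the unrounded density; report helpers round to two decimals
    (round-half-even) alongside the exact value.
    """
    if assembled_length <= 0:
        raise ValueError(f"assembled_length must be > 0, got {assembled_length}")
    if n_variants < 0:
        raise ValueError(f"n_variants must be >= 0, got {n_variants}")
    return n_variants / (assembled_length / 1000.0)


def psmcfa_symbols(
    length: int,
    het_positions: Iterable[int],
    callable_mask: Sequence[bool] | np.ndarray | None = None,
    bin_size: int = 100,
) -> str:
    """Bin one contig into the K/T/N alphabet of the PSMC input format.

    Each of the ceil(length / bin_size) bins becomes 'K' if it contains
    at least one retained heterozygote, otherwise 'N' if more than half
    of its positions are uncallable, otherwise 'T'.  Positions are
    0-based; a heterozygote position outside [0, length) is an error.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    if length < 1:
        raise ValueError(f"contig length must be >= 1, got {length}")
    n_bins = -(-length // bin_size)
    if callable_mask is None:
        uncallable_per_bin = np.zeros(n_bins)
    else:
        mask = np.asarray(callable_mask, dtype=bool)
        if mask.size != length:
            raise ValueError(
                f"callable_mask length {mask.size} != contig length {length}"
            )
        uncallable = ~mask
        uncallable_per_bin = np.array(
            [uncallable[i * bin_size : (i + 1) * bin_size].sum() for i in range(n_bins)]
        )
    bin_sizes = np.full(n_bins, bin_size)
    bin_sizes[-1] = length - (n_bins - 1) * bin_size
    het_bins = np.zeros(n_bins, dtype=bool)
    for pos in het_positions:
        if not 0 <= pos < length:
            raise ValueError(f"heterozygote position {pos} outside [0, {length})")
        het_bins[pos // bin_size] = True
    symbols = np.where(
        het_bins, "K", np.where(uncallable_per_bin > bin_sizes / 2, "N", "T")
    )
    return "".join(symbols)


def write_psmcfa(
    records: Mapping[str, tuple],
    path: str | Path,
    bin_size: int = 100,
    line_width: int = 60,
) -> None:
    """Write binned contigs as FASTA-like records wrapped at 60 symbols.

    ``records`` maps contig_id to ``(length, het_positions)`` or
    ``(length, het_positions, callable_mask)``.
    """
    with open(path, "w") as fh:
        for contig_id, rec in records.items():
            length, hets, *rest = rec
            mask = rest[0] if rest else None
            seq = psmcfa_symbols(length, hets, mask, bin_size)
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


@dataclass(frozen=True)
class RepeatSummary:
    element_total: int
    bp_total: int
    percent_of_genome: float


def summarize_repeat_classes(
    rows: pd.DataFrame, genome_length: float
) -> RepeatSummary:
    """Totals over repeat-class rows and the genome fraction they cover.

    ``rows`` carries columns repeat_class, element_count, total_bp (as
    exported from a RepeatMasker summary).  The percentage is reported
    unrounded; two-decimal presentation is left to report helpers.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be > 0, got {genome_length}")
    if rows.empty:
        return RepeatSummary(0, 0, 0.0)
    if (rows["element_count"] < 0).any() or (rows["total_bp"] < 0).any():
        raise ValueError("repeat-class totals must be >= 0")
    bp = int(rows["total_bp"].sum())
    return RepeatSummary(
        element_total=int(rows["element_count"].sum()),
        bp_total=bp,
        percent_of_genome=bp / genome_length * 100.0,
    )


@dataclass(frozen=True)
class MicrosatSummary:
    counts: pd.Series  # indexed by motif length 2..10
    total: int


def summarize_microsatellites(rows: pd.DataFrame) -> MicrosatSummary:
    """Tandem-repeat counts grouped by motif length (2-10 bp) plus total."""
    index = pd.RangeIndex(2, 11, name="motif_length")
    if rows.empty:
        return MicrosatSummary(pd.Series(0, index=index, name="count"), 0)
    bad = rows[(rows["motif_length"] < 2) | (rows["motif_length"] > 10)]
    if not bad.empty:
        first = bad.iloc[0]
        raise ValueError(
            f"motif_length {first['motif_length']} outside [2, 10] "
            f"(row index {bad.index[0]})"
        )
    grouped = rows.groupby("motif_length")["count"].sum()
    counts = grouped.reindex(index, fill_value=0).astype(int)
    counts.name = "count"
    return MicrosatSummary(counts, int(counts.sum()))


def estimate_genome_size_from_cvalue(
    c_value: float, bp_per_pg: float = BP_PER_PICOGRAM
) -> float:
    """Nuclear genome size in bp from the haploid C-value in picograms."""
    if c_value <= 0:
        raise ValueError(f"c_value must be > 0, got {c_value}")
    return c_value * bp_per_pg


VARIANT_COLUMNS = ["contig_id", "position", "var_type", "coverage", "probability"]


def read_variant_tsv(path: str | Path) -> pd.DataFrame:
    """Read a variant table TSV (contig_id, position, var_type, coverage, probability)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[VARIANT_COLUMNS]


def read_variant_vcf(
    path: str | Path, probability_field: str = "PROB"
) -> pd.DataFrame:
    """Read a minimal VCF into the variant-table layout.

    Coverage is taken from INFO/DP and the call probability from the
    named INFO field (missing probability defaults to 1.0).  Variant
    type is inferred from REF/ALT lengths.  Positions are converted to
    0-based.
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        ref = rec.REF
        alt = rec.ALT[0] if rec.ALT else ref
        if len(ref) == len(alt):
            var_type = "SNP"
        elif len(alt) > len(ref):
            var_type = "insertion"
        else:
            var_type = "deletion"
        prob = rec.INFO.get(probability_field)
        rows.append(
            {
                "contig_id": rec.CHROM,
                "position": rec.POS - 1,
                "var_type": var_type,
                "coverage": rec.INFO.get("DP", 0),
                "probability": 1.0 if prob is None else float(prob),
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
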