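"""Quality-control battery for the divergence outlier analysis.

Four independent checks guard the outlier calls:

* conserved outliers are re-scored from *all* of their non-overlapping
  HSPs, not just the top hit, and must remain below the conserved bound;
* diverged outliers are overturned when an alternative-database
  alignment outscores the original top hit by >= 15% in bits;
* pairwise correlations among contig size, GC, identity and alignment
  length confirm that no nuisance covariate drives the statistic;
* the same extreme-percentile machinery applied to raw contig sizes
  shows the size distribution does not determine outlier status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import OutlierBounds, TAIL_CONSERVED, TAIL_NONE, percentile_bounds


@dataclass
class MergedAlignment:
    """Non-overlapping HSP tiling of one contig and its re-scored composite.

    Members are pairwise disjoint on the query (half-open intervals);
    the combined identity is the alignment-length-weighted mean of the
    member identities, and the recomputed composite is that weighted
    identity fraction divided by the summed alignment length.
    """

    contig_id: str
    members: pd.DataFrame
    total_alignment_length: int
    weighted_identity: float
    recomputed_composite: float


def merge_nonoverlapping_hsps(hsps: pd.DataFrame) -> MergedAlignment:
    """Greedily tile one contig's HSPs into a non-overlapping set.

    HSPs are visited in descending bitscore order (ties by ascending
    query start then end, so the result is invariant to input row
    order); an HSP is accepted iff its query interval overlaps no
    previously accepted member by >= 1 bp.  Overlap is judged on the
    query only — subject overlap is permitted.
    """
    if hsps.empty:
        raise ValueError("merge_nonoverlapping_hsps requires at least one HSP")
    qids = hsps["query_id"].unique()
    if len(qids) != 1:
        raise ValueError(f"expected HSPs for a single contig, got {sorted(qids)}")
    ordered = hsps.sort_values(
        ["bit_score", "q_start", "q_end"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    accepted: list[int] = []
    spans: list[tuple[int, int]] = []  # 0-based half-open query intervals
    for idx, row in ordered.iterrows():
        start, end = int(row["q_start"]) - 1, int(row["q_end"])
        if all(end <= s or start >= e for s, e in spans):
            accepted.append(idx)
            spans.append((start, end))
    members = hsps.loc[accepted].reset_index(drop=True)
    lengths = members["alignment_length"].to_numpy(dtype=float)
    idents = members["percent_identity"].to_numpy(dtype=float)
    total = int(lengths.sum())
    weighted = float((idents * lengths).sum() / lengths.sum())
    return MergedAlignment(
        contig_id=str(qids[0]),
        members=members,
        total_alignment_length=total,
        weighted_identity=weighted,
        recomputed_composite=(weighted / 100.0) / total,
    )


def recheck_conserved_outliers(
    calls: pd.DataFrame, all_hsps: pd.DataFrame, bounds: OutlierBounds
) -> pd.DataFrame:
    """Re-score conserved outliers from their full non-overlapping tiling.

    For each conserved call, every HSP of that contig is tiled with
    :func:`merge_nonoverlapping_hsps` and the composite recomputed from
    the appended alignment data; ``still_outlier`` records whether the
    recomputed value stays at or below the conserved bound.  A contig
    with no HSPs in ``all_hsps`` gets a missing recomputation and a
    ``flagged`` marker instead of being dropped.
    """
    conserved = calls[calls["tail"] == TAIL_CONSERVED]
    by_contig = dict(tuple(all_hsps.groupby("query_id")))
    rows = []
    for _, call in conserved.iterrows():
        cid = call["contig_id"]
        hsps = by_contig.get(cid)
        if hsps is None or hsps.empty:
            rows.append(
                {
                    "contig_id": cid,
                    "original_composite": call["composite"],
                    "recomputed_composite": np.nan,
                    "still_outlier": False,
                    "flagged": True,
                }
            )
            continue
        merged = merge_nonoverlapping_hsps(hsps)
        rows.append(
            {
                "contig_id": cid,
                "original_composite": call["composite"],
                "recomputed_composite": merged.recomputed_composite,
                "still_outlier": merged.recomputed_composite <= bounds.lower_value,
                "flagged": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "original_composite",
            "recomputed_composite",
            "still_outlier",
            "flagged",
        ],
    )


@dataclass(frozen=True)
class TraceCheck:
    """Decision record for the trace-alignment false-positive rule."""

    original_bitscore: float
    best_alternative_bitscore: float  # NaN when no alternatives exist
    is_false_positive: bool


#: Relative bitscore margin at which an alternative alignment overturns
#: a diverged-outlier call (>= 15% larger, boundary inclusive).
TRACE_FP_FACTOR = 1.15


def trace_fp_filter(
    original_bitscore: float, alternative_bitscores
) -> TraceCheck:
    """Overturn a diverged call when an alternative alignment outscores it.

    False positive iff the maximum alternative bitscore is at least
    ``TRACE_FP_FACTOR`` times the original.  An empty alternative list
    keeps the call.
    """
    if original_bitscore <= 0:
        raise ValueError(f"original_bitscore must be > 0, got {original_bitscore}")
    alts = list(alternative_bitscores)
    if not alts:
        return TraceCheck(float(original_bitscore), float("nan"), False)
    best = float(max(alts))
    return TraceCheck(
        float(original_bitscore), best, best >= TRACE_FP_FACTOR * original_bitscore
    )


_CORR_VARS = ["contig_length", "gc_fraction", "percent_identity", "alignment_length"]


@dataclass
class CorrelationMatrices:
    """Pairwise Pearson r and tie-corrected Kendall tau-b matrices."""

    pearson: pd.DataFrame
    kendall: pd.DataFrame
    n: int
    variables: list[str] = field(default_factory=lambda: list(_CORR_VARS))


def correlation_matrix(
    meta: pd.DataFrame, composites: pd.DataFrame
) -> CorrelationMatrices:
    """Pairwise correlations over contig size, GC, identity and length.

    Joins the contig metadata and composite records on contig_id and
    returns symmetric 4x4 Pearson-r and Kendall tau-b matrices (unit
    diagonal).  A constant column has undefined correlation; its
    off-diagonal entries are reported missing with a warning.
    """
    joined = meta.merge(
        composites[["contig_id", "percent_identity", "alignment_length"]],
        on="contig_id",
        how="inner",
    )
    if len(joined) < 3:
        raise ValueError(f"need >= 3 joined rows, got {len(joined)}")
    data = pd.DataFrame(
        {
            "contig_length": joined["length"].astype(float),
            "gc_fraction": joined["gc_fraction"].astype(float),
            "percent_identity": joined["percent_identity"].astype(float),
            "alignment_length": joined["alignment_length"].astype(float),
        }
    )
    k = len(_CORR_VARS)
    r = np.eye(k)
    tau = np.eye(k)
    constant = [data[v].nunique() == 1 for v in _CORR_VARS]
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                which = _CORR_VARS[i] if constant[i] else _CORR_VARS[j]
                warnings.warn(
                    f"correlation with constant column {which!r} is undefined",
                    stacklevel=2,
                )
                r[i, j] = r[j, i] = np.nan
                tau[i, j] = tau[j, i] = np.nan
                continue
            x = data[_CORR_VARS[i]]
            y = data[_CORR_VARS[j]]
            r[i, j] = r[j, i] = stats.pearsonr(x, y).statistic
            tau[i, j] = tau[j, i] = stats.kendalltau(x, y, variant="b").statistic
    return CorrelationMatrices(
        pearson=pd.DataFrame(r, index=_CORR_VARS, columns=_CORR_VARS),
        kendall=pd.DataFrame(tau, index=_CORR_VARS, columns=_CORR_VARS),
        n=len(joined),
    )


@dataclass
class SizeControlResult:
    """Contig-size percentile control against composite outlier calls."""

    size_outlier_ids: frozenset
    overlap_ids: frozenset
    overlap_count: int


def size_percentile_control(
    meta: pd.DataFrame,
    calls: pd.DataFrame,
    lower_pct: float = 0.02,
    upper_pct: float = 99.98,
) -> SizeControlResult:
    """Apply the outlier percentile machinery to raw contig sizes.

    Computes bounds at the same extreme percentiles on the full ordered
    contig-size distribution, collects the size outliers (boundaries
    inclusive, degenerate constant distribution yields none), and
    intersects them with the composite outlier calls.  A small overlap
    argues against contig size being deterministic for outlier status.
    """
    sizes = meta["length"].to_numpy(dtype=float)
    b = percentile_bounds(sizes, lower_pct, upper_pct)
    hi = sizes >= b.upper_value
    lo = sizes <= b.lower_value
    outlier_mask = (hi ^ lo)
    size_ids = frozenset(meta.loc[outlier_mask, "contig_id"])
    call_ids = frozenset(calls.loc[calls["tail"] != TAIL_NONE, "contig_id"])
    overlap = size_ids & call_ids
    return SizeControlResult(
        size_outlier_ids=size_ids,
        overlap_ids=frozenset(overlap),
        overlap_count=len(overlap),
    )


def read_contig_meta(path: str | Path) -> pd.DataFrame:
    """Read a contig metadata TSV with columns contig_id, length, gc_fraction."""
    df = pd.read_csv(path, sep="\t")
    expected = {"contig_id", "length", "gc_fraction"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_contig_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta[["contig_id", "length", "gc_fraction"]].to_csv(path, sep="\t", index=False)
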