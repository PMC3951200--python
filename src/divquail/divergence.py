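"""The length-normalized composite divergence statistic and outlier calls.

Percent identity alone cannot rank contig-to-reference alignments for
conservation or divergence because short alignments reach 100% identity
by chance while genuinely conserved alignments are long.  The composite
statistic divides the identity fraction by the alignment length,

    composite = (percent_identity / 100) / alignment_length,

so a short perfect hit (19 bp, 100%) scores 1/19 = 0.052631579 — the
upper extreme — while a long high-identity alignment scores orders of
magnitude lower.  Conserved and diverged outliers are the contigs at or
beyond the extreme percentile bounds (by default the 0.02th and 99.98th
percentiles) of the ordered composite distribution; with those defaults
the bounds capture more than 99% of the points between them.  Bounds
are always computed per comparative alignment, never pooled across
reference genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TAIL_NONE = "none"
TAIL_CONSERVED = "conserved"
TAIL_DIVERGED = "diverged"


def compute_composite(percent_identity: float, alignment_length: int) -> float:
    """Identity fraction divided by alignment length.

    ``percent_identity`` must lie in (0, 100] and ``alignment_length``
    must be an integer >= 1.  At 100% identity the value is exactly
    ``1 / alignment_length``.
    """
    if not 0.0 < percent_identity <= 100.0:
        raise ValueError(
            f"percent_identity must be in (0, 100], got {percent_identity}"
        )
    if alignment_length < 1 or int(alignment_length) != alignment_length:
        raise ValueError(
            f"alignment_length must be an integer >= 1, got {alignment_length}"
        )
    return (percent_identity / 100.0) / alignment_length


def composite_table(top: pd.DataFrame) -> pd.DataFrame:
    """Vectorized composite statistic over a top-hit table.

    Emits one record per input row (contig_id, percent_identity,
    alignment_length, composite); no row is dropped.
    """
    cols = ["contig_id", "percent_identity", "alignment_length", "composite"]
    if top.empty:
        return pd.DataFrame(columns=cols)
    pid = top["percent_identity"].to_numpy(dtype=float)
    al = top["alignment_length"].to_numpy()
    if (pid <= 0).any() or (pid > 100).any():
        raise ValueError("percent_identity out of (0, 100] in top-hit table")
    if (al < 1).any():
        raise ValueError("alignment_length < 1 in top-hit table")
    return pd.DataFrame(
        {
            "contig_id": top["query_id"].to_numpy(),
            "percent_identity": pid,
            "alignment_length": al,
            "composite": (pid / 100.0) / al,
        }
    )


@dataclass(frozen=True)
class OutlierBounds:
    """Percentile cutoffs on an ordered composite distribution."""

    lower_percentile: float
    upper_percentile: float
    lower_value: float
    upper_value: float
    n: int
    method: str = "linear"


def percentile_bounds(
    values: Sequence[float] | np.ndarray,
    lower_pct: float = 0.02,
    upper_pct: float = 99.98,
    method: str = "linear",
) -> OutlierBounds:
    """Interval bounds at the given percentiles of the ordered values.

    The default convention interpolates linearly between the closest
    order statistics (position ``(n - 1) * q / 100`` on the sorted
    sample); ``method="nearest"`` selects the nearest rank instead.
    Requires n >= 2 and ``0 < lower_pct < upper_pct < 100``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    if not (0.0 < lower_pct < upper_pct < 100.0):
        raise ValueError(
            f"percentiles must satisfy 0 < lower < upper < 100, "
            f"got ({lower_pct}, {upper_pct})"
        )
    lo, hi = np.percentile(arr, [lower_pct, upper_pct], method=method)
    return OutlierBounds(
        lower_percentile=lower_pct,
        upper_percentile=upper_pct,
        lower_value=float(lo),
        upper_value=float(hi),
        n=int(arr.size),
        method=method,
    )


def classify_outliers(records: pd.DataFrame, bounds: OutlierBounds) -> pd.DataFrame:
    """Call each record's distribution tail against the bounds.

    ``diverged`` iff composite >= upper bound, ``conserved`` iff
    composite <= lower bound (boundaries inclusive, so the printed
    boundary values themselves are outliers), else ``none``.  A record
    qualifying for both tails at once — possible only when the
    distribution is degenerate and the bounds coincide — is resolved to
    ``none``: a constant distribution has no outliers.
    """
    comp = records["composite"].to_numpy(dtype=float)
    hi = comp >= bounds.upper_value
    lo = comp <= bounds.lower_value
    tail = np.where(hi & ~lo, TAIL_DIVERGED,
                    np.where(lo & ~hi, TAIL_CONSERVED, TAIL_NONE))
    return pd.DataFrame(
        {
            "contig_id": records["contig_id"].to_numpy(),
            "tail": tail,
            "composite": comp,
            "fp_flag": np.zeros(len(records), dtype=bool),
        }
    )


def plot_composite_histogram(values, ax=None, bins: int = 100):
    """Histogram of the composite distribution on a log x-axis.

    The left edge is extreme conservation, the right edge extreme
    putative divergence.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    arr = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    edges = np.logspace(np.log10(arr.min()), np.log10(arr.max()), bins + 1)
    ax.hist(arr, bins=edges)
    ax.set_xscale("log")
    ax.set_xlabel("composite (identity fraction / alignment length)")
    ax.set_ylabel("contigs")
    return ax
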