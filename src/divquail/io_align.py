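"""Reading and top-hit selection for tabular HSP alignment files.

The on-disk dialect is the standard 12-column tab-separated alignment
table (qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore), one row per HSP.  Query coordinates are
1-based inclusive and never inverted; an inverted subject interval
(sstart > send) encodes a minus-strand hit and is normalized at read
time with the orientation kept in a ``strand`` column.  All internal
interval arithmetic elsewhere in the package converts these boundaries
to 0-based half-open form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Column names of the tabular alignment dialect, in file order.
BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]

_NUMERIC = {
    "percent_identity": float,
    "alignment_length": int,
    "mismatches": int,
    "gap_opens": int,
    "q_start": int,
    "q_end": int,
    "s_start": int,
    "s_end": int,
    "e_value": float,
    "bit_score": float,
}

# Tie-break order for top-hit selection: minimum E-value, then maximum
# bitscore, then lexicographically smallest subject and smallest subject
# start so the choice is deterministic under input shuffling.
_TIE_COLUMNS = ["e_value", "bit_score", "subject_id", "s_start"]
_TIE_ASCENDING = [True, False, True, True]


def normalize_strand(hits: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with minus-strand subject intervals swapped.

    Adds a ``strand`` column ('+'/'-'); after this every row satisfies
    ``s_start <= s_end``.
    """
    out = hits.copy()
    minus = out["s_start"] > out["s_end"]
    out["strand"] = np.where(minus, "-", "+")
    lo = out[["s_start", "s_end"]].min(axis=1)
    hi = out[["s_start", "s_end"]].max(axis=1)
    out["s_start"] = lo
    out["s_end"] = hi
    return out


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tabular alignment file into an HSP table.

    Blank lines and ``#`` comment lines are skipped.  A row with the
    wrong column count or a non-numeric value in a numeric field raises
    :class:`ValueError` naming the offending 1-based line number.  An
    empty file yields an empty table and a warning.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(BLAST_COLUMNS)} "
                    f"tab-separated columns, found {len(fields)}"
                )
            rows.append([str(lineno)] + fields)
    if not rows:
        warnings.warn(f"{path}: no alignment rows found", stacklevel=2)
        return empty_hit_table()
    df = pd.DataFrame(rows, columns=["_line"] + BLAST_COLUMNS)
    for col, typ in _NUMERIC.items():
        try:
            df[col] = df[col].astype(float if typ is float else np.int64)
        except ValueError:
            bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna(), "_line"]
            raise ValueError(
                f"{path}: line {bad.iloc[0]}: non-numeric value "
                f"{df.loc[bad.index[0], col]!r} in column {col!r}"
            ) from None
    df = df.drop(columns="_line").reset_index(drop=True)
    return normalize_strand(df)


def write_blast_tab(hits: pd.DataFrame, path: str | Path) -> None:
    """Write an HSP table back to the 12-column tab-separated dialect."""
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def empty_hit_table() -> pd.DataFrame:
    """An empty HSP table with the standard columns and dtypes."""
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                       [("query_id", object), ("subject_id", object)]
                       + [(c, _NUMERIC[c]) for c in _NUMERIC]})
    df["strand"] = pd.Series(dtype=object)
    return df[BLAST_COLUMNS + ["strand"]]


def select_top_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Select the single best HSP per query.

    Best means minimum E-value; E-value ties are broken by maximum
    bitscore, then smallest subject_id, then smallest subject start.
    Returns one row per distinct query_id, sorted by query_id.
    """
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["query_id"] + _TIE_COLUMNS,
        ascending=[True] + _TIE_ASCENDING,
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="query_id", keep="first").reset_index(drop=True)


@dataclass
class LadderResult:
    """Outcome of the E-value step-down acceptance procedure.

    ``hits`` carries one accepted top hit per query plus a
    ``ladder_step`` column (index of the threshold at which the query
    was first satisfied); ``no_hit_ids`` lists the queries whose best
    E-value exceeded every threshold — kept explicitly, the way
    unaligned contigs are reported rather than silently dropped.
    """

    hits: pd.DataFrame
    no_hit_ids: list[str] = field(default_factory=list)


def apply_evalue_ladder(
    hits: pd.DataFrame, thresholds: Sequence[float]
) -> LadderResult:
    """Accept one top hit per query via an E-value step-down ladder.

    ``thresholds`` must be a non-empty, strictly increasing sequence
    (strictest first, e.g. ``[1e-30, 1e-10, 1e-4]``).  A query satisfied
    at a stricter threshold never re-enters later rounds, so each
    retained hit is the overall top hit for its query and is annotated
    with the index of the first threshold its E-value meets.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold ladder must not be empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("ladder thresholds must be strictly increasing")
    top = select_top_hits(hits)
    if top.empty:
        return LadderResult(hits=top.assign(ladder_step=pd.Series(dtype=int)))
    step = np.searchsorted(np.asarray(thresholds), top["e_value"].to_numpy(),
                           side="left")
    accepted = top[step < len(thresholds)].copy()
    accepted["ladder_step"] = step[step < len(thresholds)]
    rejected = top.loc[step >= len(thresholds), "query_id"].tolist()
    return LadderResult(hits=accepted.reset_index(drop=True), no_hit_ids=rejected)


def per_chromosome_identity_summary(top: pd.DataFrame) -> pd.DataFrame:
    """Summarize top-hit percent identity per reference chromosome.

    Returns one row per subject_id with hit count, median and mean
    percent identity, plus a trailing ``overall`` row over all hits.
    The median is the midpoint of the two central order statistics for
    even n (the ordinary sample median).
    """
    cols = ["subject_id", "n", "median_identity", "mean_identity"]
    if top.empty:
        return pd.DataFrame(columns=cols)
    per = (
        top.groupby("subject_id")["percent_identity"]
        .agg(n="size", median_identity="median", mean_identity="mean")
        .reset_index()
        .sort_values("subject_id", kind="mergesort")
    )
    overall = pd.DataFrame(
        [{
            "subject_id": "overall",
            "n": len(top),
            "median_identity": top["percent_identity"].median(),
            "mean_identity": top["percent_identity"].mean(),
        }]
    )
    out = pd.concat([per, overall], ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out[cols]
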