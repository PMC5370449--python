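"""Light-weight genomic interval operations on plain DataFrames.

All intervals are 0-based, half-open, held in DataFrames with at least the
columns ``chrom``, ``start``, ``end`` (optionally ``name``, ``score``,
``strand``).  The sizes handled here are desk scale (thousands of rows), so
merged sorted arrays plus binary search are sufficient and keep everything
in numpy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an interval frame (sorted, int coords)."""
    missing = {"chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"interval frame lacks columns: {sorted(missing)}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        bad = out[out["start"] >= out["end"]].iloc[0]
        raise ValueError(f"degenerate interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: disjoint, sorted per chromosome."""
    df = as_intervals(df)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merged_lookup(subject: pd.DataFrame) -> dict:
    merged = merge_intervals(subject) if len(subject) else subject
    out = {}
    if len(subject):
        for chrom, sub in merged.groupby("chrom"):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it intersect (>=1 bp) any subject interval?"""
    res = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return res
    lut = _merged_lookup(subject)
    for chrom, idx in query.groupby("chrom").groups.items():
        if chrom not in lut:
            continue
        s, e = lut[chrom]
        qs = query.loc[idx, "start"].to_numpy()
        qe = query.loc[idx, "end"].to_numpy()
        # merged intervals are disjoint and sorted, so only the last interval
        # starting before the query end can overlap
        j = np.searchsorted(s, qe, side="left") - 1
        ok = (j >= 0) & (e[np.clip(j, 0, len(e) - 1)] > qs)
        res[query.index.get_indexer(idx)] = ok
    return res


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection of the unions of two interval sets."""
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    ma, mb = merge_intervals(a), merge_intervals(b)
    rows = []
    for chrom in sorted(set(ma["chrom"]) & set(mb["chrom"])):
        xa = ma[ma["chrom"] == chrom]
        xb = mb[mb["chrom"] == chrom]
        ia = ib = 0
        sa, ea = xa["start"].to_numpy(), xa["end"].to_numpy()
        sb, eb = xb["start"].to_numpy(), xb["end"].to_numpy()
        while ia < len(sa) and ib < len(sb):
            lo = max(sa[ia], sb[ib])
            hi = min(ea[ia], eb[ib])
            if lo < hi:
                rows.append((chrom, lo, hi))
            if ea[ia] < eb[ib]:
                ia += 1
            else:
                ib += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def pad(df: pd.DataFrame, by: int) -> pd.DataFrame:
    """Expand every interval by ``by`` bp on both sides (clipped at 0)."""
    out = as_intervals(df)
    out["start"] = np.maximum(out["start"] - by, 0)
    out["end"] = out["end"] + by
    return out


def total_length(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())
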