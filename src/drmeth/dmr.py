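"""Differentially methylated region (DMR) calling on 50-CpG bins.

A DMR for a named pairwise contrast is a bin with a Benjamini-Hochberg
adjusted chi-squared p value below ``alpha`` (default 0.05) and an absolute
methylation difference of at least ``min_diff`` percentage points (default
10).  The chi-squared test runs on pooled counts (a count-based test needs
counts); the reported delta comes from the bin's quantitated levels
(mean-of-CpG-percentages by default), second group minus first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: named pairwise contrasts (first group, second group); delta = second - first
CONTRASTS: dict[str, tuple[str, str]] = {
    "age_AL": ("AL_young", "AL_old"),
    "age_DR": ("DR_young", "DR_old"),
    "diet_young": ("AL_young", "DR_young"),
    "diet_old": ("AL_old", "DR_old"),
}

#: conventional names of the three reported DMR sets
DMR_SET_NAMES = {
    "age_AL": "age-related DMRs",
    "diet_young": "Young-DR DMRs",
    "diet_old": "Old-DR DMRs",
}


def chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Vectorised Pearson chi-squared (1 df, no continuity correction) on
    2x2 tables [[a, b], [c, d]].  Degenerate margins give chi2 = 0, p = 1."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    ok = (denom > 0) & (n > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(ok, n * (a * d - b * c) ** 2 / np.where(ok, denom, 1.0), 0.0)
    p = np.where(ok, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def chi2_bin_test(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> tuple[float, float]:
    """Chi-squared test on one bin's pooled counts for two groups."""
    chi2, p = chi2_2x2(
        np.array([meth_a]), np.array([unmeth_a]), np.array([meth_b]), np.array([unmeth_b])
    )
    return float(chi2[0]), float(p[0])


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def test_bins(bins: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Chi-squared statistics and BH-adjusted p values for every bin.

    The BH family is the full set of bins testable for the contrast (both
    group totals > 0).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    g1, g2 = CONTRASTS[contrast]
    out = bins[["chrom", "start", "end", "bin_id"]].copy()
    m1 = bins[f"meth_{g1}"].to_numpy()
    u1 = bins[f"unmeth_{g1}"].to_numpy()
    m2 = bins[f"meth_{g2}"].to_numpy()
    u2 = bins[f"unmeth_{g2}"].to_numpy()
    out["level_1"] = bins[f"level_{g1}"].to_numpy()
    out["level_2"] = bins[f"level_{g2}"].to_numpy()
    out["delta"] = out["level_2"] - out["level_1"]
    chi2, p = chi2_2x2(m1, u1, m2, u2)
    out["chi2"] = chi2
    out["p"] = p
    testable = ((m1 + u1) > 0) & ((m2 + u2) > 0) & np.isfinite(out["delta"].to_numpy())
    padj = np.full(len(out), np.nan)
    if testable.any():
        padj[testable] = adjust_bh(p[testable])
    out["padj"] = padj
    out["contrast"] = contrast
    return out


def call_dmrs(
    bins: pd.DataFrame,
    contrast: str,
    min_diff: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call DMRs: padj < alpha and |delta| >= min_diff.

    direction is "hyper" iff delta > 0 (second group more methylated).
    Output order follows genomic order regardless of input order.
    """
    tested = test_bins(bins.sort_values(["chrom", "start"], kind="mergesort"), contrast)
    keep = (tested["padj"] < alpha) & (tested["delta"].abs() >= min_diff)
    dmrs = tested[keep.fillna(False)].copy()
    dmrs["direction"] = np.where(dmrs["delta"] > 0, "hyper", "hypo")
    return dmrs.reset_index(drop=True)


def summarize_magnitude(dmrs: pd.DataFrame, reference: str = "level_1") -> dict:
    """Median reference-group level and median delta per direction."""
    out: dict = {"n": int(len(dmrs))}
    for direction in ("hyper", "hypo"):
        sub = dmrs[dmrs["direction"] == direction] if len(dmrs) else dmrs
        if len(sub) == 0:
            out[direction] = {"n": 0, "median_reference_level": None, "median_delta": None}
        else:
            out[direction] = {
                "n": int(len(sub)),
                "median_reference_level": float(sub[reference].median()),
                "median_delta": float(sub["delta"].median()),
            }
    if len(dmrs):
        out["deltas"] = dmrs["delta"].to_numpy()
    return out


def replicate_delta_sign_agreement(
    table, bins: pd.DataFrame, dmrs: pd.DataFrame, contrast: str
) -> pd.DataFrame:
    """Diagnostic: per-replicate-pair delta signs over DMR bins.

    For each DMR bin, computes the pooled-level delta for each individual
    replicate pair (i-th replicate of each contrast group) and reports the
    fraction of pairs agreeing in sign with the merged-group delta.  Used to
    check that DMRs are not driven by single outlier samples.
    """
    g1, g2 = CONTRASTS[contrast]
    reps1 = sorted(s for s, g in table.sample_groups.items() if g == g1)
    reps2 = sorted(s for s, g in table.sample_groups.items() if g == g2)
    pos_index = {c: sub.index.get_level_values(1).to_numpy() for c, sub in table.df.groupby(level=0)}
    rows = []
    for _, bin_row in dmrs.iterrows():
        chrom = bin_row["chrom"]
        pos = pos_index[chrom]
        lo = np.searchsorted(pos, bin_row["start"] + 1, side="left")
        hi = np.searchsorted(pos, bin_row["end"] - 1, side="right")
        sub = table.df.loc[chrom].iloc[lo:hi]
        signs = []
        for s1, s2 in zip(reps1, reps2):
            def lev(s):
                m = sub[(s, "meth")].sum()
                u = sub[(s, "unmeth")].sum()
                return 100.0 * m / (m + u) if m + u > 0 else np.nan
            d = lev(s2) - lev(s1)
            if np.isfinite(d):
                signs.append(np.sign(d))
        agree = float(np.mean([s == np.sign(bin_row["delta"]) for s in signs])) if signs else np.nan
        rows.append({"bin_id": bin_row["bin_id"], "n_pairs": len(signs), "sign_agreement": agree})
    return pd.DataFrame(rows)
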