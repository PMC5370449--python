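"""Triglyceride (TG) composition statistics.

TG species are keyed by total acyl carbons (chain-length proxy; even values
38-60 expected) and total double bonds (saturation proxy; 0-12).  Abundances
are normalised per sample to percent of the entire TG lipidome, aggregated
by chain length or saturation, and tested with:

* one-way ANOVA + Tukey HSD across the four groups per category;
* a paired Wilcoxon signed-rank test on per-category condition means within
  an interval of the category axis (e.g. the 38-52 carbon "left tail").
  The studied protocol names this a "paired Wilcoxon-rank-sum test"; a
  rank-sum test cannot be paired, so the signed-rank test on paired means
  is what is computed here;
* a two-way ANOVA (age x diet, with interaction) on per-sample total TG.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

log = logging.getLogger("drmeth")

EXPECTED_CARBONS = tuple(range(38, 61, 2))
EXPECTED_DOUBLE_BONDS = tuple(range(0, 13))

#: the intervals used for the tail tests, inclusive category ranges
CARBON_INTERVALS = {"left": (38, 52), "right": (54, 60)}
DOUBLE_BOND_INTERVALS = {"left": (0, 3), "right": (4, 12)}


def _sample_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("carbons", "double_bonds", "species")]


def normalize_tg(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance: percent of the entire TG lipidome."""
    out = table.copy()
    cols = _sample_cols(table)
    for c in cols:
        if (out[c] < 0).any():
            raise ValueError(f"negative abundance in sample {c!r}")
        total = out[c].sum()
        if total <= 0:
            raise ValueError(f"sample {c!r} has zero total TG abundance")
        out[c] = 100.0 * out[c] / total
    odd = out["carbons"] % 2 != 0
    if odd.any():
        log.warning("%d TG species with odd carbon counts retained", int(odd.sum()))
    return out


def aggregate_by(table: pd.DataFrame, key: str) -> pd.DataFrame:
    """Category x sample matrix of summed relative abundances.

    ``key`` is "carbons" or "double_bonds".  Columns sum to 100 (mass
    conservation of the per-sample percentages).
    """
    if key not in ("carbons", "double_bonds"):
        raise ValueError(f"unknown aggregation key {key!r}")
    cols = _sample_cols(table)
    return table.groupby(key)[cols].sum().sort_index()


def per_category_test(matrix: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """One-way ANOVA across groups per category plus Tukey HSD pairwise p.

    Categories where any group has < 2 samples are skipped (logged).
    Unequal group sizes are handled by the Tukey-Kramer form of the
    studentized-range test.
    """
    by_group: dict[str, list[str]] = {}
    for s, g in groups.items():
        by_group.setdefault(g, []).append(s)
    names = sorted(by_group)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for cat, row in matrix.iterrows():
        samples = [row[by_group[g]].to_numpy(dtype=float) for g in names]
        if any(len(v) < 2 for v in samples):
            log.info("category %s skipped: group with < 2 samples", cat)
            continue
        rec = {"category": cat}
        if np.ptp(np.concatenate(samples)) == 0:
            rec["anova_F"], rec["anova_p"] = 0.0, 1.0
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    rec[f"tukey_p_{names[i]}_vs_{names[j]}"] = 1.0
        else:
            f, p = stats.f_oneway(*samples)
            rec["anova_F"], rec["anova_p"] = float(f), float(p)
            tuk = stats.tukey_hsd(*samples)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    rec[f"tukey_p_{names[i]}_vs_{names[j]}"] = float(tuk.pvalue[i, j])
        rows.append(rec)
    return pd.DataFrame(rows)


def interval_test(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    pair: tuple[str, str],
    intervals: dict[str, tuple[float, float]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Paired signed-rank test of condition means across interval categories.

    Replicates of each condition in ``pair`` are averaged per category, then
    the paired differences (second condition minus first) over the
    categories inside each inclusive interval are tested with the Wilcoxon
    signed-rank test (exact distribution where possible).  With alternative
    "greater", k strictly positive differences give p = 2**(-k).
    """
    g1, g2 = pair
    s1 = [s for s, g in groups.items() if g == g1]
    s2 = [s for s, g in groups.items() if g == g2]
    if not s1 or not s2:
        raise ValueError(f"pair {pair} not present in groups")
    m1 = matrix[s1].mean(axis=1)
    m2 = matrix[s2].mean(axis=1)
    rows = []
    for name, (lo, hi) in intervals.items():
        cats = [c for c in matrix.index if lo <= c <= hi]
        if len(cats) < 2:
            raise ValueError(f"interval {name!r} spans {len(cats)} categories; test undefined")
        diff = (m2.loc[cats] - m1.loc[cats]).to_numpy()
        nonzero = diff[diff != 0]
        if len(nonzero) == 0:
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(nonzero, alternative=alternative, method="exact").pvalue
            )
        rows.append({"interval": name, "lo": lo, "hi": hi, "n_categories": len(cats),
                     "mean_diff": float(np.mean(diff)), "p": p})
    return pd.DataFrame(rows)


def tg_content_interaction(
    totals: pd.DataFrame, typ: int = 2
) -> pd.DataFrame:
    """Two-way ANOVA of total TG on age x diet with interaction.

    ``totals`` needs columns total, age, diet.  Every age x diet cell must
    contain at least one sample.
    """
    for col in ("total", "age", "diet"):
        if col not in totals.columns:
            raise ValueError(f"totals table needs a {col!r} column")
    cells = totals.groupby(["age", "diet"]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError("empty age x diet cell")
    model = smf.ols("total ~ C(age) * C(diet)", data=totals).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    table = table.rename(index={"C(age)": "age", "C(diet)": "diet", "C(age):C(diet)": "age:diet"})
    return table
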