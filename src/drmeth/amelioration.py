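"""Detection of age-related methylation changes attenuated by DR.

For every bin three signed percentage-point deltas are computed:

* ``d_age_AL``  = level(AL_old)  - level(AL_young)   (aging under AL)
* ``d_age_DR``  = level(DR_old)  - level(DR_young)   (aging under DR)
* ``d_diet_old`` = level(DR_old) - level(AL_old)     (diet difference at old age)

``d_diet_old`` is regressed on each aging delta (ordinary least squares,
with the Pearson correlation).  If DR merely slowed genome-wide aging the
two scatters would look alike; amelioration shows up as bins that changed
with age under AL but scatter away from the aging-under-DR fit.  The sample
standard deviation sigma of the residuals from the AL fit estimates the
naturally random scatter; age-related DMRs whose residual from the *DR* fit
exceeds 2*sigma are classified as DR-ameliorated, split hyper/hypo by their
age-direction under AL.

Three per-bin label-permutation schemes provide null distributions for the
observed slopes and correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GROUPS

PERMUTATION_SCHEMES = ("all_labels", "across_age_within_diet", "across_diet_within_age")

_LEVEL_COLS = [f"level_{g}" for g in GROUPS]


def compute_deltas(bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin (d_age_AL, d_age_DR, d_diet_old) in percentage points.

    Bins with a missing group level are dropped (logged by the caller).
    """
    lv = bins[_LEVEL_COLS].to_numpy(dtype=float)
    out = bins[["chrom", "start", "end", "bin_id"]].copy()
    out["d_age_AL"] = lv[:, 1] - lv[:, 0]
    out["d_age_DR"] = lv[:, 3] - lv[:, 2]
    out["d_diet_old"] = lv[:, 3] - lv[:, 1]
    ok = np.isfinite(lv).all(axis=1)
    return out[ok].reset_index(drop=True)


def fit_scatter(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of y on x; returns (slope, intercept, pearson_r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points for a fit")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def _fit_many(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS slope and Pearson r for (n_perm, n_bins) arrays."""
    xm = X - X.mean(axis=1, keepdims=True)
    ym = Y - Y.mean(axis=1, keepdims=True)
    sxx = (xm * xm).sum(axis=1)
    syy = (ym * ym).sum(axis=1)
    sxy = (xm * ym).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        denom = np.sqrt(sxx * syy)
        r = np.where(denom > 0, sxy / np.where(denom > 0, denom, 1.0), 0.0)
    return slope, r


def permute_null(
    bins: pd.DataFrame,
    scheme: str,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Null distribution of (slope, r) for both fits under a label scheme.

    Labels are permuted independently *per bin*:

    * ``all_labels`` -- a random permutation of the four group levels;
    * ``across_age_within_diet`` -- young/old swapped with probability 1/2
      independently inside each diet;
    * ``across_diet_within_age`` -- the AL/DR labels of both ages swapped
      together with probability 1/2 (one coin per bin), which averages
      consistent diet differences away while preserving each arm's aging
      structure; independent per-age swaps would instead turn pure diet
      effects into an artificial d_diet_old = -d_age relation.
    """
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    L = bins[_LEVEL_COLS].to_numpy(dtype=float)
    L = L[np.isfinite(L).all(axis=1)]
    rng = np.random.default_rng(seed)
    n = len(L)
    rows = []
    for _ in range(n_perm):
        if scheme == "all_labels":
            P = rng.permuted(L, axis=1)
        elif scheme == "across_age_within_diet":
            P = L.copy()
            swap = rng.random(n) < 0.5
            P[swap, 0], P[swap, 1] = L[swap, 1], L[swap, 0]
            swap = rng.random(n) < 0.5
            P[swap, 2], P[swap, 3] = L[swap, 3], L[swap, 2]
        else:  # across_diet_within_age: one coin swaps both age pairs
            P = L.copy()
            swap = rng.random(n) < 0.5
            P[swap, 0], P[swap, 2] = L[swap, 2], L[swap, 0]
            P[swap, 1], P[swap, 3] = L[swap, 3], L[swap, 1]
        d_age_al = P[:, 1] - P[:, 0]
        d_age_dr = P[:, 3] - P[:, 2]
        d_diet = P[:, 3] - P[:, 1]
        sa, ra = _fit_many(d_age_al[None, :], d_diet[None, :])
        sd, rd = _fit_many(d_age_dr[None, :], d_diet[None, :])
        rows.append((sa[0], ra[0], sd[0], rd[0]))
    return pd.DataFrame(rows, columns=["slope_AL", "r_AL", "slope_DR", "r_DR"])


def classify_ameliorated(
    age_dmrs: pd.DataFrame,
    deltas: pd.DataFrame,
    fit_DR: tuple[float, float],
    sigma: float,
    n_sigma: float = 2.0,
) -> pd.DataFrame:
    """Flag age-related DMRs scattering beyond n_sigma*sigma from the DR fit.

    Residuals are d_diet_old - (intercept + slope * d_age_DR).  The hyper/
    hypo split follows the DMR's age direction under AL.
    """
    if len(age_dmrs) == 0:
        return pd.DataFrame(
            columns=["bin_id", "chrom", "start", "end", "d_age_AL", "d_age_DR",
                     "d_diet_old", "residual", "direction"]
        )
    slope, intercept = fit_DR
    cutoff = n_sigma * sigma
    sub = deltas[deltas["bin_id"].isin(set(age_dmrs["bin_id"]))].copy()
    sub["residual"] = sub["d_diet_old"] - (intercept + slope * sub["d_age_DR"])
    direction = age_dmrs.set_index("bin_id")["direction"]
    sub["direction"] = sub["bin_id"].map(direction)
    flagged = sub[sub["residual"].abs() > cutoff]
    return flagged.reset_index(drop=True)


def residual_sigma(deltas: pd.DataFrame, fit_AL: tuple[float, float]) -> float:
    """Sample standard deviation (ddof=1) of residuals from the AL fit."""
    slope, intercept = fit_AL
    resid = deltas["d_diet_old"] - (intercept + slope * deltas["d_age_AL"])
    return float(np.std(resid.to_numpy(), ddof=1))


@dataclass
class AmeliorationResult:
    deltas: pd.DataFrame
    fit_AL: tuple[float, float]
    fit_DR: tuple[float, float]
    r_AL: float
    r_DR: float
    sigma: float
    cutoff: float
    ameliorated: pd.DataFrame
    permutations: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> dict:
        amel = self.ameliorated
        return {
            "n_bins": int(len(self.deltas)),
            "slope_AL": self.fit_AL[0],
            "intercept_AL": self.fit_AL[1],
            "slope_DR": self.fit_DR[0],
            "intercept_DR": self.fit_DR[1],
            "r_AL": self.r_AL,
            "r_DR": self.r_DR,
            "sigma": self.sigma,
            "cutoff": self.cutoff,
            "n_ameliorated": int(len(amel)),
            "n_ameliorated_hyper": int((amel["direction"] == "hyper").sum()) if len(amel) else 0,
            "n_ameliorated_hypo": int((amel["direction"] == "hypo").sum()) if len(amel) else 0,
            "permutation_envelopes": {
                scheme: {
                    col: [float(np.quantile(df[col], 0.025)), float(np.quantile(df[col], 0.975))]
                    for col in df.columns
                }
                for scheme, df in self.permutations.items()
            },
        }


def analyze(
    bins: pd.DataFrame,
    age_dmrs: pd.DataFrame,
    sigma_scope: str = "all_bins",
    n_sigma: float = 2.0,
    n_perm: int = 0,
    seed: int = 0,
) -> AmeliorationResult:
    """Full amelioration analysis on quantified bins plus an age-DMR set.

    ``sigma_scope`` selects whether sigma is estimated from the AL-fit
    residuals of all bins (default; genome-wide "natural scattering") or of
    the age-related DMRs only.
    """
    deltas = compute_deltas(bins)
    sa, ia, ra = fit_scatter(deltas["d_age_AL"], deltas["d_diet_old"])
    sd, idr, rd = fit_scatter(deltas["d_age_DR"], deltas["d_diet_old"])
    if sigma_scope == "all_bins":
        sigma = residual_sigma(deltas, (sa, ia))
    elif sigma_scope == "dmrs":
        sub = deltas[deltas["bin_id"].isin(set(age_dmrs["bin_id"]))]
        sigma = residual_sigma(sub, (sa, ia))
    else:
        raise ValueError(f"unknown sigma_scope {sigma_scope!r}")
    ameliorated = classify_ameliorated(age_dmrs, deltas, (sd, idr), sigma, n_sigma)
    perms = {}
    if n_perm > 0:
        for k, scheme in enumerate(PERMUTATION_SCHEMES):
            perms[scheme] = permute_null(bins, scheme, n_perm=n_perm, seed=seed + k)
    return AmeliorationResult(
        deltas=deltas,
        fit_AL=(sa, ia),
        fit_DR=(sd, idr),
        r_AL=ra,
        r_DR=rd,
        sigma=sigma,
        cutoff=n_sigma * sigma,
        ameliorated=ameliorated,
        permutations=perms,
    )
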