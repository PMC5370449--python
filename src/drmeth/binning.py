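"""Fixed-CpG-count sliding windows and the pre-binning filters.

Windows contain exactly ``size`` CpGs (default 50) and start every ``step``
retained CpGs (default 25), so consecutive bins share half their CpGs.  Bins
are defined by CpG count rather than genomic width to equalise data content
and statistical power between CpG-dense (island) and CpG-poor regions.

Two quantitations are provided per group:

``mean_of_cpgs``
    unweighted mean of per-CpG methylation percentages over covered CpGs
    (the default; this is the rule used for reported bin levels), and
``pooled``
    100 * sum(meth) / sum(meth + unmeth) over the bin's CpGs (used by the
    count-based chi-squared test downstream).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import CpGTable

log = logging.getLogger("drmeth")


def filter_high_observation_regions(
    table: CpGTable,
    window: int = 25_000,
    stringency: float = 10.0,
) -> CpGTable:
    """Drop CpGs inside windows with outlying total read counts.

    Total observations (meth + unmeth over all samples) are summed in
    non-overlapping ``window``-bp windows (only windows containing data are
    considered); windows whose count exceeds Q3 + stringency * IQR are
    removed, where quartiles use linear interpolation (numpy default,
    type 7).  Emulates a box-whisker outlier filter for PCR/mapping pileups.
    """
    if table.n_cpgs == 0:
        raise ValueError("empty CpG table")
    if not np.isfinite(stringency):
        return table
    pos = table.df.index.get_level_values(1).to_numpy()
    chrom = table.df.index.get_level_values(0).to_numpy()
    win = (pos - 1) // window
    total = np.zeros(table.n_cpgs, dtype=np.int64)
    for s in table.samples:
        m, u = table.counts(s)
        total += m + u
    key = pd.MultiIndex.from_arrays([chrom, win])
    counts = pd.Series(total).groupby(key).sum()
    q1, q3 = np.percentile(counts.to_numpy(), [25, 75])
    threshold = q3 + stringency * (q3 - q1)
    bad = set(counts.index[counts > threshold])
    if not bad:
        return table
    mask = ~pd.MultiIndex.from_arrays([chrom, win]).isin(bad)
    log.info(
        "high-observation filter: removed %d/%d windows (> %.1f), %d CpGs dropped",
        len(bad), len(counts), threshold, int((~mask).sum()),
    )
    return table.subset_rows(mask)


def filter_min_coverage(table: CpGTable, min_obs: int = 3) -> CpGTable:
    """Keep CpGs with >= min_obs observations in *every* sample/group."""
    if min_obs <= 0:
        return table
    mask = np.ones(table.n_cpgs, dtype=bool)
    for s in table.samples:
        m, u = table.counts(s)
        mask &= (m + u) >= min_obs
    return table.subset_rows(mask)


def mean_of_cpg_level(meth: np.ndarray, unmeth: np.ndarray) -> float:
    """Unweighted mean of per-CpG methylation percentages (covered CpGs)."""
    cov = meth + unmeth
    ok = cov > 0
    if not ok.any():
        return np.nan
    return float(np.mean(100.0 * meth[ok] / cov[ok]))


def pooled_level(meth_sum: float, unmeth_sum: float) -> float:
    tot = meth_sum + unmeth_sum
    return float(100.0 * meth_sum / tot) if tot > 0 else np.nan


def make_bins(
    table: CpGTable,
    size: int = 50,
    step: int = 25,
    quantitation: str = "mean_of_cpgs",
) -> pd.DataFrame:
    """Build sliding 50-CpG bins from a (group-merged, filtered) CpGTable.

    Returns a DataFrame with one row per bin: chrom, start, end (0-based
    half-open span covering both strands of the first and last CpG
    dinucleotide), bin_id, cpg_lo (index of the first CpG within the
    chromosome's retained CpGs), n_cpg, and per group ``level_<g>`` plus
    pooled ``meth_<g>`` / ``unmeth_<g>`` counts.

    Bins start at retained-CpG indices 0, step, 2*step, ... per chromosome
    and are emitted only while ``size`` CpGs remain, so the number of bins on
    a chromosome with n >= size CpGs is floor((n - size)/step) + 1.
    """
    if quantitation not in ("mean_of_cpgs", "pooled"):
        raise ValueError(f"unknown quantitation {quantitation!r}")
    groups = table.samples
    rows = []
    for chrom, sub in table.df.groupby(level=0, sort=True):
        n = len(sub)
        if n < size:
            log.warning("chromosome %s has %d < %d retained CpGs; no bins", chrom, n, size)
            continue
        pos = sub.index.get_level_values(1).to_numpy()
        starts = np.arange(0, n - size + 1, step)
        rec = {
            "chrom": chrom,
            "start": pos[starts] - 1,
            "end": pos[starts + size - 1] + 1,
            "cpg_lo": starts,
            "n_cpg": size,
        }
        for g in groups:
            m = sub[(g, "meth")].to_numpy(dtype=np.float64)
            u = sub[(g, "unmeth")].to_numpy(dtype=np.float64)
            cm = np.concatenate([[0.0], np.cumsum(m)])
            cu = np.concatenate([[0.0], np.cumsum(u)])
            msum = cm[starts + size] - cm[starts]
            usum = cu[starts + size] - cu[starts]
            cov = m + u
            covered = cov > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(covered, m / np.where(covered, cov, 1.0), 0.0)
            cf = np.concatenate([[0.0], np.cumsum(frac)])
            cc = np.concatenate([[0.0], np.cumsum(covered.astype(np.float64))])
            ncov = cc[starts + size] - cc[starts]
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_level = np.where(ncov > 0, 100.0 * (cf[starts + size] - cf[starts]) / np.where(ncov > 0, ncov, 1.0), np.nan)
                pool_level = np.where(msum + usum > 0, 100.0 * msum / np.where(msum + usum > 0, msum + usum, 1.0), np.nan)
            rec[f"level_{g}"] = mean_level if quantitation == "mean_of_cpgs" else pool_level
            rec[f"pooled_level_{g}"] = pool_level
            rec[f"meth_{g}"] = msum.astype(np.int64)
            rec[f"unmeth_{g}"] = usum.astype(np.int64)
        rows.append(pd.DataFrame(rec))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "bin_id", "cpg_lo", "n_cpg"])
    bins = pd.concat(rows, ignore_index=True)
    bins["bin_id"] = bins["chrom"].astype(str) + ":" + bins["cpg_lo"].astype(str)
    cols = ["chrom", "start", "end", "bin_id", "cpg_lo", "n_cpg"] + [
        c for c in bins.columns if c not in ("chrom", "start", "end", "bin_id", "cpg_lo", "n_cpg")
    ]
    return bins[cols]


def expected_bin_count(n_cpgs: int, size: int = 50, step: int = 25) -> int:
    """floor((n - size)/step) + 1 for n >= size, else 0."""
    if n_cpgs < size:
        return 0
    return (n_cpgs - size) // step + 1
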