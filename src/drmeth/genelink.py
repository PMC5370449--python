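"""Linking DMRs to genes: whole-gene-body methylation and methylation vs
expression coupling.

The gene body is the full transcript span (TSS to TES, isoforms merged per
gene id); DMRs are matched against that span, so promoter-only DMRs
upstream of the TSS do not contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .dmr import adjust_bh
from .io_formats import CpGTable


def map_bins_to_genes(bins: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """(bin_id, gene) pairs for every bin whose span intersects a gene body.

    A bin overlapping two genes contributes to both.  A gene id appearing on
    more than one chromosome is an error.
    """
    genes = iv.as_intervals(genes)
    per_gene_chroms = genes.groupby("name")["chrom"].nunique()
    multi = per_gene_chroms[per_gene_chroms > 1]
    if len(multi):
        raise ValueError(f"gene ids on multiple chromosomes: {list(multi.index)}")
    pairs = []
    for chrom, gsub in genes.groupby("chrom"):
        bsub = bins[bins["chrom"] == chrom]
        if len(bsub) == 0:
            continue
        starts = bsub["start"].to_numpy()
        ends = bsub["end"].to_numpy()
        ids = bsub["bin_id"].to_numpy()
        # bins are sorted by start and their ends are monotone (fixed CpG count)
        for _, g in gsub.iterrows():
            lo = np.searchsorted(ends, g["start"], side="right")
            hi = np.searchsorted(starts, g["end"], side="left")
            for b in ids[lo:hi]:
                pairs.append((b, g["name"]))
    return pd.DataFrame(pairs, columns=["bin_id", "gene"])


def genebody_quantify(
    gene: pd.Series, table: CpGTable, contrast: tuple[str, str] | None = None
) -> dict:
    """Pooled-count methylation per group over all CpGs in the gene body.

    Returns per-group levels and, if a (group1, group2) contrast is given,
    delta = level(group2) - level(group1) in percentage points.  A gene with
    no covered CpGs yields NaN levels.
    """
    chrom = gene["chrom"]
    try:
        sub = table.df.loc[chrom]
    except KeyError:
        sub = table.df.iloc[0:0].droplevel(0)
    pos0 = sub.index.to_numpy() - 1  # 0-based C position
    inside = (pos0 >= gene["start"]) & (pos0 < gene["end"])
    out: dict = {"n_cpgs": int(inside.sum())}
    for g in table.samples:
        m = sub[(g, "meth")].to_numpy()[inside].sum()
        u = sub[(g, "unmeth")].to_numpy()[inside].sum()
        out[f"level_{g}"] = 100.0 * m / (m + u) if m + u > 0 else np.nan
    if contrast is not None:
        g1, g2 = contrast
        out["delta"] = out[f"level_{g2}"] - out[f"level_{g1}"]
    return out


def whole_gene_body_genes(
    dmrs: pd.DataFrame,
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    table: CpGTable,
    contrast: tuple[str, str],
    min_bins: int = 4,
    alpha: float = 0.05,
    min_delta: float = 2.5,
    exclude_gene_bins_from_background: bool = False,
) -> pd.DataFrame:
    """Genes with consistent differential methylation across their body.

    Per gene with >= min_bins overlapping bins, a one-sided (greater)
    hypergeometric/Fisher test asks whether its bins are enriched for DMR
    bins relative to the genome-wide bin set; p values are BH-corrected
    across tested genes.  Significant genes are then quantified over *all*
    gene-body CpGs and retained iff |gene-wide delta| >= min_delta points.

    Returns a per-tested-gene table; the ``detected`` column marks genes
    passing all three rules.
    """
    genes = iv.as_intervals(genes)
    pairs = map_bins_to_genes(bins, genes)
    dmr_ids = set(dmrs["bin_id"])
    N = len(bins)
    K = len(dmr_ids & set(bins["bin_id"]))
    per_gene = pairs.groupby("gene")["bin_id"].agg(list)
    rows = []
    n_excluded = 0
    for _, gene in genes.iterrows():
        bin_ids = per_gene.get(gene["name"], [])
        nb = len(bin_ids)
        if nb < min_bins:
            n_excluded += 1
            continue
        k = sum(b in dmr_ids for b in bin_ids)
        if exclude_gene_bins_from_background and N > nb:
            # reference population without the gene's own bins
            p = stats.hypergeom.sf(k - 1, N - nb, K - k, nb)
        else:
            # gene bins drawn from the full genome-wide bin set (default)
            p = stats.hypergeom.sf(k - 1, N, K, nb)
        rows.append({"gene": gene["name"], "chrom": gene["chrom"],
                     "start": gene["start"], "end": gene["end"],
                     "n_bins_overlapping": nb, "n_dmrs_overlapping": k, "fisher_p": p})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        out["padj"] = []
        out["genebody_delta"] = []
        out["detected"] = []
        return out
    out["padj"] = adjust_bh(out["fisher_p"].to_numpy())
    deltas = []
    for _, row in out.iterrows():
        if row["padj"] < alpha:
            deltas.append(genebody_quantify(row, table, contrast)["delta"])
        else:
            deltas.append(np.nan)
    out["genebody_delta"] = deltas
    out["detected"] = (out["padj"] < alpha) & (out["genebody_delta"].abs() >= min_delta)
    return out.sort_values("gene", kind="mergesort").reset_index(drop=True)


def quadrant_label(delta: float, log2fc: float) -> str:
    meth = "hyper" if delta > 0 else "hypo"
    expr = "up" if log2fc > 0 else "down"
    return f"{meth}_{expr}"


@dataclass
class CouplingResult:
    genes: pd.DataFrame          # gene, mean_dmr_delta, n_dmrs, log2FC, padj, quadrant
    quadrants: dict[str, int]
    fisher_p: float
    fisher_midp: float
    pearson_r: float
    deg_quadrants: dict[str, int]
    deg_fisher_p: float
    deg_fisher_midp: float
    deg_pearson_r: float

    def summary(self) -> dict:
        return {
            "n_genes": int(len(self.genes)),
            "quadrants": self.quadrants,
            "fisher_p": self.fisher_p,
            "fisher_midp": self.fisher_midp,
            "pearson_r": self.pearson_r,
            "deg_quadrants": self.deg_quadrants,
            "deg_fisher_p": self.deg_fisher_p,
            "deg_fisher_midp": self.deg_fisher_midp,
            "deg_pearson_r": self.deg_pearson_r,
        }


def _quadrant_test(sub: pd.DataFrame) -> tuple[dict, float, float, float]:
    counts = {q: int((sub["quadrant"] == q).sum())
              for q in ("hyper_down", "hyper_up", "hypo_down", "hypo_up")}
    a, b = counts["hyper_down"], counts["hyper_up"]
    c, d = counts["hypo_down"], counts["hypo_up"]
    if len(sub) == 0:
        return counts, np.nan, np.nan, np.nan
    # inverse-relationship direction: hyper goes with down, hypo with up
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    # mid-p companion for calibration diagnostics: the exact p of a discrete
    # test is conservative by construction, the mid-p is ~uniform under null
    n = a + b + c + d
    midp = float(stats.hypergeom.sf(a, n, a + c, a + b)
                 + 0.5 * stats.hypergeom.pmf(a, n, a + c, a + b))
    if len(sub) >= 3 and sub["mean_dmr_delta"].nunique() > 1 and sub["log2FC"].nunique() > 1:
        r = float(stats.pearsonr(sub["mean_dmr_delta"], sub["log2FC"]).statistic)
    else:
        r = np.nan
    return counts, float(p), midp, r


def meth_expr_correlation(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    de_table: pd.DataFrame,
    min_dmrs: int = 2,
    min_delta: float = 10.0,
    deg_alpha: float = 0.05,
) -> CouplingResult:
    """Directional coupling of gene-body DMR methylation with expression.

    Genes overlapped by >= min_dmrs DMRs get the average DMR delta; genes
    with |mean delta| < min_delta are dropped (ambiguous hyper+hypo mixtures
    average out and are excluded).  The quadrant distribution of (delta
    sign, log2FC sign) is tested one-sidedly for the inverse relationship
    (hyper&down with hypo&up), and the Pearson correlation of mean delta vs
    log2FC is reported; both are repeated restricted to significant DEGs
    (padj < deg_alpha).
    """
    pairs = map_bins_to_genes(dmrs, genes)
    if len(pairs) == 0:
        joined = pd.DataFrame(
            columns=["gene", "n_dmrs", "mean_dmr_delta", "log2FC", "padj", "quadrant"]
        )
    else:
        delta_lut = dmrs.set_index("bin_id")["delta"]
        pairs["delta"] = pairs["bin_id"].map(delta_lut)
        agg = pairs.groupby("gene").agg(n_dmrs=("bin_id", "size"), mean_dmr_delta=("delta", "mean"))
        agg = agg[agg["n_dmrs"] >= min_dmrs]
        agg = agg[agg["mean_dmr_delta"].abs() >= min_delta]
        de = de_table.set_index("gene_id")
        joined = agg.join(de[["log2FC", "padj"]], how="inner")
        joined = joined.rename_axis("gene").reset_index()
    joined["quadrant"] = [quadrant_label(d, f) for d, f in zip(joined["mean_dmr_delta"], joined["log2FC"])]
    quad, p, midp, r = _quadrant_test(joined)
    deg = joined[joined["padj"] < deg_alpha]
    dquad, dp, dmidp, dr = _quadrant_test(deg)
    return CouplingResult(joined, quad, p, midp, r, dquad, dp, dmidp, dr)
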