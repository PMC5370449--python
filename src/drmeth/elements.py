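"""Rule-based genomic/epigenetic element classes and DMR enrichment.

Element definitions (all intervals 0-based half-open):

* promoter: strand-aware [TSS - 5000, TSS + 100), clipped to the chromosome;
* CGI classes: promoter > gene > intergenic precedence over raw CGIs;
* active enhancer: H3K4me1 peak overlapping an H3K27ac peak, split into
  geneic (touching a gene or promoter) and distal;
* active promoter chromatin: H3K4me3 peak within 100 bp of an H3K9ac peak,
  not within 100 bp of H3K27me3, overlapping a promoter;
* repressive promoter chromatin: narrow (< 3.5 kbp) H3K27me3 peak not within
  100 bp of H3K27ac/H3K4me3, overlapping a promoter;
* repressive geneic chromatin: as above without the length cap, overlapping
  a gene body; peaks also overlapping a promoter count as promoter marks;
* bivalent CGI: CGI overlapped by >= 1 coChIP (H3K4me3-H3K27me3) peak.

Enrichment of a DMR set over an element uses a one-sided Fisher exact test
of [DMR bins overlapping vs not] against [background bins overlapping vs
not], with obs/exp = (k/n)/(K/N).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .dmr import adjust_bh


def build_promoters(
    genes: pd.DataFrame,
    upstream: int = 5000,
    downstream: int = 100,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter regions around each gene's TSS."""
    if "strand" not in genes.columns or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("gene intervals require explicit +/- strand")
    genes = iv.as_intervals(genes)
    plus = genes["strand"] == "+"
    tss = np.where(plus, genes["start"], genes["end"])
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    out = pd.DataFrame(
        {"chrom": genes["chrom"], "start": np.maximum(start, 0), "end": end,
         "name": genes.get("name", "."), "score": 0, "strand": genes["strand"]}
    )
    if chrom_sizes:
        out["end"] = [
            min(e, chrom_sizes.get(c, e)) for c, e in zip(out["chrom"], out["end"])
        ]
    return iv.as_intervals(out)


def classify_cgis(
    cgis: pd.DataFrame, promoters: pd.DataFrame, genes: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Partition CGIs into promoter / gene / intergenic (promoter wins)."""
    cgis = iv.as_intervals(cgis)
    in_prom = iv.overlaps_any(cgis, promoters)
    in_gene = iv.overlaps_any(cgis, genes)
    return {
        "promoter_cgi": cgis[in_prom].reset_index(drop=True),
        "gene_cgi": cgis[~in_prom & in_gene].reset_index(drop=True),
        "intergenic_cgi": cgis[~in_prom & ~in_gene].reset_index(drop=True),
    }


def build_chromatin_elements(
    peaks: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    promoters: pd.DataFrame,
    cgis: pd.DataFrame,
    proximity: int = 100,
    max_repressive_len: int = 3500,
) -> dict[str, pd.DataFrame]:
    """Apply the chromatin-state rules to peak tracks.

    ``peaks`` must contain H3K4me1, H3K27ac, H3K4me3, H3K9ac, H3K27me3 and
    coChIP interval frames.  Proximity is edge-to-edge.
    """
    required = ["H3K4me1", "H3K27ac", "H3K4me3", "H3K9ac", "H3K27me3", "coChIP"]
    for track in required:
        if track not in peaks:
            raise ValueError(f"missing required peak track {track!r}")
    k4me1, k27ac, k4me3, k9ac, k27me3, cochip = (iv.as_intervals(peaks[t]) for t in required)
    out: dict[str, pd.DataFrame] = {}

    enhancer = iv.intersect(k4me1, k27ac)
    gene_or_prom = pd.concat(
        [genes[["chrom", "start", "end"]], promoters[["chrom", "start", "end"]]],
        ignore_index=True,
    )
    geneic = iv.overlaps_any(enhancer, gene_or_prom)
    out["active_enhancer_geneic"] = enhancer[geneic].reset_index(drop=True)
    out["active_enhancer_distal"] = enhancer[~geneic].reset_index(drop=True)

    near_k9 = iv.overlaps_any(k4me3, iv.pad(k9ac, proximity)) if len(k9ac) else np.zeros(len(k4me3), bool)
    near_k27me3 = iv.overlaps_any(k4me3, iv.pad(k27me3, proximity)) if len(k27me3) else np.zeros(len(k4me3), bool)
    on_prom = iv.overlaps_any(k4me3, promoters)
    out["active_promoter"] = k4me3[near_k9 & ~near_k27me3 & on_prom].reset_index(drop=True)

    active = pd.concat([k27ac[["chrom", "start", "end"]], k4me3[["chrom", "start", "end"]]], ignore_index=True)
    near_active = iv.overlaps_any(k27me3, iv.pad(active, proximity)) if len(active) else np.zeros(len(k27me3), bool)
    peak_len = (k27me3["end"] - k27me3["start"]).to_numpy()
    rep_on_prom = iv.overlaps_any(k27me3, promoters)
    rep_on_gene = iv.overlaps_any(k27me3, genes)
    out["repressive_promoter"] = k27me3[
        (peak_len < max_repressive_len) & ~near_active & rep_on_prom
    ].reset_index(drop=True)
    # promoter-overlap takes precedence over the geneic class
    out["repressive_geneic"] = k27me3[~near_active & rep_on_gene & ~rep_on_prom].reset_index(drop=True)

    cgis = iv.as_intervals(cgis)
    out["bivalent_cgi"] = cgis[iv.overlaps_any(cgis, cochip)].reset_index(drop=True)
    return out


def build_catalog(
    annotations: dict,
    upstream: int = 5000,
    downstream: int = 100,
    proximity: int = 100,
    max_repressive_len: int = 3500,
) -> dict[str, pd.DataFrame]:
    """Full element catalog from an annotation bundle (genes, cgis, repeats,
    peaks, chrom_sizes)."""
    genes = iv.as_intervals(annotations["genes"])
    promoters = build_promoters(genes, upstream, downstream, annotations.get("chrom_sizes"))
    catalog: dict[str, pd.DataFrame] = {"promoter": promoters, "gene_body": genes}
    catalog.update(classify_cgis(annotations["cgis"], promoters, genes))
    if "repeats" in annotations and len(annotations["repeats"]):
        catalog["repeat"] = iv.as_intervals(annotations["repeats"])
    catalog.update(
        build_chromatin_elements(
            annotations["peaks"], genes, promoters, annotations["cgis"],
            proximity, max_repressive_len,
        )
    )
    return catalog


def enrich(
    dmrs: pd.DataFrame,
    background_bins: pd.DataFrame,
    element: pd.DataFrame,
    name: str = "element",
    alternative: str = "greater",
) -> dict:
    """One-sided Fisher enrichment of a DMR set over one element class.

    Overlap means >= 1 bp intersection of the bin's genomic span with the
    element.  The background is the full bin set (DMRs included).
    """
    n = len(dmrs)
    N = len(background_bins)
    if N == 0:
        raise ValueError("empty background bin set")
    if len(element) == 0:
        return {"element": name, "n_dmr": n, "n_dmr_overlap": 0, "n_background": N,
                "n_background_overlap": 0, "obs_exp": np.nan, "p": np.nan}
    k = int(iv.overlaps_any(dmrs, element).sum()) if n else 0
    K = int(iv.overlaps_any(background_bins, element).sum())
    if K == 0 or n == 0:
        obs_exp = np.nan
        p = np.nan
    else:
        obs_exp = (k / n) / (K / N)
        _, p = stats.fisher_exact([[k, n - k], [K, N - K]], alternative=alternative)
    return {"element": name, "n_dmr": n, "n_dmr_overlap": k, "n_background": N,
            "n_background_overlap": K, "obs_exp": obs_exp, "p": p}


def enrich_all(
    dmrs: pd.DataFrame,
    background_bins: pd.DataFrame,
    catalog: dict[str, pd.DataFrame],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Enrichment over every element class, BH-corrected across the run."""
    rows = [enrich(dmrs, background_bins, el, name, alternative) for name, el in catalog.items()]
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    padj = np.full(len(out), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = adjust_bh(out.loc[ok, "p"].to_numpy())
    out["padj"] = padj
    with np.errstate(divide="ignore"):
        out["neg_log10_padj"] = -np.log10(out["padj"])
    return out
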