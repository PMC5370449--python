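"""End-to-end orchestration of the synthetic analysis.

``run_pipeline`` simulates a methylome and its annotations, applies the
filters and binning, calls DMRs for all four contrasts, runs the
amelioration, enrichment, gene-linkage and lipidomics stages, and writes
every result as deterministic plain-text files (TSV/JSON) into ``outdir``.
Identical (config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import amelioration, binning, dmr, elements, genelink, lipidomics, simdata
from .io_formats import merge_replicates, write_bed, write_coverage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return [float(v) for v in o]
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


def run_pipeline(
    config: simdata.SimConfig | None = None,
    outdir: str | Path = "results",
    n_perm: int = 100,
    min_diff: float = 10.0,
    alpha: float = 0.05,
    wholegene_min_diff: float = 2.5,
    write_inputs: bool = False,
) -> dict:
    """Run every stage on a synthetic dataset; return the summary dict.

    The whole-gene-body stage consumes significant bins called at the
    gene-level difference cutoff (``wholegene_min_diff``); all focal-DMR
    analyses use ``min_diff``.
    """
    config = config or simdata.SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table, truth = simdata.simulate_methylome(config)
    ann = simdata.simulate_annotations(config)
    truth.to_json(outdir / "ground_truth.json")
    if write_inputs:
        write_coverage(table, outdir / "coverage")
        write_bed(ann["genes"], outdir / "genes.bed")
        write_bed(ann["cgis"], outdir / "cgis.bed")

    table = binning.filter_high_observation_regions(table)
    groups = merge_replicates(table)
    groups = binning.filter_min_coverage(groups, min_obs=3)
    bins = binning.make_bins(groups)
    _write_tsv(bins, outdir / "bins.tsv")

    dmr_sets = {}
    for contrast in dmr.CONTRASTS:
        dmrs = dmr.call_dmrs(bins, contrast, min_diff=min_diff, alpha=alpha)
        dmr_sets[contrast] = dmrs
        _write_tsv(dmrs, outdir / f"dmrs_{contrast}.tsv")

    amel = amelioration.analyze(
        bins, dmr_sets["age_AL"], n_perm=n_perm, seed=config.seed + 1
    )
    _write_tsv(amel.deltas, outdir / "bin_deltas.tsv")
    _write_tsv(amel.ameliorated, outdir / "ameliorated_dmrs.tsv")
    _write_json(amel.summary(), outdir / "amelioration.json")

    catalog = elements.build_catalog(ann)
    enrichment = elements.enrich_all(dmr_sets["age_AL"], bins, catalog)
    _write_tsv(enrichment, outdir / "enrichment_age_AL.tsv")

    wg_dmrs = dmr.call_dmrs(bins, "diet_old", min_diff=wholegene_min_diff, alpha=alpha)
    wholegene = genelink.whole_gene_body_genes(
        wg_dmrs, bins, ann["genes"], groups, dmr.CONTRASTS["diet_old"]
    )
    _write_tsv(wholegene, outdir / "wholegene_diet_old.tsv")

    de_table = simdata.simulate_expression(truth, noise_sd=0.3, seed=config.seed + 2)
    coupling = genelink.meth_expr_correlation(dmr_sets["diet_old"], ann["genes"], de_table)
    _write_tsv(coupling.genes, outdir / "meth_expr_genes.tsv")
    _write_json(coupling.summary(), outdir / "meth_expr.json")

    tg, sheet = simdata.simulate_tg_table(
        n_samples_per_group=4, shift=1.0, seed=config.seed + 3
    )
    rel = lipidomics.normalize_tg(tg)
    group_map = dict(zip(sheet["sample"], sheet["group"]))
    carbon = lipidomics.aggregate_by(rel, "carbons")
    db = lipidomics.aggregate_by(rel, "double_bonds")
    _write_tsv(carbon.reset_index(), outdir / "tg_by_carbons.tsv")
    _write_tsv(db.reset_index(), outdir / "tg_by_double_bonds.tsv")
    cat_tests = lipidomics.per_category_test(carbon, group_map)
    _write_tsv(cat_tests, outdir / "tg_carbon_tests.tsv")
    tails = lipidomics.interval_test(
        carbon, group_map, ("AL_old", "DR_old"), lipidomics.CARBON_INTERVALS
    )
    _write_tsv(tails, outdir / "tg_carbon_intervals.tsv")
    totals = simdata.simulate_tg_totals(
        n_per_group={"AL_young": 4, "DR_young": 4, "AL_old": 3, "DR_old": 3},
        age_effect=5.0, diet_effect=0.0, interaction=15.0, seed=config.seed + 4,
    )
    anova = lipidomics.tg_content_interaction(totals)

    summary = {
        "seed": config.seed,
        "n_cpgs": int(table.n_cpgs),
        "n_bins": int(len(bins)),
        "dmr_counts": {
            c: {
                "total": int(len(d)),
                "hyper": int((d["direction"] == "hyper").sum()),
                "hypo": int((d["direction"] == "hypo").sum()),
            }
            for c, d in dmr_sets.items()
        },
        "amelioration": amel.summary(),
        "n_wholegene_detected": int(wholegene["detected"].sum()) if len(wholegene) else 0,
        "coupling": coupling.summary(),
        "tg_left_tail_p": float(tails.set_index("interval").loc["left", "p"]),
        "tg_interaction_p": float(anova.loc["age:diet", "PR(>F)"]),
    }
    _write_json(summary, outdir / "summary.json")
    return summary
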