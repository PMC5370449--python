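"""Synthetic methylomes, annotations, expression and TG tables with known
ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* CpG positions on a sparse background with dense CGI-like island clusters
  (>= 200 bp of closely spaced CpGs);
* bimodal baseline methylation: low at promoter-island CpGs, high elsewhere,
  with mild region-to-region baseline variation;
* four groups (AL/DR x young/old) with ``n_replicates`` samples each;
  per-CpG, per-sample counts are beta-binomial around the group mean with a
  single overdispersion knob rho (alpha = m(1-rho)/rho);
* planted effect regions in CpG-index space (runs of ``plant_len``
  consecutive CpGs, spanning at least one full 50-CpG bin): age effects
  (applied to both old groups), diet effects (both DR groups), a subset of
  age regions whose DR effect is scaled by ``attenuation_factor``
  (amelioration), diet-effect pairs inside "coupled" genes, and whole-gene
  diet effects of ``wholegene_effect`` across entire gene bodies;
* small per-region biological scatter in diet and age effects on background
  regions (planted regions override it), so the genome-wide residual
  scatter that calibrates the 2-sigma amelioration cutoff is biological
  rather than pure counting noise, as in real methylomes;
* a differential-expression table whose log2FC anticorrelates with the
  planted gene-level methylation effects;
* TG species tables (even carbons 38-60 x double bonds 0-12) with a planted
  chain-length shift toward shorter chains under DR.

Identical (seed, config) pairs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GROUPS, CpGTable

PLANT_TYPES = (
    "age_hyper", "age_hypo", "diet_hyper", "diet_hypo",
    "ameliorated_hyper", "ameliorated_hypo", "wholegene",
)


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: four groups (AL/DR x young/old) with
    three replicates each, ~30x mean coverage, planted effect sizes drawn
    uniformly from 10-35 percentage points.
    """

    n_chroms: int = 4
    chrom_len: int = 25_000_000
    n_cpgs_per_chrom: int = 20_000
    island_fraction: float = 0.15
    n_replicates: int = 3
    depth_mean: float = 30.0
    dispersion: float = 0.05
    baseline_high: float = 0.85
    baseline_low: float = 0.08
    n_age_dmr: int = 100
    n_diet_dmr: int = 60
    amelioration_fraction: float = 0.5
    attenuation_factor: float = 0.1
    effect_range: tuple = (0.10, 0.35)
    n_genes_per_chrom: int = 25
    n_coupled_genes: int = 50
    n_wholegene_genes: int = 10
    wholegene_effect: float = 0.05
    bio_scatter_sd: float = 3.5  # percentage points, per background region
    plant_len: int = 75
    seed: int = 0

    def validate(self) -> None:
        for name in ("island_fraction", "dispersion", "baseline_high", "baseline_low",
                     "amelioration_fraction", "attenuation_factor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.dispersion >= 1:
            raise SimConfigError("dispersion must be < 1")
        lo, hi = self.effect_range
        if not (0 < lo <= hi < 1):
            raise SimConfigError(f"effect_range {self.effect_range} outside (0, 1)")
        for name in ("n_chroms", "chrom_len", "n_cpgs_per_chrom", "n_replicates",
                     "n_genes_per_chrom", "plant_len"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in ("n_age_dmr", "n_diet_dmr", "n_coupled_genes", "n_wholegene_genes"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.plant_len < 60:
            raise SimConfigError("plant_len must be >= 60 (one full bin guaranteed)")
        n_genes = self.n_chroms * self.n_genes_per_chrom
        if self.n_coupled_genes + self.n_wholegene_genes > n_genes:
            raise SimConfigError("more coupled+wholegene genes than genes")
        # rough capacity check in CpG-index space
        per_chrom = (
            self.n_genes_per_chrom * 300
            + ((self.n_age_dmr + self.n_diet_dmr) // self.n_chroms + 1) * (self.plant_len + 120)
        )
        if per_chrom > self.n_cpgs_per_chrom:
            raise SimConfigError(
                f"chromosomes too small for requested features "
                f"(~{per_chrom} CpGs needed, {self.n_cpgs_per_chrom} available)"
            )
        n_island_cpgs = int(self.island_fraction * self.n_cpgs_per_chrom * self.n_chroms)
        if self.island_fraction > 0 and n_island_cpgs < 40:
            raise SimConfigError("island_fraction x n_cpgs too small for one island")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    planted_regions: pd.DataFrame  # chrom, start, end, cpg_lo, cpg_hi, effect_type, effect_size
    gene_assignments: dict = field(default_factory=dict)  # gene -> coupled|wholegene
    gene_effects: dict = field(default_factory=dict)      # gene -> signed effect (pp)
    genes: list = field(default_factory=list)
    tg_shift: float | None = None
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "planted_regions": self.planted_regions.to_dict(orient="records"),
            "gene_assignments": self.gene_assignments,
            "gene_effects": self.gene_effects,
            "genes": self.genes,
            "tg_shift": self.tg_shift,
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# layout: deterministic feature placement in CpG-index space
# ---------------------------------------------------------------------------

_G = {g: i for i, g in enumerate(GROUPS)}  # AL_young, AL_old, DR_young, DR_old


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _layout(config: SimConfig) -> dict:
    """Place genes, islands and planted regions; return per-chrom structures.

    Everything is derived from the first spawned random stream so that
    simulate_methylome and simulate_annotations agree on coordinates.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(streams[0])
    sd = config.bio_scatter_sd / 100.0
    e_lo, e_hi = config.effect_range
    L = config.plant_len

    # global role lists, distributed round-robin over chromosomes
    n_genes = config.n_chroms * config.n_genes_per_chrom
    roles = (["coupled"] * config.n_coupled_genes
             + ["wholegene"] * config.n_wholegene_genes
             + ["plain"] * (n_genes - config.n_coupled_genes - config.n_wholegene_genes))
    rng.shuffle(roles)

    def signed_effects(n):
        signs = np.array([1] * (n // 2) + [-1] * (n - n // 2))
        rng.shuffle(signs)
        return signs * rng.uniform(e_lo, e_hi, size=n)

    age_effects = signed_effects(config.n_age_dmr)
    n_amel = int(round(config.amelioration_fraction * config.n_age_dmr))
    amel_idx = set(rng.choice(config.n_age_dmr, size=n_amel, replace=False)) if n_amel else set()
    diet_effects = signed_effects(config.n_diet_dmr)

    plant_queue = [("age", e, i in amel_idx) for i, e in enumerate(age_effects)]
    plant_queue += [("diet", e, False) for e in diet_effects]
    rng.shuffle(plant_queue)

    chroms = []
    gene_counter = 0
    truth_rows = []
    gene_assignments: dict[str, str] = {}
    gene_effects: dict[str, float] = {}
    all_genes: list[str] = []

    island_budget = int(config.island_fraction * config.n_cpgs_per_chrom)

    for c in range(config.n_chroms):
        chrom = _chrom_name(c)
        n = config.n_cpgs_per_chrom
        features: list[tuple] = []
        for gi in range(config.n_genes_per_chrom):
            features.append(("gene", roles[gene_counter + gi]))
        for j, spec in enumerate(plant_queue):
            if j % config.n_chroms == c:
                features.append(("plant", spec))
        rng.shuffle(features)

        base = np.full(n, np.nan)
        eff = np.zeros((n, 4))
        island_kind = np.zeros(n, dtype=np.int8)  # 0 none, 1 promoter, 2 genebody, 3 intergenic
        blocks = []  # (kind, lo, hi) for scatter bookkeeping
        genes_rows = []
        islands_used = 0

        i = 0

        def add_gap(lo, hi):
            # split long gaps into ~120-CpG segments so biological scatter
            # and density draws stay region-scale, never chromosome-scale
            while hi > lo:
                seg = min(hi - lo, int(rng.integers(80, 161)))
                if hi - lo - seg < 40:
                    seg = hi - lo
                blocks.append(("gap", lo, lo + seg))
                lo += seg

        for feat in features:
            gap = int(40 + rng.integers(0, 81))
            add_gap(i, i + gap)
            i += gap
            if feat[0] == "gene":
                role = feat[1]
                gene_id = f"g{len(all_genes):04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                has_prom_island = False
                if role == "plain":
                    gl = int(rng.integers(150, 261))
                    g_lo, g_hi = i, i + gl
                    blocks.append(("gene", g_lo, g_hi))
                    # promoter island straddling the TSS for some genes
                    if rng.random() < 0.6 and islands_used + 40 <= island_budget:
                        has_prom_island = True
                        if strand == "+":
                            island_kind[g_lo:g_lo + 40] = 1
                        else:
                            island_kind[g_hi - 40:g_hi] = 1
                        islands_used += 40
                    if gl >= 140 and rng.random() < 0.3 and islands_used + 40 <= island_budget:
                        island_kind[g_lo + 60:g_lo + 100] = 2
                        islands_used += 40
                elif role == "wholegene":
                    gl = int(rng.integers(170, 241))
                    g_lo, g_hi = i, i + gl
                    blocks.append(("plant", g_lo, g_hi))
                    s = 1 if rng.random() < 0.5 else -1
                    e = s * config.wholegene_effect
                    base[g_lo:g_hi] = rng.uniform(0.60, 0.80)
                    eff[g_lo:g_hi, _G["DR_young"]] += e
                    eff[g_lo:g_hi, _G["DR_old"]] += e
                    gene_assignments[gene_id] = "wholegene"
                    gene_effects[gene_id] = 100.0 * e
                    truth_rows.append((chrom, g_lo, g_hi, "wholegene", e))
                else:  # coupled: two diet-effect plants inside the body
                    flank = int(rng.integers(8, 16))
                    mid = int(rng.integers(10, 31))
                    gl = 2 * flank + 2 * L + mid
                    g_lo, g_hi = i, i + gl
                    blocks.append(("plant", g_lo, g_hi))
                    s = 1 if rng.random() < 0.5 else -1
                    base[g_lo:g_hi] = rng.uniform(0.75, 0.92)
                    es = []
                    for p_lo in (g_lo + flank, g_lo + flank + L + mid):
                        e = s * rng.uniform(e_lo, e_hi)
                        es.append(e)
                        base[p_lo:p_lo + L] = (
                            rng.uniform(0.30, 0.55) if s > 0 else rng.uniform(0.70, 0.90)
                        )
                        eff[p_lo:p_lo + L, _G["DR_young"]] += e
                        eff[p_lo:p_lo + L, _G["DR_old"]] += e
                        truth_rows.append(
                            (chrom, p_lo, p_lo + L, "diet_hyper" if s > 0 else "diet_hypo", e)
                        )
                    gene_assignments[gene_id] = "coupled"
                    gene_effects[gene_id] = 100.0 * float(np.mean(es))
                genes_rows.append((gene_id, g_lo, g_hi, strand, role, has_prom_island))
                all_genes.append(gene_id)
                i = g_hi
            else:  # intergenic plant
                kind, e, ameliorated = feat[1]
                p_lo, p_hi = i, i + L
                blocks.append(("plant", p_lo, p_hi))
                base[p_lo:p_hi] = rng.uniform(0.30, 0.55) if e > 0 else rng.uniform(0.70, 0.90)
                if kind == "age":
                    eff[p_lo:p_hi, _G["AL_old"]] += e
                    dr_e = e * (config.attenuation_factor if ameliorated else 1.0)
                    eff[p_lo:p_hi, _G["DR_old"]] += dr_e
                    if ameliorated:
                        t = "ameliorated_hyper" if e > 0 else "ameliorated_hypo"
                    else:
                        t = "age_hyper" if e > 0 else "age_hypo"
                else:
                    eff[p_lo:p_hi, _G["DR_young"]] += e
                    eff[p_lo:p_hi, _G["DR_old"]] += e
                    t = "diet_hyper" if e > 0 else "diet_hypo"
                truth_rows.append((chrom, p_lo, p_hi, t, float(e)))
                i = p_hi
            if i > n:
                raise SimConfigError(
                    f"{chrom}: features need > {n} CpGs; increase n_cpgs_per_chrom"
                )
        add_gap(i, n)

        # intergenic islands to fill the island budget
        gap_blocks = [b for b in blocks if b[0] == "gap" and b[2] - b[1] >= 60]
        rng.shuffle(gap_blocks)
        for _, lo, hi in gap_blocks:
            if islands_used + 60 > island_budget:
                break
            island_kind[lo + 10:lo + 70] = 3
            islands_used += 60

        # baselines and biological scatter for background blocks
        for kind, lo, hi in blocks:
            if kind == "plant":
                continue
            unset = np.isnan(base[lo:hi])
            base[lo:hi][unset] = rng.uniform(0.75, 0.92)
            if sd > 0:
                diet_s = rng.normal(0.0, sd)
                age_s = rng.normal(0.0, sd)
                eff[lo:hi, _G["DR_young"]] += diet_s
                eff[lo:hi, _G["DR_old"]] += diet_s + age_s
                eff[lo:hi, _G["AL_old"]] += age_s
        base[island_kind == 1] = np.clip(
            rng.normal(config.baseline_low, 0.02, size=int((island_kind == 1).sum())),
            0.01, 0.2,
        )

        # genomic positions: sparse background with block-to-block density
        # variation (real CpG density is heavy-tailed), dense islands
        spacing_mean = max(20.0, 0.85 * config.chrom_len / n - 10.0)
        lam = np.full(n, spacing_mean)
        for _, lo, hi in blocks:
            # lognormal block density (sigma 0.6), rescaled below
            lam[lo:hi] = spacing_mean * np.exp(rng.normal(-0.18, 0.6))
        # keep the total span inside the chromosome regardless of draws
        lam *= (0.85 * config.chrom_len) / lam.sum()
        spacing = 2 + rng.poisson(np.maximum(lam, 5.0))
        in_island = island_kind > 0
        spacing[in_island] = 2 + rng.poisson(8, size=int(in_island.sum()))
        pos = 1000 + np.cumsum(spacing)
        if pos[-1] >= config.chrom_len:
            raise SimConfigError(
                f"{chrom}: CpG positions exceed chrom_len ({pos[-1]} >= {config.chrom_len})"
            )

        means = np.clip(base[:, None] + eff, 0.01, 0.99)
        chroms.append({
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "means": means,
            "island_kind": island_kind,
            "genes": genes_rows,
            "blocks": blocks,
        })
        gene_counter += config.n_genes_per_chrom

    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "cpg_lo", "cpg_hi", "effect_type", "effect_size"]
    )
    return {
        "chroms": chroms,
        "truth_rows": truth,
        "gene_assignments": gene_assignments,
        "gene_effects": gene_effects,
        "genes": all_genes,
        "seeds": streams,
    }


def _truth_with_bp(layout: dict) -> pd.DataFrame:
    """Attach bp coordinates to the planted-region table."""
    rows = []
    pos_by_chrom = {c["chrom"]: c["pos"] for c in layout["chroms"]}
    for _, r in layout["truth_rows"].iterrows():
        pos = pos_by_chrom[r["chrom"]]
        rows.append({
            "chrom": r["chrom"],
            "start": int(pos[r["cpg_lo"]] - 1),
            "end": int(pos[r["cpg_hi"] - 1] + 1),
            "cpg_lo": int(r["cpg_lo"]),
            "cpg_hi": int(r["cpg_hi"]),
            "effect_type": r["effect_type"],
            "effect_size": float(r["effect_size"]),
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cpg_lo", "cpg_hi",
                                       "effect_type", "effect_size"])


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def simulate_methylome(config: SimConfig) -> tuple[CpGTable, GroundTruth]:
    """Simulate per-CpG, per-sample beta-binomial counts plus ground truth."""
    layout = _layout(config)
    rng = np.random.default_rng(layout["seeds"][1])
    rho = config.dispersion
    samples = [f"{g}_r{k + 1}" for g in GROUPS for k in range(config.n_replicates)]
    sample_groups = {s: s.rsplit("_r", 1)[0] for s in samples}

    frames = []
    for ch in layout["chroms"]:
        n = len(ch["pos"])
        data = {}
        for g in GROUPS:
            m = np.clip(ch["means"][:, _G[g]], 1e-6, 1 - 1e-6)
            for k in range(config.n_replicates):
                s = f"{g}_r{k + 1}"
                depth = rng.poisson(config.depth_mean, size=n)
                if rho > 0:
                    a = m * (1 - rho) / rho
                    b = (1 - m) * (1 - rho) / rho
                    p = rng.beta(a, b)
                else:
                    p = m
                meth = rng.binomial(depth, p)
                data[(s, "meth")] = meth
                data[(s, "unmeth")] = depth - meth
        df = pd.DataFrame(data, index=pd.MultiIndex.from_arrays(
            [np.repeat(ch["chrom"], n), ch["pos"]], names=["chrom", "pos"]))
        frames.append(df)
    df = pd.concat(frames)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    table = CpGTable(df, sample_groups)
    truth = GroundTruth(
        planted_regions=_truth_with_bp(layout),
        gene_assignments=layout["gene_assignments"],
        gene_effects=layout["gene_effects"],
        genes=layout["genes"],
        seed=config.seed,
    )
    return table, truth


def simulate_annotations(config: SimConfig) -> dict:
    """Gene models, CGIs, repeats and histone/coChIP peak tracks.

    Coordinates are consistent with :func:`simulate_methylome` for the same
    config (both derive from the same placement stream).
    """
    layout = _layout(config)
    rng = np.random.default_rng(layout["seeds"][2])

    gene_rows, cgi_rows, repeat_rows = [], [], []
    peaks: dict[str, list] = {t: [] for t in
                              ("H3K4me1", "H3K27ac", "H3K4me3", "H3K9ac", "H3K27me3", "coChIP")}
    chrom_sizes = {}

    for ch in layout["chroms"]:
        chrom, pos = ch["chrom"], ch["pos"]
        chrom_sizes[chrom] = config.chrom_len

        for gene_id, g_lo, g_hi, strand, _role, has_prom_island in ch["genes"]:
            # a promoter island straddles the TSS: the first 10 island CpGs
            # lie upstream of the transcript span
            if has_prom_island and strand == "+":
                start, end = int(pos[g_lo + 10] - 1), int(pos[g_hi - 1] + 201)
            elif has_prom_island:
                start, end = int(pos[g_lo] - 201), int(pos[g_hi - 11] + 1)
            else:
                start, end = int(pos[g_lo] - 201), int(pos[g_hi - 1] + 201)
            gene_rows.append((chrom, max(start, 0), end, gene_id, 0, strand))
            tss = start if strand == "+" else end
            # active promoter chromatin at some promoters
            u = rng.random()
            if u < 0.5:
                peaks["H3K4me3"].append((chrom, max(tss - 300, 0), tss + 300))
                peaks["H3K9ac"].append((chrom, max(tss - 350, 0), tss + 250))
                if rng.random() < 0.2:
                    peaks["H3K27me3"].append((chrom, max(tss - 200, 0), tss + 400))
            elif u < 0.65:
                width = int(rng.integers(1200, 3000))
                peaks["H3K27me3"].append((chrom, max(tss - width // 2, 0), tss + width // 2))
            elif u < 0.70:
                width = int(rng.integers(4000, 6000))
                peaks["H3K27me3"].append((chrom, max(tss - width // 2, 0), tss + width // 2))
            if rng.random() < 0.2:
                mid = (start + end) // 2
                peaks["H3K27me3"].append((chrom, mid - 1000, mid + 1000))
            if rng.random() < 0.15:
                mid = (start + end) // 2
                peaks["H3K4me1"].append((chrom, mid - 400, mid + 400))
                peaks["H3K27ac"].append((chrom, mid - 200, mid + 600))

        # islands -> CGIs
        kind = ch["island_kind"]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], (kind > 0).astype(int), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            cgi_rows.append((chrom, int(pos[lo] - 1), int(pos[hi - 1] + 1),
                             f"cgi_{chrom}_{lo}", 0, "."))
            if rng.random() < 0.2:
                peaks["coChIP"].append((chrom, int(pos[lo] - 101), int(pos[hi - 1] + 101)))

        # distal enhancers and repeats in intergenic space
        for b_kind, lo, hi in ch["blocks"]:
            if b_kind != "gap" or hi - lo < 20:
                continue
            mid = int(pos[(lo + hi) // 2])
            if rng.random() < 0.3:
                peaks["H3K4me1"].append((chrom, mid - 400, mid + 400))
                peaks["H3K27ac"].append((chrom, mid - 200, mid + 600))
            if rng.random() < 0.25:
                width = int(rng.integers(500, 5000))
                repeat_rows.append((chrom, mid, mid + width, "repeat", 0, "."))

    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = {
        "genes": pd.DataFrame(gene_rows, columns=cols),
        "cgis": pd.DataFrame(cgi_rows, columns=cols),
        "repeats": pd.DataFrame(repeat_rows, columns=cols),
        "peaks": {
            t: pd.DataFrame(rows, columns=["chrom", "start", "end"])
            for t, rows in peaks.items()
        },
        "chrom_sizes": chrom_sizes,
    }
    return out


def simulate_expression(
    truth: GroundTruth,
    noise_sd: float = 0.1,
    seed: int | None = None,
    couple: bool = True,
) -> pd.DataFrame:
    """Differential-expression table (gene_id, log2FC, padj, expressed).

    Genes carrying planted methylation effects receive a log2FC of opposite
    sign (magnitude effect/10 in log2 units) plus Gaussian noise when
    ``couple`` is True; all other genes (and every gene when ``couple`` is
    False) draw log2FC ~ N(0, noise_sd).
    """
    if seed is None:
        seed = truth.seed + 10_007
    rng = np.random.default_rng(seed)
    rows = []
    for gene in truth.genes:
        effect = truth.gene_effects.get(gene, 0.0)
        if couple and effect != 0.0:
            log2fc = -effect / 10.0 + rng.normal(0.0, noise_sd)
            padj = rng.uniform(0.0, 0.049)
        else:
            log2fc = rng.normal(0.0, noise_sd)
            padj = rng.uniform(0.0, 1.0)
        rows.append({"gene_id": gene, "log2FC": float(log2fc), "padj": float(padj),
                     "expressed": True})
    return pd.DataFrame(rows)


def simulate_tg_table(
    n_samples_per_group: int = 4,
    shift: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.2,
    carbon_center: float = 54.0,
    carbon_sd: float = 3.0,
    db_center: float = 3.0,
    db_sd: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TG species abundances with a chain-length shift under DR.

    Species live on the grid even carbons 38-60 x double bonds 0-12.  The
    per-sample abundance profile is a discretised Gaussian over carbons
    (center ``carbon_center``; shifted left by ``2 * shift`` carbons, i.e.
    ``shift`` chain-length categories, in DR samples) times an independent
    Gaussian over double bonds, with multiplicative lognormal noise.

    Returns (species table, sample sheet) where the species table has
    columns carbons, double_bonds plus one column per sample and the sample
    sheet maps sample -> age, diet, group.
    """
    rng = np.random.default_rng(seed)
    carbons = np.array([c for c in range(38, 61, 2)], dtype=float)
    dbs = np.arange(0, 13, dtype=float)
    grid = [(c, d) for c in carbons for d in dbs]
    cols = {"carbons": [g[0] for g in grid], "double_bonds": [g[1] for g in grid]}
    sheet_rows = []
    for group in GROUPS:
        diet, age = group.split("_")
        center = carbon_center - 2.0 * shift if diet == "DR" else carbon_center
        pc = np.exp(-0.5 * ((carbons - center) / carbon_sd) ** 2)
        pd_ = np.exp(-0.5 * ((dbs - db_center) / db_sd) ** 2)
        joint = np.outer(pc / pc.sum(), pd_ / pd_.sum()).ravel()
        for k in range(n_samples_per_group):
            sample = f"{group}_s{k + 1}"
            total = rng.lognormal(np.log(100.0), 0.1)
            noise = rng.lognormal(0.0, noise_sd, size=len(joint))
            cols[sample] = total * joint * noise
            sheet_rows.append({"sample": sample, "age": age, "diet": diet, "group": group})
    return pd.DataFrame(cols), pd.DataFrame(sheet_rows)


def simulate_tg_totals(
    n_per_group: dict[str, int] | int = 4,
    base: float = 30.0,
    age_effect: float = 0.0,
    diet_effect: float = 0.0,
    interaction: float = 0.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample total TG content under an age x diet cell-means model.

    total = base + age_effect*[old] + diet_effect*[DR] + interaction*[old & AL]
    + N(0, noise_sd).  The interaction term models the AL-specific
    age-related TG accumulation.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in GROUPS}
    rows = []
    for g in GROUPS:
        diet, age = g.split("_")
        mu = base
        if age == "old":
            mu += age_effect
        if diet == "DR":
            mu += diet_effect
        if age == "old" and diet == "AL":
            mu += interaction
        for k in range(n_per_group[g]):
            rows.append({"sample": f"{g}_s{k + 1}", "age": age, "diet": diet,
                         "total": float(mu + rng.normal(0.0, noise_sd))})
    return pd.DataFrame(rows)
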