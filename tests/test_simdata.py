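import numpy as np
import pandas as pd
import pytest

import drmeth
from drmeth import simdata
from drmeth.io_formats import GROUPS
from drmeth.simdata import SimConfig, SimConfigError

SMALL = dict(n_chroms=1, chrom_len=12_000_000, n_cpgs_per_chrom=8000,
             n_genes_per_chrom=8, n_age_dmr=8, n_diet_dmr=4,
             n_coupled_genes=3, n_wholegene_genes=2)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"island_fraction": 1.5},
        {"dispersion": 1.0},
        {"effect_range": (0.0, 0.35)},
        {"effect_range": (0.4, 0.2)},
        {"n_replicates": 0},
        {"plant_len": 50},
        {"n_coupled_genes": 500},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**{**SMALL, **kwargs}).validate()

    def test_capacity_error_when_chromosome_too_small(self):
        with pytest.raises(SimConfigError, match="too small"):
            SimConfig(**{**SMALL, "n_cpgs_per_chrom": 500}).validate()


class TestDeterminism:
    def test_same_seed_same_methylome(self):
        cfg = SimConfig(**SMALL, seed=5)
        t1, tr1 = simdata.simulate_methylome(cfg)
        t2, tr2 = simdata.simulate_methylome(SimConfig(**SMALL, seed=5))
        assert t1.checksum() == t2.checksum()
        pd.testing.assert_frame_equal(tr1.planted_regions, tr2.planted_regions)

    def test_different_seed_differs(self):
        t1, _ = simdata.simulate_methylome(SimConfig(**SMALL, seed=5))
        t2, _ = simdata.simulate_methylome(SimConfig(**SMALL, seed=6))
        assert t1.checksum() != t2.checksum()

    def test_annotations_deterministic_and_coordinate_consistent(self):
        cfg = SimConfig(**SMALL, seed=7)
        a1 = simdata.simulate_annotations(cfg)
        a2 = simdata.simulate_annotations(cfg)
        pd.testing.assert_frame_equal(a1["genes"], a2["genes"])
        pd.testing.assert_frame_equal(a1["cgis"], a2["cgis"])
        # gene coordinates must bracket the methylome's CpGs for those genes
        table, truth = simdata.simulate_methylome(cfg)
        assert set(a1["genes"]["name"]) == set(truth.genes)


class TestCountModel:
    def test_noise_free_limit_matches_group_means(self):
        """dispersion=0 at very high depth: per-sample methylation fraction
        approaches the group mean (1% tolerance at depth 10,000)."""
        cfg = SimConfig(**SMALL, seed=8, dispersion=0.0, depth_mean=10_000,
                        bio_scatter_sd=0.0, n_replicates=1)
        table, truth = simdata.simulate_methylome(cfg)
        from drmeth.simdata import _layout
        means = _layout(cfg)["chroms"][0]["means"]
        for gi, g in enumerate(GROUPS):
            m, u = table.counts(f"{g}_r1")
            frac = m / (m + u)
            err = np.abs(frac - means[:, gi])
            assert err.mean() < 0.01
            assert np.quantile(err, 0.99) < 0.02

    def test_overdispersion_inflates_replicate_variance(self):
        """Beta-binomial with rho>0 exceeds binomial variance (depth 30)."""
        base = dict(SMALL, n_cpgs_per_chrom=8000, seed=9, depth_mean=30,
                    n_replicates=12, bio_scatter_sd=0.0,
                    n_age_dmr=0, n_diet_dmr=0, n_coupled_genes=0, n_wholegene_genes=0)
        out = {}
        for rho in (0.0, 0.1):
            cfg = SimConfig(**{**base, "dispersion": rho})
            table, _ = simdata.simulate_methylome(cfg)
            samples = [f"AL_young_r{k}" for k in range(1, 13)]
            fracs = []
            for s in samples:
                m, u = table.counts(s)
                cov = m + u
                with np.errstate(invalid="ignore"):
                    fracs.append(np.where(cov > 0, m / np.maximum(cov, 1), np.nan))
            F = np.vstack(fracs)[:, :200]
            out[rho] = np.nanvar(F, axis=0).mean()
        assert out[0.1] > 2 * out[0.0]

    def test_attenuated_regions_have_scaled_dr_age_effect(self):
        cfg = SimConfig(**SMALL, seed=10, attenuation_factor=0.2,
                        amelioration_fraction=1.0)
        from drmeth.simdata import _layout, _G
        lay = _layout(cfg)
        means = lay["chroms"][0]["means"]
        tr = lay["truth_rows"]
        amel = tr[tr["effect_type"].str.startswith("ameliorated")]
        assert len(amel) == cfg.n_age_dmr
        for _, r in amel.iterrows():
            lo = r["cpg_lo"] + 1
            d_al = means[lo, _G["AL_old"]] - means[lo, _G["AL_young"]]
            d_dr = means[lo, _G["DR_old"]] - means[lo, _G["DR_young"]]
            assert d_dr == pytest.approx(0.2 * d_al, abs=1e-12)


class TestGroundTruth:
    def test_planted_regions_inside_chromosomes(self):
        cfg = SimConfig(**SMALL, seed=11)
        _, truth = simdata.simulate_methylome(cfg)
        pr = truth.planted_regions
        assert (pr["start"] >= 0).all()
        assert (pr["end"] <= cfg.chrom_len).all()
        assert (pr["start"] < pr["end"]).all()

    def test_ameliorated_subset_of_age_regions(self):
        cfg = SimConfig(**SMALL, seed=12, amelioration_fraction=0.5)
        _, truth = simdata.simulate_methylome(cfg)
        pr = truth.planted_regions
        n_age_like = pr["effect_type"].str.contains("age|ameliorated").sum()
        n_amel = pr["effect_type"].str.startswith("ameliorated").sum()
        assert n_age_like == cfg.n_age_dmr
        assert n_amel == round(0.5 * cfg.n_age_dmr)

    def test_wholegene_genes_span_at_least_four_bins_of_cpgs(self):
        cfg = SimConfig(**SMALL, seed=13)
        _, truth = simdata.simulate_methylome(cfg)
        wg = truth.planted_regions.query("effect_type == 'wholegene'")
        assert len(wg) == cfg.n_wholegene_genes
        # >= 4 overlapping bins needs >= 50 + 3*25 CpGs
        assert ((wg["cpg_hi"] - wg["cpg_lo"]) >= 125).all()

    def test_ground_truth_round_trips_to_json(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=14)
        _, truth = simdata.simulate_methylome(cfg)
        import json
        path = truth.to_json(tmp_path / "truth.json")
        payload = json.loads(path.read_text())
        assert payload["seed"] == 14
        assert len(payload["planted_regions"]) == len(truth.planted_regions)


class TestExpression:
    def test_zero_noise_signs_oppose_methylation(self):
        cfg = SimConfig(**SMALL, seed=15)
        _, truth = simdata.simulate_methylome(cfg)
        de = simdata.simulate_expression(truth, noise_sd=0.0, seed=1)
        de = de.set_index("gene_id")
        for gene, eff in truth.gene_effects.items():
            assert np.sign(de.loc[gene, "log2FC"]) == -np.sign(eff)

    def test_padj_in_unit_interval(self):
        cfg = SimConfig(**SMALL, seed=16)
        _, truth = simdata.simulate_methylome(cfg)
        de = simdata.simulate_expression(truth, noise_sd=0.2, seed=2)
        assert de["padj"].between(0, 1).all()

    def test_planted_gene_coupling_is_negative(self):
        cfg = SimConfig(seed=17)  # default: 60 planted genes
        _, truth = simdata.simulate_methylome(cfg)
        de = simdata.simulate_expression(truth, noise_sd=0.1, seed=3).set_index("gene_id")
        planted = [g for g in truth.genes if g in truth.gene_effects]
        assert len(planted) >= 50
        eff = np.array([truth.gene_effects[g] for g in planted])
        fc = de.loc[planted, "log2FC"].to_numpy()
        assert np.corrcoef(eff, fc)[0, 1] < -0.9

    def test_decoupled_mode_ignores_effects(self):
        cfg = SimConfig(**SMALL, seed=18)
        _, truth = simdata.simulate_methylome(cfg)
        de = simdata.simulate_expression(truth, noise_sd=0.3, seed=4, couple=False)
        assert de["log2FC"].abs().max() < 2.0  # pure noise scale


class TestTgTables:
    def test_abundances_positive_with_positive_totals(self):
        tg, sheet = simdata.simulate_tg_table(4, shift=1.0, seed=19)
        samples = list(sheet["sample"])
        assert (tg[samples].to_numpy() > 0).all()
        assert (tg[samples].sum(axis=0) > 0).all()

    def test_species_grid_is_even_carbons_38_60(self):
        tg, _ = simdata.simulate_tg_table(2, shift=0.0, seed=20)
        assert sorted(tg["carbons"].unique()) == list(range(38, 61, 2))
        assert sorted(tg["double_bonds"].unique()) == list(range(0, 13))

    def test_zero_shift_gives_equal_mean_profiles(self):
        from drmeth import lipidomics
        tg, sheet = simdata.simulate_tg_table(60, shift=0.0, seed=21, noise_sd=0.1)
        carbon = lipidomics.aggregate_by(lipidomics.normalize_tg(tg), "carbons")
        groups = dict(zip(sheet["sample"], sheet["group"]))
        al = [s for s, g in groups.items() if g == "AL_old"]
        dr = [s for s, g in groups.items() if g == "DR_old"]
        diff = (carbon[dr].mean(axis=1) - carbon[al].mean(axis=1)).abs().max()
        assert diff < 1.0  # percentage points, n=60 per group

    def test_shift_moves_mass_to_shorter_chains(self):
        from drmeth import lipidomics
        tg, sheet = simdata.simulate_tg_table(8, shift=1.0, seed=22)
        carbon = lipidomics.aggregate_by(lipidomics.normalize_tg(tg), "carbons")
        groups = dict(zip(sheet["sample"], sheet["group"]))
        al = [s for s, g in groups.items() if g == "AL_old"]
        dr = [s for s, g in groups.items() if g == "DR_old"]
        left = carbon.loc[38:52]
        assert left[dr].mean(axis=1).sum() > left[al].mean(axis=1).sum()
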