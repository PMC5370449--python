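import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drmeth import elements, intervals as iv


def _frame(rows, strand=False):
    cols = ["chrom", "start", "end"] + (["name", "score", "strand"] if strand else [])
    return pd.DataFrame(rows, columns=cols)


GENES = _frame([("chr1", 10_000, 40_000, "gA", 0, "+"),
                ("chr1", 60_000, 90_000, "gB", 0, "-")], strand=True)


class TestPromoters:
    def test_plus_strand_rule(self):
        p = elements.build_promoters(_frame([("chr1", 10_000, 40_000, "g", 0, "+")], strand=True))
        assert (p["start"].iloc[0], p["end"].iloc[0]) == (5_000, 10_100)

    def test_minus_strand_mirrored(self):
        p = elements.build_promoters(_frame([("chr1", 5_000, 10_000, "g", 0, "-")], strand=True))
        assert (p["start"].iloc[0], p["end"].iloc[0]) == (9_900, 15_000)

    def test_clipped_at_chromosome_start(self):
        p = elements.build_promoters(_frame([("chr1", 100, 5_000, "g", 0, "+")], strand=True))
        assert p["start"].iloc[0] == 0

    def test_missing_strand_is_error(self):
        with pytest.raises(ValueError, match="strand"):
            elements.build_promoters(_frame([("chr1", 0, 10)]))


class TestCgiClasses:
    def test_precedence_promoter_gene_intergenic(self):
        promoters = elements.build_promoters(GENES)
        cgis = _frame([
            ("chr1", 9_000, 11_000),   # spans promoter AND gene body -> promoter
            ("chr1", 20_000, 21_000),  # inside gene only -> gene
            ("chr1", 45_000, 46_000),  # nothing -> intergenic
        ])
        classes = elements.classify_cgis(cgis, promoters, GENES)
        assert len(classes["promoter_cgi"]) == 1
        assert classes["promoter_cgi"]["start"].iloc[0] == 9_000
        assert classes["gene_cgi"]["start"].iloc[0] == 20_000
        assert classes["intergenic_cgi"]["start"].iloc[0] == 45_000

    def test_classes_partition_input(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 100_000, size=40)
        cgis = _frame([("chr1", s, s + 500) for s in starts])
        promoters = elements.build_promoters(GENES)
        classes = elements.classify_cgis(cgis, promoters, GENES)
        assert sum(len(c) for c in classes.values()) == len(cgis)


class TestChromatinRules:
    def _peaks(self, **over):
        base = {t: _frame([]) for t in ("H3K4me1", "H3K27ac", "H3K4me3", "H3K9ac",
                                        "H3K27me3", "coChIP")}
        base.update(over)
        return base

    def test_wide_h3k27me3_is_not_repressive_promoter(self):
        promoters = elements.build_promoters(GENES)
        peaks = self._peaks(H3K27me3=_frame([("chr1", 6_000, 10_000)]))  # 4000 bp
        cat = elements.build_chromatin_elements(peaks, GENES, promoters, _frame([]))
        assert len(cat["repressive_promoter"]) == 0
        # overlapping the gene body, it still counts as repressive geneic? no:
        # promoter overlap wins, so the peak is excluded from both classes
        assert len(cat["repressive_geneic"]) == 0

    def test_narrow_promoter_h3k27me3_is_repressive_promoter(self):
        promoters = elements.build_promoters(GENES)
        peaks = self._peaks(H3K27me3=_frame([("chr1", 7_000, 9_000)]))
        cat = elements.build_chromatin_elements(peaks, GENES, promoters, _frame([]))
        assert len(cat["repressive_promoter"]) == 1

    def test_genebody_h3k27me3_without_promoter_is_repressive_geneic(self):
        promoters = elements.build_promoters(GENES)
        peaks = self._peaks(H3K27me3=_frame([("chr1", 20_000, 26_000)]))  # no length cap
        cat = elements.build_chromatin_elements(peaks, GENES, promoters, _frame([]))
        assert len(cat["repressive_geneic"]) == 1
        assert len(cat["repressive_promoter"]) == 0

    def test_enhancer_requires_overlap_and_distal_classification(self):
        promoters = elements.build_promoters(GENES)
        peaks = self._peaks(
            H3K4me1=_frame([("chr1", 45_000, 45_100), ("chr1", 20_000, 20_300)]),
            H3K27ac=_frame([("chr1", 45_050, 45_300), ("chr1", 20_100, 20_400)]),
        )
        cat = elements.build_chromatin_elements(peaks, GENES, promoters, _frame([]))
        assert len(cat["active_enhancer_distal"]) == 1
        assert cat["active_enhancer_distal"]["start"].iloc[0] == 45_050
        assert len(cat["active_enhancer_geneic"]) == 1

    def test_active_promoter_needs_h3k9ac_within_100bp(self):
        promoters = elements.build_promoters(GENES)
        k4 = _frame([("chr1", 9_000, 9_500)])
        near = self._peaks(H3K4me3=k4, H3K9ac=_frame([("chr1", 9_550, 9_700)]))   # 50 bp away
        far = self._peaks(H3K4me3=k4, H3K9ac=_frame([("chr1", 9_650, 9_700)]))    # 150 bp away
        assert len(elements.build_chromatin_elements(near, GENES, promoters, _frame([]))["active_promoter"]) == 1
        assert len(elements.build_chromatin_elements(far, GENES, promoters, _frame([]))["active_promoter"]) == 0

    def test_nearby_h3k27me3_vetoes_active_promoter(self):
        promoters = elements.build_promoters(GENES)
        peaks = self._peaks(
            H3K4me3=_frame([("chr1", 9_000, 9_500)]),
            H3K9ac=_frame([("chr1", 9_000, 9_500)]),
            H3K27me3=_frame([("chr1", 9_520, 9_800)]),
        )
        cat = elements.build_chromatin_elements(peaks, GENES, promoters, _frame([]))
        assert len(cat["active_promoter"]) == 0

    def test_bivalent_cgi_is_cgi_overlapped_by_cochip(self):
        promoters = elements.build_promoters(GENES)
        cgis = _frame([("chr1", 9_000, 10_000), ("chr1", 50_000, 51_000)])
        peaks = self._peaks(coChIP=_frame([("chr1", 9_500, 9_600)]))
        cat = elements.build_chromatin_elements(peaks, GENES, promoters, cgis)
        assert len(cat["bivalent_cgi"]) == 1
        assert cat["bivalent_cgi"]["start"].iloc[0] == 9_000

    def test_missing_track_is_error_naming_track(self):
        with pytest.raises(ValueError, match="coChIP"):
            peaks = {t: _frame([]) for t in ("H3K4me1", "H3K27ac", "H3K4me3", "H3K9ac", "H3K27me3")}
            elements.build_chromatin_elements(peaks, GENES, elements.build_promoters(GENES), _frame([]))

    def test_construction_is_order_independent(self):
        promoters = elements.build_promoters(GENES)
        rng = np.random.default_rng(1)
        k27 = _frame([("chr1", int(s), int(s) + 2000) for s in rng.integers(0, 80_000, 10)])
        peaks_a = self._peaks(H3K27me3=k27)
        peaks_b = self._peaks(H3K27me3=k27.sample(frac=1, random_state=2).reset_index(drop=True))
        a = elements.build_chromatin_elements(peaks_a, GENES, promoters, _frame([]))
        b = elements.build_chromatin_elements(peaks_b, GENES, promoters, _frame([]))
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])


def _fake_bins(n, width=500, gap=1000):
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * gap,
        "end": np.arange(n) * gap + width,
        "bin_id": [f"chr1:{i}" for i in range(n)],
    })


class TestEnrichment:
    def test_obs_exp_ratio_example(self):
        # 4/10 DMRs vs 100/1000 background bins -> obs/exp 4.0
        bins = _fake_bins(1000)
        element = bins.iloc[:100][["chrom", "start", "end"]]
        dmrs = pd.concat([bins.iloc[:4], bins.iloc[200:206]], ignore_index=True)
        row = elements.enrich(dmrs, bins, element)
        assert row["obs_exp"] == pytest.approx(4.0)
        assert row["n_dmr_overlap"] == 4 and row["n_background_overlap"] == 100

    def test_fisher_matches_hypergeometric_tail(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            N = int(rng.integers(20, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, 12))
            bins = _fake_bins(N)
            element = bins.iloc[:K][["chrom", "start", "end"]]
            dmr_idx = rng.choice(N, size=n, replace=False)
            row = elements.enrich(bins.iloc[dmr_idx], bins, element)
            k = row["n_dmr_overlap"]
            # the table is [[k, n-k], [K, N-K]]: population n+N with k+K
            # overlapping members, n drawn into the DMR row
            oracle = stats.hypergeom.sf(k - 1, n + N, k + K, n)
            assert row["p"] == pytest.approx(oracle, rel=1e-9)

    def test_empty_element_reports_na(self):
        bins = _fake_bins(10)
        row = elements.enrich(bins.iloc[:2], bins, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert np.isnan(row["obs_exp"])

    def test_depletion_detectable_with_flipped_sidedness(self):
        bins = _fake_bins(1000)
        element = bins.iloc[:500][["chrom", "start", "end"]]
        dmrs = bins.iloc[900:950]  # avoids the element entirely
        greater = elements.enrich(dmrs, bins, element, alternative="greater")
        less = elements.enrich(dmrs, bins, element, alternative="less")
        assert less["p"] < 1e-10 and greater["p"] > 0.99

    def test_enrich_all_applies_bh_across_elements(self):
        bins = _fake_bins(200)
        catalog = {
            "a": bins.iloc[:50][["chrom", "start", "end"]],
            "b": bins.iloc[50:100][["chrom", "start", "end"]],
        }
        dmrs = bins.iloc[:20]
        out = elements.enrich_all(dmrs, bins, catalog)
        assert set(out["element"]) == {"a", "b"}
        assert (out["padj"] >= out["p"] - 1e-12).all()
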