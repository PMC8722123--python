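"""DAR calling, uDAG derivation, DAR-DMR overlap comparison."""

import numpy as np
import pytest
from scipy import stats

from acetylseq import (CoverageTrack, DMRRecord, GenomeLayout, GenomicInterval,
                       build_count_matrix, call_dars, dar_dmr_overlap_comparison,
                       identify_udags)
from acetylseq.differential import dar_genes, methylation_fold_change_comparison

from conftest import make_gene


def const_track(length, value, chrom="chr1"):
    return CoverageTrack.from_binned({chrom: np.full(length // 100, float(value))}, 100)


def region(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestCountMatrix:
    def test_constant_track_region_sum(self):
        m, libs = build_count_matrix([region(0, 100)],
                                     {"s1": const_track(10_000, 2.0)})
        assert m.loc["chr1:0-100", "s1"] == pytest.approx(200.0)
        assert libs["s1"] == pytest.approx(20_000.0)

    def test_empty_region_list(self):
        m, _ = build_count_matrix([], {"s1": const_track(1000, 1.0)})
        assert m.empty

    def test_missing_chromosome_counts_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m, _ = build_count_matrix([region(0, 100, "chrX")],
                                      {"s1": const_track(1000, 1.0)})
        assert m.iloc[0, 0] == 0.0 and "chrX" in caplog.text

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            build_count_matrix([region(0, 100), region(50, 150)],
                               {"s1": const_track(1000, 1.0)})


def two_group_setup(wt_value, mut_value, n_regions=40, seg=slice(0, 1)):
    """Equal-library tracks; selected regions differ between groups."""
    length = n_regions * 1000
    wt_vals = np.full(length // 100, 1.0)
    mut_vals = np.full(length // 100, 1.0)
    regions = [region(i * 1000 + 200, i * 1000 + 400) for i in range(n_regions)]
    for i in list(range(n_regions))[seg]:
        wt_vals[(i * 1000 + 200) // 100:(i * 1000 + 400) // 100] = wt_value
        mut_vals[(i * 1000 + 200) // 100:(i * 1000 + 400) // 100] = mut_value
    tracks = {"wt_1": CoverageTrack.from_binned({"chr1": wt_vals}, 100),
              "mut_1": CoverageTrack.from_binned({"chr1": mut_vals}, 100)}
    matrix, libs = build_count_matrix(regions, tracks)
    groups = {"wt_1": "wt", "mut_1": "mut"}
    return matrix, libs, groups, regions


class TestCallDars:
    def test_identical_groups_give_no_dars(self):
        matrix, libs, groups, regions = two_group_setup(1.0, 1.0)
        assert call_dars(matrix, libs, groups, regions) == []

    def test_strong_loss_is_a_dar_with_expected_log2fc(self):
        # pooled 200 (wt) vs 20 (mut) in the differential region
        matrix, libs, groups, regions = two_group_setup(1.0, 0.1)
        recs = call_dars(matrix, libs, groups, regions, return_all=True)
        hit = recs[0]
        # counts scale to the mean library size before the fold change
        mean_lib = (libs["wt_1"] + libs["mut_1"]) / 2
        want_fc = np.log2((20 * mean_lib / libs["mut_1"] + 0.5)
                          / (200 * mean_lib / libs["wt_1"] + 0.5))
        assert hit.log2fc == pytest.approx(want_fc, abs=1e-9)  # ~ -3.29
        assert hit.log2fc == pytest.approx(np.log2(20.5 / 200.5), abs=0.01)
        # exact binomial tail oracle
        p_null = libs["mut_1"] / (libs["mut_1"] + libs["wt_1"])
        want_p = stats.binomtest(20, 220, p_null).pvalue
        assert hit.p == pytest.approx(want_p, rel=1e-9)
        dars = call_dars(matrix, libs, groups, regions)
        assert [d.interval.start for d in dars] == [200]

    def test_fold_1p5_never_a_dar(self):
        matrix, libs, groups, regions = two_group_setup(1.0, 1.5)
        recs = call_dars(matrix, libs, groups, regions, return_all=True)
        assert abs(recs[0].log2fc) < 1.0  # |log2FC| gate can never pass
        assert call_dars(matrix, libs, groups, regions) == []

    def test_label_swap_negates_log2fc_preserves_q(self):
        matrix, libs, groups, regions = two_group_setup(1.0, 0.1, seg=slice(0, 3))
        fwd = call_dars(matrix, libs, groups, regions, return_all=True)
        swapped = {s: ("mut" if g == "wt" else "wt") for s, g in groups.items()}
        rev = call_dars(matrix, libs, swapped, regions, return_all=True)
        np.testing.assert_allclose([r.log2fc for r in fwd],
                                   [-r.log2fc for r in rev], atol=1e-12)
        np.testing.assert_allclose([r.q for r in fwd], [r.q for r in rev],
                                   rtol=1e-12)


class TestUdags:
    @pytest.fixture
    def genes(self):
        return [make_gene("dag_clean", start=10_000, end=12_000, strand="+"),
                make_gene("dag_body_dmr", start=20_000, end=22_000, strand="+"),
                make_gene("dag_upstream_dmr", start=30_000, end=32_000, strand="+")]

    def test_dmr_in_body_or_upstream_excludes(self, genes):
        dmrs = [GenomicInterval("chr1", 21_000, 21_200),   # body of second
                GenomicInterval("chr1", 29_300, 29_500)]   # 1-kb upstream of third
        got = identify_udags([g.gene_id for g in genes], genes, dmrs)
        assert got == ["dag_clean"]

    def test_unknown_gene_rejected(self, genes):
        with pytest.raises(ValueError, match="unknown gene_id"):
            identify_udags(["nope"], genes, [])

    def test_dar_genes_promoter_counts(self, genes):
        dars = [GenomicInterval("chr1", 9500, 9600)]  # promoter of first
        assert dar_genes(dars, genes) == ["dag_clean"]


class TestDarDmrOverlap:
    def test_total_overlap_extreme_p(self):
        layout = GenomeLayout({"chr1": 10_000_000})
        dars = [region(i * 500_000, i * 500_000 + 200) for i in range(10)]
        dmrs = [region(i * 500_000, i * 500_000 + 200) for i in range(10)]
        got = dar_dmr_overlap_comparison(dars, dmrs, layout, seed=3)
        assert got["observed_percent"] == 100.0
        if got["null_percent"] == 0.0:
            # closed-form hypergeometric extreme for the 10/10 vs 0/10 table
            want = stats.fisher_exact([[10, 0], [0, 10]])[1]
            assert got["fisher_p"] == pytest.approx(want, abs=1e-12)

    def test_empty_dmrs(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        got = dar_dmr_overlap_comparison([region(0, 100)], [], layout, seed=0)
        assert (got["observed_percent"], got["null_percent"]) == (0.0, 0.0)
        assert got["fisher_p"] == 1.0

    def test_empty_dars_rejected(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        with pytest.raises(ValueError):
            dar_dmr_overlap_comparison([], [region(0, 100)], layout, seed=0)


class TestFoldChangeComparison:
    def test_independent_methylation_gives_similar_distributions(self, small_sim):
        import acetylseq as a
        mut = a.generate_mutant_epigenome(small_sim, "met1", plant_dars=False)
        # random regions in the euchromatic arms, independent of methylation
        rng = np.random.default_rng(12)
        regions = []
        for _ in range(40):
            s = int(rng.integers(0, 350_000))
            regions.append(GenomicInterval("chr1", s, s + 500))
        got = methylation_fold_change_comparison(
            regions, small_sim.methylation, mut.methylation, "CHG",
            small_sim.layout, seed=5)
        # CHG is untouched by the CG-erasure mutant: both arms centre on 0
        assert abs(np.median(got["fc_regions"])) < 0.35
        assert got["mannwhitney_p"] > 0.01
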