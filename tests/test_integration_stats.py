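"""Mark x expression statistics: Fisher overlaps, quartiles, rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acetylseq import (GenomeLayout, GenomicInterval, build_marked_gene_table,
                       colocalization_table, compare_marked_expression,
                       expressed_gene_overlap, expression_quartile_groups)
from acetylseq._stats import fisher_exact, mannwhitney_p
from acetylseq.formats_io import ExpressionRecord

from conftest import make_gene


def toy_table(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "fpkm", "acetylation"])
    df["mcg_class"] = "undefined"
    return df.set_index("gene_id")


class TestExpressedOverlap:
    def test_all_marked_and_expressed(self):
        t = toy_table([(f"g{i}", 5.0, "tss_marked") for i in range(10)])
        got = expressed_gene_overlap(t)
        assert got["counts"] == [[10, 0], [0, 0]]
        assert got["fisher_p"] == 1.0
        assert got["pct_expressed_marked"] == 100.0

    def test_counts_and_closed_form_p(self):
        rows = ([("a%d" % i, 2.0, "tss_marked") for i in range(30)]
                + [("b%d" % i, 2.0, "unmarked") for i in range(10)]
                + [("c%d" % i, 0.0, "tss_marked") for i in range(10)]
                + [("d%d" % i, 0.0, "unmarked") for i in range(30)])
        got = expressed_gene_overlap(toy_table(rows))
        assert got["counts"] == [[30, 10], [10, 30]]
        M, K, n = 80, 40, 40
        pmf = lambda k: (math.comb(K, k) * math.comb(M - K, n - k)) / math.comb(M, n)
        want = sum(pmf(k) for k in range(0, 41) if pmf(k) <= pmf(30) * (1 + 1e-7))
        assert got["fisher_p"] == pytest.approx(want, rel=1e-9)

    def test_independent_marks_give_calibrated_p(self):
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fpkm = np.where(rng.random(2000) < 0.5, 0.0, 1.0)
            marked = rng.random(2000) < 0.4
            rows = [(f"g{i}", f, "tss_marked" if m else "unmarked")
                    for i, (f, m) in enumerate(zip(fpkm, marked))]
            ps.append(expressed_gene_overlap(toy_table(rows))["fisher_p"])
        assert 0.25 <= float(np.median(ps)) <= 0.75

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            expressed_gene_overlap(toy_table([]))


class TestQuartiles:
    def test_distinct_values_rank_order(self):
        recs = [ExpressionRecord(f"g{i}", float(i)) for i in range(8)]
        got = expression_quartile_groups(recs)
        assert [got[f"g{i}"] for i in range(8)] == \
               ["Q4", "Q4", "Q3", "Q3", "Q2", "Q2", "Q1", "Q1"]

    def test_remainders_go_to_top_groups(self):
        recs = [ExpressionRecord(f"g{i:02d}", float(10 - i)) for i in range(10)]
        got = expression_quartile_groups(recs)
        sizes = {q: sum(1 for v in got.values() if v == q) for q in ("Q1", "Q2", "Q3", "Q4")}
        assert sizes == {"Q1": 3, "Q2": 3, "Q3": 2, "Q4": 2}

    def test_ties_broken_by_gene_id(self):
        recs = [ExpressionRecord(g, 1.0) for g in ("d", "c", "b", "a")]
        got = expression_quartile_groups(recs)
        assert got == {"a": "Q1", "b": "Q2", "c": "Q3", "d": "Q4"}

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            expression_quartile_groups([ExpressionRecord("a", 1.0)] * 3)


class TestMannWhitney:
    def test_identical_constant_groups_p_one(self):
        assert mannwhitney_p([2.0] * 5, [2.0] * 5) == 1.0

    def test_separated_triples_exact_tenth(self):
        # full enumeration of C(6,3)=20 assignments: 2 extreme -> p = 0.1
        assert mannwhitney_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_p([], [1.0])

    def test_exact_branch_agrees_with_scipy_enumeration(self):
        rng = np.random.default_rng(6)
        for n1, n2 in itertools.product(range(2, 7), range(2, 7)):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)  # continuous: no ties
            want = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue
            assert mannwhitney_p(x, y) == pytest.approx(want, abs=1e-12)

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(7)
        x = np.round(rng.normal(size=300), 1)
        y = np.round(rng.normal(0.3, size=300), 1)
        want = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert mannwhitney_p(x, y) == pytest.approx(want, rel=1e-12)


class TestCompareMarkedExpression:
    def test_group_summaries_and_pairs(self):
        rows = ([(f"a{i}", float(i), "tss_marked") for i in range(1, 6)]
                + [(f"b{i}", float(i + 10), "unmarked") for i in range(1, 6)])
        got = compare_marked_expression(toy_table(rows), "acetylation")
        assert got["groups"]["tss_marked"]["median"] == 3.0
        assert got["groups"]["unmarked"]["median"] == 13.0
        p = got["pairwise_p"][("tss_marked", "unmarked")]
        assert p == pytest.approx(2 / math.comb(10, 5) * 1)

    def test_empty_group_named_in_error(self):
        rows = [(f"a{i}", 1.0, "tss_marked") for i in range(4)]
        with pytest.raises(ValueError, match="unmarked"):
            compare_marked_expression(toy_table(rows), "acetylation",
                                      pairs=[("tss_marked", "unmarked")])


class TestColocalization:
    def test_reference_covering_genome(self):
        layout = GenomeLayout({"chr1": 100_000})
        peaks = [GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(20)]
        refs = {"all": [GenomicInterval("chr1", 0, 100_000)]}
        got = colocalization_table(peaks, refs, layout, seed=1)
        row = got.iloc[0]
        assert row["observed_percent"] == 100.0
        assert row["expected_percent"] == 100.0
        assert row["fisher_p"] == 1.0

    def test_self_reference_on_sparse_genome_extreme(self):
        layout = GenomeLayout({"chr1": 50_000_000})
        peaks = [GenomicInterval("chr1", i * 2_000_000, i * 2_000_000 + 200)
                 for i in range(20)]
        got = colocalization_table(peaks, {"self": peaks}, layout, seed=2)
        row = got.iloc[0]
        assert row["observed_percent"] == 100.0
        if row["expected_percent"] == 0.0:
            want = stats.fisher_exact([[20, 0], [0, 20]])[1]
            assert row["fisher_p"] == pytest.approx(want, abs=1e-12)

    def test_disjoint_reference_zero(self):
        layout = GenomeLayout({"chr1": 100_000})
        peaks = [GenomicInterval("chr1", 0, 100)]
        got = colocalization_table(peaks, {"far": [GenomicInterval("chr1", 50_000, 50_100)]},
                                   layout, seed=0)
        assert got.iloc[0]["observed_percent"] == 0.0

    def test_empty_reference_warns_p_one(self, caplog):
        layout = GenomeLayout({"chr1": 100_000})
        with caplog.at_level("WARNING"):
            got = colocalization_table([GenomicInterval("chr1", 0, 100)],
                                       {"none": []}, layout, seed=0)
        assert got.iloc[0]["fisher_p"] == 1.0 and "none" in caplog.text

    def test_min_overlap_monotone(self):
        layout = GenomeLayout({"chr1": 100_000})
        rng = np.random.default_rng(10)
        peaks = [GenomicInterval("chr1", int(s), int(s) + 300)
                 for s in rng.integers(0, 90_000, 30)]
        refs = {"r": [GenomicInterval("chr1", int(s), int(s) + 150)
                      for s in rng.integers(0, 90_000, 30)]}
        obs = [colocalization_table(peaks, refs, layout, seed=0,
                                    min_overlap_bp=m).iloc[0]["observed_percent"]
               for m in (1, 50, 150)]
        assert obs[0] >= obs[1] >= obs[2]


def test_fisher_invariant_under_simultaneous_row_col_swap():
    rng = np.random.default_rng(11)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_exact([[d, c], [b, a]]), abs=1e-12)


def test_marked_gene_table_columns(small_sim):
    from acetylseq import tss_marked_classification
    labels = tss_marked_classification(small_sim.manifest.peak_intervals(),
                                       small_sim.genes, layout=small_sim.layout)
    table = build_marked_gene_table(
        small_sim.genes, small_sim.expression, labels,
        histone_peaks=small_sim.histone_peaks, dhs=small_sim.dhs,
        tf_peaks=small_sim.tf_peaks, layout=small_sim.layout)
    assert len(table) == len(small_sim.genes)
    assert set(small_sim.histone_peaks) <= set(table.columns)
    assert table["acetylation"].isin(["tss_marked", "nontss_marked", "unmarked"]).all()
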