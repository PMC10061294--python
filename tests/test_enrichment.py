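"""Hypergeometric enrichment, BH correction, contingency comparisons."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mallowsmix import (bh_adjust, compare_labelings, contingency_test,
                        hypergeom_enrichment, read_gmt, write_gmt)
from mallowsmix.datasets import (brca_vs_pam50, kirc_vs_mrna_subtypes,
                                 squamous_vs_integrative_clusters)
from mallowsmix.enrichment import GeneSetCollection


class TestReadGmt:
    def test_two_sets(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg1\tg4\tg5\tg6\tg7\n")
        coll = read_gmt(p)
        assert len(coll) == 2
        assert coll.sets["setA"] == {"g1", "g2", "g3"}

    def test_name_only_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("setA\tdesc\tg1\nonlyname\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(p)

    def test_duplicate_members_deduplicated(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("setA\tdesc\tg1\tg1\tg2\n")
        assert read_gmt(p).sets["setA"] == {"g1", "g2"}

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(sets={"s1": {"a", "b"}, "s2": {"c"}},
                                 provenance="test")
        p = tmp_path / "rt.gmt"
        write_gmt(coll, p)
        assert read_gmt(p).sets == coll.sets


def brute_force_upper_tail(M, K, N, x):
    """P(overlap >= x) by summing hypergeometric pmf terms directly."""
    total = 0
    for j in range(x, min(K, N) + 1):
        total += math.comb(K, j) * math.comb(M - K, N - j)
    return total / math.comb(M, N)


class TestHypergeomEnrichment:
    def test_worked_example(self):
        background = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection(sets={"s": set(background[:4])})
        gene_list = background[:4] + [background[9]]
        row = hypergeom_enrichment(gene_list, coll, background).iloc[0]
        assert row["p_value"] == pytest.approx(6 / 252, rel=1e-12)
        assert row["fold_enrichment"] == pytest.approx(2.0)

    def test_zero_overlap(self):
        background = [f"g{i}" for i in range(12)]
        coll = GeneSetCollection(sets={"s": set(background[:4])})
        row = hypergeom_enrichment(background[8:], coll, background).iloc[0]
        assert row["p_value"] == 1.0 and row["fold_enrichment"] == 0.0

    def test_list_equal_background_saturates(self):
        background = [f"g{i}" for i in range(8)]
        coll = GeneSetCollection(sets={"a": set(background[:3]),
                                       "b": set(background[2:6])})
        res = hypergeom_enrichment(background, coll, background)
        assert np.allclose(res["p_value"], 1.0)
        assert np.allclose(res["fold_enrichment"], 1.0)
        assert (res["overlap"] == res["effective_set_size"]).all()

    def test_background_bug_is_an_error(self):
        with pytest.raises(ValueError, match="background"):
            hypergeom_enrichment(["x"], GeneSetCollection(sets={"s": {"a"}}),
                                 ["a", "b"])

    def test_sets_intersected_with_background(self):
        background = ["a", "b", "c", "d"]
        coll = GeneSetCollection(sets={"s": {"a", "b", "zz1", "zz2"}})
        row = hypergeom_enrichment(["a", "b"], coll, background).iloc[0]
        assert row["effective_set_size"] == 2
        assert row["p_value"] == pytest.approx(
            brute_force_upper_tail(4, 2, 2, 2), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.data())
    def test_matches_brute_force_enumeration_on_small_backgrounds(self, data):
        M = data.draw(st.integers(4, 20))
        background = [f"g{i}" for i in range(M)]
        K = data.draw(st.integers(1, M))
        N = data.draw(st.integers(1, M))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        members = set(rng.choice(background, size=K, replace=False))
        gene_list = list(rng.choice(background, size=N, replace=False))
        coll = GeneSetCollection(sets={"s": members})
        row = hypergeom_enrichment(gene_list, coll, background).iloc[0]
        x = len(members & set(gene_list))
        assert row["p_value"] == pytest.approx(
            brute_force_upper_tail(M, K, N, x), rel=1e-12)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_invariant_under_input_permutation(self, ps, rnd):
        order = list(range(len(ps)))
        rnd.shuffle(order)
        direct = bh_adjust(ps)
        shuffled = bh_adjust([ps[i] for i in order])
        restored = np.empty(len(ps))
        restored[order] = shuffled
        assert np.allclose(direct, restored)


def textbook_chi2(counts):
    counts = np.asarray(counts, float)
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    return ((counts - expected) ** 2 / expected).sum()


class TestContingency:
    @pytest.mark.parametrize("table_fn", [
        squamous_vs_integrative_clusters, kirc_vs_mrna_subtypes, brca_vs_pam50])
    def test_chi2_matches_textbook_formula(self, table_fn):
        table = table_fn()
        res = contingency_test(table)
        assert res.chi2 == pytest.approx(textbook_chi2(table.to_numpy()),
                                         rel=1e-12)
        assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_percentages_sum_to_hundred(self):
        res = contingency_test(kirc_vs_mrna_subtypes())
        assert res.percentages.to_numpy().sum() == pytest.approx(100, abs=0.3)

    def test_min_expected_drops_sparse_columns(self):
        res = contingency_test(squamous_vs_integrative_clusters(),
                               min_expected=5)
        assert set(res.dropped_categories) == {"iC2", "iC7", "iC13", "iC17"}
        assert res.df == 6
        # percentages still refer to the full printed table
        assert res.percentages.loc["RankCluster 5", "iC10"] == 21.7

    def test_perfect_association(self):
        a = pd.Series(["x"] * 50 + ["y"] * 50,
                      index=[f"s{i}" for i in range(100)])
        b = pd.Series(["u"] * 50 + ["v"] * 50,
                      index=[f"s{i}" for i in range(100)])
        res = compare_labelings(a, b)
        assert res.p_value < 1e-10
        assert np.trace(res.table.to_numpy()[:2, :2]) == 100

    def test_samples_missing_labels_dropped_and_counted(self):
        a = pd.Series({"s1": "x", "s2": "y", "s3": "x", "s4": None})
        b = pd.Series({"s1": "u", "s2": "v", "s3": "u", "s4": "u",
                       "s5": "v"})
        with pytest.raises(ValueError):
            # after dropping s4/s5 only 3 samples remain in a 2x2 -> fine,
            # but a single-category axis must error
            compare_labelings(a[["s1", "s3"]], b)
        res = compare_labelings(a, b)
        assert res.n_dropped == 1
        assert res.table.to_numpy().sum() == 3

    def test_formatted_matches_published_style(self):
        res = contingency_test(kirc_vs_mrna_subtypes())
        assert res.formatted().loc["RankCluster 15", "mRNA1"] == "130 (33.6)"

    def test_fewer_than_two_categories_rejected(self):
        with pytest.raises(ValueError, match="2 categories"):
            contingency_test(pd.DataFrame([[5, 5]]))
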