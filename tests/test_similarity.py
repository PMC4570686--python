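"""Similarity indices: worked examples, bounds, orderings and matrix behavior."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossgwas.similarity as sim
from crossgwas.catalog import TraitProfile
from crossgwas.similarity import (
    INDEX_NAMES,
    chao_estimators,
    chao_index,
    csi_matrix,
    morisita_index,
    pair_index_values,
    similarity_matrix,
    simple_index,
    summarize_overlap,
)
from conftest import random_profile


def make_summary(a1: dict, a2: dict):
    return summarize_overlap(
        TraitProfile("t1", "snp", a1), TraitProfile("t2", "snp", a2)
    )


class TestSummarizeOverlap:
    def test_worked_example(self, chao_profiles):
        s = summarize_overlap(*chao_profiles)
        assert s.k == 2
        assert s.shared_items == (("a", 1, 2), ("b", 2, 1))
        assert (s.f_plus1, s.f_plus2, s.f_1plus, s.f_2plus) == (1, 1, 1, 1)
        # brute-force cross-check of the f-statistics
        shared = set("abc") & set("abd")
        assert s.k == len(shared)
        assert s.s_t == 3 + 3 - 2

    def test_disjoint(self):
        s = make_summary({"a": 1}, {"b": 2})
        assert s.k == 0 and s.shared_items == ()
        assert (s.f_plus1, s.f_plus2, s.f_1plus, s.f_2plus) == (0, 0, 0, 0)

    def test_self_overlap(self):
        s = make_summary({"a": 1, "b": 2}, {"a": 1, "b": 2})
        assert s.k == 2 and s.s_t == 2

    def test_mixed_units_rejected(self):
        with pytest.raises(ValueError):
            summarize_overlap(
                TraitProfile("t1", "snp", {"a": 1}), TraitProfile("t2", "gene", {"a": 1})
            )


class TestSimpleIndices:
    def test_jaccard_crohns_palmitoleic_counts(self):
        # 2 shared items between traits of 5 and 163 items
        s = make_summary(
            {"x1": 1, "x2": 1, "p3": 1, "p4": 1, "p5": 1},
            {f"c{i}": 1 for i in range(161)} | {"x1": 1, "x2": 1},
        )
        assert s.n1_unique == 5 and s.n2_unique == 163 and s.k == 2
        assert simple_index(s, "jaccard") == pytest.approx(2 / 166)

    def test_sorensen_identical_is_one(self):
        s = make_summary({"a": 1, "b": 1}, {"a": 1, "b": 1})
        assert simple_index(s, "sorensen") == 1.0

    def test_pearson_independence_is_zero(self):
        s = make_summary({"a": 1, "b": 1}, {"a": 1, "c": 1})
        assert simple_index(s, "pearson", n_universe=4) == 0.0

    def test_pearson_requires_large_universe(self):
        s = make_summary({"a": 1, "b": 1}, {"a": 1, "c": 1})
        with pytest.raises(ValueError):
            simple_index(s, "pearson", n_universe=2)

    def test_geometric_as_printed_with_one_time_warning(self):
        sim._geometric_warned = False
        s = make_summary({f"i{j}": 1 for j in range(4)}, {f"i{j}": 1 for j in range(4)})
        with pytest.warns(UserWarning, match="geometric"):
            v = simple_index(s, "geometric")
        assert v == pytest.approx(16 / 4)  # k^2/sqrt(n1*n2) = 16/4, exceeds 1
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            simple_index(s, "geometric")  # warned once only
        assert simple_index(s, "geometric", conventional_geometric=True) == 1.0

    @pytest.mark.parametrize("name", ["cosine", "simpson"])
    def test_cosine_simpson_formulas(self, name):
        s = make_summary({"a": 1, "b": 1, "c": 1}, {"a": 1, "d": 1})
        expected = {"cosine": 1 / math.sqrt(6), "simpson": 1 / 2}[name]
        assert simple_index(s, name) == pytest.approx(expected)


class TestChaoFamily:
    def test_worked_estimators(self, chao_profiles):
        s = summarize_overlap(*chao_profiles)
        u, v = chao_estimators(s)
        assert u == pytest.approx(0.625)
        assert v == pytest.approx(0.958333, abs=1e-6)

    def test_worked_indices(self):
        # exact rationals: U=5/8, V=23/24 give S_CS=115/152~0.756579 and
        # S_CJ=115/189~0.608466
        assert chao_index(5 / 8, 23 / 24, "chao_sorensen") == pytest.approx(115 / 152)
        assert chao_index(5 / 8, 23 / 24, "chao_jaccard") == pytest.approx(115 / 189)

    def test_no_singletons_reduces_to_observed_fractions(self):
        s = make_summary({"a": 3, "b": 2, "c": 5}, {"a": 2, "b": 4, "d": 1})
        assert s.f_plus1 == 0 and s.f_1plus == 0
        u, v = chao_estimators(s)
        assert u == pytest.approx(5 / 10) and v == pytest.approx(6 / 7)

    def test_identical_single_item_capped_at_one(self):
        s = make_summary({"a": 5}, {"a": 5})
        assert chao_estimators(s) == (1.0, 1.0)
        assert chao_index(1.0, 1.0, "chao_sorensen") == 1.0
        assert chao_index(1.0, 1.0, "chao_jaccard") == 1.0

    def test_zero_overlap(self):
        s = make_summary({"a": 1}, {"b": 1})
        assert chao_estimators(s) == (0.0, 0.0)
        assert chao_index(0.0, 0.7, "chao_sorensen") == 0.0


class TestMorisita:
    def test_worked_examples(self, morisita_profiles):
        s = summarize_overlap(*morisita_profiles)
        assert morisita_index(s, "morisita_horn") == pytest.approx(0.282353, abs=1e-6)
        assert morisita_index(s, "morisita") == pytest.approx(0.4)

    def test_disjoint_zero(self):
        s = make_summary({"a": 2, "b": 2}, {"c": 3, "d": 2})
        assert morisita_index(s, "morisita") == 0.0
        assert morisita_index(s, "morisita_horn") == 0.0

    def test_morisita_needs_two_reports(self):
        s = make_summary({"a": 1}, {"a": 1})
        with pytest.raises(ValueError, match="morisita_horn"):
            morisita_index(s, "morisita")


class TestCsi:
    def make_pearson(self, vals):
        traits = [f"T{i}" for i in range(len(vals))]
        return pd.DataFrame(vals, index=traits, columns=traits)

    def test_no_specific_connection(self):
        # both other traits correlate as strongly with T0/T1 as the pair does
        m = self.make_pearson(
            [
                [1.0, 0.5, 0.5, 0.5],
                [0.5, 1.0, 0.5, 0.5],
                [0.5, 0.5, 1.0, 0.1],
                [0.5, 0.5, 0.1, 1.0],
            ]
        )
        assert csi_matrix(m).loc["T0", "T1"] == 0.0

    def test_both_others_below_threshold(self):
        m = self.make_pearson(
            [
                [1.0, 0.8, 0.1, 0.1],
                [0.8, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.1],
                [0.1, 0.1, 0.1, 1.0],
            ]
        )
        # exhaustive count: T2 and T3 both correlate < 0.8-0.05 with T0 and T1
        assert csi_matrix(m).loc["T0", "T1"] == pytest.approx(2 / 4)

    def test_two_traits_only(self):
        m = self.make_pearson([[1.0, 0.9], [0.9, 1.0]])
        assert csi_matrix(m).loc["T0", "T1"] == 0.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            csi_matrix(pd.DataFrame(np.ones((2, 3))))


class TestSimilarityMatrix:
    def test_disjoint_traits_identity(self):
        profiles = [TraitProfile(f"T{i}", "snp", {f"rs{i}": 1}) for i in range(3)]
        mat, _ = similarity_matrix(profiles, "jaccard")
        assert np.allclose(mat.to_numpy(), np.eye(3))

    def test_planted_pair_off_diagonal(self):
        p1 = TraitProfile("A", "snp", {"s1": 1, "s2": 1, "s3": 1, "s4": 1})
        p2 = TraitProfile("B", "snp", {"s3": 1, "s4": 1, "s5": 1, "s6": 1})
        mat, _ = similarity_matrix([p1, p2], "jaccard")
        assert mat.loc["A", "B"] == pytest.approx(2 / 6)

    @pytest.mark.parametrize("index_name", INDEX_NAMES)
    def test_symmetry_all_indices(self, index_name):
        rng = np.random.default_rng(7)
        profiles = [random_profile(rng, f"T{i}", pool_size=40) for i in range(6)]
        mat, _ = similarity_matrix(profiles, index_name)
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)

    def test_unknown_index_rejected(self):
        profiles = [TraitProfile(f"T{i}", "snp", {"a": 1}) for i in range(2)]
        with pytest.raises(ValueError):
            similarity_matrix(profiles, "nope")


@st.composite
def abundance_pair(draw):
    pool = [f"i{j}" for j in range(12)]
    n1 = draw(st.integers(1, 8))
    n2 = draw(st.integers(1, 8))
    items1 = draw(st.permutations(pool))[:n1]
    items2 = draw(st.permutations(pool))[:n2]
    a1 = {i: draw(st.integers(1, 4)) for i in items1}
    a2 = {i: draw(st.integers(1, 4)) for i in items2}
    return a1, a2


class TestIndexProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(abundance_pair())
    def test_bounds_and_orderings(self, pair):
        a1, a2 = pair
        s = make_summary(a1, a2)
        vals = pair_index_values(s, n_universe=20)
        for name in ("jaccard", "sorensen", "cosine", "simpson",
                     "chao_jaccard", "chao_sorensen", "morisita_horn"):
            assert 0.0 <= vals[name] <= 1.0 + 1e-12
        assert -1.0 <= vals["pearson"] <= 1.0 + 1e-12
        assert vals["sorensen"] >= vals["jaccard"] - 1e-12
        assert vals["chao_sorensen"] >= vals["chao_jaccard"] - 1e-12
        assert 0.0 <= vals.U_hat <= 1.0 and 0.0 <= vals.V_hat <= 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(abundance_pair())
    def test_identity_and_disjoint_limits(self, pair):
        a1, _ = pair
        s_id = make_summary(a1, a1)
        for name in ("jaccard", "sorensen", "cosine", "simpson", "chao_jaccard",
                     "chao_sorensen"):
            v = (
                simple_index(s_id, name)
                if name in sim.SIMPLE_INDEX_NAMES
                else chao_index(*chao_estimators(s_id), name)
            )
            assert v == pytest.approx(1.0)
        disjoint = {f"z{j}": v for j, v in enumerate(a1.values())}
        s_dis = make_summary(a1, disjoint)
        vals = pair_index_values(s_dis, n_universe=40)
        for name in ("jaccard", "sorensen", "cosine", "simpson", "chao_jaccard",
                     "chao_sorensen", "morisita_horn"):
            assert vals[name] == 0.0
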