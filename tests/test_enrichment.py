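import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panomix import (
    AnalysisError,
    GeneSetCollection,
    common_pathways,
    hypergeom_enrich,
    mirna_consensus,
    mirna_de,
    pearson_screen,
)
from conftest import make_matrix, two_group_labels


class TestPearsonScreen:
    def test_self_correlation(self, rng):
        a = rng.normal(size=10)
        em = make_matrix(np.vstack([a, a, -a]), genes=["anchor", "same", "neg"])
        screen = pearson_screen("anchor", em)
        assert screen.table.at["same", "r"] == pytest.approx(1.0)
        assert screen.table.at["neg", "r"] == pytest.approx(-1.0)
        assert "anchor" not in screen.positive + screen.negative
        assert "same" in screen.positive and "neg" in screen.negative

    def test_p_matches_scipy_closed_form(self, rng):
        mat = rng.normal(size=(6, 10))
        em = make_matrix(mat, genes=[f"g{i}" for i in range(6)])
        screen = pearson_screen("g0", em)
        for i in range(1, 6):
            r_ref, p_ref = stats.pearsonr(mat[0], mat[i])
            assert screen.table.at[f"g{i}", "r"] == pytest.approx(r_ref, abs=1e-12)
            assert screen.table.at[f"g{i}", "pvalue"] == pytest.approx(p_ref, abs=1e-6)

    def test_zero_variance_gene_dropped(self, rng):
        mat = rng.normal(size=(3, 8))
        mat[2] = 4.0
        em = make_matrix(mat, genes=["a", "b", "flat"])
        screen = pearson_screen("a", em)
        assert screen.dropped == ["flat"]
        assert "flat" not in screen.table.index

    def test_anchor_negation_swaps_sets(self, rng):
        mat = rng.normal(size=(8, 12))
        em = make_matrix(mat)
        s1 = pearson_screen("g0", em)
        mat2 = mat.copy()
        mat2[0] = -mat2[0]
        s2 = pearson_screen("g0", make_matrix(mat2))
        assert set(s1.positive) == set(s2.negative)
        assert set(s1.negative) == set(s2.positive)

    def test_too_few_samples_rejected(self, rng):
        em = make_matrix(rng.normal(size=(2, 2)))
        with pytest.raises(AnalysisError):
            pearson_screen("g0", em)


class TestHypergeom:
    def test_complete_overlap_combinatorial_p(self):
        # overlap 5 of set 5 in query 5 from universe 20: p = 1/C(20,5)
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"P": frozenset(universe[:5])})
        out = hypergeom_enrich(universe[:5], sets, universe)
        assert out.at["P", "pvalue"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_set_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection({"P": frozenset(universe)})
        out = hypergeom_enrich(universe[:4], sets, universe)
        assert out.at["P", "pvalue"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # N=12, K=4, n=5: compare to brute-force counting over all C(12,5) draws
        universe = [f"g{i}" for i in range(12)]
        pathway = frozenset(universe[:4])
        sets = GeneSetCollection({"P": pathway})
        for query in (universe[:5], universe[2:7], universe[4:9], universe[7:12]):
            k_obs = len(pathway & set(query))
            count = sum(
                1
                for draw in itertools.combinations(universe, 5)
                if len(pathway & set(draw)) >= k_obs
            )
            p_enum = count / math.comb(12, 5)
            out = hypergeom_enrich(query, sets, universe)
            assert out.at["P", "pvalue"] == pytest.approx(p_enum, rel=1e-9)

    def test_monotone_in_overlap(self):
        universe = [f"g{i}" for i in range(40)]
        sets = GeneSetCollection({"P": frozenset(universe[:10])})
        pvals = []
        for k in range(0, 6):
            query = universe[:k] + universe[20 : 20 + (5 - k)]
            pvals.append(hypergeom_enrich(query, sets, universe).at["P", "pvalue"])
        assert all(pvals[i + 1] <= pvals[i] + 1e-12 for i in range(5))

    def test_empty_universe_rejected(self):
        sets = GeneSetCollection({"P": frozenset(["a"])})
        with pytest.raises(AnalysisError):
            hypergeom_enrich(["a"], sets, [])


class TestCommonPathways:
    def test_intersection(self):
        assert common_pathways([["A", "B"], ["B", "C"], ["B"]]) == ["B"]

    def test_disjoint(self):
        assert common_pathways([["A"], ["B"]]) == []

    def test_order_invariance(self):
        lists = [["A", "B", "C"], ["B", "C"], ["C", "B"]]
        for perm in itertools.permutations(lists):
            assert common_pathways(list(perm)) == ["B", "C"]

    def test_subset_of_every_input(self):
        lists = [["A", "B", "C"], ["B", "C", "D"]]
        out = common_pathways(lists)
        for lst in lists:
            assert set(out) <= set(lst)

    def test_single_dataset_rejected(self):
        with pytest.raises(AnalysisError):
            common_pathways([["A"]])


class TestMirna:
    LISTS = {
        "db1": ["m1", "m2", "m3", "m3"],
        "db2": ["m2", "m3"],
        "db3": ["m3", "m4"],
    }

    def test_consensus_rule(self):
        out = mirna_consensus(self.LISTS, min_support=2)
        assert out.at["m2", "consensus"] and out.at["m3", "consensus"]
        assert not out.at["m1", "consensus"] and not out.at["m4", "consensus"]

    def test_duplicates_within_list_count_once(self):
        out = mirna_consensus(self.LISTS)
        assert out.at["m3", "support"] == 3

    def test_min_support_exceeds_lists_rejected(self):
        with pytest.raises(AnalysisError):
            mirna_consensus(self.LISTS, min_support=4)

    def test_identical_groups_make_no_calls(self, rng):
        vals = rng.normal(size=(5, 10))
        vals[:, 5:] = vals[:, :5]
        em = make_matrix(vals, kind="mirna", genes=[f"m{i}" for i in range(5)])
        de = mirna_de(em, two_group_labels(5, 5))
        assert (de["call"] == 0).all()

    def test_planted_shift_direction_and_antisymmetry(self, rng):
        base = rng.normal(size=(20, 60))
        up = base.copy()
        up[0, :30] += 1.0
        em_up = make_matrix(up, kind="mirna", genes=[f"m{i}" for i in range(20)])
        de_up = mirna_de(em_up, two_group_labels(30, 30))
        assert de_up["call"].iloc[0] == 1 and de_up["fdr"].iloc[0] < 0.05
        down = base.copy()
        down[0, :30] -= 1.0
        de_down = mirna_de(
            make_matrix(down, kind="mirna", genes=[f"m{i}" for i in range(20)]),
            two_group_labels(30, 30),
        )
        assert de_down["call"].iloc[0] == -1

    def test_subset_restriction(self, rng):
        em = make_matrix(rng.normal(size=(6, 12)), kind="mirna", genes=[f"m{i}" for i in range(6)])
        de = mirna_de(em, two_group_labels(6, 6), mirnas=["m1", "m3", "absent"])
        assert list(de.index) == ["m1", "m3"]
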