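"""Fuzzy-rough approximations, dependency degree and reduct search.

The classical (crisp) rough-set model is the oracle throughout: with 0/1
similarities and crisp decision classes the fuzzy operators must reproduce
exactly what explicit partition enumeration gives.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frscreen.chem_io import DescriptorTable, normalize_table
from frscreen.fuzzy_rough import (
    FuzzyRelation,
    FuzzySet,
    ReductResult,
    attribute_similarity,
    brute_force_reduct,
    dependency_degree,
    fuzzify_decision,
    lower_approx,
    quickreduct,
    subset_relation,
    upper_approx,
)
from frscreen.synthetic_data import generate_crisp_table, plant_redundancy

from conftest import random_table


def classical_lower(partition, a_members):
    """Oracle: x is in the lower approximation iff its whole class is in A."""
    out = {}
    for block in partition:
        inside = set(block) <= set(a_members)
        for x in block:
            out[x] = 1.0 if inside else 0.0
    return out


def classical_upper(partition, a_members):
    """Oracle: x is in the upper approximation iff its class meets A."""
    out = {}
    for block in partition:
        meets = bool(set(block) & set(a_members))
        for x in block:
            out[x] = 1.0 if meets else 0.0
    return out


class TestAttributeSimilarity:
    def test_identical_values_fully_similar(self):
        v = np.array([0.3, 0.3, 0.9])
        assert attribute_similarity(v, 0, 1) == 1.0

    def test_range_extremes_fully_dissimilar(self):
        v = np.array([0.0, 1.0, 0.4])
        assert attribute_similarity(v, 0, 1) == 0.0

    def test_half_range_pair(self):
        v = np.array([0.0, 5.0, 10.0])
        assert attribute_similarity(v, 0, 1) == pytest.approx(0.5)

    def test_constant_attribute_gives_one(self):
        v = np.array([2.0, 2.0, 2.0])
        assert attribute_similarity(v, 0, 2) == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            attribute_similarity(np.array([0.0, np.nan]), 0, 1)


class TestSubsetRelation:
    def test_singleton_equals_attribute_matrix(self, small_table):
        rel = subset_relation(small_table, ["f0"])
        col = small_table.column("f0")
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else attribute_similarity(col, i, j)
                assert rel.matrix[i, j] == pytest.approx(expected)

    def test_empty_subset_is_all_ones(self, small_table):
        rel = subset_relation(small_table, [])
        assert np.all(rel.matrix == 1.0)

    def test_reflexive_symmetric_bounded(self, rng):
        for _ in range(20):
            t = random_table(rng, 8, 4)
            rel = subset_relation(t, t.feature_names[:2])
            assert np.all(np.diag(rel.matrix) == 1.0)
            np.testing.assert_array_equal(rel.matrix, rel.matrix.T)
            assert rel.matrix.min() >= 0.0 and rel.matrix.max() <= 1.0

    def test_adding_a_feature_never_increases_entries(self, rng):
        for _ in range(100):
            t = random_table(rng, 6, 3)
            base = subset_relation(t, ["f0"]).matrix
            bigger = subset_relation(t, ["f0", "f1"]).matrix
            assert np.all(bigger <= base + 1e-12)

    def test_unknown_feature_rejected(self, small_table):
        with pytest.raises(KeyError):
            subset_relation(small_table, ["nope"])


class TestApproximations:
    def test_universe_is_its_own_lower(self, small_table):
        rel = subset_relation(small_table, small_table.feature_names)
        a = FuzzySet(np.ones(small_table.n_compounds))
        assert np.all(lower_approx(rel, a).membership == 1.0)

    def test_identity_relation_preserves_any_set(self, rng):
        n = 7
        rel = FuzzyRelation(np.eye(n))
        a = FuzzySet(rng.uniform(0, 1, n))
        np.testing.assert_allclose(lower_approx(rel, a).membership, a.membership)
        np.testing.assert_allclose(upper_approx(rel, a).membership, a.membership)

    def test_crisp_partition_oracle(self):
        # partition {x1,x2},{x3}; A = {x1,x3}
        table, _ = generate_crisp_table(3, 2, [[0, 1], [2]])
        rel = subset_relation(table, table.feature_names)
        a = FuzzySet(np.array([1.0, 0.0, 1.0]))
        np.testing.assert_array_equal(lower_approx(rel, a).membership, [0.0, 0.0, 1.0])
        np.testing.assert_array_equal(upper_approx(rel, a).membership, [1.0, 1.0, 1.0])

    def test_empty_set_has_empty_upper(self, small_table):
        rel = subset_relation(small_table, small_table.feature_names)
        a = FuzzySet(np.zeros(small_table.n_compounds))
        assert np.all(upper_approx(rel, a).membership == 0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lower_below_upper_everywhere(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 9))
        m = r.uniform(0, 1, (n, n))
        m = np.minimum(m, m.T)
        np.fill_diagonal(m, 1.0)
        rel = FuzzyRelation(m)
        a = FuzzySet(r.uniform(0, 1, n))
        lo = lower_approx(rel, a).membership
        up = upper_approx(rel, a).membership
        assert np.all(lo <= up + 1e-12)
        assert lo.min() >= 0 and up.max() <= 1

    def test_crisp_degeneration_all_small_partitions(self):
        # every crisp table up to 8 objects from a pool of partition shapes
        shapes = [
            [[0], [1], [2]],
            [[0, 1], [2]],
            [[0, 1, 2, 3]],
            [[0, 1], [2, 3], [4]],
            [[0, 3], [1, 4], [2, 5]],
            [[0, 1, 2], [3, 4], [5, 6, 7]],
        ]
        rng = np.random.default_rng(5)
        for partition in shapes:
            n = sum(len(b) for b in partition)
            table, _ = generate_crisp_table(n, 4, partition, seed=3)
            rel = subset_relation(table, table.feature_names)
            members = sorted(rng.choice(n, size=max(1, n // 2), replace=False))
            a = FuzzySet(np.isin(np.arange(n), members).astype(float))
            lo = classical_lower(partition, members)
            up = classical_upper(partition, members)
            np.testing.assert_array_equal(
                lower_approx(rel, a).membership, [lo[x] for x in range(n)]
            )
            np.testing.assert_array_equal(
                upper_approx(rel, a).membership, [up[x] for x in range(n)]
            )

    def test_dimension_mismatch_rejected(self):
        rel = FuzzyRelation(np.eye(3))
        with pytest.raises(ValueError):
            lower_approx(rel, FuzzySet(np.zeros(4)))


class TestFuzzifyDecision:
    def test_tertiles_split_nine_targets_evenly(self):
        y = np.array([1, 2, 3, 10, 20, 30, 100, 200, 300], dtype=float)
        sets = fuzzify_decision(y, bins=3)
        sizes = [int(s.membership.sum()) for s in sets]
        assert sizes == [3, 3, 3]
        # potent band = the three lowest IC50s
        np.testing.assert_array_equal(
            sets[0].membership, [1, 1, 1, 0, 0, 0, 0, 0, 0]
        )

    def test_crisp_sets_partition_the_universe(self, rng):
        y = rng.uniform(0.1, 100, size=20)
        sets = fuzzify_decision(y, bins=3)
        total = np.sum([s.membership for s in sets], axis=0)
        np.testing.assert_array_equal(total, np.ones(20))

    def test_too_few_distinct_values_suggests_fuzzy(self):
        with pytest.raises(ValueError, match="fuzzy"):
            fuzzify_decision(np.array([1.0, 1.0, 2.0, 2.0]), bins=3)

    def test_fuzzy_method_returns_similarity_classes(self):
        y = np.array([0.0, 5.0, 10.0])
        sets = fuzzify_decision(y, method="fuzzy")
        assert len(sets) == 3
        np.testing.assert_allclose(sets[0].membership, [1.0, 0.5, 0.0])


class TestDependencyDegree:
    def test_consistent_crisp_table_has_full_dependency(self):
        table, dsets = generate_crisp_table(6, 3, [[0, 1], [2, 3], [4, 5]])
        assert dependency_degree(table, table.feature_names, dsets) == pytest.approx(1.0)

    def test_empty_subset_with_crisp_classes_gives_zero(self):
        table, dsets = generate_crisp_table(6, 3, [[0, 1], [2, 3], [4, 5]])
        assert dependency_degree(table, [], dsets) == pytest.approx(0.0)

    def test_monotone_under_feature_addition(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 21))
            f = int(rng.integers(2, 11))
            t = random_table(rng, n, f)
            y = rng.uniform(0.1, 10, n)
            dec = fuzzify_decision(y, bins=3) if np.unique(y).size >= 3 else None
            subset = list(rng.choice(t.feature_names, size=f // 2, replace=False))
            extra = next(x for x in t.feature_names if x not in subset)
            g1 = dependency_degree(t, subset, dec)
            g2 = dependency_degree(t, subset + [extra], dec)
            assert g2 >= g1 - 1e-12

    def test_empty_decision_rejected(self, small_table):
        with pytest.raises(ValueError):
            dependency_degree(small_table, [], [])


class TestQuickReduct:
    def _planted_table(self, seed=0):
        """Binary f1 alone determines a 2-block decision; f2..f4 are noise."""
        rng = np.random.default_rng(seed)
        n = 12
        f1 = np.repeat([0.0, 1.0], 6)
        noise = rng.uniform(0.0, 1.0, size=(n, 3))
        values = np.column_stack([f1, noise])
        t = normalize_table(DescriptorTable(
            [f"c{i}" for i in range(n)], ["f1", "f2", "f3", "f4"], values
        ))
        dsets = [
            FuzzySet((np.repeat([0, 1], 6) == k).astype(float)) for k in range(2)
        ]
        return t, dsets

    def test_single_determining_feature_selected_alone(self):
        t, dsets = self._planted_table()
        r = quickreduct(t, dsets, tolerance=1e-9)
        assert r.selected == ["f1"]
        assert [b for b in brute_force_reduct(t, dsets) if len(b) == 1] == [("f1",)]

    def test_greedy_matches_exhaustive_gamma(self, rng):
        for k in range(50):
            t = random_table(rng, int(rng.integers(5, 10)), int(rng.integers(2, 9)))
            y = rng.uniform(0.1, 10, t.n_compounds)
            dec = fuzzify_decision(y, bins=3)
            greedy = quickreduct(t, dec, tolerance=1e-6)
            minimal = brute_force_reduct(t, dec)
            best = max(
                (dependency_degree(t, list(s), dec) for s in minimal), default=0.0
            )
            assert greedy.gamma >= best - 1e-6

    def test_gamma_trace_non_decreasing(self, rng):
        t = random_table(rng, 15, 6)
        y = rng.uniform(0.1, 10, 15)
        r = quickreduct(t, fuzzify_decision(y, bins=3))
        assert all(b >= a - 1e-12 for a, b in zip(r.gamma_trace, r.gamma_trace[1:]))
        assert r.gamma >= r.gamma_full - r.tolerance

    def test_huge_tolerance_selects_nothing(self, small_table):
        y = np.linspace(1, 10, small_table.n_compounds)
        r = quickreduct(small_table, fuzzify_decision(y, bins=3), tolerance=1.0)
        assert r.selected == [] and r.gamma_trace == []

    def test_json_round_trip(self):
        r = ReductResult(["a", "b"], [0.4, 0.9], 0.9, 1e-6, universe=["a", "b", "c"])
        assert ReductResult.from_json(r.to_json()).selected == ["a", "b"]


class TestBruteForceReduct:
    def test_duplicate_columns_never_cooccur_in_minimal_reduct(self, rng):
        t = random_table(rng, 8, 4)
        t2 = plant_redundancy(t, "f0")
        y = rng.uniform(0.1, 10, 8)
        dec = fuzzify_decision(y, bins=3)
        for subset in brute_force_reduct(t2, dec):
            assert not {"f0", "f0_copy"} <= set(subset)

    def test_single_feature_table_unique_reduct(self, rng):
        t = random_table(rng, 6, 1)
        y = rng.uniform(0.1, 10, 6)
        dec = fuzzify_decision(y, bins=3)
        assert brute_force_reduct(t, dec) == [("f0",)]

    def test_minimality_no_proper_subset_qualifies(self, rng):
        t = random_table(rng, 7, 5)
        y = rng.uniform(0.1, 10, 7)
        dec = fuzzify_decision(y, bins=3)
        gamma_full = dependency_degree(t, t.feature_names, dec)
        from itertools import combinations

        for subset in brute_force_reduct(t, dec):
            assert dependency_degree(t, list(subset), dec) >= gamma_full - 1e-12
            for r in range(len(subset)):
                for sub in combinations(subset, r):
                    assert dependency_degree(t, list(sub), dec) < gamma_full - 1e-12

    def test_refuses_large_tables(self, rng):
        t = random_table(rng, 5, 13)
        with pytest.raises(ValueError, match="12"):
            brute_force_reduct(t, [FuzzySet(np.ones(5))])
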