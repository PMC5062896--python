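"""Clonal hierarchies: significance, depth, order statistics, topology."""

import itertools
from types import SimpleNamespace

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from hemaclone import (
    CloneNode,
    CloneParams,
    CohortResult,
    CompartmentState,
    HierarchyTree,
    SystemState,
    canonical_topology,
    clone_order_statistics,
    depth_vs_max_self_renewal,
    hierarchy_depth,
    significant_clones,
    welch_t_test,
)
from hemaclone.hierarchy import cohort_summary, fraction_second_exceeds_first


def _node(cid, parent, depth, a=0.9, p=0.3, birth=None, significant=None):
    return CloneNode(
        id=cid, parent=parent, birth_time=float(birth if birth is not None else depth),
        depth=depth, params=CloneParams(a_max=a, p=p),
        significant=dict(significant or {}),
    )


def _chain(n, sig_flags=None):
    tree = HierarchyTree()
    for i in range(1, n + 1):
        flags = {"terminal": sig_flags[i - 1]} if sig_flags else None
        tree.add(_node(i, i - 1 if i > 1 else None, i, significant=flags))
    return tree


def _star(n_children):
    tree = HierarchyTree()
    tree.add(_node(1, None, 1))
    for i in range(2, n_children + 2):
        tree.add(_node(i, 1, 2))
    return tree


class TestSignificantClones:
    def _state(self, clone_masses, healthy_mass=0.0):
        clones = [
            (i + 1, CloneParams(0.9, 0.3), CompartmentState(m, 0.0))
            for i, m in enumerate(clone_masses)
        ]
        return SystemState(
            time=0.0, healthy=CompartmentState(0.0, healthy_mass), clones=clones
        )

    def test_single_clone_dominates(self):
        assert significant_clones(self._state([1e6]), 0.5) == {1}

    def test_exact_threshold_included(self):
        # clone 1 holds exactly 1% of total mass: "at least" includes it
        state = self._state([1.0, 99.0])
        assert 1 in significant_clones(state, 0.01)

    def test_mass_fraction_cutoff(self):
        # fractions 0.009 and 0.011 of the total -> exactly one significant
        state = self._state([0.9, 1.1], healthy_mass=98.0)
        assert significant_clones(state, 0.01) == {2}

    def test_empty_system(self):
        state = SystemState(time=0.0, healthy=CompartmentState(0.0, 0.0))
        assert significant_clones(state, 0.01) == set()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            significant_clones(self._state([1.0]), 0.0)

    def test_total_includes_healthy_cells(self):
        state = self._state([1.0], healthy_mass=1000.0)
        assert significant_clones(state, 0.01) == set()


class TestHierarchyDepth:
    def test_founder_only(self):
        assert hierarchy_depth(_chain(1)) == 1

    def test_chain_depth_counts_accumulated_mutations(self):
        assert hierarchy_depth(_chain(3)) == 3

    def test_star_is_flat(self):
        assert hierarchy_depth(_star(5)) == 2

    def test_significance_filter(self):
        tree = _chain(3, sig_flags=[True, True, False])
        assert hierarchy_depth(tree, significant_only=True, mode="terminal") == 2
        assert hierarchy_depth(tree, significant_only=False) == 3

    def test_no_significant_clones_gives_zero(self):
        tree = _chain(2, sig_flags=[False, False])
        assert hierarchy_depth(tree, significant_only=True, mode="terminal") == 0

    def test_child_depth_invariant_enforced(self):
        tree = HierarchyTree()
        tree.add(_node(1, None, 1))
        with pytest.raises(ValueError):
            tree.add(_node(2, 1, 3))


class TestCanonicalTopology:
    def test_child_order_irrelevant(self):
        t1 = HierarchyTree()
        t1.add(_node(1, None, 1))
        t1.add(_node(2, 1, 2))
        t1.add(_node(3, 1, 2))
        t1.add(_node(4, 2, 3))
        t2 = HierarchyTree()
        t2.add(_node(1, None, 1))
        t2.add(_node(3, 1, 2))
        t2.add(_node(2, 1, 2))
        t2.add(_node(4, 3, 3))
        assert canonical_topology(t1) == canonical_topology(t2)

    def test_chain_differs_from_star(self):
        assert canonical_topology(_chain(3)) != canonical_topology(_star(2))

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 2), (4, 4), (5, 9), (6, 20), (7, 48)])
    def test_counts_match_rooted_tree_enumeration(self, n, expected):
        """Distinct canonical strings over all labeled rooted trees on n
        nodes equal the number of rooted unordered trees (brute-force
        enumeration oracle; 9 distinct trees on 5 nodes)."""
        seen = set()
        parent_choices = [range(j) for j in range(1, n)]
        for parents in itertools.product(*parent_choices):
            tree = HierarchyTree()
            depths = {0: 1}
            tree.add(_node(1, None, 1))
            for child, par in enumerate(parents, start=1):
                depths[child] = depths[par] + 1
                tree.add(_node(child + 1, par + 1, depths[child]))
            seen.add(canonical_topology(tree, significant_only=False))
        assert len(seen) == expected

    def test_agrees_with_networkx_isomorphism(self):
        """Independent cross-check: canonical equality iff rooted-tree
        isomorphism as decided by networkx, over all trees on 5 nodes."""
        trees = []
        for parents in itertools.product(*[range(j) for j in range(1, 5)]):
            tree = HierarchyTree()
            depths = {0: 1}
            tree.add(_node(1, None, 1))
            g = nx.DiGraph()
            g.add_node(1)
            for child, par in enumerate(parents, start=1):
                depths[child] = depths[par] + 1
                tree.add(_node(child + 1, par + 1, depths[child]))
                g.add_edge(par + 1, child + 1)
            trees.append((canonical_topology(tree, significant_only=False), g))
        for (s1, g1), (s2, g2) in itertools.combinations(trees, 2):
            iso = nx.algorithms.isomorphism.rooted_tree_isomorphism(
                g1.to_undirected(), 1, g2.to_undirected(), 1
            )
            assert (s1 == s2) == (len(iso) > 0)

    def test_insignificant_nodes_are_contracted_to_nearest_ancestor(self):
        # founder(sig) -> mid(insig) -> leaf(sig): contracts to a 2-chain
        tree = _chain(3, sig_flags=[True, False, True])
        contracted = canonical_topology(tree, significant_only=True, mode="terminal")
        assert contracted == canonical_topology(_chain(2), significant_only=False)

    def test_relabeling_invariance(self):
        t1 = HierarchyTree()
        t1.add(_node(1, None, 1))
        t1.add(_node(5, 1, 2))
        t1.add(_node(9, 5, 3))
        assert canonical_topology(t1) == canonical_topology(_chain(3))


class TestWelchTTest:
    def test_identical_samples(self):
        stat, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_constant_samples(self):
        assert welch_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_separated_samples(self, rng):
        a = np.zeros(4) + rng.normal(0, 1e-6, 4)
        b = np.full(4, 10.0) + rng.normal(0, 1e-6, 4)
        _, p = welch_t_test(a, b)
        assert p < 1e-6

    def test_type_one_error_rate_is_calibrated(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1, 50)
            _, p = welch_t_test(a, b)
            rejections += p < 0.05
        assert 0.03 < rejections / reps < 0.07

    def test_matches_reference_implementation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 2, 40)
        stat, p = welch_t_test(a, b)
        ref_stat, ref_p = stats.ttest_ind(a, b, equal_var=False)
        assert stat == pytest.approx(float(ref_stat))
        assert p == pytest.approx(float(ref_p))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


def _fake_patient(sig_as, depths=None, insig=0):
    """Patient stub with significant clones of given self-renewal values in
    emergence order (plus optional insignificant clones)."""
    tree = HierarchyTree()
    tree.add(CloneNode(id=1, parent=None, birth_time=0.0,
                       depth=1, params=CloneParams(a_max=sig_as[0], p=0.3),
                       significant={"terminal": True}))
    for i, a in enumerate(sig_as[1:], start=2):
        d = depths[i - 2] if depths else 2
        parent = 1 if d == 2 else i - 1
        tree.add(CloneNode(id=i, parent=parent, birth_time=float(i),
                           depth=d, params=CloneParams(a_max=a, p=0.3),
                           significant={"terminal": True}))
    nid = len(sig_as) + 1
    for j in range(insig):
        tree.add(CloneNode(id=nid + j, parent=1, birth_time=100.0 + j, depth=2,
                           params=CloneParams(a_max=0.6, p=0.3),
                           significant={"terminal": False}))
    return SimpleNamespace(
        hierarchy=tree, status="died_of_disease", death_time=1000.0, seed=0,
        n_mutation_events=len(tree.nodes) - 1,
    )


class TestCloneOrderStatistics:
    def test_constructed_ranks_recovered_exactly(self):
        cohort = CohortResult(patients=[
            _fake_patient([0.88, 0.90, 0.92]) for _ in range(5)
        ])
        df = clone_order_statistics(cohort, mode="terminal")
        means = df.groupby("rank")["a_max"].mean()
        assert list(means.round(10)) == [0.88, 0.90, 0.92]

    def test_single_patient_cohort_returns_its_values(self):
        cohort = CohortResult(patients=[_fake_patient([0.87, 0.91])])
        df = clone_order_statistics(cohort, mode="terminal")
        assert list(df["a_max"]) == [0.87, 0.91]

    def test_subgroup_restriction_by_terminal_count(self):
        cohort = CohortResult(patients=[
            _fake_patient([0.88, 0.90]),
            _fake_patient([0.88, 0.90, 0.92]),
        ])
        df = clone_order_statistics(cohort, mode="terminal", n_significant=3)
        assert df["patient"].nunique() == 1
        assert df["rank"].max() == 3

    def test_fraction_second_exceeds_first(self):
        cohort = CohortResult(patients=[
            _fake_patient([0.88, 0.90]),   # increasing
            _fake_patient([0.90, 0.88]),   # decreasing
            _fake_patient([0.88]),         # ineligible (single clone)
        ])
        frac, n = fraction_second_exceeds_first(cohort, mode="terminal")
        assert n == 2
        assert frac == pytest.approx(0.5)

    def test_insignificant_clones_never_ranked(self):
        cohort = CohortResult(patients=[_fake_patient([0.88], insig=4)])
        df = clone_order_statistics(cohort, mode="terminal")
        assert len(df) == 1


class TestDepthVsMaxSelfRenewal:
    def _cohort(self, rng, ordered=True):
        patients = []
        for depth in (1, 2, 3):
            for _ in range(30):
                base = 0.88 + (0.02 * depth if ordered else 0.0)
                a_vals = [base + rng.normal(0, 0.002)]
                depths = None
                if depth >= 2:
                    a_vals.append(base + 0.005 + rng.normal(0, 0.002))
                    depths = [2]
                if depth >= 3:
                    a_vals.append(base + 0.01 + rng.normal(0, 0.002))
                    depths = [2, 3]
                a_vals = [min(a, 1.0) for a in a_vals]
                patients.append(_fake_patient(a_vals, depths=depths))
        return CohortResult(patients=patients)

    def test_ordered_cohort_gives_significant_pairwise_tests(self, rng):
        out = depth_vs_max_self_renewal(self._cohort(rng), mode="terminal")
        means = out["per_depth_mean"]
        assert means[1] < means[2] < means[3]
        assert all(p < 0.05 for _, p in out["pairwise_welch"].values())

    def test_shuffled_labels_destroy_association(self, rng):
        """Permutation oracle: shuffling depth labels across patients
        removes the depth effect in ~95% of shuffles."""
        out = depth_vs_max_self_renewal(self._cohort(rng), mode="terminal")
        depths = np.concatenate([[d] * len(v) for d, v in out["by_depth"].items()])
        values = np.concatenate([v for v in out["by_depth"].values()])
        insignificant = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            perm = rng.permutation(depths)
            _, p = welch_t_test(values[perm == 1], values[perm == 3])
            insignificant += p > 0.05
        assert insignificant / n_shuffles > 0.85

    def test_needs_two_depths(self):
        cohort = CohortResult(patients=[_fake_patient([0.9]) for _ in range(3)])
        with pytest.raises(ValueError):
            depth_vs_max_self_renewal(cohort, mode="terminal")


class TestCohortSummary:
    def test_summary_consistent_with_trees(self):
        cohort = CohortResult(patients=[
            _fake_patient([0.88, 0.90, 0.92], depths=[2, 3], insig=2),
            _fake_patient([0.89]),
        ])
        df = cohort_summary(cohort, mode="terminal")
        assert list(df["n_significant"]) == [3, 1]
        assert list(df["depth"]) == [3, 1]
        assert list(df["n_clones"]) == [5, 1]
        assert df["max_a_significant"].iloc[0] == pytest.approx(0.92)
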