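"""Pigeonhole reconciliation of clusters into clone trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from somaclone import (
    MutationCluster,
    SimulationConfig,
    build_tree,
    check_pigeonhole,
    simulate_truth,
    vaf_to_prevalence,
)
from somaclone.tree import SYNTHETIC_ROOT, CloneTree, PigeonholeInfeasibleError


def cluster(cid, prevalence, samples=None, burden=10):
    samples = samples or [f"S{i}" for i in range(len(prevalence))]
    prev = pd.Series(prevalence, index=samples, dtype=float)
    return MutationCluster(
        cluster_id=cid,
        members=[f"c{cid}_m{i}" for i in range(burden)],
        theta_hat=prev / 2,
        prevalence=prev,
    )


class TestVafToPrevalence:
    @pytest.mark.parametrize(
        "theta,expected", [(0.0, 0.0), (0.5, 1.0), (0.2, 0.4), (0.7, 1.0)]
    )
    def test_diploid_mapping(self, theta, expected):
        assert vaf_to_prevalence(theta) == pytest.approx(expected)

    def test_vectorised(self):
        np.testing.assert_allclose(
            vaf_to_prevalence(np.array([0.1, 0.6])), [0.2, 1.0]
        )


def enumerate_admissible_trees(prevs, epsilon):
    """Oracle: all parent assignments over clusters + unit root that satisfy
    pigeonhole (capacity at every node, containment on every edge)."""
    n = len(prevs)
    nodes = list(range(n))
    admissible = []
    for parents in itertools.product([-1] + nodes, repeat=n):
        if any(parents[i] == i for i in nodes):
            continue
        # acyclicity
        ok = True
        for i in nodes:
            seen, j = set(), i
            while parents[j] != -1:
                j = parents[j]
                if j in seen:
                    ok = False
                    break
                seen.add(j)
            if not ok:
                break
        if not ok:
            continue
        # containment + capacity
        prev_of = {-1: np.ones_like(prevs[0]), **{i: prevs[i] for i in nodes}}
        for node in [-1] + nodes:
            kids = [i for i in nodes if parents[i] == node]
            if not kids:
                continue
            ksum = np.sum([prevs[k] for k in kids], axis=0)
            if np.any(ksum > prev_of[node] + epsilon):
                ok = False
                break
            for k in kids:
                if np.any(prevs[k] > prev_of[node] + epsilon):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            admissible.append(parents)
    return admissible


class TestBuildTree:
    def test_single_clonal_cluster(self):
        t = build_tree([cluster(0, [1.0, 1.0])])
        assert t.parents == {0: None}
        assert (t.clone_size.to_numpy() == 1.0).all()

    def test_chain_attachment_deepest_admissible(self):
        """R=(1,1), A=(0.6,0.2), B=(0.3,0.1): B goes under A, the deepest
        admissible parent; cross-checked against exhaustive enumeration."""
        clusters = [
            cluster(0, [1.0, 1.0]),
            cluster(1, [0.6, 0.2]),
            cluster(2, [0.3, 0.1]),
        ]
        t = build_tree(clusters, epsilon=0.05)
        assert t.parents == {0: None, 1: 0, 2: 1}
        # the produced assignment is among the admissible ones, and it is
        # the (unique) deepest placement of B among them
        prevs = [np.array(c.prevalence) for c in clusters[1:]]
        admissible = enumerate_admissible_trees(prevs, 0.05)
        assert (-1, -1) in admissible  # both directly under R
        assert (-1, 0) in admissible  # the chain placement, one level deeper
        assert (1, -1) not in admissible  # A can never sit under B

    def test_crossing_profiles_become_siblings(self):
        # each cluster beats the other in one sample: no nesting possible
        clusters = [cluster(1, [0.6, 0.2]), cluster(2, [0.3, 0.7])]
        t = build_tree(clusters, epsilon=0.05)
        assert t.parents[1] == SYNTHETIC_ROOT
        assert t.parents[2] == SYNTHETIC_ROOT

    def test_one_sided_containment_nests(self):
        # C=(0.6,0.7) can contain A=(0.6,0.2) in every sample, so the
        # deepest-admissible rule nests A under C rather than keeping
        # siblings
        clusters = [cluster(1, [0.6, 0.2]), cluster(2, [0.6, 0.7])]
        t = build_tree(clusters, epsilon=0.05)
        assert t.parents[2] == SYNTHETIC_ROOT
        assert t.parents[1] == 2

    def test_synthetic_root_only_when_needed(self):
        with_root = [cluster(0, [1.0, 1.0]), cluster(1, [0.5, 0.3])]
        t1 = build_tree(with_root)
        assert SYNTHETIC_ROOT not in t1.parents
        t2 = build_tree(with_root[1:])
        assert t2.parents == {SYNTHETIC_ROOT: None, 1: SYNTHETIC_ROOT}
        # other parent relations unchanged by the root's nature
        assert t1.parents[1] == t1.root and t2.parents[1] == t2.root

    def test_infeasible_set_raises_with_samples(self):
        clusters = [
            cluster(1, [0.8, 0.8]),
            cluster(2, [0.8, 0.2]),
            cluster(3, [0.2, 0.8]),
        ]
        with pytest.raises(PigeonholeInfeasibleError, match="sample"):
            build_tree(clusters, epsilon=0.05)

    def test_burden_conservation(self):
        clusters = [
            cluster(0, [1.0, 1.0], burden=40),
            cluster(1, [0.6, 0.2], burden=25),
            cluster(2, [0.3, 0.1], burden=7),
        ]
        t = build_tree(clusters)
        assert sum(t.burden.values()) == 72


class TestCloneSizes:
    def tree_rab(self):
        clusters = [
            cluster(0, [1.0, 1.0]),
            cluster(1, [0.6, 0.2]),
            cluster(2, [0.3, 0.1]),
        ]
        return build_tree(clusters)

    def test_leaf_equals_prevalence(self):
        t = self.tree_rab()
        np.testing.assert_allclose(t.clone_size.loc[2], [0.3, 0.1])

    def test_internal_subtracts_children(self):
        t = self.tree_rab()
        np.testing.assert_allclose(t.clone_size.loc[1], [0.3, 0.1])
        np.testing.assert_allclose(t.clone_size.loc[0], [0.4, 0.8])

    def test_total_clone_mass_bounded(self):
        t = self.tree_rab()
        assert (t.clone_size.sum(axis=0) <= 1 + t.epsilon).all()


class TestCheckPigeonhole:
    def test_built_trees_always_pass(self):
        t = build_tree(
            [cluster(0, [1.0, 1.0]), cluster(1, [0.5, 0.5]), cluster(2, [0.4, 0.3])]
        )
        ok, violations = check_pigeonhole(t, epsilon=t.epsilon)
        assert ok and not violations

    def test_constructed_violation_reported(self):
        prev = pd.DataFrame(
            {"S0": [0.8, 0.7, 0.5]}, index=[0, 1, 2]
        )
        bad = CloneTree(
            parents={0: None, 1: 0, 2: 0},
            prevalence=prev,
            burden={0: 1, 1: 1, 2: 1},
            epsilon=0.0,
        )
        ok, violations = check_pigeonhole(bad)
        assert not ok
        assert violations[0]["node"] == 0 and violations[0]["sample"] == "S0"
        assert violations[0]["children_sum"] == pytest.approx(1.2)

    @pytest.mark.parametrize("seed", range(25))
    def test_generator_and_checker_agree(self, seed):
        cfg = SimulationConfig(
            n_samples=3 + seed % 4, n_clones=1 + seed % 6,
            burden_range=(5, 10), seed=seed,
        )
        truth = simulate_truth(cfg)
        ok, violations = check_pigeonhole(truth, epsilon=0.0)
        assert ok, violations


class TestExports:
    def test_newick_and_json_and_dot(self):
        t = build_tree(
            [cluster(0, [1.0, 1.0], burden=12), cluster(1, [0.5, 0.2], burden=3)]
        )
        assert t.to_newick() == "(c1:3)c0:12;"
        blob = t.to_json()
        assert '"burden": 12' in blob and '"clone_size_pct"' in blob
        assert "n0 -> n1;" in t.to_dot()
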