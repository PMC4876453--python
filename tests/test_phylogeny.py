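"""Clone-tree inference: enumeration, pigeonhole constraints, selection."""

import numpy as np
import pytest

import clonekin as ck
from clonekin.ccf import ccf_log_likelihood_grid, make_grid
from clonekin.evaluation import topology_recovery_experiment, tree_oracle_experiment
from clonekin.phylogeny import GERMLINE, find_trunk

GRID = make_grid(0.01)


def make_clusters(ccfs: dict, depth=5000, muts=3, seed=0):
    """CloneCluster objects whose posteriors concentrate at given CCFs."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i+1}" for i in range(len(next(iter(ccfs.values()))))]
    out = []
    for c, vec in ccfs.items():
        ll = np.zeros((len(samples), len(GRID)))
        for s, ccf in enumerate(vec):
            alt = rng.binomial(depth, ccf / 2.0, size=muts)
            ll[s] = ccf_log_likelihood_grid(alt, np.full(muts, depth), 1.0, GRID).sum(0)
        out.append(ck.CloneCluster(
            cluster_id=c, members=[f"c{c}m{j}" for j in range(muts)],
            samples=samples, grid=GRID, log_liks=ll,
        ))
    return out


class TestEnumeration:
    def test_single_cluster_single_tree(self):
        trees = ck.enumerate_valid_trees({1: [1.0, 1.0]}, epsilon=0.1)
        assert len(trees) == 1
        assert trees[0].parent == {1: GERMLINE}

    def test_crossing_ccfs_force_siblings(self):
        # A dominates in sample 1, B in sample 2; sums stay below the trunk
        trees = ck.enumerate_valid_trees(
            {1: [1.0, 1.0], 2: [0.7, 0.2], 3: [0.2, 0.6]}, epsilon=0.1
        )
        assert [t.parent for t in trees] == [{1: GERMLINE, 2: 1, 3: 1}]

    def test_pigeonhole_forces_chain(self):
        # 0.8 + 0.5 > 1 rules out siblings; only trunk->A->B survives
        trees = ck.enumerate_valid_trees(
            {1: [1.0, 1.0], 2: [0.8, 0.9], 3: [0.5, 0.6]}, epsilon=0.1
        )
        assert [t.parent for t in trees] == [{1: GERMLINE, 2: 1, 3: 2}]

    def test_no_trunk_is_diagnosed(self):
        with pytest.raises(ck.NoTrunkError, match="CCF"):
            ck.enumerate_valid_trees({1: [0.6, 0.5], 2: [0.3, 0.2]}, epsilon=0.1)

    def test_trunk_is_highest_qualifier(self):
        assert find_trunk({1: np.array([1.0, 1.0]), 2: np.array([0.92, 0.95])},
                          epsilon=0.1) == 1


class TestSelection:
    def test_single_candidate_returned(self):
        clusters = make_clusters({1: [1.0, 1.0]})
        trees = ck.enumerate_valid_trees(clusters)
        selected, scores = ck.score_and_select_tree(trees, clusters, seed=1)
        assert selected.parent == trees[0].parent
        assert len(scores) == 1

    @pytest.mark.parametrize("ccfs,expected", [
        ({1: [1.0, 1.0], 2: [0.7, 0.2], 3: [0.2, 0.6]}, {1: GERMLINE, 2: 1, 3: 1}),
        ({1: [1.0, 1.0], 2: [0.8, 0.9], 3: [0.5, 0.6]}, {1: GERMLINE, 2: 1, 3: 2}),
    ])
    def test_unique_valid_tree_selected(self, ccfs, expected):
        clusters = make_clusters(ccfs)
        selected, _ = ck.select_tree(clusters, seed=2)
        assert selected.parent == expected
        assert not selected.constraint_flag

    def test_empty_candidate_list_propagates(self):
        with pytest.raises(ck.NoValidTreeError):
            ck.score_and_select_tree([], [], seed=0)

    def test_least_violating_fallback_is_flagged(self):
        # crossing CCFs too large for siblings and incompatible with nesting
        clusters = make_clusters({1: [1.0, 1.0], 2: [0.9, 0.3], 3: [0.8, 0.9]})
        selected, _ = ck.select_tree(clusters, epsilon=0.01, seed=3)
        assert selected.constraint_flag
        assert selected.total_violation > 0

    def test_four_clone_topology_recovery(self):
        out = topology_recovery_experiment(n_seeds=10, base_seed=5)
        assert out["topology_recovered_percent"] >= 90.0


class TestExclusiveFractions:
    def test_leaf_exclusive_equals_inclusive(self):
        tree = ck.CloneTree(
            parent={1: GERMLINE, 2: 1},
            inclusive={1: np.array([1.0]), 2: np.array([0.4])},
            samples=["S1"],
        )
        excl, clipped = ck.exclusive_fractions(tree)
        assert excl[2][0] == 0.4
        assert excl[1][0] == pytest.approx(0.6)
        assert clipped == 0.0

    def test_trunk_minus_children(self):
        tree = ck.CloneTree(
            parent={1: GERMLINE, 2: 1, 3: 1},
            inclusive={1: np.array([1.0]), 2: np.array([0.6]), 3: np.array([0.3])},
            samples=["S1"],
        )
        excl, _ = ck.exclusive_fractions(tree)
        assert excl[1][0] == pytest.approx(0.1)

    def test_overshoot_clipped_and_reported(self):
        tree = ck.CloneTree(
            parent={1: GERMLINE, 2: 1},
            inclusive={1: np.array([0.95]), 2: np.array([1.0])},
            samples=["S1"],
        )
        excl, clipped = ck.exclusive_fractions(tree)
        assert excl[1][0] == 0.0
        assert clipped == pytest.approx(0.05)


class TestOracleInvariants:
    def test_selected_tree_matches_exhaustive_oracle(self):
        out = tree_oracle_experiment(n_instances=25, base_seed=42)
        assert out["oracle_agreement_percent"] == 100.0
        assert out["max_score_percent"] == 100.0
        assert out["invariants_percent"] == 100.0

    def test_newick_roundtrippable(self):
        from skbio import TreeNode
        from io import StringIO

        tree = ck.CloneTree(
            parent={1: GERMLINE, 2: 1, 3: 1},
            inclusive={1: np.array([1.0]), 2: np.array([0.6]), 3: np.array([0.3])},
            samples=["S1"],
        )
        parsed = TreeNode.read(StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == {"clone2", "clone3"}
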