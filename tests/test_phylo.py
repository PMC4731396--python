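import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from vipermorph.phylo import (
    PhyloTree,
    bm_covariance,
    bm_simulate,
    dtt,
    squared_change_parsimony,
)
from vipermorph.simulate import crotalus9_tree

from test_classify import _random_tree


class TestTreeIO:
    def test_prune_hand_example(self, tmp_path):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        pruned = tree.prune(["A", "C"])
        c = bm_covariance(pruned)
        # A's depth is unchanged (1 + 1 summed across the suppressed node)
        assert c.loc["A", "A"] == pytest.approx(2.0)
        assert c.loc["C", "C"] == pytest.approx(2.0)
        assert c.loc["A", "C"] == pytest.approx(0.0)
        assert sorted(pruned.tip_labels) == ["A", "C"]

    def test_prune_to_all_tips_is_identity(self):
        tree = crotalus9_tree()
        pruned = tree.prune(tree.tip_labels)
        pd.testing.assert_frame_equal(bm_covariance(tree), bm_covariance(pruned))

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        tree = crotalus9_tree()
        path = tmp_path / "t.nwk"
        tree.write_newick(path)
        back = PhyloTree.from_file(path)
        c1 = bm_covariance(tree, order=sorted(tree.tip_labels))
        c2 = bm_covariance(back, order=sorted(back.tip_labels))
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-9)

    def test_missing_branch_lengths_error(self):
        with pytest.raises(ValueError, match="branch length"):
            PhyloTree.from_newick("((A,B):1,C:2);")

    def test_prune_unknown_tip_error(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="unknown"):
            tree.prune(["A", "Z"])


class TestBmCovariance:
    def test_hand_tree(self):
        c = bm_covariance(PhyloTree.from_newick("((A:1,B:1):1,C:2);"))
        assert c.loc["A", "B"] == pytest.approx(1.0)
        assert c.loc["A", "C"] == pytest.approx(0.0)
        assert c.loc["A", "A"] == pytest.approx(2.0)

    def test_ultrametric_diagonal_is_tree_height(self):
        c = bm_covariance(crotalus9_tree())
        np.testing.assert_allclose(np.diag(c.to_numpy()), 1.0, atol=1e-9)

    def test_psd_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            labels = [f"t{i}" for i in range(rng.integers(3, 10))]
            c = bm_covariance(_random_tree(rng, labels)).to_numpy()
            assert np.linalg.eigvalsh(c).min() >= -1e-10


class TestSquaredChangeParsimony:
    def test_star_tree_root_is_tip_mean(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:1);")
        anc = squared_change_parsimony(tree, np.array([[1.0], [2.0], [3.0]]))
        assert anc.states.iloc[0, 0] == pytest.approx(2.0)

    def test_two_tip_inverse_length_weighting(self):
        # minimizing (r-xA)^2/a + (r-xB)^2/b gives r = (b xA + a xB)/(a+b)
        tree = PhyloTree.from_newick("(A:0.5,B:2.0);")
        anc = squared_change_parsimony(
            tree, pd.DataFrame([[1.0], [4.0]], index=["A", "B"])
        )
        expected = (2.0 * 1.0 + 0.5 * 4.0) / 2.5
        assert anc.states.iloc[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_matches_numeric_minimizer_on_random_trees(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            labels = [f"t{i}" for i in range(6)]
            tree = _random_tree(rng, labels)
            tips = pd.DataFrame(rng.standard_normal((6, 2)), index=labels)
            anc = squared_change_parsimony(tree, tips)

            internal = [n for n in tree._tree.preorder_node_iter() if not n.is_leaf()]
            ids = tree.internal_node_ids()

            def objective(flat):
                states = {id(n): flat[2 * i : 2 * i + 2] for i, n in enumerate(internal)}
                total = 0.0
                for node in tree._tree.preorder_node_iter():
                    if node.parent_node is None:
                        continue
                    parent = states[id(node.parent_node)]
                    child = (
                        tips.loc[node.taxon.label].to_numpy()
                        if node.is_leaf()
                        else states[id(node)]
                    )
                    total += np.sum((parent - child) ** 2) / node.edge.length
                return total

            x0 = np.zeros(2 * len(internal))
            opt = scipy.optimize.minimize(objective, x0, method="BFGS", tol=1e-12)
            for i, node in enumerate(internal):
                np.testing.assert_allclose(
                    anc.states.loc[ids[node]].to_numpy(),
                    opt.x[2 * i : 2 * i + 2],
                    atol=1e-6,
                )

    def test_equals_gls_brownian_reconstruction(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(7)]
        tree = _random_tree(rng, labels)
        tips = pd.DataFrame(rng.standard_normal((7, 3)), index=labels)
        anc = squared_change_parsimony(tree, tips)

        # independent GLS oracle: root by GLS, nodes via shared-path covariances
        c = bm_covariance(tree).to_numpy()
        x = tips.loc[tree.tip_labels].to_numpy()
        cinv = np.linalg.inv(c)
        one = np.ones(len(labels))
        root = (one @ cinv @ x) / (one @ cinv @ one)
        depths = tree.node_depths()
        ids = tree.internal_node_ids()
        leaf_by_label = {
            leaf.taxon.label: leaf for leaf in tree._tree.leaf_node_iter()
        }
        for node in tree._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            cov_vec = np.empty(len(labels))
            node_anc = set()
            walker = node
            while walker is not None:
                node_anc.add(id(walker))
                walker = walker.parent_node
            for i, lab in enumerate(tree.tip_labels):
                walker = leaf_by_label[lab]
                while id(walker) not in node_anc:
                    walker = walker.parent_node
                cov_vec[i] = depths[walker]
            estimate = root + cov_vec @ cinv @ (x - root[None, :])
            np.testing.assert_allclose(
                anc.states.loc[ids[node]].to_numpy(), estimate, atol=1e-8
            )

    def test_zero_length_edge_floored_with_warning(self):
        tree = PhyloTree.from_newick("((A:1,B:0):1,C:2);")
        with pytest.warns(RuntimeWarning, match="floored"):
            squared_change_parsimony(tree, np.array([[1.0], [2.0], [3.0]]))

    def test_distance_tables_shapes(self):
        tree = crotalus9_tree()
        rng = np.random.default_rng(3)
        tips = pd.DataFrame(rng.standard_normal((9, 4)), index=tree.tip_labels)
        anc = squared_change_parsimony(tree, tips)
        assert anc.node_distances.shape == (8, 8)
        assert anc.node_tip_distances.shape == (8, 9)
        assert list(anc.states.index) == list(range(10, 18))
        np.testing.assert_allclose(
            anc.node_distances.to_numpy(), anc.node_distances.to_numpy().T, atol=1e-12
        )


class TestBmSimulate:
    def test_zero_rate_gives_root_state(self):
        tree = crotalus9_tree()
        tips = bm_simulate(tree, np.zeros((3, 3)), root_state=np.array([1.0, 2.0, 3.0]), seed=0)
        np.testing.assert_allclose(tips.to_numpy(), np.tile([1.0, 2.0, 3.0], (9, 1)))

    def test_fixed_seed_reproducible(self):
        tree = crotalus9_tree()
        a = bm_simulate(tree, 0.5, root_state=np.zeros(2), seed=42)
        b = bm_simulate(tree, 0.5, root_state=np.zeros(2), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_rate_error(self):
        tree = crotalus9_tree()
        with pytest.raises(ValueError, match="positive semidefinite"):
            bm_simulate(tree, np.array([[1.0, 2.0], [2.0, 1.0]]), np.zeros(2), seed=0)


class TestDtt:
    def _tip_data(self, tree, seed=0, q=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.standard_normal((tree.n_tips, q)), index=tree.tip_labels)

    def test_root_point_is_one_and_times_scaled(self):
        tree = crotalus9_tree()
        res = dtt(tree, self._tip_data(tree), n_sim=20, seed=1)
        assert res.observed_disparity[0] == pytest.approx(1.0)
        assert res.relative_times[0] == 0.0
        assert res.relative_times[-1] == pytest.approx(1.0)
        assert np.all(np.diff(res.relative_times) > 0)

    def test_mdi_definitions_consistent_with_curves(self):
        tree = crotalus9_tree()
        res = dtt(tree, self._tip_data(tree, seed=2), n_sim=50, seed=3)
        assert res.mdi == pytest.approx(
            np.mean((res.observed_disparity - res.sim_median) ** 2)
        )
        assert res.mdi_area == pytest.approx(
            np.mean(res.observed_disparity - res.sim_median)
        )
        assert res.mdi_squared >= 0.0

    def test_invariant_to_global_rescaling(self):
        tree = crotalus9_tree()
        tips = self._tip_data(tree, seed=4)
        res1 = dtt(tree, tips, n_sim=10, seed=5)
        res2 = dtt(tree, tips * 37.0, n_sim=10, seed=5)
        np.testing.assert_allclose(
            res1.observed_disparity, res2.observed_disparity, atol=1e-10
        )
        # branch-length rescaling changes absolute, not relative, node times
        scaled = PhyloTree.from_newick(tree.to_newick())
        for edge in scaled._tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 11.0
        res3 = dtt(scaled, tips, n_sim=10, seed=5)
        np.testing.assert_allclose(res1.relative_times, res3.relative_times, atol=1e-10)

    def test_zero_disparity_error(self):
        tree = crotalus9_tree()
        tips = pd.DataFrame(np.ones((9, 2)), index=tree.tip_labels)
        with pytest.raises(ValueError, match="disparity"):
            dtt(tree, tips, n_sim=5, seed=0)

    def test_too_few_tips_error(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="3 tips"):
            dtt(tree, np.array([[0.0], [1.0]]), n_sim=5, seed=0)
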