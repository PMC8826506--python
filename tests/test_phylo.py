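"""Trait index, Brownian-motion ancestral states, and phylogenetic PCA."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from tastekit.phylo import (
    UndefinedIndexError,
    bm_ancestral_states,
    edge_trait_interpolation,
    phylo_pca,
    phylo_vcv,
    response_index,
)
from tastekit.simulate import generate_tree


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


class TestResponseIndex:
    def test_endpoints_and_worked_values(self):
        assert response_index({"s": 2.0, "a": 0.0}, ["s"], ["a"]) == 1.0
        assert response_index({"s": 1.5, "a": 1.5}, ["s"], ["a"]) == 0.0
        assert response_index({"s": 3.0, "a": 1.0}, ["s"], ["a"]) == 0.5

    def test_negative_values_clipped_before_summation(self):
        assert response_index({"s": 1.0, "a": -5.0}, ["s"], ["a"]) == 1.0

    def test_scale_invariance(self, rng):
        vals = {f"l{i}": float(v) for i, v in enumerate(rng.uniform(0, 2, 8))}
        sugars, aminos = [f"l{i}" for i in range(4)], [f"l{i}" for i in range(4, 8)]
        i1 = response_index(vals, sugars, aminos)
        i2 = response_index({k: 7.3 * v for k, v in vals.items()}, sugars, aminos)
        assert i1 == pytest.approx(i2)

    def test_bounded_on_random_profiles(self, rng):
        sugars, aminos = ["s1", "s2"], ["a1", "a2", "a3"]
        for _ in range(500):
            vals = dict(
                zip(sugars + aminos, rng.uniform(0, 5, 5))
            )
            assert -1.0 <= response_index(vals, sugars, aminos) <= 1.0

    def test_errors(self):
        with pytest.raises(UndefinedIndexError):
            response_index({"s": 0.0, "a": -1.0}, ["s"], ["a"])
        with pytest.raises(ValueError, match="both sets"):
            response_index({"s": 1.0}, ["s"], ["s"])
        with pytest.raises(KeyError):
            response_index({"s": 1.0}, ["s"], ["missing"])


class TestVCV:
    def test_three_tip_worked_example(self):
        c, labels = phylo_vcv(tree_from("((A:1,B:1):2,C:3);"))
        idx = {lab: i for i, lab in enumerate(labels)}
        a, b, cc = idx["A"], idx["B"], idx["C"]
        assert c[a, a] == pytest.approx(3.0)
        assert c[b, b] == pytest.approx(3.0)
        assert c[a, b] == pytest.approx(2.0)
        assert c[a, cc] == pytest.approx(0.0)

    def test_star_tree_is_diagonal(self):
        c, _ = phylo_vcv(tree_from("(A:2,B:2,C:2,D:2);"))
        assert np.allclose(c, 2.0 * np.eye(4))

    def test_shared_never_exceeds_total(self):
        for seed in range(5):
            tree = generate_tree(7, seed=seed, rate_sd=0.6)
            c, _ = phylo_vcv(tree)
            diag = np.diag(c)
            assert np.all(c <= np.minimum.outer(diag, diag) + 1e-12)
            assert np.allclose(c, c.T)
            assert np.all(np.linalg.eigvalsh(c) > -1e-10)


def _bruteforce_states(tree, tip_values):
    """Independent oracle: explicitly re-root a clone of the tree at
    each internal node and solve the GLS mean with a dense solve."""
    ref_internal = [
        n.label for n in tree.preorder_node_iter() if not n.is_leaf()
    ]
    states = {}
    for k, label in enumerate(ref_internal):
        clone = dendropy.Tree(tree)
        target = [
            n for n in clone.preorder_node_iter() if not n.is_leaf()
        ][k]
        if target is not clone.seed_node:
            clone.reroot_at_node(target, update_bipartitions=False)
        # shared root-to-tip path lengths on the re-rooted clone
        tips = list(clone.leaf_node_iter())
        paths = []
        for tip in tips:
            path, node = [], tip
            while node.parent_node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(set(path))
        n = len(tips)
        c = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                shared = paths[i] & paths[j]
                c[i, j] = sum(max(nd.edge.length or 0.0, 1e-9) for nd in shared)
        x = np.array([tip_values[t.taxon.label] for t in tips])
        ci = np.linalg.inv(c)
        one = np.ones(n)
        states[label] = float(one @ ci @ x) / float(one @ ci @ one)
    return states


class TestAncestralStates:
    def test_two_tip_symmetry(self):
        tree = tree_from("(A:1,B:1);")
        tm = bm_ancestral_states(tree, {"A": 0.2, "B": 0.8})
        (root_state,) = tm.node_states.values()
        assert root_state == pytest.approx(0.5)

    def test_star_tree_weighted_mean(self):
        tree = tree_from("(A:1,B:1,C:2);")
        tm = bm_ancestral_states(tree, {"A": 0.0, "B": 0.0, "C": 1.0})
        (root_state,) = tm.node_states.values()
        # GLS on a star = 1/length-weighted mean = 0.5 / 2.5
        assert root_state == pytest.approx(0.2)

    def test_matches_rerooted_gls_oracle(self, rng):
        for seed in range(10):
            tree = generate_tree(6, seed=seed, rate_sd=0.5)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            vals = dict(zip(tips, rng.normal(0, 1, len(tips))))
            tm = bm_ancestral_states(tree, vals)
            oracle = _bruteforce_states(tree, vals)
            for label, state in tm.node_states.items():
                assert state == pytest.approx(oracle[label], abs=1e-8)

    def test_invariant_to_tip_order_and_branch_rescaling(self, rng):
        tree = generate_tree(8, seed=3, rate_sd=0.4)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        vals = dict(zip(tips, rng.normal(0, 1, len(tips))))
        tm1 = bm_ancestral_states(tree, vals)
        shuffled = dict(sorted(vals.items(), key=lambda kv: kv[0], reverse=True))
        tm2 = bm_ancestral_states(tree, shuffled)
        assert tm1.node_states == pytest.approx(tm2.node_states)

        scaled = generate_tree(8, seed=3, rate_sd=0.4)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 4.0
        tm4 = bm_ancestral_states(scaled, vals)
        for label in tm1.node_states:
            assert tm4.node_states[label] == pytest.approx(tm1.node_states[label])
        assert tm4.sigma2 == pytest.approx(tm1.sigma2 / 4.0)

    def test_missing_tip_value_raises(self):
        tree = tree_from("(A:1,B:1);")
        with pytest.raises(KeyError):
            bm_ancestral_states(tree, {"A": 0.0})


class TestEdgeInterpolation:
    def test_linear_between_parent_and_child(self):
        tree = tree_from("(A:1,B:1);")
        tm = bm_ancestral_states(tree, {"A": 1.0, "B": 0.0})
        tm = edge_trait_interpolation(tree, tm, n_points=3)
        by_child = {e.child: e for e in tm.edge_samples}
        root_state = tm.node_states[next(iter(tm.node_states))]
        assert np.allclose(
            by_child["A"].states, [root_state, (root_state + 1) / 2, 1.0]
        )
        assert by_child["A"].states[0] == pytest.approx(root_state)
        assert by_child["B"].states[-1] == 0.0

    def test_constant_trait_gives_constant_samples(self):
        tree = generate_tree(5, seed=2, rate_sd=0.3)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        tm = bm_ancestral_states(tree, {t: 0.7 for t in tips})
        tm = edge_trait_interpolation(tree, tm, n_points=4)
        for e in tm.edge_samples:
            assert np.allclose(e.states, 0.7)

    def test_rejects_single_point(self):
        tree = tree_from("(A:1,B:1);")
        tm = bm_ancestral_states(tree, {"A": 0.0, "B": 1.0})
        with pytest.raises(ValueError):
            edge_trait_interpolation(tree, tm, n_points=1)


def _star_tree(n, length=1.0):
    newick = "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");"
    return tree_from(newick)


class TestPhyloPCA:
    def test_star_tree_reduces_to_ordinary_pca(self, rng):
        n, p = 9, 4
        x = pd.DataFrame(
            rng.normal(0, 1, (n, p)),
            index=[f"t{i}" for i in range(n)],
            columns=[f"trait{j}" for j in range(p)],
        )
        res = phylo_pca(_star_tree(n), x)
        assert np.allclose(res.mean.to_numpy(), x.mean(axis=0), atol=1e-10)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        ordinary = np.linalg.eigvalsh(xc.T @ xc / (n - 1))[::-1]
        assert np.allclose(res.eigenvalues, ordinary, atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, rng):
        tree = generate_tree(7, seed=5, rate_sd=0.4)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        x = pd.DataFrame(rng.normal(0, 1, (7, 5)), index=tips)
        x.columns = [f"tr{j}" for j in range(5)]
        res = phylo_pca(tree, x)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(res.evo_cov.to_numpy())
        )
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_scores_reconstruct_centered_data(self, rng):
        tree = generate_tree(8, seed=6, rate_sd=0.4)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        x = pd.DataFrame(rng.normal(0, 1, (8, 5)), index=tips)
        x.columns = [f"tr{j}" for j in range(5)]
        res = phylo_pca(tree, x)
        v = res.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(5), atol=1e-10)
        xc = x.to_numpy() - res.mean.to_numpy()
        assert np.allclose(res.scores.to_numpy() @ v.T, xc, atol=1e-10)

    def test_correlation_mode_unit_diagonal_and_constant_trait_error(self, rng):
        tree = generate_tree(6, seed=7, rate_sd=0.4)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        x = pd.DataFrame(rng.normal(0, 1, (6, 3)), index=tips)
        x.columns = ["u", "v", "w"]
        res = phylo_pca(tree, x, mode="correlation")
        assert np.allclose(np.diag(res.evo_cov), 1.0)
        x["w"] = 1.0
        with pytest.raises(ValueError, match="w"):
            phylo_pca(tree, x, mode="correlation")

    def test_sign_convention_deterministic(self, rng):
        tree = generate_tree(6, seed=8, rate_sd=0.4)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        x = pd.DataFrame(rng.normal(0, 1, (6, 3)), index=tips)
        x.columns = ["u", "v", "w"]
        res = phylo_pca(tree, x)
        for j in range(3):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0
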