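"""Continuous-trait phylogenetics: response index, Brownian-motion
ancestral states, edge interpolation, and phylogenetic PCA.

Trees are :class:`dendropy.Tree` objects whose seed node is taken as
the root; branch lengths are in whatever units the tree carries (for
receptor work, per-branch synonymous substitution rates dS). Under
Brownian motion a trait's covariance between two tips equals the branch
length shared by their root-to-tip paths, which is all these methods
need: ancestral states are generalized-least-squares means computed
with the tree re-rooted at each internal node, and phylogenetic PCA
eigendecomposes the evolutionary (GLS-whitened) trait covariance about
the phylogenetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "TraitMap",
    "PhyloPCAResult",
    "EdgeSamples",
    "response_index",
    "phylo_vcv",
    "bm_ancestral_states",
    "edge_trait_interpolation",
    "phylo_pca",
    "ensure_node_labels",
]

#: Zero-length branches are lifted to this before matrix inversion.
BRANCH_EPS = 1e-9


class UndefinedIndexError(ValueError):
    """Sugar and amino-acid sums are both zero; the index is undefined."""


def response_index(
    profile,
    sugar_set: Sequence[str],
    amino_set: Sequence[str],
) -> float:
    """Relative sugar-to-amino-acid response index (S - A) / (S + A).

    S and A are the sums of the profile's normalized values over the
    sugar and amino-acid ligand sets, with negative values clipped to 0
    before summation, confining the index to [-1, 1]: +1 means a purely
    sugar-responsive receptor, -1 purely amino-acid-responsive.

    ``profile`` may be a :class:`~tastekit.assay.NormalizedProfile` or
    any ligand -> value mapping. The two sets must be disjoint,
    non-empty and present in the profile.
    """
    values = getattr(profile, "values", profile)
    if callable(values):  # a plain dict's bound .values method
        values = profile
    sugar_set, amino_set = set(sugar_set), set(amino_set)
    if not sugar_set or not amino_set:
        raise ValueError("sugar and amino-acid sets must be non-empty")
    overlap = sugar_set & amino_set
    if overlap:
        raise ValueError(f"ligands in both sets: {sorted(overlap)}")
    missing = (sugar_set | amino_set) - set(values)
    if missing:
        raise KeyError(f"ligands absent from profile: {sorted(missing)}")
    s = sum(max(0.0, values[name]) for name in sugar_set)
    a = sum(max(0.0, values[name]) for name in amino_set)
    if s + a == 0:
        raise UndefinedIndexError("all clipped responses are zero")
    return (s - a) / (s + a)


def _edge_len(node: dendropy.Node) -> float:
    length = node.edge.length
    if length is None:
        return 0.0
    if length < 0:
        raise ValueError("branch lengths must be non-negative")
    return max(float(length), BRANCH_EPS)


class _TreeMetrics:
    """Path-length bookkeeping for one rooted tree.

    Precomputes root distances and parent pointers so that the shared
    path length between two tips seen from any candidate root v can be
    obtained as (d(v,i) + d(v,j) - d(i,j)) / 2.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.root = tree.seed_node
        self.tips = [leaf for leaf in tree.leaf_node_iter()]
        labels = [t.taxon.label if t.taxon else None for t in self.tips]
        if any(lab is None for lab in labels):
            raise ValueError("every tip must carry a taxon label")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        self.tip_labels = labels

        self.rd: dict = {self.root: 0.0}
        self.parent: dict = {self.root: None}
        for node in tree.preorder_node_iter():
            if node is self.root:
                continue
            self.parent[node] = node.parent_node
            self.rd[node] = self.rd[node.parent_node] + _edge_len(node)
        self._anc_cache: dict = {}

    def ancestors(self, node: dendropy.Node) -> dict:
        cached = self._anc_cache.get(node)
        if cached is None:
            cached = {}
            cur = node
            while cur is not None:
                cached[cur] = self.rd[cur]
                cur = self.parent[cur]
            self._anc_cache[node] = cached
        return cached

    def mrca_depth(self, u: dendropy.Node, v: dendropy.Node) -> float:
        anc_u = self.ancestors(u)
        cur = v
        while cur is not None:
            if cur in anc_u:
                return self.rd[cur]
            cur = self.parent[cur]
        raise RuntimeError("nodes share no ancestor")  # pragma: no cover

    def dist(self, u: dendropy.Node, v: dendropy.Node) -> float:
        return self.rd[u] + self.rd[v] - 2.0 * self.mrca_depth(u, v)

    def vcv(self, order: Sequence[str] | None = None) -> tuple[np.ndarray, list]:
        """Tip variance-covariance matrix seen from the seed root."""
        if order is None:
            order = self.tip_labels
        by_label = dict(zip(self.tip_labels, self.tips))
        missing = [lab for lab in order if lab not in by_label]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        tips = [by_label[lab] for lab in order]
        n = len(tips)
        c = np.empty((n, n))
        for i in range(n):
            c[i, i] = self.rd[tips[i]]
            for j in range(i + 1, n):
                c[i, j] = c[j, i] = self.mrca_depth(tips[i], tips[j])
        return c, list(order)

    def vcv_from(self, v: dendropy.Node) -> np.ndarray:
        """Tip covariance with the tree re-rooted at node v: shared
        path length from v, computed from unrooted path distances."""
        n = len(self.tips)
        dv = np.array([self.dist(v, t) for t in self.tips])
        c = np.empty((n, n))
        for i in range(n):
            c[i, i] = dv[i]
            for j in range(i + 1, n):
                dij = self.dist(self.tips[i], self.tips[j])
                c[i, j] = c[j, i] = 0.5 * (dv[i] + dv[j] - dij)
        return c


def phylo_vcv(
    tree: dendropy.Tree, order: Sequence[str] | None = None
) -> tuple[np.ndarray, list]:
    """Brownian-motion variance-covariance matrix of the tree's tips.

    ``C[i, j]`` is the branch length shared by the root-to-i and
    root-to-j paths; the diagonal holds root-to-tip distances. Returns
    (C, tip label order). ``order`` selects/fixes the label order.
    """
    return _TreeMetrics(tree).vcv(order)


def _gls_mean(c: np.ndarray, x: np.ndarray) -> float:
    cf = linalg.cho_factor(c)
    ones = np.ones(c.shape[0])
    ci_one = linalg.cho_solve(cf, ones)
    ci_x = linalg.cho_solve(cf, x)
    return float(ones @ ci_x) / float(ones @ ci_one)


@dataclass
class EdgeSamples:
    """Interpolated trait states along one edge, parent to child."""

    parent: str
    child: str
    fractions: np.ndarray  # positions in [0, 1] from the parent
    states: np.ndarray


@dataclass
class TraitMap:
    """A continuous trait on a tree: observed tip values, ML internal
    states under Brownian motion, the ML rate sigma2 (trait^2 per unit
    branch length), and optional per-edge interpolated samples."""

    tip_values: dict
    node_states: dict
    sigma2: float
    edge_samples: list = field(default_factory=list)

    def state(self, label: str) -> float:
        if label in self.tip_values:
            return self.tip_values[label]
        return self.node_states[label]


def ensure_node_labels(tree: dendropy.Tree) -> None:
    """Assign labels n0, n1, ... (preorder) to unlabeled internal nodes."""
    used = {n.label for n in tree.preorder_node_iter() if n.label}
    used |= {t.taxon.label for t in tree.leaf_node_iter() if t.taxon}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label:
            continue
        while f"n{i}" in used:
            i += 1
        node.label = f"n{i}"
        used.add(node.label)


def bm_ancestral_states(
    tree: dendropy.Tree, tip_values: Mapping[str, float]
) -> TraitMap:
    """Maximum-likelihood ancestral states of a continuous trait under
    Brownian motion.

    Each internal node's state is the GLS estimate of the phylogenetic
    mean with the tree re-rooted at that node — the standard ML point
    reconstruction under BM. The rate is the ML estimator
    sigma2 = (x - a)' C^-1 (x - a) / n with C taken at the original
    root. Zero-length branches are lifted by 1e-9 before inversion.
    Unlabeled internal nodes are labeled in place (n0, n1, ...).
    """
    metrics = _TreeMetrics(tree)
    labels = metrics.tip_labels
    if len(labels) < 2:
        raise ValueError("need at least 2 tips")
    missing = [lab for lab in labels if lab not in tip_values]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")
    x = np.array([float(tip_values[lab]) for lab in labels])

    ensure_node_labels(tree)
    try:
        c_root, _ = metrics.vcv(labels)
        root_hat = _gls_mean(c_root, x)
        node_states = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node is metrics.root:
                node_states[node.label] = root_hat
            else:
                node_states[node.label] = _gls_mean(metrics.vcv_from(node), x)
        cf = linalg.cho_factor(c_root)
        resid = x - root_hat
        sigma2 = float(resid @ linalg.cho_solve(cf, resid)) / len(x)
    except linalg.LinAlgError as err:  # pragma: no cover - degenerate trees
        raise np.linalg.LinAlgError(
            f"singular phylogenetic covariance ({len(labels)} tips; "
            f"min branch length {min(_edge_len(n) for n in tree.preorder_node_iter() if n.parent_node)}): {err}"
        ) from err

    return TraitMap(
        tip_values={lab: float(tip_values[lab]) for lab in labels},
        node_states=node_states,
        sigma2=sigma2,
    )


def edge_trait_interpolation(
    tree: dendropy.Tree, trait_map: TraitMap, n_points: int = 25
) -> TraitMap:
    """Fill ``trait_map.edge_samples`` with linear interpolation between
    parent and child states at ``n_points`` equally spaced positions
    (fraction 0 = parent, 1 = child) on every edge."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    samples = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        p_label = parent.label if parent.label else parent.taxon.label
        c_label = node.taxon.label if node.is_leaf() else node.label
        p_state = trait_map.state(p_label)
        c_state = trait_map.state(c_label)
        frac = np.linspace(0.0, 1.0, n_points)
        samples.append(
            EdgeSamples(p_label, c_label, frac, p_state + frac * (c_state - p_state))
        )
    trait_map.edge_samples = samples
    return trait_map


@dataclass
class PhyloPCAResult:
    """Phylogenetic PCA decomposition.

    ``mean`` is the GLS phylogenetic mean per trait, ``evo_cov`` the
    evolutionary covariance (or correlation) matrix, ``eigenvalues``
    descending, ``loadings`` unit-norm columns with a deterministic
    sign (largest-magnitude entry positive), and ``scores`` the
    projections (X - 1 a') V indexed by taxon.
    """

    mean: pd.Series
    evo_cov: pd.DataFrame
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    mode: str


def phylo_pca(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    mode: str = "covariance",
) -> PhyloPCAResult:
    """Phylogenetic principal components analysis.

    The phylogenetic mean a = (1'C^-1 1)^-1 1'C^-1 X and evolutionary
    covariance R = (X - 1a')' C^-1 (X - 1a') / (n - 1) replace the
    ordinary mean and covariance, discounting resemblance due to shared
    ancestry; components are eigenvectors of R (rescaled to unit
    diagonal in ``correlation`` mode) and scores are ordinary
    projections of the mean-centered data.

    ``traits`` is a taxa x traits DataFrame whose index matches the
    tree's tip labels; missing values are not allowed.
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    if traits.shape[1] < 2:
        raise ValueError("need >= 2 traits")
    if traits.isna().any().any():
        raise ValueError("missing trait values are not allowed")
    c, order = phylo_vcv(tree, list(traits.index))
    x = traits.to_numpy(dtype=float)
    n = x.shape[0]

    cf = linalg.cho_factor(c)
    ones = np.ones(n)
    ci_one = linalg.cho_solve(cf, ones)
    a = (ones @ linalg.cho_solve(cf, x)) / (ones @ ci_one)
    xc = x - a
    r = xc.T @ linalg.cho_solve(cf, xc) / (n - 1)

    if mode == "correlation":
        d = np.sqrt(np.diag(r))
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            names = [traits.columns[i] for i in bad]
            raise ValueError(f"constant trait(s) in correlation mode: {names}")
        r = r / np.outer(d, d)

    evals, vecs = linalg.eigh(r)
    idx = np.argsort(evals)[::-1]
    evals, vecs = evals[idx], vecs[:, idx]
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = xc @ vecs

    comp_names = [f"PC{j + 1}" for j in range(vecs.shape[1])]
    return PhyloPCAResult(
        mean=pd.Series(a, index=traits.columns, name="phylogenetic_mean"),
        evo_cov=pd.DataFrame(r, index=traits.columns, columns=traits.columns),
        eigenvalues=evals,
        loadings=pd.DataFrame(vecs, index=traits.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=traits.index, columns=comp_names),
        mode=mode,
    )
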