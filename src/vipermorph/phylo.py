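"""Phylogenetic machinery: trees, Brownian covariance, ancestral shapes, DTT.

A rooted, branch-length tree over group labels supplies (a) the Brownian
covariance matrix used for phylogenetically informed classification
priors, (b) weighted squared-change-parsimony ancestral shape estimates,
(c) multivariate Brownian simulation, and (d) disparity-through-time
curves with simulation envelopes and the morphological disparity index.

Newick parsing and tree surgery are delegated to dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "AncestralStates",
    "DTTResult",
    "read_newick",
    "bm_covariance",
    "squared_change_parsimony",
    "bm_simulate",
    "dtt",
]

_MIN_EDGE = 1e-12


class PhyloTree:
    """A rooted tree with positive branch lengths over group labels.

    Internal nodes are numbered ``k+1, k+2, ...`` in preorder (the root
    first), after the ``k`` tips numbered ``1..k`` in leaf order — the
    usual numbering for ancestral-state tables.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.seed_node.edge.length = None  # root edge carries no time
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges with missing branch lengths")
            if edge.length < 0:
                raise ValueError("tree has negative branch lengths")
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels are not unique")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string (or the contents of a file via read_newick)."""
        tree = dendropy.Tree.get(data=source, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    def to_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
            + "\n"
        )

    # -- basic structure ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def prune(self, keep: list[str]) -> "PhyloTree":
        """Keep only the named tips, suppressing degree-2 nodes.

        Branch lengths across suppressed nodes are summed, so root-to-tip
        depths of the kept tips are unchanged.
        """
        tips = set(self.tip_labels)
        missing = set(keep) - tips
        if missing:
            raise ValueError(f"keep set contains unknown tips: {sorted(missing)}")
        clone = dendropy.Tree(self._tree)
        clone.retain_taxa_with_labels(list(keep))
        return PhyloTree(clone)

    def node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def internal_node_ids(self) -> dict[dendropy.Node, int]:
        """Preorder numbering of internal nodes starting at n_tips + 1."""
        ids = {}
        next_id = self.n_tips + 1
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf():
                ids[node] = next_id
                next_id += 1
        return ids

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_tips} tips: {', '.join(self.tip_labels)})"


def read_newick(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    return PhyloTree.from_file(path)


def bm_covariance(
    tree: PhyloTree, order: list[str] | None = None
) -> pd.DataFrame:
    """Brownian trait covariance among tips.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j
    (the diagonal is root-to-tip depth); symmetric positive semidefinite.
    """
    labels = order if order is not None else tree.tip_labels
    depths = tree.node_depths()
    leaf_by_label = {leaf.taxon.label: leaf for leaf in tree._tree.leaf_node_iter()}
    missing = set(labels) - set(leaf_by_label)
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    # ancestors (including self) of each requested leaf, for MRCA lookup
    anc: dict[str, list[dendropy.Node]] = {}
    for lab in labels:
        chain = []
        node = leaf_by_label[lab]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[lab] = chain
    k = len(labels)
    c = np.zeros((k, k))
    for i, a in enumerate(labels):
        set_a = set(id(n) for n in anc[a])
        c[i, i] = depths[leaf_by_label[a]]
        for j in range(i + 1, k):
            mrca = next(n for n in anc[labels[j]] if id(n) in set_a)
            c[i, j] = c[j, i] = depths[mrca]
    return pd.DataFrame(c, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# squared-change parsimony
# ---------------------------------------------------------------------------


@dataclass
class AncestralStates:
    """Weighted squared-change-parsimony ancestral estimates.

    ``states`` is indexed by internal node id; ``node_distances`` holds
    Euclidean distances among ancestral states and ``node_tip_distances``
    between ancestral states and tip values.
    """

    states: pd.DataFrame
    node_distances: pd.DataFrame
    node_tip_distances: pd.DataFrame

    def to_csv(self, states_path, distances_path=None) -> None:
        self.states.to_csv(states_path, float_format="%.10g")
        if distances_path is not None:
            self.node_distances.to_csv(distances_path, float_format="%.10g")


def squared_change_parsimony(
    tree: PhyloTree, tip_values: pd.DataFrame | np.ndarray, labels: list[str] | None = None
) -> AncestralStates:
    """Ancestral states minimizing branch-length-weighted squared change.

    Minimizes ``sum over edges of |Delta state|^2 / length`` over the
    internal-node states, coordinate by coordinate — the exact solution
    of the sparse linear system, which coincides with the generalized
    least squares (Brownian motion) reconstruction.  Zero-length edges
    are floored at 1e-12 with a warning.
    """
    if isinstance(tip_values, pd.DataFrame):
        values = tip_values
    else:
        arr = np.atleast_2d(np.asarray(tip_values, float))
        if labels is None:
            labels = tree.tip_labels
        values = pd.DataFrame(arr, index=labels)
    missing = set(tree.tip_labels) - set(values.index)
    if missing:
        raise ValueError(f"tip values missing for: {sorted(missing)}")
    q = values.shape[1]

    internal = [n for n in tree._tree.preorder_node_iter() if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)
    a_mat = np.zeros((m, m))
    b_mat = np.zeros((m, q))
    floored = False
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        if length < _MIN_EDGE:
            length = _MIN_EDGE
            floored = True
        w = 1.0 / length
        pi = idx[id(node.parent_node)]
        if node.is_leaf():
            x = values.loc[node.taxon.label].to_numpy(float)
            a_mat[pi, pi] += w
            b_mat[pi] += w * x
        else:
            ci = idx[id(node)]
            a_mat[pi, pi] += w
            a_mat[ci, ci] += w
            a_mat[pi, ci] -= w
            a_mat[ci, pi] -= w
    if floored:
        warnings.warn(
            "zero-length edges floored at 1e-12 for squared-change parsimony",
            RuntimeWarning,
            stacklevel=2,
        )
    states = np.linalg.solve(a_mat, b_mat)

    ids = tree.internal_node_ids()
    node_index = [ids[n] for n in internal]
    states_df = pd.DataFrame(states, index=node_index, columns=values.columns)
    states_df = states_df.sort_index()

    def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt(np.einsum("ijq,ijq->ij", diff, diff))

    s_arr = states_df.to_numpy()
    tips_arr = values.loc[tree.tip_labels].to_numpy(float)
    node_distances = pd.DataFrame(
        _dist(s_arr, s_arr), index=states_df.index, columns=states_df.index
    )
    node_tip = pd.DataFrame(
        _dist(s_arr, tips_arr), index=states_df.index, columns=tree.tip_labels
    )
    return AncestralStates(states_df, node_distances, node_tip)


# ---------------------------------------------------------------------------
# Brownian simulation
# ---------------------------------------------------------------------------


def _psd_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -1e-8 * max(1.0, abs(vals.max())):
        raise ValueError(f"{name} is not positive semidefinite")
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def bm_simulate(
    tree: PhyloTree,
    rate: np.ndarray | float,
    root_state: np.ndarray | float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_traits: int | None = None,
) -> pd.DataFrame:
    """Simulate tip values under multivariate Brownian motion.

    Tip values are multivariate normal with mean the root state and
    covariance ``C (x) R`` — the Kronecker product of the tree's shared
    path-length matrix and the trait rate matrix ``R`` (symmetric PSD;
    a scalar is taken as ``sigma^2 I``).
    """
    c = bm_covariance(tree)
    labels = list(c.index)
    rate_arr = np.asarray(rate, float)
    if rate_arr.ndim == 0:
        if n_traits is None:
            n_traits = np.atleast_1d(np.asarray(root_state, float)).size
        rate_arr = rate_arr * np.eye(n_traits)
    q = rate_arr.shape[0]
    root = np.broadcast_to(np.atleast_1d(np.asarray(root_state, float)), (q,))
    l_c = _psd_sqrt(c.to_numpy(), "tree covariance")
    l_r = _psd_sqrt(rate_arr, "rate matrix")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(labels), q))
    tips = root[None, :] + l_c @ z @ l_r.T
    return pd.DataFrame(tips, index=labels)


# ---------------------------------------------------------------------------
# disparity through time
# ---------------------------------------------------------------------------


@dataclass
class DTTResult:
    """Observed and simulated relative-disparity curves plus MDI.

    ``mdi`` is, by default, the mean squared difference between the
    observed curve and the simulation median ("squared" mode); the
    signed area convention (mean of observed minus median) is also
    computed as ``mdi_area``.
    """

    relative_times: np.ndarray
    observed_disparity: np.ndarray
    sim_median: np.ndarray
    sim_lo: np.ndarray
    sim_hi: np.ndarray
    mdi: float
    mdi_squared: float
    mdi_area: float
    mdi_mode: str
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_time": self.relative_times,
                "observed": self.observed_disparity,
                "sim_median": self.sim_median,
                "sim_lo": self.sim_lo,
                "sim_hi": self.sim_hi,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _mean_sq_pairwise(x: np.ndarray) -> float:
    """Mean squared pairwise Euclidean distance (0 for singletons)."""
    n = x.shape[0]
    if n < 2:
        return 0.0
    centered = x - x.mean(axis=0)
    # sum over ordered pairs of |xi - xj|^2 equals 2 n sum |xi - xbar|^2
    return float(2.0 * n * np.sum(centered**2) / (n * (n - 1)))


def _dtt_structure(tree: PhyloTree, labels: list[str]):
    """Per node time, the tip-index sets of lineages crossing that time."""
    pos = {lab: i for i, lab in enumerate(labels)}
    depths = tree.node_depths()
    leaf_sets: dict[int, np.ndarray] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            leaf_sets[id(node)] = np.array([pos[node.taxon.label]])
        else:
            leaf_sets[id(node)] = np.concatenate(
                [leaf_sets[id(ch)] for ch in node.child_nodes()]
            )
    internal_depths = sorted(
        {depths[n] for n in tree._tree.preorder_node_iter() if not n.is_leaf()}
    )
    times = []
    memberships: list[list[np.ndarray]] = []
    for t in internal_depths:
        if t == internal_depths[0]:  # root: the whole tree is one clade
            times.append(t)
            memberships.append([np.arange(len(labels))])
            continue
        lineages = []
        for node in tree._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if depths[node.parent_node] <= t < depths[node]:
                lineages.append(leaf_sets[id(node)])
        times.append(t)
        memberships.append(lineages)
    max_t = max(times)
    rel = np.array(times) / max_t if max_t > 0 else np.zeros(len(times))
    return rel, memberships


def _dtt_curve(tips: np.ndarray, memberships: list[list[np.ndarray]]) -> np.ndarray:
    total = _mean_sq_pairwise(tips)
    if total <= 0:
        raise ValueError("zero total disparity among tip values")
    return np.array(
        [
            np.mean([_mean_sq_pairwise(tips[idx]) for idx in lineages]) / total
            for lineages in memberships
        ]
    )


def estimate_bm_rate(tree: PhyloTree, tip_values: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimate of the Brownian rate matrix and root state from tips.

    Equivalent to the phylogenetically independent contrasts estimator:
    ``R = (X - 1 a)' C^{-1} (X - 1 a) / (k - 1)`` with the GLS root
    ``a``.
    """
    c = bm_covariance(tree).to_numpy()
    x = tip_values.loc[tree.tip_labels].to_numpy(float)
    k = x.shape[0]
    cinv = np.linalg.inv(c)
    one = np.ones(k)
    root = (one @ cinv @ x) / (one @ cinv @ one)
    d = x - root[None, :]
    r = d.T @ cinv @ d / (k - 1)
    return (r + r.T) / 2, root


def dtt(
    tree: PhyloTree,
    tip_values: pd.DataFrame | np.ndarray,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
    mdi_mode: str = "squared",
) -> DTTResult:
    """Disparity-through-time with a Brownian simulation envelope.

    Disparity of a tip set is the mean squared pairwise Euclidean
    distance among its members (singletons contribute 0).  At each
    internal-node time (rescaled to [0, 1] from root to the most recent
    divergence) the relative disparity is the mean over lineages
    crossing that time of their subclade disparity divided by the
    whole-tree disparity; the curve starts at 1 at the root.  The
    envelope (pointwise median and 95% limits) comes from ``n_sim``
    Brownian simulations with the rate matrix estimated from the tip
    data; MDI summarizes the observed curve's deviation from the
    simulation median.
    """
    if tree.n_tips < 3:
        raise ValueError("DTT needs at least 3 tips")
    if isinstance(tip_values, pd.DataFrame):
        values = tip_values
    else:
        arr = np.atleast_2d(np.asarray(tip_values, float))
        values = pd.DataFrame(arr, index=labels if labels is not None else tree.tip_labels)
    order = tree.tip_labels
    tips = values.loc[order].to_numpy(float)

    rel_times, memberships = _dtt_structure(tree, order)
    observed = _dtt_curve(tips, memberships)

    rate, root = estimate_bm_rate(tree, values)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(rel_times)))
    c = bm_covariance(tree).to_numpy()
    l_c = _psd_sqrt(c, "tree covariance")
    l_r = _psd_sqrt(rate, "rate matrix")
    q = rate.shape[0]
    for s in range(n_sim):
        z = rng.standard_normal((len(order), q))
        sims[s] = _dtt_curve(root[None, :] + l_c @ z @ l_r.T, memberships)
    median = np.median(sims, axis=0)
    lo = np.percentile(sims, 2.5, axis=0)
    hi = np.percentile(sims, 97.5, axis=0)
    mdi_squared = float(np.mean((observed - median) ** 2))
    mdi_area = float(np.mean(observed - median))
    if mdi_mode not in ("squared", "area"):
        raise ValueError("mdi_mode must be 'squared' or 'area'")
    mdi = mdi_squared if mdi_mode == "squared" else mdi_area
    return DTTResult(
        rel_times, observed, median, lo, hi, mdi, mdi_squared, mdi_area, mdi_mode, n_sim
    )
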