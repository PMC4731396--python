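"""Bayesian posterior classification of specimens to groups.

Each specimen's shape vector is scored against every group's
multivariate normal density with the group centroid and the pooled
within-group covariance; posteriors combine the densities with either
equal priors or phylogenetically informed priors built from Brownian
covariances on the group tree.  Distinctness of a group is summarized
by whether the interquartile range of its members' correct-assignment
posteriors overlaps the IQR of any alternative assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .phylo import PhyloTree, bm_covariance

__all__ = [
    "equal_priors",
    "phylo_priors",
    "PosteriorTable",
    "posterior_classify",
    "DistinctnessReport",
    "iqr_distinctness",
]


def equal_priors(groups: list[str] | int) -> pd.Series:
    """Uniform prior over k groups."""
    if isinstance(groups, int):
        labels = [str(i) for i in range(groups)]
    else:
        labels = [str(g) for g in groups]
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    return pd.Series(np.full(k, 1.0 / k), index=labels)


def phylo_priors(tree: PhyloTree, designation: str) -> pd.Series:
    """Phylogenetically informed prior for a specimen designated ``j``.

    The prior weight of hypothetical group ``k`` is the Brownian
    covariance between ``j`` and ``k`` (shared root-to-MRCA path
    length; the diagonal is the root-to-tip depth of ``j``), normalized
    to sum to 1 over the hypothetical groups.  Shared path length — not
    raw patristic distance — is the covariance under Brownian motion,
    so closer relatives of ``j`` receive larger priors, as intended.

    On a star tree all off-diagonal covariances vanish and the prior
    degenerates to an indicator on ``j``; this is flagged with a
    warning.
    """
    c = bm_covariance(tree)
    if designation not in c.index:
        raise ValueError(f"designation {designation!r} is not a tip of the tree")
    row = c.loc[designation]
    total = row.sum()
    if total <= 0:
        raise ValueError("tree has zero depth; priors undefined")
    prior = row / total
    off = row.drop(designation)
    if len(off) and np.allclose(off.to_numpy(), 0.0):
        warnings.warn(
            f"star-tree degeneracy: phylogenetic prior for {designation!r} "
            "is an indicator on the designation itself",
            RuntimeWarning,
            stacklevel=2,
        )
    return prior


@dataclass
class PosteriorTable:
    """Posterior assignment probabilities and per-group quartile summaries."""

    posterior: pd.DataFrame  # n x k, rows sum to 1
    true_groups: pd.Series  # specimen designations
    quartiles: pd.DataFrame  # (true, assigned) -> Q1, median, Q3
    n_components: int  # dimensionality used for the densities

    def assigned(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)

    def accuracy(self) -> float:
        return float((self.assigned().to_numpy() == self.true_groups.to_numpy()).mean())

    def to_csv(self, posterior_path, quartiles_path=None) -> None:
        self.posterior.to_csv(posterior_path, float_format="%.10g")
        if quartiles_path is not None:
            self.quartiles.to_csv(quartiles_path, float_format="%.10g")


def _prior_matrix(
    priors: pd.Series | pd.DataFrame | np.ndarray | dict,
    groups: list[str],
    designations: pd.Series,
) -> np.ndarray:
    """Normalize the accepted prior formats to an n x k matrix."""
    n = len(designations)
    k = len(groups)
    if isinstance(priors, dict):
        mat = np.vstack(
            [np.asarray(pd.Series(priors[d]).reindex(groups), float) for d in designations]
        )
    elif isinstance(priors, pd.DataFrame):
        mat = priors.reindex(columns=groups).to_numpy(float)
    elif isinstance(priors, pd.Series):
        mat = np.tile(priors.reindex(groups).to_numpy(float), (n, 1))
    else:
        arr = np.asarray(priors, float)
        mat = np.tile(arr, (n, 1)) if arr.ndim == 1 else arr
    if mat.shape != (n, k):
        raise ValueError(f"priors have shape {mat.shape}, expected ({n}, {k})")
    if np.any(mat < -1e-15):
        raise ValueError("negative prior probabilities")
    sums = mat.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("prior rows must sum to 1")
    return np.clip(mat, 0.0, None)


def posterior_classify(
    Y: np.ndarray,
    groups: pd.Series | list[str],
    priors: pd.Series | pd.DataFrame | np.ndarray | dict | None = None,
    var_tol: float = 1e-10,
) -> PosteriorTable:
    """Posterior probabilities of group membership from normal densities.

    ``Pr(k | y) = Pr(y | k) Pr(k) / sum_k Pr(y | k) Pr(k)`` with
    ``Pr(y | k)`` the multivariate normal density at the group-k
    centroid with the pooled within-group covariance, evaluated in log
    space for stability.  Because the covariance is pooled, any density
    normalization constant cancels in the posterior.

    Procrustes tangent data are rank-deficient, so the data are first
    projected onto the principal components of the pooled within-group
    scatter, retaining at most ``min(q, n - k)`` components whose
    eigenvalues exceed ``var_tol`` relative to the largest.

    ``priors`` may be a single probability vector (shared by all
    specimens), an ``n x k`` matrix / DataFrame, or a dict mapping each
    designation to its prior vector (the phylogenetically informed
    case, where a specimen's prior depends on its current designation).
    ``None`` means equal priors.  A group with zero prior receives
    exactly zero posterior regardless of its density.
    """
    y = np.asarray(Y, float)
    designations = pd.Series(groups).astype(str).reset_index(drop=True)
    labels = sorted(designations.unique())
    n, q = y.shape
    k = len(labels)
    counts = designations.value_counts()
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise ValueError(f"groups with fewer than 2 members: {small}")
    if priors is None:
        priors = equal_priors(labels)
    prior_mat = _prior_matrix(priors, labels, designations)

    grand = y.mean(axis=0)
    yc = y - grand
    centroids = np.vstack(
        [yc[(designations == g).to_numpy()].mean(axis=0) for g in labels]
    )
    within = np.zeros((q, q))
    for gi, g in enumerate(labels):
        block = yc[(designations == g).to_numpy()] - centroids[gi]
        within += block.T @ block
    eigvals, eigvecs = np.linalg.eigh(within)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > var_tol * max(eigvals[0], 1e-300)
    r = int(min(keep.sum(), q, n - k))
    if r < 1:
        raise ValueError(
            "pooled within-group covariance has no usable variance; "
            "check for duplicated specimens or provide more data"
        )
    basis = eigvecs[:, :r]
    z = yc @ basis
    mu = centroids @ basis
    cw = np.zeros((r, r))
    for gi, g in enumerate(labels):
        block = z[(designations == g).to_numpy()] - mu[gi]
        cw += block.T @ block
    cw /= n - k
    try:
        chol = cho_factor(cw)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-group covariance is singular after reduction; "
            "lower var_tol or reduce dimensionality further"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))

    log_density = np.empty((n, k))
    for gi in range(k):
        diff = z - mu[gi]
        maha = np.einsum("nq,nq->n", diff, cho_solve(chol, diff.T).T)
        log_density[:, gi] = -0.5 * (maha + logdet + r * np.log(2.0 * np.pi))
    with np.errstate(divide="ignore"):
        log_post = log_density + np.log(prior_mat)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    posterior = np.exp(log_post)
    posterior[prior_mat == 0.0] = 0.0
    post_df = pd.DataFrame(posterior, columns=labels)
    quartiles = _quartile_table(post_df, designations)
    return PosteriorTable(post_df, designations, quartiles, r)


def _quartile_table(posterior: pd.DataFrame, truth: pd.Series) -> pd.DataFrame:
    """Q1/median/Q3 of Pr(assigned | y) within each true group.

    Quartiles use linear interpolation (the "type 7" convention).
    Groups with fewer than 4 specimens are marked not evaluable (NaN).
    """
    rows = []
    for true_g in posterior.columns:
        block = posterior[(truth == true_g).to_numpy()]
        evaluable = len(block) >= 4
        for assigned in posterior.columns:
            if evaluable:
                q1, med, q3 = np.percentile(block[assigned], [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append(
                {
                    "true": true_g,
                    "assigned": assigned,
                    "Q1": q1,
                    "median": med,
                    "Q3": q3,
                    "n": len(block),
                    "evaluable": evaluable,
                }
            )
    return pd.DataFrame(rows).set_index(["true", "assigned"])


@dataclass
class DistinctnessReport:
    """Per-group distinctness from IQR overlap of posterior probabilities."""

    per_group: pd.DataFrame  # distinct flag (or not evaluable) per true group
    overlaps: pd.DataFrame  # per (true, alternative) overlap + reciprocal flag

    def to_csv(self, path) -> None:
        self.overlaps.to_csv(path)


def iqr_distinctness(table: PosteriorTable) -> DistinctnessReport:
    """Flag groups whose correct-assignment IQR overlaps no alternative.

    For true group j, the IQR of Pr(j | y) among j's specimens is
    compared with the IQR of Pr(k | y) for every alternative k; j is
    distinct iff no alternative IQR overlaps it.  An overlap is marked
    reciprocal when it also appears in the reverse comparison (group k's
    specimens overlapping toward j) — the signature of mutual
    misassignment between a pair.
    """
    quart = table.quartiles
    labels = list(table.posterior.columns)

    def iqr(true_g: str, assigned: str) -> tuple[float, float]:
        row = quart.loc[(true_g, assigned)]
        return float(row["Q1"]), float(row["Q3"])

    def overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
        return a[0] <= b[1] and b[0] <= a[1]

    evaluable = {g: bool(quart.loc[(g, g), "evaluable"]) for g in labels}
    raw_overlap: dict[tuple[str, str], bool] = {}
    for j in labels:
        if not evaluable[j]:
            continue
        own = iqr(j, j)
        for k in labels:
            if k == j:
                continue
            raw_overlap[(j, k)] = overlap(own, iqr(j, k))

    overlap_rows = []
    for (j, k), ov in raw_overlap.items():
        overlap_rows.append(
            {
                "true": j,
                "alternative": k,
                "overlap": ov,
                "reciprocal": ov and raw_overlap.get((k, j), False),
            }
        )
    overlaps = pd.DataFrame(
        overlap_rows, columns=["true", "alternative", "overlap", "reciprocal"]
    ).set_index(["true", "alternative"])

    group_rows = []
    for j in labels:
        if not evaluable[j]:
            group_rows.append({"group": j, "distinct": pd.NA, "status": "not evaluable"})
        else:
            distinct = not any(raw_overlap[(j, k)] for k in labels if k != j)
            group_rows.append(
                {"group": j, "distinct": distinct, "status": "evaluated"}
            )
    per_group = pd.DataFrame(group_rows).set_index("group")
    return DistinctnessReport(per_group, overlaps)
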