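"""Morphological integration of the dorsal and lateral views.

Two-block partial least squares tests whether the two views covary
enough to be treated as integrated subsets of a single head shape; the
separate-subsets combination then merges both residual vectors into one
shape vector with unit combined centroid size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlsResult", "CombinedShape", "two_block_pls", "combine_subsets"]


@dataclass
class PlsResult:
    """First-axis correlation and permutation test of a two-block PLS."""

    r_pls: float
    p_value: float
    singular_values: np.ndarray
    n_permutations: int


def _first_axis_r(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    cross = x.T @ y / (x.shape[0] - 1)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    scores_x = x @ u[:, 0]
    scores_y = y @ vt[0]
    denom = scores_x.std() * scores_y.std()
    if denom == 0:
        return 0.0, s
    r = float(np.corrcoef(scores_x, scores_y)[0, 1])
    return abs(r), s


def two_block_pls(
    block1: np.ndarray,
    block2: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PlsResult:
    """Two-block PLS: SVD of the between-block cross-covariance.

    ``r_pls`` is the Pearson correlation of the first left/right singular
    scores.  Significance comes from permuting the rows of ``block2``
    relative to ``block1``; the observed case counts as one of the
    ``n_perm`` permutations, so the smallest attainable P is
    ``1/n_perm``.
    """
    x = np.asarray(block1, float)
    y = np.asarray(block2, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    n = x.shape[0]
    if n < 3:
        raise ValueError("two-block PLS needs at least 3 specimens")
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    if np.allclose(x, 0) or np.allclose(y, 0):
        raise ValueError("zero-variance block")
    r_obs, s = _first_axis_r(x, y)
    rng = np.random.default_rng(seed)
    count = 1  # the observed case
    for _ in range(n_perm - 1):
        perm = rng.permutation(n)
        r_perm, _ = _first_axis_r(x, y[perm])
        if r_perm >= r_obs - 1e-12:
            count += 1
    return PlsResult(r_obs, count / n_perm, s, n_perm)


@dataclass
class CombinedShape:
    """One specimen's combined dorsal+lateral shape vector (unit centroid size)."""

    y_total: np.ndarray
    cs_dorsal: float
    cs_lateral: float

    @property
    def dorsal_weight(self) -> float:
        """Fraction of the combined squared centroid size carried by the dorsal view."""
        return self.cs_dorsal / (self.cs_dorsal + self.cs_lateral)

    @property
    def lateral_weight(self) -> float:
        return self.cs_lateral / (self.cs_dorsal + self.cs_lateral)


def combine_subsets(
    y_dorsal: np.ndarray,
    y_lateral: np.ndarray,
    cs_dorsal: float,
    cs_lateral: float,
) -> CombinedShape:
    """Separate-subsets combination of the two views into one shape vector.

    Each block is rescaled by the square root of its share of total
    centroid size, ``sqrt(CS_i / (CS_D + CS_L))``, dorsal coordinates
    first.  The squared weights are exactly the centroid-size ratios
    (``CS_D/(CS_D+CS_L)`` for the dorsal block), so given unit-centroid-
    size subset vectors the combined configuration has unit centroid
    size identically.
    """
    if cs_dorsal <= 0 or cs_lateral <= 0:
        raise ValueError("centroid sizes must be positive")
    y_d = np.asarray(y_dorsal, float).ravel()
    y_l = np.asarray(y_lateral, float).ravel()
    total = cs_dorsal + cs_lateral
    w_d = np.sqrt(cs_dorsal / total)
    w_l = np.sqrt(cs_lateral / total)
    return CombinedShape(
        np.concatenate([w_d * y_d, w_l * y_l]), float(cs_dorsal), float(cs_lateral)
    )
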