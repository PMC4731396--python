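"""Procrustes superimposition with sliding semilandmarks.

Implements the standard geometric-morphometric alignment chain for 2D
landmark configurations:

* centroid size (the square root of summed squared landmark distances
  from the configuration centroid),
* the fixed-angle correction that rotates an articulated subunit (the
  mandible) about its joint to a standard angle before superimposition,
* generalized Procrustes analysis (GPA) with proper rotations only,
  iterated with minimum-bending-energy sliding of semilandmarks along
  their curve tangents,
* orthogonal projection of aligned shapes into the tangent space at the
  mean shape, and
* thin-plate-spline (TPS) deformation grids between shapes.

Vectorized shape rows are in landmark-major order
``[x1, y1, x2, y2, ...]`` (C order of the ``(p, 2)`` coordinate array).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration

__all__ = [
    "ArticulationSpec",
    "ProcrustesResult",
    "TpsGrid",
    "centroid_size",
    "fixed_angle_align",
    "gpa",
    "tangent_project",
    "procrustes_distance",
    "bending_energy_matrix",
    "tps_warp",
]


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid.

    Invariant to translation and rotation; scales linearly under uniform
    scaling.  Raises on degenerate (all-coincident) configurations.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.linalg.norm(centered))
    if cs < 1e-12:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return cs


# ---------------------------------------------------------------------------
# fixed-angle articulation correction
# ---------------------------------------------------------------------------


@dataclass
class ArticulationSpec:
    """Landmarks defining the mandible articulation in the lateral view.

    ``pivot`` is the quadrate/articular joint; ``jaw`` the set of landmark
    indices belonging to the mandible (rotated as a rigid unit);
    ``reference`` a cranial landmark fixing the cranial ray; ``jaw_ray``
    the jaw landmark defining the mandibular ray (defaults to the first
    jaw landmark).
    """

    pivot: int
    jaw: list[int]
    reference: int
    jaw_ray: int | None = None

    def __post_init__(self) -> None:
        if not self.jaw:
            raise ValueError("jaw landmark subset is empty")
        if self.pivot in self.jaw:
            raise ValueError("pivot landmark cannot be part of the jaw subset")
        if self.reference in self.jaw:
            raise ValueError("cranial reference cannot be part of the jaw subset")
        if self.jaw_ray is None:
            self.jaw_ray = self.jaw[0]
        if self.jaw_ray not in self.jaw:
            raise ValueError("jaw_ray must be one of the jaw landmarks")


def measure_articulation_angle(
    config: LandmarkConfiguration, articulation: ArticulationSpec
) -> float:
    """Signed angle (degrees) from the cranial ray to the jaw ray at the pivot."""
    coords = config.coords
    v_ref = coords[articulation.reference] - coords[articulation.pivot]
    v_jaw = coords[articulation.jaw_ray] - coords[articulation.pivot]
    if np.linalg.norm(v_ref) < 1e-12 or np.linalg.norm(v_jaw) < 1e-12:
        raise ValueError("articulation angle undefined: ray landmark coincides with pivot")
    cross = v_ref[0] * v_jaw[1] - v_ref[1] * v_jaw[0]
    return float(np.degrees(np.arctan2(cross, np.dot(v_ref, v_jaw))))


def fixed_angle_align(
    config: LandmarkConfiguration,
    articulation: ArticulationSpec,
    target_angle_deg: float = 40.0,
) -> LandmarkConfiguration:
    """Rotate the jaw rigidly about the pivot to a standard articulation angle.

    The mandible subset is rotated so the angle between the cranial ray
    (reference -> pivot -> jaw ray) equals ``target_angle_deg`` (default
    40 degrees), on the same side of the cranial ray as observed.  All
    non-jaw landmarks are untouched and within-jaw distances are
    preserved exactly (rigid rotation).
    """
    if config.view != "lateral":
        raise ValueError("fixed-angle correction applies to the lateral view only")
    theta = measure_articulation_angle(config, articulation)
    side = 1.0 if theta >= 0 else -1.0
    delta = np.radians(side * target_angle_deg - theta)
    c, s = np.cos(delta), np.sin(delta)
    rot = np.array([[c, -s], [s, c]])
    out = config.copy()
    pivot_xy = out.coords[articulation.pivot]
    jaw = np.array(articulation.jaw, dtype=int)
    out.coords[jaw] = (out.coords[jaw] - pivot_xy) @ rot.T + pivot_xy
    return out


# ---------------------------------------------------------------------------
# GPA with bending-energy sliding
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesResult:
    """Aligned configurations, consensus, sizes and tangent coordinates."""

    aligned: np.ndarray  # (n, p, 2), unit centroid size each
    mean_shape: np.ndarray  # (p, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,), original units
    residual_matrix: np.ndarray  # (n, 2p) tangent coordinates
    converged: bool
    n_iterations: int
    slide_energy: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]


def _center_unit(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / np.linalg.norm(centered)


def _opa_rotation(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Proper 2D rotation R minimizing ||x @ R - ref|| (no reflection)."""
    h = x.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def bending_energy_matrix(points: np.ndarray) -> np.ndarray:
    """Bending energy matrix of a 2D configuration.

    The upper-left p x p block of the inverse of the TPS system matrix
    built on ``points`` with kernel U(r) = r^2 log r^2.  Positive
    semidefinite with the affine maps in its null space.
    """
    points = np.asarray(points, float)
    p = points.shape[0]
    diff = points[:, None, :] - points[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    q = np.column_stack([np.ones(p), points])
    lmat = np.zeros((p + 3, p + 3))
    lmat[:p, :p] = k
    lmat[:p, p:] = q
    lmat[p:, :p] = q.T
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system: collinear or duplicate landmarks") from exc
    be = linv[:p, :p]
    return (be + be.T) / 2.0


def _curve_neighbors(curves: list[list[int]], p: int) -> dict[int, tuple[int, int]]:
    nbrs: dict[int, tuple[int, int]] = {}
    for c in curves:
        for prev_i, i, next_i in zip(c[:-2], c[1:-1], c[2:]):
            nbrs[i] = (prev_i, next_i)
    return nbrs


def _slide_all(
    aligned: np.ndarray,
    mean: np.ndarray,
    be: np.ndarray,
    semi: np.ndarray,
    nbrs: dict[int, tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slide all specimens' semilandmarks along their curve tangents.

    Jointly minimizes the total bending energy of the deformations from
    ``mean``, subject to the slide magnitudes averaging to zero across
    specimens at every semilandmark.  The zero-mean constraint fixes the
    gauge freedom (all specimens sliding along the outline together
    changes nothing relative), which is what lets the GPA/sliding
    iteration converge; since the zero slide is feasible, the total
    energy never increases.  Returns the slid configurations and the
    per-specimen energies before and after.
    """
    n = aligned.shape[0]
    s = semi.size
    d = aligned - mean[None]
    e_before = np.einsum("nic,ij,njc->n", d, be, d)
    if s == 0:
        return aligned, e_before, e_before.copy()
    tangents = np.empty((n, s, 2))
    for i in range(n):
        for row, j in enumerate(semi):
            a, b = nbrs[j]
            t = aligned[i, b] - aligned[i, a]
            nrm = np.linalg.norm(t)
            tangents[i, row] = t / nrm if nrm > 1e-12 else 0.0
    # per specimen:  E_i(t) = const + 2 b_i' t + t' A_i t  along the tangents
    be_ss = be[np.ix_(semi, semi)]
    a_inv = np.empty((n, s, s))
    a_inv_b = np.empty((n, s))
    b_vecs = np.empty((n, s))
    for i in range(n):
        a_mat = np.einsum("jc,kc->jk", tangents[i], tangents[i]) * be_ss
        bd = be @ d[i]
        b_vecs[i] = np.einsum("jc,jc->j", tangents[i], bd[semi])
        try:
            a_inv[i] = np.linalg.inv(a_mat)
        except np.linalg.LinAlgError:
            a_inv[i] = np.linalg.pinv(a_mat)
        a_inv_b[i] = a_inv[i] @ b_vecs[i]
    # Lagrange multiplier for the zero-mean-slide constraint
    mu = -np.linalg.lstsq(a_inv.sum(axis=0), a_inv_b.sum(axis=0), rcond=None)[0]
    t_sol = -np.einsum("njk,nk->nj", a_inv, b_vecs + mu[None, :])
    slid = aligned.copy()
    slid[:, semi, :] += t_sol[:, :, None] * tangents
    d_new = slid - mean[None]
    e_after = np.einsum("nic,ij,njc->n", d_new, be, d_new)
    if e_after.sum() > e_before.sum() + 1e-12:  # numerical safeguard
        return aligned, e_before, e_before.copy()
    return slid, e_before, e_after


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    """Proper rotation sending the mean's major principal axis to +x.

    The axis sign is fixed by requiring positive third moment along x
    (falling back to y), making GPA output orientation deterministic and
    invariant to rotations of the input.
    """
    cov = mean.T @ mean
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    rot = np.array([[v[0], -v[1]], [v[1], v[0]]])
    rotated = mean @ rot
    skew_x = np.sum(rotated[:, 0] ** 3)
    crit = skew_x if abs(skew_x) > 1e-12 else np.sum(rotated[:, 1] ** 3)
    if crit < 0:
        rot = -rot  # rotate by a further 180 degrees (still proper)
    return rot


def gpa(
    configs: list[LandmarkConfiguration] | np.ndarray,
    curves: list[list[int]] | None = None,
    landmark_kind: np.ndarray | None = None,
    max_iter: int = 10,
    tol: float = 1e-8,
    n_slide_iter: int = 5,
) -> ProcrustesResult:
    """Generalized Procrustes analysis with bending-energy sliding.

    Iterates {align every configuration to the current consensus by
    translation, scaling and proper rotation; slide each semilandmark
    along its local curve tangent (central difference of its curve
    neighbors) to minimize the bending energy of its deformation from
    the consensus; recompute the consensus} until the consensus changes
    by less than ``tol`` or ``max_iter`` is reached.  With no declared
    semilandmarks the sliding step is a no-op and this is plain GPA.

    Non-convergence is recorded on the result (``converged=False``) with
    a warning, not an error.
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, float)
        if curves is None:
            curves = []
        if landmark_kind is None:
            landmark_kind = np.full(arr.shape[1], "fixed", dtype=object)
    else:
        if len(configs) == 0:
            raise ValueError("no configurations")
        p0 = configs[0].n_landmarks
        kinds0 = list(configs[0].landmark_kind)
        for c in configs:
            if c.n_landmarks != p0 or list(c.landmark_kind) != kinds0:
                raise ValueError("configurations differ in landmark count or kind")
        arr = np.stack([c.coords for c in configs])
        if curves is None:
            curves = configs[0].curves
        landmark_kind = np.asarray(configs[0].landmark_kind)

    n, p, _ = arr.shape
    semi = np.flatnonzero(np.asarray(landmark_kind) == "semi")
    nbrs = _curve_neighbors(curves or [], p)
    for j in semi:
        if j not in nbrs:
            raise ValueError(f"semilandmark {j} is not interior to any curve")

    centroid_sizes = np.array([centroid_size(arr[i]) for i in range(n)])
    aligned = np.stack([_center_unit(arr[i]) for i in range(n)])

    mean = aligned[0].copy()
    converged = False
    n_it = 0
    slide_energy: list[tuple[np.ndarray, np.ndarray]] = []
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ _opa_rotation(aligned[i], mean)
        if semi.size and n > 1 and n_it <= n_slide_iter:
            be = bending_energy_matrix(mean)
            aligned, e_before, e_after = _slide_all(aligned, mean, be, semi, nbrs)
            for i in range(n):
                aligned[i] = _center_unit(aligned[i])
                aligned[i] = aligned[i] @ _opa_rotation(aligned[i], mean)
            slide_energy.append((e_before, e_after))
        new_mean = _center_unit(aligned.mean(axis=0))
        new_mean = new_mean @ _opa_rotation(new_mean, mean)
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    # final alignment to the converged consensus, then canonical orientation
    for i in range(n):
        aligned[i] = aligned[i] @ _opa_rotation(aligned[i], mean)
    rot = _canonical_rotation(mean)
    mean = mean @ rot
    aligned = aligned @ rot
    residual_matrix = _project_rows(aligned.reshape(n, 2 * p), mean.reshape(-1))
    return ProcrustesResult(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=centroid_sizes,
        residual_matrix=residual_matrix,
        converged=converged,
        n_iterations=n_it,
        slide_energy=slide_energy,
    )


def _project_rows(rows: np.ndarray, mean_vec: np.ndarray) -> np.ndarray:
    m = mean_vec / np.linalg.norm(mean_vec)
    # orthogonal projection onto the tangent space at m, anchored at m:
    # y -> m + (y - m)(I - m m'); since m(I - mm') = 0 this is y + (1 - y.m) m
    return rows + np.outer(1.0 - rows @ m, m)


def tangent_project(result: ProcrustesResult) -> np.ndarray:
    """Project vectorized aligned shapes into the tangent space at the mean.

    Orthogonal projection ``y -> m + (y - m)(I - m m')`` with ``m`` the
    unit mean-shape vector; idempotent, fixes the mean shape itself.
    """
    n, p, _ = result.aligned.shape
    return _project_rows(result.aligned.reshape(n, 2 * p), result.mean_shape.reshape(-1))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the difference of tangent-space shape vectors."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("shape vectors differ in length")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# thin-plate-spline deformation grids
# ---------------------------------------------------------------------------


@dataclass
class TpsGrid:
    """A regular grid deformed by the TPS map from source to target."""

    source_shape: np.ndarray
    target_shape: np.ndarray
    grid_points: np.ndarray  # (g, 2) deformed grid
    grid_shape: tuple[int, int]
    bending_energy: float

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.grid_points, columns=["x", "y"]).to_csv(path, index=False)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r2 > 0, r2 * np.log(r2), 0.0)


def tps_warp(
    source: np.ndarray,
    target: np.ndarray,
    grid_resolution: int = 24,
    margin: float = 0.05,
) -> TpsGrid:
    """Thin-plate-spline interpolant mapping source landmarks onto target.

    Uses the kernel U(r) = r^2 log r^2; the returned bending energy is
    the quadratic form of the non-affine part (zero iff the source to
    target map is affine).  The deformed grid covers the source bounding
    box plus a margin.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    p = source.shape[0]
    if p < 4:
        raise ValueError("TPS warp needs at least 4 landmarks")
    diff = source[:, None, :] - source[None, :, :]
    k = _tps_kernel(np.einsum("ijk,ijk->ij", diff, diff))
    q = np.column_stack([np.ones(p), source])
    lmat = np.zeros((p + 3, p + 3))
    lmat[:p, :p] = k
    lmat[:p, p:] = q
    lmat[p:, :p] = q.T
    rhs = np.zeros((p + 3, 2))
    rhs[:p] = target
    try:
        wmat = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system: collinear or duplicate landmarks") from exc
    w, affine = wmat[:p], wmat[p:]
    be = float(np.einsum("ic,ij,jc->", w, k, w))
    be = max(be, 0.0)

    lo = source.min(axis=0)
    hi = source.max(axis=0)
    pad = margin * (hi - lo)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_resolution)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_resolution)
    grid = np.stack(np.meshgrid(gx, gy, indexing="xy"), axis=-1).reshape(-1, 2)
    d2 = ((grid[:, None, :] - source[None, :, :]) ** 2).sum(axis=2)
    warped = (
        affine[0]
        + grid @ affine[1:]
        + _tps_kernel(d2) @ w
    )
    return TpsGrid(source, target, warped, (grid_resolution, grid_resolution), be)


def tps_map(source: np.ndarray, target: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Evaluate the TPS interpolant from source to target at given points."""
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    points = np.asarray(points, float)
    p = source.shape[0]
    diff = source[:, None, :] - source[None, :, :]
    k = _tps_kernel(np.einsum("ijk,ijk->ij", diff, diff))
    q = np.column_stack([np.ones(p), source])
    lmat = np.zeros((p + 3, p + 3))
    lmat[:p, :p] = k
    lmat[:p, p:] = q
    lmat[p:, :p] = q.T
    rhs = np.zeros((p + 3, 2))
    rhs[:p] = target
    wmat = np.linalg.solve(lmat, rhs)
    w, affine = wmat[:p], wmat[p:]
    d2 = ((points[:, None, :] - source[None, :, :]) ** 2).sum(axis=2)
    return affine[0] + points @ affine[1:] + _tps_kernel(d2) @ w
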