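import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vipermorph.io import LandmarkConfiguration
from vipermorph.superimpose import (
    ArticulationSpec,
    bending_energy_matrix,
    centroid_size,
    fixed_angle_align,
    gpa,
    measure_articulation_angle,
    procrustes_distance,
    tangent_project,
    tps_map,
    tps_warp,
)

from conftest import random_similarity


def _config(coords, view="dorsal", curves=None, kind=None):
    coords = np.asarray(coords, float)
    p = len(coords)
    if kind is None:
        kind = np.full(p, "fixed", dtype=object)
    return LandmarkConfiguration(coords, kind, curves or [], view)


class TestCentroidSize:
    def test_unit_square(self):
        # four corners at distance sqrt(0.5) from the centroid
        cs = centroid_size(_config([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert cs == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_homogeneity_and_translation_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.standard_normal((7, 2))
        base = centroid_size(coords)
        assert centroid_size(3.0 * coords) == pytest.approx(3.0 * base, rel=1e-12)
        assert centroid_size(coords + [10.0, -5.0]) == pytest.approx(base, rel=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.standard_normal((5, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert centroid_size(coords @ rot.T) == pytest.approx(
            centroid_size(coords), rel=1e-12
        )

    def test_coincident_landmarks_error(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((4, 2)))


class TestFixedAngle:
    art = ArticulationSpec(pivot=0, jaw=[3, 4], reference=1, jaw_ray=3)

    def _jaw_config(self, angle_deg):
        """Pivot at origin, cranial ray along +x, jaw ray at -angle below it."""
        th = -np.radians(angle_deg)
        ray = np.array([np.cos(th), np.sin(th)])
        coords = np.array(
            [[0.0, 0.0], [1.0, 0.0], [0.5, 0.3], 1.2 * ray, 0.6 * ray + [0.1, -0.1]]
        )
        return _config(coords, view="lateral")

    def test_already_at_target_is_fixed_point(self):
        cfg = self._jaw_config(40.0)
        out = fixed_angle_align(cfg, self.art, 40.0)
        np.testing.assert_allclose(out.coords, cfg.coords, atol=1e-12)

    def test_remeasured_angle_equals_target(self):
        cfg = self._jaw_config(60.0)
        out = fixed_angle_align(cfg, self.art, 40.0)
        assert abs(measure_articulation_angle(out, self.art)) == pytest.approx(
            40.0, abs=1e-9
        )
        # non-jaw landmarks untouched
        np.testing.assert_allclose(out.coords[:3], cfg.coords[:3], atol=0)

    def test_zero_target_gives_collinear_rays(self):
        cfg = self._jaw_config(55.0)
        out = fixed_angle_align(cfg, self.art, 0.0)
        v_ref = out.coords[1] - out.coords[0]
        v_jaw = out.coords[3] - out.coords[0]
        assert abs(v_ref[0] * v_jaw[1] - v_ref[1] * v_jaw[0]) < 1e-9

    def test_within_jaw_distances_preserved(self):
        cfg = self._jaw_config(70.0)
        out = fixed_angle_align(cfg, self.art, 40.0)
        d_before = np.linalg.norm(cfg.coords[3] - cfg.coords[4])
        d_after = np.linalg.norm(out.coords[3] - out.coords[4])
        assert d_after == pytest.approx(d_before, rel=1e-12)

    def test_pivot_coincident_with_ray_is_error(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [0.5, 0.3], [1.0, -1.0], [0.5, -0.5]])
        with pytest.raises(ValueError, match="undefined"):
            fixed_angle_align(_config(coords, view="lateral"), self.art, 40.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pivot": 0, "jaw": [], "reference": 1},
            {"pivot": 0, "jaw": [0, 3], "reference": 1},
            {"pivot": 0, "jaw": [3], "reference": 3},
        ],
    )
    def test_invalid_articulation_spec(self, kwargs):
        with pytest.raises(ValueError):
            ArticulationSpec(**kwargs)


class TestGpa:
    def test_orbit_of_one_shape(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((9, 2))
        configs = [_config(random_similarity(rng, base)) for _ in range(6)]
        res = gpa(configs, tol=1e-12, max_iter=50)
        for i in range(6):
            np.testing.assert_allclose(res.aligned[i], res.aligned[0], atol=1e-8)
        # consensus is that shape, up to similarity
        d = procrustes_distance(
            res.mean_shape.ravel(), res.aligned[0].ravel()
        )
        assert d < 1e-8

    def test_no_semilandmarks_reduces_to_plain_gpa(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((5, 8, 2))
        res_plain = gpa(arr)
        assert res_plain.slide_energy == []
        np.testing.assert_allclose(
            np.abs(res_plain.aligned.mean(axis=1)).max(), 0.0, atol=1e-9
        )

    def test_two_triangles_match_rotation_grid_oracle(self):
        t1 = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.9]])
        t2 = np.array([[0.0, 0.1], [1.1, 0.0], [0.6, 1.3]])
        res = gpa(np.stack([t1, t2]), tol=1e-13, max_iter=100)
        d = np.linalg.norm(res.aligned[0] - res.aligned[1])

        def unit(x):
            c = x - x.mean(axis=0)
            return c / np.linalg.norm(c)

        a, b = unit(t1), unit(t2)
        thetas = np.arange(0.0, 2.0 * np.pi, 1e-4)
        cos, sin = np.cos(thetas), np.sin(thetas)
        rots = np.stack([np.stack([cos, -sin], -1), np.stack([sin, cos], -1)], -2)
        dists = np.linalg.norm(a[None] - b @ rots, axis=(1, 2))
        assert d == pytest.approx(dists.min(), abs=1e-6)

    def test_unit_centroid_size_and_centering(self, tiny_configs):
        res = gpa(tiny_configs, tol=1e-10, max_iter=30)
        for cfg in res.aligned:
            assert np.abs(cfg.mean(axis=0)).max() < 1e-9
            assert np.linalg.norm(cfg) == pytest.approx(1.0, abs=1e-9)
        # consensus equals the (re-normalized) coordinate-wise mean
        avg = res.aligned.mean(axis=0)
        avg = (avg - avg.mean(axis=0)) / np.linalg.norm(avg - avg.mean(axis=0))
        np.testing.assert_allclose(res.mean_shape, avg, atol=1e-8)

    def test_sliding_never_increases_total_bending_energy(self, tiny_configs):
        res = gpa(tiny_configs, tol=1e-10, max_iter=30)
        assert res.slide_energy  # sliding did run
        for e_before, e_after in res.slide_energy:
            assert e_after.sum() <= e_before.sum() + 1e-12

    def test_similarity_invariance(self, tiny_configs):
        res = gpa(tiny_configs, tol=1e-12, max_iter=40)
        rng = np.random.default_rng(7)
        moved = []
        for c in tiny_configs:
            c2 = c.copy()
            c2.coords = random_similarity(rng, c.coords)
            moved.append(c2)
        res2 = gpa(moved, tol=1e-12, max_iter=40)
        np.testing.assert_allclose(
            res.residual_matrix, res2.residual_matrix, atol=1e-8
        )

    def test_single_specimen_gives_zero_residuals(self, tiny_configs):
        res = gpa(tiny_configs[:1])
        assert res.residual_matrix.shape[0] == 1
        np.testing.assert_allclose(
            res.aligned[0], res.mean_shape, atol=1e-12
        )


class TestTangentProjection:
    def test_mean_is_fixed_point_and_idempotent(self, tiny_configs):
        res = gpa(tiny_configs, tol=1e-10, max_iter=30)
        m = res.mean_shape.reshape(1, -1)
        res_m = res
        projected = tangent_project(res)
        # project the mean itself: build a result whose aligned rows are the mean
        from vipermorph.superimpose import _project_rows

        np.testing.assert_allclose(
            _project_rows(m, res.mean_shape.ravel()), m, atol=1e-12
        )
        twice = _project_rows(projected, res_m.mean_shape.ravel())
        np.testing.assert_allclose(twice, projected, atol=1e-12)

    def test_small_variation_preserves_distances(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((12, 2))
        arr = base[None] + 1e-3 * rng.standard_normal((6, 12, 2))
        res = gpa(arr, tol=1e-13, max_iter=60)
        raw = res.aligned.reshape(6, -1)
        proj = tangent_project(res)
        for i in range(6):
            for j in range(i + 1, 6):
                d_raw = np.linalg.norm(raw[i] - raw[j])
                d_proj = np.linalg.norm(proj[i] - proj[j])
                assert d_proj == pytest.approx(d_raw, rel=1e-6)


class TestProcrustesDistance:
    def test_identical_is_zero_and_mismatch_raises(self):
        v = np.arange(6.0)
        assert procrustes_distance(v, v) == 0.0
        with pytest.raises(ValueError):
            procrustes_distance(v, v[:4])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.standard_normal((3, 10))
        assert procrustes_distance(a, b) == pytest.approx(procrustes_distance(b, a))
        assert procrustes_distance(a, c) <= (
            procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-12
        )


class TestTpsWarp:
    source = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.4, 0.6]])

    def test_identity_map_zero_energy(self):
        grid = tps_warp(self.source, self.source)
        assert grid.bending_energy == pytest.approx(0.0, abs=1e-12)

    def test_affine_target_zero_energy(self):
        affine = self.source @ np.array([[1.2, 0.3], [-0.1, 0.8]]) + [0.5, -1.0]
        grid = tps_warp(self.source, affine)
        assert grid.bending_energy == pytest.approx(0.0, abs=1e-9)

    def test_interpolation_at_landmarks(self):
        rng = np.random.default_rng(9)
        target = self.source + 0.2 * rng.standard_normal(self.source.shape)
        mapped = tps_map(self.source, target, self.source)
        np.testing.assert_allclose(mapped, target, atol=1e-9)
        assert tps_warp(self.source, target).bending_energy >= 0.0

    def test_collinear_source_is_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="singular"):
            tps_warp(line, line + 0.1)

    def test_bending_energy_matrix_psd_with_affine_null(self):
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((8, 2))
        be = bending_energy_matrix(pts)
        vals = np.linalg.eigvalsh(be)
        assert vals.min() > -1e-10
        # affine functions of the points are in the null space
        for vec in (np.ones(8), pts[:, 0], pts[:, 1]):
            assert np.abs(be @ vec).max() < 1e-8
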