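"""Convex-hull construction, distance-to-rim geometry, radial profiles."""

import numpy as np
import pandas as pd
import pytest

from spheroquant import spatial as sp

CUBE = np.array(
    [[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)], dtype=float
)


def sphere_points(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * radius


class TestBuildHull:
    def test_cube_corners(self):
        hull = sp.build_hull(CUBE)
        assert np.allclose(hull.center, 0.0, atol=1e-12)
        assert sorted(map(tuple, hull.vertices)) == sorted(map(tuple, CUBE))

    def test_interior_points_ignored(self):
        rng = np.random.default_rng(1)
        interior = rng.uniform(-0.8, 0.8, size=(30, 3))
        hull = sp.build_hull(np.vstack([CUBE, interior]))
        assert sorted(map(tuple, hull.vertices)) == sorted(map(tuple, CUBE))
        assert np.allclose(hull.center, 0.0, atol=1e-9)

    def test_all_points_inside_by_halfspace_test(self):
        pts = np.random.default_rng(2).normal(size=(500, 3)) * 5
        hull = sp.build_hull(pts)
        # sign test against every face plane: n·x + d <= 0 (within tolerance)
        margins = pts @ hull.equations[:, :3].T + hull.equations[:, 3]
        assert (margins <= 1e-9).all()

    def test_degenerate_input_errors(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(sp.DegenerateHullError):
            sp.build_hull(flat)
        with pytest.raises(sp.DegenerateHullError):
            sp.build_hull(CUBE[:3])

    def test_center_definitions(self):
        pts = np.vstack([CUBE, [[0.9, 0.9, 0.9]] * 5])
        vol_c = sp.build_hull(pts, center="volume_centroid").center
        mean_c = sp.build_hull(pts, center="centroid_mean").center
        assert np.allclose(vol_c, 0.0, atol=1e-9)  # duplicated point has no volume
        assert not np.allclose(mean_c, 0.0, atol=1e-3)


class TestDistanceToHull:
    def test_centroid_on_vertex_is_zero(self):
        hull = sp.build_hull(CUBE)
        assert sp.distance_to_hull(hull, CUBE[0]) == pytest.approx(0.0, abs=1e-9)

    def test_cube_analytic_case(self):
        hull = sp.build_hull(CUBE)
        d = sp.distance_to_hull(hull, np.array([0.5, 0.0, 0.0]))
        assert d == pytest.approx(0.5, rel=1e-9)

    def test_spherical_shell_analytic(self):
        R = 10.0
        hull = sp.build_hull(sphere_points(500, R, seed=3))
        rng = np.random.default_rng(4)
        dirs = rng.normal(size=(30, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for r in (1.0, 2.5, 5.0, 8.0):
            errs = [abs(sp.distance_to_hull(hull, u * r) - (R - r)) for u in dirs]
            assert np.mean(errs) <= 0.02 * R

    def test_matches_ray_triangle_oracle(self):
        # independent Möller–Trumbore ray–triangle intersection over every
        # hull facet, versus the half-space exit-point computation
        def ray_triangle_hit(orig, direc, v0, v1, v2):
            e1, e2 = v1 - v0, v2 - v0
            h = np.cross(direc, e1)
            a = e2 @ h
            if abs(a) < 1e-12:
                return None
            f = 1.0 / a
            s = orig - v0
            u = f * (s @ h)
            if u < -1e-9 or u > 1 + 1e-9:
                return None
            q = np.cross(s, e2)
            v = f * (direc @ q)
            if v < -1e-9 or u + v > 1 + 1e-9:
                return None
            t = f * (e1 @ q)
            return t if t > 1e-9 else None

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(120, 3)) * 10
        hull = sp.build_hull(pts)
        faces = pts[hull.faces]
        interior = np.random.default_rng(9).uniform(-2, 2, size=(15, 3))
        for p in interior:
            d = p - hull.center
            d /= np.linalg.norm(d)
            hits = [
                t
                for v0, v1, v2 in faces
                if (t := ray_triangle_hit(hull.center, d, v0, v1, v2)) is not None
            ]
            expect = abs(min(hits) - np.linalg.norm(p - hull.center))
            assert sp.distance_to_hull(hull, p) == pytest.approx(expect, abs=1e-6)

    def test_rigid_transform_invariance(self):
        pts = np.random.default_rng(11).normal(size=(200, 3)) * 8
        probes = np.random.default_rng(12).uniform(-2, 2, size=(10, 3))
        hull = sp.build_hull(pts)
        d0 = sp.distances_to_hull(hull, probes)

        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([5.0, -3.0, 11.0])
        hull_t = sp.build_hull(pts @ rot.T + shift)
        d1 = sp.distances_to_hull(hull_t, probes @ rot.T + shift)
        assert np.allclose(d0, d1, atol=1e-6 * 10)

    def test_max_distance_bounded_by_diameter(self):
        pts = np.random.default_rng(13).normal(size=(100, 3)) * 6
        hull = sp.build_hull(pts)
        d = sp.distances_to_hull(hull, pts)
        pairwise_max = max(
            np.linalg.norm(a - b) for a in pts[:30] for b in pts[:30]
        )
        diam = np.linalg.norm(
            pts.max(axis=0) - pts.min(axis=0)
        )  # loose upper bound on pairwise max
        assert d.max() <= diam

    def test_center_coincident_warns(self):
        hull = sp.build_hull(CUBE)
        with pytest.warns(UserWarning):
            d = sp.distance_to_hull(hull, hull.center)
        assert d == pytest.approx(1.0, rel=1e-9)  # min face distance of the cube


class TestRadialProfile:
    def test_single_distance_single_bin(self):
        df = pd.DataFrame(
            {
                "distance_to_hull_um": [5.0] * 7,
                "nc_ratio": np.linspace(1, 2, 7),
                "ki67_status": [True, False] * 3 + [True],
            }
        )
        out = sp.radial_profile(df, 4)
        assert len(out) == 4
        assert out.n.sum() == 7
        assert (out.n > 0).sum() == 1

    def test_manual_two_bin_assignment(self):
        d = [0.5, 1.0, 2.0, 3.0, 4.0, 5.5, 6.0, 7.5, 9.0, 10.0]
        df = pd.DataFrame(
            {
                "distance_to_hull_um": d,
                "nc_ratio": np.arange(10, dtype=float),
                "ki67_status": [False] * 10,
            }
        )
        out = sp.radial_profile(df, 2)
        assert out.n.tolist() == [5, 5]  # split at 5.0; right-inclusive bins
        assert out.mean_nc_ratio.iloc[0] == pytest.approx(np.mean([0, 1, 2, 3, 4]))

    def test_programmed_gradient_is_monotone(self, clean_spheroid):
        t = clean_spheroid.truth
        df = pd.DataFrame(
            {
                "distance_to_hull_um": t.true_distance_to_rim_um,
                "nc_ratio": t.true_nc_ratio,
                "ki67_status": t.ki67_status,
            }
        )
        out = sp.radial_profile(df, 4)
        means = out.mean_nc_ratio.dropna().to_numpy()
        # rim-high programmed gradient: N/C falls strictly with depth
        assert (np.diff(means) < 0).all()

    def test_validation(self):
        df = pd.DataFrame(
            {"distance_to_hull_um": [1.0], "nc_ratio": [1.0], "ki67_status": [False]}
        )
        with pytest.raises(ValueError):
            sp.radial_profile(df, 0)
        with pytest.raises(ValueError):
            sp.radial_profile(df.iloc[:0], 3)
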