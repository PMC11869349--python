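"""Geometric primitive fits against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phmorph.geometry import (
    DegenerateGeometryError,
    Line3D,
    Plane,
    angle_between,
    fit_axis,
    fit_circle_in_plane,
    fit_plane,
    fit_sphere,
    point_line_distance,
)

from conftest import random_rotation


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def plane_oracle_eigh(points):
    """Smallest-scatter direction via eigendecomposition of the covariance."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    cov = (pts - centroid).T @ (pts - centroid)
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0]
    return normal, float(normal @ centroid)


def circumscribed_circle(p1, p2, p3):
    """Closed-form circumcircle of three points (3D, perpendicular bisectors)."""
    a, b, c = map(np.asarray, (p1, p2, p3))
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    center = a + ((ac @ ac) * np.cross(n, ab)
                  + (ab @ ab) * np.cross(ac, n)) / (2 * (n @ n))
    return center, float(np.linalg.norm(center - a))


def four_point_sphere(p1, p2, p3, p4):
    """Exact sphere through four points via the linearised system."""
    pts = np.array([p1, p2, p3, p4], float)
    a = np.column_stack([2.0 * pts, np.ones(4)])
    b = np.einsum("ij,ij->i", pts, pts)
    sol = np.linalg.solve(a, b)
    center = sol[:3]
    return center, float(np.sqrt(sol[3] + center @ center))


def sample_sphere(rng, center, radius, n):
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return center + radius * v


# ---------------------------------------------------------------------------
# fit_plane
# ---------------------------------------------------------------------------

class TestFitPlane:
    def test_exact_plane_through_three_points(self):
        plane, rms = fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
        assert abs(plane.offset) < 1e-12
        assert rms < 1e-12

    def test_matches_svd_scatter_oracle_on_perturbed_cloud(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-5, 5, 50), rng.uniform(-5, 5, 50),
                               np.full(50, 2.0)])
        pts[:, 2] += 0.01 * rng.standard_normal(50)
        plane, _ = fit_plane(pts)
        n_o, off_o = plane_oracle_eigh(pts)
        if n_o @ plane.normal < 0:
            n_o, off_o = -n_o, -off_o
        assert np.allclose(plane.normal, n_o, atol=1e-9)
        assert abs(plane.offset - off_o) < 1e-9

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([(0, 0, 0), (1, 1, 1), (2, 2, 2)])

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([(0, 0, 0), (1, 0, 0)])


# ---------------------------------------------------------------------------
# fit_sphere
# ---------------------------------------------------------------------------

class TestFitSphere:
    def test_exact_octahedral_sphere(self):
        pts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
               (0, 0, -1)]
        sphere, rms = fit_sphere(pts)
        assert np.allclose(sphere.center, 0, atol=1e-12)
        assert abs(sphere.radius - 1.0) < 1e-12
        assert rms < 1e-12

    def test_recovers_generating_sphere(self):
        # Head-sized sphere (radius = half the cohort-mean head diameter).
        rng = np.random.default_rng(1)
        center = np.array([13.0, -41.0, 7.5])
        pts = sample_sphere(rng, center, 22.43, 500)
        sphere, rms = fit_sphere(pts)
        assert np.linalg.norm(sphere.center - center) < 1e-9
        assert abs(sphere.radius - 22.43) < 1e-9
        assert rms < 1e-9

    def test_coplanar_points_raise(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-3, 3, (20, 2)), np.zeros(20)])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)


# ---------------------------------------------------------------------------
# fit_circle_in_plane
# ---------------------------------------------------------------------------

class TestFitCircle:
    Z0 = Plane(np.array([0.0, 0.0, 1.0]), 0.0)

    def test_three_symmetric_points_give_unit_circle(self):
        ang = np.radians([0.0, 120.0, 240.0])
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(3)])
        circle, rms = fit_circle_in_plane(pts, self.Z0)
        assert np.allclose(circle.center, 0, atol=1e-12)
        assert abs(circle.radius - 1.0) < 1e-12
        assert rms < 1e-12

    def test_cap_rim_matches_spherical_cap_identity(self):
        # Rim of a spherical cap: r = sqrt(h (2R - h)) for R = 22.43, h = 14.31.
        big_r, h = 22.43, 14.31
        r_expected = np.sqrt(h * (2 * big_r - h))
        ang = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([r_expected * np.cos(ang),
                               r_expected * np.sin(ang), np.zeros(60)])
        circle, _ = fit_circle_in_plane(pts, self.Z0)
        assert abs(circle.radius - r_expected) < 1e-9
        assert abs(2 * circle.radius - 41.82) < 0.01

    def test_matches_circumscribed_circle_for_any_triple(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pts2d = rng.uniform(-10, 10, (3, 2))
            ab, ac = pts2d[1] - pts2d[0], pts2d[2] - pts2d[0]
            if abs(ab[0] * ac[1] - ab[1] * ac[0]) < 1e-3:
                continue
            pts = np.column_stack([pts2d, np.zeros(3)])
            circle, _ = fit_circle_in_plane(pts, self.Z0)
            c_o, r_o = circumscribed_circle(*pts)
            assert np.linalg.norm(circle.center - c_o) < 1e-8
            assert abs(circle.radius - r_o) < 1e-8

    def test_two_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_in_plane([(0, 0, 0), (1, 0, 0)], self.Z0)


# ---------------------------------------------------------------------------
# fit_axis
# ---------------------------------------------------------------------------

def ring_cylinder(radius=10.0, length=100.0, n_rings=40, n_theta=90):
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    rings = []
    for z in np.linspace(0.0, -length, n_rings):
        rings.append(np.column_stack([radius * np.cos(theta),
                                      radius * np.sin(theta),
                                      np.full(n_theta, z)]))
    return np.vstack(rings)


class TestFitAxis:
    def test_symmetric_cylinder_recovers_z_axis(self):
        pts = ring_cylinder()
        axis = fit_axis(pts, (0, 0, 1.0))
        assert abs(abs(axis.direction[2]) - 1.0) < 1e-6
        assert np.hypot(axis.anchor[0], axis.anchor[1]) < 1e-6

    def test_equivariant_under_known_rotation(self):
        pts = ring_cylinder()
        rng = np.random.default_rng(4)
        rot = random_rotation(rng)
        shift = np.array([5.0, -3.0, 11.0])
        axis = fit_axis(pts @ rot.T + shift, rot @ np.array([0, 0, 1.0]))
        true_dir = rot @ np.array([0, 0, 1.0])
        assert np.degrees(np.arccos(np.clip(abs(axis.direction @ true_dir),
                                            -1, 1))) < 1e-6
        # anchor must lie on the transformed axis
        assert point_line_distance(axis.anchor,
                                   Line3D(shift, true_dir)) < 1e-6

    def test_direction_sign_follows_provisional(self):
        pts = ring_cylinder()
        down = fit_axis(pts, (0, 0, -1.0))
        assert down.direction[2] < 0

    def test_single_slab_raises(self):
        # Five points in one slab: no extent along the slicing direction.
        pts = np.column_stack([np.arange(5.0), np.arange(5.0) ** 2,
                               np.full(5, 3.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_axis(pts, (0, 0, 1.0))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_point_line_distance_345(self):
        line = Line3D(np.zeros(3), np.array([0, 0, 1.0]))
        assert abs(point_line_distance((3, 4, 0), line) - 5.0) < 1e-12

    def test_angle_between_antiparallel_is_180(self):
        assert abs(angle_between((0, 0, 1), (0, 0, -1)) - 180.0) < 1e-12

    def test_angle_matches_atan2_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            u, v = rng.standard_normal(3), rng.standard_normal(3)
            expected = np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)),
                                             u @ v))
            assert abs(angle_between(u, v) - expected) < 1e-10

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            angle_between((0, 0, 0), (1, 0, 0))


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

@given(st.integers(min_value=0, max_value=10_000))
def test_fits_are_rigid_motion_equivariant(seed):
    """Fitting transformed points equals transforming the fit."""
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    shift = rng.uniform(-50, 50, 3)

    plane_pts = np.column_stack([rng.uniform(-5, 5, (30, 2)), np.zeros(30)])
    plane_pts[:, 2] += 0.05 * rng.standard_normal(30)
    plane, _ = fit_plane(plane_pts)
    plane_t, _ = fit_plane(plane_pts @ rot.T + shift)
    n_expected = rot @ plane.normal
    if n_expected @ plane_t.normal < 0:
        n_expected = -n_expected
    assert np.allclose(plane_t.normal, n_expected, atol=1e-8)

    sphere_pts = sample_sphere(rng, rng.uniform(-20, 20, 3),
                               rng.uniform(5, 30), 80)
    sphere, _ = fit_sphere(sphere_pts)
    sphere_t, _ = fit_sphere(sphere_pts @ rot.T + shift)
    assert np.allclose(sphere_t.center, rot @ sphere.center + shift, atol=1e-8)
    assert abs(sphere_t.radius - sphere.radius) < 1e-8


@given(st.integers(min_value=0, max_value=10_000))
def test_lengths_scale_linearly_angles_unchanged(seed):
    rng = np.random.default_rng(seed)
    scale = rng.uniform(0.2, 5.0)
    sphere_pts = sample_sphere(rng, rng.uniform(-20, 20, 3),
                               rng.uniform(5, 30), 60)
    sphere, _ = fit_sphere(sphere_pts)
    sphere_s, _ = fit_sphere(sphere_pts * scale)
    assert abs(sphere_s.radius - scale * sphere.radius) < 1e-8 * max(1, scale)

    u, v = rng.standard_normal(3), rng.standard_normal(3)
    assert abs(angle_between(u * scale, v * scale)
               - angle_between(u, v)) < 1e-10
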