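"""Least-squares geometric primitives for 3D bone morphometry.

This module provides the fitted primitives that the measurement pipeline is
built from: total-least-squares planes, algebraic spheres and in-plane circles
(each with a single geometric Gauss-Newton refinement pass), slice-centroid
axis lines, and the metric helpers (point-line distance, angles in degrees).

All coordinates are millimetres.  Every fit is deterministic and closed-form
(no random initialisation): a noise-free sample drawn from a primitive is
recovered exactly, and all fits are equivariant under rigid motions and scale.
Degenerate inputs (collinear points for a plane, coplanar points for a sphere)
raise :class:`DegenerateGeometryError` rather than returning garbage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "Line3D",
    "Sphere",
    "Circle3D",
    "fit_plane",
    "fit_sphere",
    "fit_circle_in_plane",
    "fit_axis",
    "point_line_distance",
    "angle_between",
]

# Relative collinearity / coplanarity tolerance and the linear-system condition
# bound beyond which a fit is declared degenerate.
COLLINEAR_RTOL = 1e-9
MAX_CONDITION = 1e8

_UNIT_ATOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when input points cannot determine the requested primitive."""


def _as_points(points, min_points: int, name: str) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name}: expected an (n, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name}: points contain non-finite values")
    if pts.shape[0] < min_points:
        raise DegenerateGeometryError(
            f"{name}: needs at least {min_points} points, got {pts.shape[0]}"
        )
    return pts


def _unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0.0:
        raise ValueError(f"{name}: zero or non-finite vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``{p : normal . p = offset}``.

    ``offset`` is the signed distance of the plane from the origin along the
    unit normal, so ``signed_distance(p) = normal . p - offset`` exactly.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_ATOL:
            raise ValueError("Plane normal must be unit length")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.normal - self.offset

    def project(self, points) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(points)
        return points - d[:, None] * self.normal

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """A deterministic orthonormal in-plane basis (e1, e2)."""
        n = self.normal
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(n)))] = 1.0
        e1 = _unit(np.cross(n, helper))
        e2 = np.cross(n, e1)
        return e1, e2

    @property
    def origin(self) -> np.ndarray:
        """The plane point closest to the coordinate origin."""
        return self.offset * self.normal


@dataclass(frozen=True)
class Line3D:
    """Orientation-carrying line ``anchor + t * direction`` (unit direction)."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > _UNIT_ATOL:
            raise ValueError("Line3D direction must be unit length")
        object.__setattr__(self, "anchor", a)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        r = float(self.radius)
        if not r > 0:
            raise ValueError("Sphere radius must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "radius", r)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class Circle3D:
    """Circle embedded in a 3D plane; the center must lie on the plane."""

    center: np.ndarray
    radius: float
    plane: Plane = field(repr=False)

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        r = float(self.radius)
        if not r > 0:
            raise ValueError("Circle3D radius must be positive")
        if abs(float(self.plane.signed_distance(c[None, :])[0])) > 1e-6:
            raise ValueError("Circle3D center does not lie on its plane")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "radius", r)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def fit_plane(points) -> tuple[Plane, float]:
    """Total-least-squares plane through ``points``.

    Minimises the sum of squared orthogonal distances (the smallest-scatter
    direction of the centered cloud).  With exactly three non-collinear points
    the residual is zero.  Normal orientation is arbitrary at this level.

    Returns ``(plane, rms_residual_mm)``.
    """
    pts = _as_points(points, 3, "fit_plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered cloud: the right-singular vector of the smallest
    # singular value is the plane normal.
    _, s, vh = np.linalg.svd(centered, full_matrices=False)
    if s[0] == 0.0 or s[1] <= COLLINEAR_RTOL * s[0]:
        raise DegenerateGeometryError("fit_plane: points are (near-)collinear")
    normal = vh[2]
    plane = Plane(normal, float(normal @ centroid))
    rms = float(np.sqrt(np.mean(plane.signed_distance(pts) ** 2)))
    return plane, rms


def fit_sphere(points) -> tuple[Sphere, float]:
    """Least-squares sphere: algebraic (linearised) fit + one Gauss-Newton pass.

    The algebraic step solves ``|p|^2 = 2 c.p + (r^2 - |c|^2)`` in the
    least-squares sense; the geometric pass refines center and radius against
    true orthogonal residuals.  Exact on points sampled from a sphere.

    Returns ``(sphere, rms_residual_mm)``.
    """
    pts = _as_points(points, 4, "fit_sphere")
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    s = np.linalg.svd(a, compute_uv=False)
    if s[-1] == 0.0 or s[0] / s[-1] > MAX_CONDITION:
        raise DegenerateGeometryError(
            "fit_sphere: points are coplanar or nearly so (ill-conditioned)"
        )
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if not r2 > 0:
        raise DegenerateGeometryError("fit_sphere: non-positive squared radius")
    radius = float(np.sqrt(r2))

    # One geometric Gauss-Newton refinement pass on (cx, cy, cz, r).
    diff = pts - center
    dist = np.linalg.norm(diff, axis=1)
    good = dist > 1e-12
    if np.count_nonzero(good) >= 4:
        res = dist[good] - radius
        jac = np.column_stack([-diff[good] / dist[good, None], -np.ones(good.sum())])
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
        if np.all(np.isfinite(step)) and radius + step[3] > 0:
            center = center + step[:3]
            radius = float(radius + step[3])

    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return Sphere(center, radius), rms


def fit_circle_in_plane(points, plane: Plane, max_plane_distance: float | None = None
                        ) -> tuple[Circle3D, float]:
    """Best-fit circle of (near-)planar points within a given plane.

    Points are orthogonally projected onto ``plane``; a 2D algebraic (Kasa)
    circle fit followed by one geometric Gauss-Newton pass is performed in
    plane coordinates, and the result is lifted back to 3D.  Agrees with the
    circumscribed circle for any three non-collinear points.

    Parameters
    ----------
    max_plane_distance:
        Optional gate: raise if any point is farther than this from the plane.

    Returns ``(circle, rms_residual_mm)`` with the residual measured in-plane.
    """
    pts = _as_points(points, 3, "fit_circle_in_plane")
    d = plane.signed_distance(pts)
    if max_plane_distance is not None and np.any(np.abs(d) > max_plane_distance):
        raise ValueError(
            "fit_circle_in_plane: points exceed max_plane_distance from plane"
        )
    e1, e2 = plane.basis()
    rel = pts - plane.origin
    xy = np.column_stack([rel @ e1, rel @ e2])

    a = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.einsum("ij,ij->i", xy, xy)
    s = np.linalg.svd(a, compute_uv=False)
    if s[-1] == 0.0 or s[1] <= COLLINEAR_RTOL * s[0]:
        raise DegenerateGeometryError(
            "fit_circle_in_plane: projected points are (near-)collinear"
        )
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cxy = sol[:2]
    r2 = sol[2] + cxy @ cxy
    if not r2 > 0:
        raise DegenerateGeometryError("fit_circle_in_plane: non-positive radius")
    radius = float(np.sqrt(r2))

    diff = xy - cxy
    dist = np.linalg.norm(diff, axis=1)
    good = dist > 1e-12
    if np.count_nonzero(good) >= 3:
        res = dist[good] - radius
        jac = np.column_stack([-diff[good] / dist[good, None], -np.ones(good.sum())])
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
        if np.all(np.isfinite(step)) and radius + step[2] > 0:
            cxy = cxy + step[:2]
            radius = float(radius + step[2])

    center3d = plane.origin + cxy[0] * e1 + cxy[1] * e2
    rms = float(np.sqrt(np.mean((np.linalg.norm(xy - cxy, axis=1) - radius) ** 2)))
    return Circle3D(center3d, radius, plane), rms


def fit_axis(points, provisional_direction, n_slices: int = 8,
             trim_ends: bool = False) -> Line3D:
    """Slice-centroid axis of an elongated point cloud (e.g. a bone shaft).

    Points are binned into ``n_slices`` slabs perpendicular to the provisional
    direction; a total-least-squares line is fitted through the slab
    centroids; the procedure is repeated once with the fitted direction as the
    new slicing direction.  The returned direction has positive dot product
    with ``provisional_direction``.

    ``trim_ends`` bins into ``n_slices + 2`` slabs and fits through the
    interior centroids only.  When the cloud was carved out of a longer
    structure by two cutting planes that are slightly oblique to the true
    axis, the boundary slabs hold partially-cut cross-sections whose
    centroids are displaced off-axis (by up to 2r/pi for a half cross-
    section); dropping them removes that bias.

    Meshes reconstructed from tomographic slices are layered: vertices
    cluster in discrete rings, and a slab boundary that lands on a ring
    splits it into two arcs whose centroids sit far off-axis (up to 2r/pi),
    biasing the fit.  Two safeguards address this: slab boundaries are
    snapped into the widest nearby sampling gap (so layered clouds are cut
    between layers, while the snap is a no-op for continuously sampled
    clouds), and each pass ends with one robust refinement dropping
    centroids whose perpendicular residual exceeds 3x the median.  Passes
    repeat (up to 5) until the direction stabilises.
    """
    pts = _as_points(points, 3, "fit_axis")
    if n_slices < 3:
        raise ValueError("fit_axis: n_slices must be >= 3")
    direction = _unit(provisional_direction, "provisional_direction")
    n_bins = n_slices + 2 if trim_ends else n_slices

    def tls_line(centroids):
        anchor = centroids.mean(axis=0)
        _, _, vh = np.linalg.svd(centroids - anchor, full_matrices=False)
        return anchor, _unit(vh[0])

    def snapped_edges(t_sorted, lo, hi):
        """Nominal bin edges, each moved to the widest nearby sampling gap."""
        width = (hi - lo) / n_bins
        edges = lo + width * np.arange(1, n_bins)
        for i, edge in enumerate(edges):
            a, b = np.searchsorted(t_sorted, [edge - 0.25 * width,
                                              edge + 0.25 * width])
            window = t_sorted[max(a - 1, 0):b + 1]
            if len(window) >= 2:
                gaps = np.diff(window)
                j = int(np.argmax(gaps))
                if gaps[j] > 0:
                    edges[i] = 0.5 * (window[j] + window[j + 1])
        return edges

    d = direction
    anchor = pts.mean(axis=0)
    for _ in range(5):  # re-slice along the fitted direction until stable
        t = pts @ d
        lo, hi = float(t.min()), float(t.max())
        if hi - lo <= 0:
            raise DegenerateGeometryError("fit_axis: points have no extent along axis")
        idx = np.searchsorted(snapped_edges(np.sort(t), lo, hi), t)
        keep = range(1, n_bins - 1) if trim_ends else range(n_bins)
        centroids = np.array([pts[idx == k].mean(axis=0)
                              for k in keep if np.any(idx == k)])
        if len(centroids) < 3:
            raise DegenerateGeometryError(
                f"fit_axis: only {len(centroids)} non-empty slabs (need >= 3)"
            )
        anchor, d_new = tls_line(centroids)
        resid = np.linalg.norm(
            np.cross(centroids - anchor, d_new), axis=1)
        gate = max(3.0 * float(np.median(resid)), 1e-6)
        good = resid <= gate
        if 3 <= np.count_nonzero(good) < len(centroids):
            anchor, d_new = tls_line(centroids[good])
        if d_new @ direction < 0:
            d_new = -d_new
        converged = abs(d_new @ d) > 1.0 - 1e-14
        d = d_new
        if converged:
            break
    return Line3D(anchor, d)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def point_line_distance(p, line: Line3D) -> float:
    """Perpendicular distance (mm) from a point to a line."""
    p = np.asarray(p, dtype=float)
    return float(np.linalg.norm(np.cross(p - line.anchor, line.direction)))


def angle_between(v1, v2) -> float:
    """Angle between two nonzero vectors, degrees in [0, 180]."""
    u1 = _unit(v1, "v1")
    u2 = _unit(v2, "v2")
    return float(np.degrees(np.arccos(np.clip(u1 @ u2, -1.0, 1.0))))
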