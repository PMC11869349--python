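"""Parametric proximal-humerus mesh generator with exact ground truth.

The generator emulates the idealised anatomy implied by the measurement
definitions: the humeral head is a perfect spherical cap truncated by the
anatomical-neck plane, joined by a straight conical blend to a medially
offset cylindrical metaphyseal shaft.  Every parameter of interest (head
diameter HHD, head height HHH, neck-shaft angle, medial offset) is a direct
construction input, so a measurement pipeline can be validated against exact
ground truth without any scan data.

Canonical frame: the shaft axis runs along -z from the origin; the medial
direction is +x; the head axis u lies in the xz-plane with the requested
angle to the distal (-z) direction.  Rigid-motion tests randomise the frame
afterwards.

The blend cone is synthetic plumbing: its vertices lie strictly between the
neck plane and the metaphyseal band, so neither the head-sphere fit nor the
shaft-axis fit sees them.  The mesh is manifold on the cap and cylinder;
watertightness of the whole surface is not guaranteed (nor needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Circle3D, Line3D, Plane
from .pipeline import LandmarkSet, TriMesh

__all__ = ["AnatomyParams", "GroundTruth", "generate_humerus", "TABLE_MEANS"]

# Cohort mean parameter set (mm / degrees) used as generator defaults.
TABLE_MEANS = {
    "hhd": 44.86,
    "hhh": 14.31,
    "neck_shaft_angle": 131.25,
    "medial_offset": 6.25,
}

BLEND_CLEARANCE_MM = 5.0  # vertical gap between the lowest rim point and z=0


@dataclass(frozen=True)
class AnatomyParams:
    """Construction parameters of one synthetic proximal humerus."""

    hhd: float = TABLE_MEANS["hhd"]                    # head sphere diameter, mm
    hhh: float = TABLE_MEANS["hhh"]                    # head (cap) height, mm
    neck_shaft_angle: float = TABLE_MEANS["neck_shaft_angle"]  # degrees
    medial_offset: float = TABLE_MEANS["medial_offset"]        # mm
    shaft_radius: float = 10.0                         # metaphyseal radius, mm
    shaft_length: float = 150.0                        # mm, must cover the band
    mesh_resolution: int = 48000                       # target vertex count
    vertex_noise_sd: float = 0.0                       # isotropic, mm
    landmark_jitter_sd: float = 0.0                    # along-rim arc length, mm
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.hhh < self.hhd:
            raise ValueError("require 0 < hhh < hhd")
        if not 0 < self.neck_shaft_angle < 180:
            raise ValueError("neck_shaft_angle must lie in (0, 180)")
        if self.medial_offset < 0:
            raise ValueError("medial_offset must be >= 0")
        if not 0 < self.shaft_radius < self.hhd / 2:
            raise ValueError("require 0 < shaft_radius < hhd/2")
        if self.shaft_length <= 0 or self.mesh_resolution < 200:
            raise ValueError("shaft_length > 0 and mesh_resolution >= 200 required")
        if self.vertex_noise_sd < 0 or self.landmark_jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact parameter values and geometry implied by the construction."""

    hhd: float
    hhh: float
    neck_shaft_angle: float
    medial_offset: float
    asd: float                 # = 2 sqrt(hhh (hhd - hhh)), cap identity
    apex: np.ndarray           # point A
    sphere_center: np.ndarray  # point E
    circle_center: np.ndarray  # point B
    circle_radius: float
    neck_plane: Plane          # normal = head axis (head side positive)
    shaft_axis: Line3D         # oriented proximal -> distal

    def parameters(self) -> dict:
        return {
            "neck_shaft_angle": self.neck_shaft_angle,
            "hhh": self.hhh,
            "asd": self.asd,
            "hhd": self.hhd,
            "medial_offset": self.medial_offset,
        }

    @property
    def articular_circle(self) -> Circle3D:
        return Circle3D(self.circle_center, self.circle_radius, self.neck_plane)


def _row_allocation(params: AnatomyParams) -> tuple[int, int, int, int]:
    """(n_theta, cap_rows, blend_rows, cylinder_rows) from the vertex budget."""
    n_theta = 3 * max(8, int(round(np.sqrt(params.mesh_resolution) / 2.5)))
    rows = max(16, params.mesh_resolution // n_theta)
    cap_rows = max(8, int(round(0.35 * rows)))
    blend_rows = max(3, int(round(0.08 * rows)))
    cyl_rows = max(8, rows - cap_rows - blend_rows)
    return n_theta, cap_rows, blend_rows, cyl_rows


def generate_humerus(params: AnatomyParams | None = None
                     ) -> tuple[TriMesh, LandmarkSet, GroundTruth]:
    """Build one synthetic proximal humerus.

    Returns the triangulated surface, the three neck-ridge landmarks (on the
    analytic rim circle, optionally jittered along the rim), and the exact
    :class:`GroundTruth` computed before any noise is applied.  Deterministic
    for a given seed.
    """
    p = params or AnatomyParams()
    rng = np.random.default_rng(p.seed)

    alpha = np.radians(p.neck_shaft_angle)
    radius = p.hhd / 2.0
    cap_h = p.hhh
    rim_r = float(np.sqrt(cap_h * (p.hhd - cap_h)))

    distal = np.array([0.0, 0.0, -1.0])
    # Head axis u in the xz-plane: angle(u, distal) = alpha, tipped medially.
    u = np.array([np.sin(alpha), 0.0, -np.cos(alpha)])
    e2 = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(e2, u)  # in-plane basis of the neck plane, |e1| = 1

    # Place the sphere center high enough that the cap (and its rim) clears
    # the cylinder top at z = 0 by BLEND_CLEARANCE_MM.
    phi_max = float(np.arccos((radius - cap_h) / radius))
    rim_center_rel = (radius - cap_h) * u        # B - E
    rim_min_z_rel = rim_center_rel[2] - rim_r * abs(e1[2])
    cap_min_z_rel = rim_min_z_rel
    if -u[2] >= np.cos(phi_max):                 # -z sphere pole inside the cap
        cap_min_z_rel = min(cap_min_z_rel, -radius)
    z_e = BLEND_CLEARANCE_MM + max(0.0, -cap_min_z_rel)
    center_e = np.array([p.medial_offset, 0.0, z_e])

    center_b = center_e + rim_center_rel
    apex = center_e + radius * u
    plane = Plane(u, float(u @ center_b))
    truth = GroundTruth(
        hhd=p.hhd, hhh=p.hhh, neck_shaft_angle=p.neck_shaft_angle,
        medial_offset=p.medial_offset, asd=2.0 * rim_r,
        apex=apex, sphere_center=center_e, circle_center=center_b,
        circle_radius=rim_r, neck_plane=plane,
        shaft_axis=Line3D(np.zeros(3), distal),
    )

    n_theta, cap_rows, blend_rows, cyl_rows = _row_allocation(p)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    ring_dirs = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)

    verts: list[np.ndarray] = [apex[None, :]]
    # Spherical cap rings, apex (phi=0) to rim (phi=phi_max, exactly on circle).
    for i in range(1, cap_rows + 1):
        phi = phi_max * i / cap_rows
        ring = center_e + radius * (np.sin(phi) * ring_dirs + np.cos(phi) * u)
        verts.append(ring)
    rim_ring = verts[-1]

    # Straight cone blending rim -> cylinder top circle at z = 0.
    cyl_top = np.column_stack([
        p.shaft_radius * np.cos(theta),
        p.shaft_radius * np.sin(theta),
        np.zeros(n_theta),
    ])
    for k in range(1, blend_rows):
        t = k / blend_rows
        verts.append((1 - t) * rim_ring + t * cyl_top)

    # Cylinder rings, z = 0 down to -shaft_length.
    for m in range(cyl_rows + 1):
        z = -p.shaft_length * m / cyl_rows
        verts.append(cyl_top + np.array([0.0, 0.0, z]))

    vertices = np.vstack(verts)

    # Faces: apex fan + quad strips between consecutive rings.
    faces = []
    nxt = (np.arange(n_theta) + 1) % n_theta
    for j in range(n_theta):
        faces.append((0, 1 + j, 1 + nxt[j]))
    n_rings = (len(vertices) - 1) // n_theta
    for ring in range(n_rings - 1):
        a0 = 1 + ring * n_theta
        b0 = a0 + n_theta
        for j in range(n_theta):
            faces.append((a0 + j, b0 + j, b0 + nxt[j]))
            faces.append((a0 + j, b0 + nxt[j], a0 + nxt[j]))
    faces = np.array(faces, dtype=np.int64)

    if p.vertex_noise_sd > 0:
        vertices = vertices + rng.normal(0.0, p.vertex_noise_sd, vertices.shape)

    # Landmarks on the analytic rim circle at 0/120/240 degrees, optionally
    # jittered along the rim (arc-length sd converted to an angle).
    land_theta = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])
    if p.landmark_jitter_sd > 0:
        land_theta = land_theta + rng.normal(0.0, p.landmark_jitter_sd / rim_r, 3)
    land_pts = center_b + rim_r * (np.outer(np.cos(land_theta), e1)
                                   + np.outer(np.sin(land_theta), e2))
    landmarks = LandmarkSet(*land_pts)

    return TriMesh(vertices, faces), landmarks, truth
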