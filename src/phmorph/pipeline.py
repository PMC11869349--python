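"""Measurement protocol: from a proximal-humerus mesh to the five parameters.

Given a triangulated surface mesh (millimetres) and three anatomical-neck
landmarks, the pipeline runs the stages in their natural order:

1.  fit the anatomical-neck plane to the three ridge landmarks and orient its
    normal toward the head side;
2.  extract the plane-mesh intersection contour nearest the landmarks and fit
    the articular-surface circle (center B) in the neck plane;
3.  collect head-side vertices, fit the humeral-head sphere (center E) with a
    single residual-trim pass to reject tuberosity contamination;
4.  locate the head apex (point A);
5.  fit the metaphyseal shaft axis (line g) from slice centroids in a band
    distal to the neck plane;
6.  derive the parameters: neck-shaft angle (angle between B->A and the
    distal shaft direction), humeral head height |AB|, articular surface
    diameter (2x circle radius), humeral head diameter (2x sphere radius) and
    medial offset (perpendicular distance from E to the shaft axis).

Each stage reports its fit residual into the result diagnostics, and stage
failures propagate as :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    Circle3D,
    DegenerateGeometryError,
    Line3D,
    Plane,
    Sphere,
    angle_between,
    fit_axis,
    fit_circle_in_plane,
    fit_plane,
    fit_sphere,
    point_line_distance,
)

__all__ = [
    "TriMesh",
    "LandmarkSet",
    "MeasurementFrame",
    "MorphometryResult",
    "MeasureConfig",
    "PipelineError",
    "orient_neck_plane",
    "extract_rim_points",
    "extract_head_vertices",
    "find_apex",
    "shaft_axis",
    "measure",
    "average_observers",
]

logger = logging.getLogger("phmorph.pipeline")


class PipelineError(RuntimeError):
    """A measurement stage failed; the message names the stage."""


@dataclass(frozen=True)
class TriMesh:
    """Triangulated surface: vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 4:
            raise ValueError("TriMesh: vertices must be an (n>=4, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) < 1:
            raise ValueError("TriMesh: faces must be an (m>=1, 3) array")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("TriMesh: face indices out of range")
        if not np.all(np.isfinite(v)):
            raise ValueError("TriMesh: non-finite vertex coordinates")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def transformed(self, rotation=None, translation=None, scale: float = 1.0
                    ) -> "TriMesh":
        """Apply ``v -> scale * R v + t`` to all vertices."""
        v = self.vertices * scale
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces)


@dataclass(frozen=True)
class LandmarkSet:
    """The three anatomical-neck ridge points seeding the neck plane."""

    p_junction: np.ndarray        # junction of articular surface / greater tuberosity
    p_anteroinferior: np.ndarray  # anteroinferior articular margin
    p_posteroinferior: np.ndarray # posteroinferior articular margin

    def __post_init__(self):
        pts = []
        for name in ("p_junction", "p_anteroinferior", "p_posteroinferior"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"LandmarkSet: {name} has non-finite coordinates")
            object.__setattr__(self, name, p)
            pts.append(p)
        pts = np.array(pts)
        if (np.linalg.norm(pts[0] - pts[1]) < 1e-9
                or np.linalg.norm(pts[0] - pts[2]) < 1e-9
                or np.linalg.norm(pts[1] - pts[2]) < 1e-9):
            raise ValueError("LandmarkSet: landmarks must be three distinct points")
        cross = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        scale = max(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[0]))
        if np.linalg.norm(cross) < 1e-9 * scale**2:
            raise ValueError("LandmarkSet: landmarks are collinear")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_junction, self.p_anteroinferior,
                         self.p_posteroinferior])

    def centroid(self) -> np.ndarray:
        return self.as_array().mean(axis=0)

    def transformed(self, rotation=None, translation=None, scale: float = 1.0
                    ) -> "LandmarkSet":
        pts = self.as_array() * scale
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return LandmarkSet(*pts)


@dataclass(frozen=True)
class MeasurementFrame:
    """All intermediate geometry of one measurement."""

    neck_plane: Plane            # normal oriented toward the head side
    articular_circle: Circle3D   # center = point B
    head_sphere: Sphere          # center = point E
    shaft_axis: Line3D           # line g, oriented proximal -> distal
    apex: np.ndarray             # point A
    apex_vertex: np.ndarray      # mesh vertex farthest from the neck plane


@dataclass(frozen=True)
class MorphometryResult:
    """The five morphometric parameters with fit diagnostics.

    ``hhd >= asd`` is deliberately not enforced: real bones may violate the
    spherical-head assumption.
    """

    neck_shaft_angle: float  # degrees
    hhh: float               # humeral head height |AB|, mm
    asd: float               # articular surface diameter (line c), mm
    hhd: float               # humeral head diameter (line h), mm
    medial_offset: float     # distance E -> shaft axis (line EF), mm
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.neck_shaft_angle < 180.0):
            raise ValueError("neck_shaft_angle must lie in (0, 180) degrees")
        for name in ("hhh", "asd", "hhd", "medial_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    PARAMETER_FIELDS = ("neck_shaft_angle", "hhh", "asd", "hhd", "medial_offset")

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in self.PARAMETER_FIELDS}


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable knobs of the measurement protocol (defaults are sensible)."""

    rim_band_mm: float = 1.0          # half-width of optional rim vertex augmentation
    rim_augment: bool = False         # add near-plane vertices to the rim contour
    head_margin_mm: float = 0.5       # min signed distance for head-sphere vertices
    min_head_vertices: int = 20
    meta_band: tuple[float, float] = (1.0, 2.5)  # in units of provisional HHD
    n_slices: int = 8
    apex_method: str = "sphere"       # "sphere" (model-based) or "vertex"
    circle_from_landmarks: bool = False  # fall back to the 3 landmarks only

    def __post_init__(self):
        if self.rim_band_mm < 0 or self.head_margin_mm < 0:
            raise ValueError("tolerances must be non-negative")
        if not 0 < self.meta_band[0] < self.meta_band[1]:
            raise ValueError("meta_band must satisfy 0 < near < far")
        if self.apex_method not in ("sphere", "vertex"):
            raise ValueError("apex_method must be 'sphere' or 'vertex'")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def orient_neck_plane(plane: Plane, mesh: TriMesh) -> Plane:
    """Flip the plane normal (if needed) so the head side is positive.

    The humeral head is a compact cap reaching at most one head-height above
    the neck plane, whereas the shaft extends several head-diameters below
    it, so the head side is the side with the *smaller* maximal extent.  If
    one side is empty (e.g. a hemisphere resting on the plane), the occupied
    side is the head side.  Idempotent: re-orienting an oriented plane is a
    no-op.
    """
    d = plane.signed_distance(mesh.vertices)
    pos_extent = float(max(d.max(), 0.0))
    neg_extent = float(max(-d.min(), 0.0))
    if pos_extent < 1e-6 and neg_extent < 1e-6:
        raise DegenerateGeometryError(
            "orient_neck_plane: all vertices lie on the plane"
        )
    if neg_extent < 1e-6:
        return plane
    if pos_extent < 1e-6:
        return plane.flipped()
    return plane.flipped() if pos_extent > neg_extent else plane


def _unique_edges_with_faces(faces: np.ndarray):
    """(edge array sorted per-row, parallel face-id array); edges repeat."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    face_ids = np.tile(np.arange(len(faces)), 3)
    return edges, face_ids


def extract_rim_points(mesh: TriMesh, plane: Plane, band_mm: float = 1.0,
                       landmarks: LandmarkSet | None = None,
                       augment: bool = False) -> np.ndarray:
    """Intersection contour of the oriented neck plane with the mesh.

    The contour is built from mesh edges strictly crossing the plane plus
    vertices lying on the plane (within a scale-relative tolerance, which
    catches meshes whose vertex rings coincide exactly with the plane).  When
    several closed contours exist, the connected contour nearest the landmark
    centroid is returned.  ``band_mm`` only controls the optional vertex
    augmentation (off by default): the crossing set itself is band-independent.
    """
    verts = mesh.vertices
    d = plane.signed_distance(verts)
    eps_on = 1e-9 * max(mesh.bbox_diagonal, 1.0)
    on_plane = np.abs(d) <= eps_on

    edges, face_ids = _unique_edges_with_faces(mesh.faces)
    da, db = d[edges[:, 0]], d[edges[:, 1]]
    crossing = (da * db < 0) & ~on_plane[edges[:, 0]] & ~on_plane[edges[:, 1]]

    # items: (point, faces touching it) -- crossings keyed by undirected edge
    points: list[np.ndarray] = []
    item_faces: list[list[int]] = []
    seen_edges: dict[tuple[int, int], int] = {}
    for e_idx in np.nonzero(crossing)[0]:
        a, b = int(edges[e_idx, 0]), int(edges[e_idx, 1])
        key = (a, b)
        if key in seen_edges:
            item_faces[seen_edges[key]].append(int(face_ids[e_idx]))
            continue
        t = d[a] / (d[a] - d[b])
        points.append(verts[a] + t * (verts[b] - verts[a]))
        item_faces.append([int(face_ids[e_idx])])
        seen_edges[key] = len(points) - 1

    vertex_ids = np.nonzero(on_plane)[0]
    if augment and band_mm > 0:
        vertex_ids = np.nonzero(np.abs(d) <= max(band_mm, eps_on))[0]
    if len(vertex_ids):
        vert_face_map: dict[int, list[int]] = {int(v): [] for v in vertex_ids}
        for fi, face in enumerate(mesh.faces):
            for v in face:
                if int(v) in vert_face_map:
                    vert_face_map[int(v)].append(fi)
        for v in vertex_ids:
            points.append(verts[int(v)])
            item_faces.append(vert_face_map[int(v)])

    if not points:
        raise DegenerateGeometryError(
            "extract_rim_points: plane does not intersect the mesh"
        )

    # Union-find over items sharing a face -> connected contours.
    parent = list(range(len(points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_face: dict[int, int] = {}
    for item, faces in enumerate(item_faces):
        for fi in faces:
            if fi in by_face:
                ra, rb = find(by_face[fi]), find(item)
                if ra != rb:
                    parent[rb] = ra
            else:
                by_face[fi] = item

    roots = np.array([find(i) for i in range(len(points))])
    pts = np.array(points)
    components = [pts[roots == r] for r in np.unique(roots)]
    if len(components) == 1:
        return components[0]
    if landmarks is None:
        return max(components, key=len)
    # Several contours (or a fragmented one, when vertex noise is comparable
    # to the edge length): keep every component consistent with the rim
    # circle sketched by the three landmarks, and merge them.
    lm_circle, _ = fit_circle_in_plane(landmarks.as_array(), plane)
    e1, e2 = plane.basis()

    def radial_deviation(component):
        rel = component - lm_circle.center
        inplane = np.column_stack([rel @ e1, rel @ e2])
        return float(np.mean(np.abs(np.linalg.norm(inplane, axis=1)
                                    - lm_circle.radius)))

    kept = [c for c in components if radial_deviation(c) < 0.25 * lm_circle.radius]
    if kept:
        return np.vstack(kept)
    center = landmarks.centroid()
    return min(components,
               key=lambda c: float(np.mean(np.linalg.norm(c - center, axis=1))))


def extract_head_vertices(mesh: TriMesh, plane: Plane, margin_mm: float = 0.5,
                          min_vertices: int = 20) -> np.ndarray:
    """Head-side vertices feeding the humeral-head sphere fit.

    Keeps vertices with signed distance > ``margin_mm`` above the oriented
    neck plane, then performs a single trim pass: after a provisional sphere
    fit, vertices with absolute residual above 2x the RMS residual are
    discarded (reducing greater-tuberosity contamination).  The caller refits
    the sphere on the returned set.
    """
    d = plane.signed_distance(mesh.vertices)
    pts = mesh.vertices[d > margin_mm]
    if len(pts) < min_vertices:
        raise DegenerateGeometryError(
            f"extract_head_vertices: only {len(pts)} vertices above the plane"
        )
    sphere, rms = fit_sphere(pts)
    resid = np.abs(np.linalg.norm(pts - sphere.center, axis=1) - sphere.radius)
    keep = resid <= max(2.0 * rms, 1e-9)
    if np.count_nonzero(keep) >= min_vertices:
        pts = pts[keep]
    return pts


def find_apex(mesh: TriMesh, plane: Plane) -> np.ndarray:
    """Mesh vertex with maximal signed distance from the oriented neck plane.

    Exact ties are broken by the smallest vertex index (``argmax`` returns the
    first maximum).
    """
    d = plane.signed_distance(mesh.vertices)
    return mesh.vertices[int(np.argmax(d))].copy()


def _provisional_shaft_direction(mesh: TriMesh, apex: np.ndarray) -> np.ndarray:
    """First principal direction of all vertices, oriented away from the apex."""
    centered = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, vh = np.linalg.svd(centered, full_matrices=False)
    direction = vh[0]
    if (mesh.vertices.mean(axis=0) - apex) @ direction < 0:
        direction = -direction
    return direction


def shaft_axis(mesh: TriMesh, neck_center: np.ndarray, hhd_provisional: float,
               apex: np.ndarray, band: tuple[float, float] = (1.0, 2.5),
               n_slices: int = 8) -> Line3D:
    """Metaphyseal shaft axis (line g), oriented proximal -> distal.

    The metaphyseal band holds vertices whose depth below the neck-plane
    center, measured along the provisional axis, lies in
    ``[band[0], band[1]] * hhd_provisional``.
    """
    direction = _provisional_shaft_direction(mesh, apex)
    # depth: how far distal each vertex sits below the neck center along the
    # provisional (distal-pointing) axis.
    depth = (mesh.vertices - neck_center) @ direction
    near, far = band[0] * hhd_provisional, band[1] * hhd_provisional
    sel = (depth >= near) & (depth <= far)
    if not np.any(sel):
        raise DegenerateGeometryError("shaft_axis: metaphyseal band is empty")
    # The band planes are perpendicular to the provisional direction, which
    # may be a few degrees off the true axis; trim_ends drops the boundary
    # slabs whose obliquely-cut cross-sections would bias the fit.
    axis = fit_axis(mesh.vertices[sel], direction, n_slices=n_slices,
                    trim_ends=True)
    band_centroid = mesh.vertices[sel].mean(axis=0)
    if (band_centroid - apex) @ axis.direction < 0:
        axis = Line3D(axis.anchor, -axis.direction)
    return axis


def _sphere_apex(circle_center: np.ndarray, normal: np.ndarray,
                 sphere: Sphere) -> np.ndarray:
    """Far intersection of the ray ``B + t n`` (t > 0) with the head sphere."""
    rel = circle_center - sphere.center
    b = rel @ normal
    c = rel @ rel - sphere.radius**2
    disc = b * b - c
    if disc < 0:
        # Ray misses the sphere (strongly aspheric head): fall back to the
        # sphere point farthest along the plane normal.
        return sphere.center + sphere.radius * normal
    return circle_center + (-b + np.sqrt(disc)) * normal


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{self.label}': {exc}") from exc
            return False

    return _Ctx(name)


def measure(mesh: TriMesh, landmarks: LandmarkSet,
            config: MeasureConfig | None = None
            ) -> tuple[MorphometryResult, MeasurementFrame]:
    """Run the full measurement protocol.

    Returns the five parameters plus the intermediate geometry.  Stage
    failures raise :class:`PipelineError` naming the stage.
    """
    cfg = config or MeasureConfig()
    diagnostics: dict = {}

    with _stage("neck_plane"):
        plane, plane_rms = fit_plane(landmarks.as_array())
        plane = orient_neck_plane(plane, mesh)
        diagnostics["plane_rms_mm"] = plane_rms

    with _stage("articular_circle"):
        if cfg.circle_from_landmarks:
            rim = landmarks.as_array()
        else:
            rim = extract_rim_points(mesh, plane, band_mm=cfg.rim_band_mm,
                                     landmarks=landmarks, augment=cfg.rim_augment)
        circle, circle_rms = fit_circle_in_plane(rim, plane)
        diagnostics["circle_rms_mm"] = circle_rms
        diagnostics["n_rim_points"] = int(len(rim))

    with _stage("head_sphere"):
        head_pts = extract_head_vertices(mesh, plane,
                                         margin_mm=cfg.head_margin_mm,
                                         min_vertices=cfg.min_head_vertices)
        sphere, sphere_rms = fit_sphere(head_pts)
        diagnostics["sphere_rms_mm"] = sphere_rms
        diagnostics["n_head_vertices"] = int(len(head_pts))

    with _stage("apex"):
        apex_vertex = find_apex(mesh, plane)
        if cfg.apex_method == "vertex":
            apex = apex_vertex
        else:
            apex = _sphere_apex(circle.center, plane.normal, sphere)

    with _stage("shaft_axis"):
        axis = shaft_axis(mesh, circle.center, sphere.diameter, apex,
                          band=cfg.meta_band, n_slices=cfg.n_slices)
        centroids_resid = point_line_distance(circle.center, axis)
        diagnostics["axis_offset_at_neck_mm"] = centroids_resid

    with _stage("parameters"):
        head_vec = apex - circle.center               # B -> A, points proximal
        angle = angle_between(head_vec, axis.direction)  # obtuse for anatomy
        result = MorphometryResult(
            neck_shaft_angle=angle,
            hhh=float(np.linalg.norm(head_vec)),
            asd=circle.diameter,
            hhd=sphere.diameter,
            medial_offset=point_line_distance(sphere.center, axis),
            diagnostics=diagnostics,
        )

    frame = MeasurementFrame(neck_plane=plane, articular_circle=circle,
                             head_sphere=sphere, shaft_axis=axis,
                             apex=np.asarray(apex, dtype=float),
                             apex_vertex=apex_vertex)
    return result, frame


def average_observers(results: list[MorphometryResult]) -> MorphometryResult:
    """Arithmetic mean of per-observer readings, per parameter."""
    if not results:
        raise ValueError("average_observers: empty result list")
    means = {
        name: float(np.mean([getattr(r, name) for r in results]))
        for name in MorphometryResult.PARAMETER_FIELDS
    }
    merged = {"observers": [r.diagnostics for r in results]}
    return MorphometryResult(**means, diagnostics=merged)
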