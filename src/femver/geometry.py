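"""Low-level geometric primitives for bone morphometry.

Everything downstream (slice levels, anteversion angles, registration of the
postoperative femur) is built from the operations here: algebraic circle
fitting, total-least-squares line fitting, plane/mesh cross-sections, signed
projected angles, and rigid iterative-closest-point registration.

Units are millimetres for lengths and degrees for angles throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import (
    DegenerateGeometryError,
    InsufficientGeometryError,
    MissingLandmarkError,
    NonConvergenceWarning,
    RegistrationError,
    UndefinedProjectionError,
)

# canonical landmark names (landmark JSON keys)
GT = "GT"
CLT = "CLT"
MED_POST_CONDYLE = "MED_POST_CONDYLE"
LAT_POST_CONDYLE = "LAT_POST_CONDYLE"
MED_EPICONDYLE = "MED_EPICONDYLE"
LAT_EPICONDYLE = "LAT_EPICONDYLE"
STEM_NECK = "STEM_NECK"  # face-label key, not a point landmark

REQUIRED_LANDMARKS = (
    GT,
    CLT,
    MED_POST_CONDYLE,
    LAT_POST_CONDYLE,
    MED_EPICONDYLE,
    LAT_EPICONDYLE,
)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Line3D:
    """An infinite 3D line through ``origin`` with unit ``direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n < 1e-12:
            raise DegenerateGeometryError("line direction has zero norm")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def at(self, t: float) -> np.ndarray:
        return self.origin + float(t) * self.direction

    def station_of(self, point) -> float:
        """Signed coordinate of ``point`` along the line from ``origin``."""
        return float(np.dot(np.asarray(point, float) - self.origin, self.direction))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise DegenerateGeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise DegenerateGeometryError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class PlanarContour:
    """A cross-section loop in the 2D slice frame at a given axial station."""

    station: float
    points: np.ndarray  # (n, 2), ordered, counter-clockwise if closed
    closed: bool = True
    open_warning: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 3:
            raise DegenerateGeometryError("contour needs at least 3 points")

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def area(self) -> float:
        return float(self.polygon().area)

    def contains(self, other: "PlanarContour") -> bool:
        return self.polygon().contains(Polygon(other.points).representative_point())

    def resampled(self, n: int) -> np.ndarray:
        """Arc-length uniform resampling of the (closed) boundary to n points."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0:
            raise DegenerateGeometryError("zero-length contour")
        t = np.linspace(0.0, total, n, endpoint=not self.closed)
        x = np.interp(t, s, pts[:, 0])
        y = np.interp(t, s, pts[:, 1])
        return np.column_stack([x, y])


@dataclass
class SurfaceModel:
    """Triangulated bone (or bone+implant) surface with named landmarks.

    ``landmarks`` maps canonical names to 3D points in the mesh frame;
    ``face_labels`` maps region names (e.g. STEM_NECK) to face-index arrays.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    landmarks: dict = field(default_factory=dict)
    side: str = "right"  # "left" | "right"
    face_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) < 4:
            raise DegenerateGeometryError("mesh needs at least 4 vertices")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.landmarks = {
            k: np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()
        }
        self.face_labels = {
            k: np.asarray(v, dtype=np.int64).ravel() for k, v in self.face_labels.items()
        }

    # -- queries ------------------------------------------------------------

    def landmark(self, name: str) -> np.ndarray:
        try:
            return self.landmarks[name]
        except KeyError:
            raise MissingLandmarkError(f"landmark {name!r} not present") from None

    def has_landmark(self, name: str) -> bool:
        return name in self.landmarks

    def labeled_vertices(self, label: str) -> np.ndarray:
        """Vertices referenced by the faces carrying ``label``."""
        if label not in self.face_labels:
            raise MissingLandmarkError(f"face label {label!r} not present")
        idx = np.unique(self.faces[self.face_labels[label]].ravel())
        return self.vertices[idx]

    def vertices_excluding_label(self, label: str | None) -> np.ndarray:
        """Vertices not exclusively used by faces carrying ``label``."""
        if label is None or label not in self.face_labels:
            return self.vertices
        mask = np.ones(len(self.faces), dtype=bool)
        mask[self.face_labels[label]] = False
        keep = np.unique(self.faces[mask].ravel())
        return self.vertices[keep]

    def is_edge_manifold(self) -> bool:
        """True when every edge is shared by exactly two faces (closed surface)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def landmark_surface_distances(self) -> dict:
        """Distance of every landmark to the nearest mesh vertex (mm)."""
        tree = cKDTree(self.vertices)
        return {k: float(tree.query(v)[0]) for k, v in self.landmarks.items()}

    # -- constructive -------------------------------------------------------

    def transformed(self, T: RigidTransform) -> "SurfaceModel":
        return SurfaceModel(
            T.apply(self.vertices),
            self.faces.copy(),
            {k: T.apply(v) for k, v in self.landmarks.items()},
            self.side,
            {k: v.copy() for k, v in self.face_labels.items()},
        )

    def mirrored(self) -> "SurfaceModel":
        """Mirror through the x-z plane, flipping the side label.

        Face winding is reversed so orientation stays consistent."""
        M = np.diag([1.0, -1.0, 1.0])
        return SurfaceModel(
            self.vertices @ M,
            self.faces[:, ::-1].copy(),
            {k: v @ M for k, v in self.landmarks.items()},
            "left" if self.side == "right" else "right",
            {k: v.copy() for k, v in self.face_labels.items()},
        )


# --------------------------------------------------------------------------
# fitting primitives
# --------------------------------------------------------------------------


class CircleFit(NamedTuple):
    center: np.ndarray  # (2,)
    radius: float
    rms: float  # RMS radial residual


def fit_circle(points) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through 2D points.

    Raises DegenerateGeometryError for < 3 points or collinear input.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    mean = pts.mean(axis=0)
    centered = pts - mean  # shift to the centroid for numerical conditioning
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("circle fit points are collinear")
    A = np.column_stack([2.0 * centered, np.ones(len(pts))])
    b = (centered**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2] + mean
    radius = float(np.sqrt(sol[2] + sol[:2] @ sol[:2]))
    r = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((r - radius) ** 2)))
    return CircleFit(center, radius, rms)


def fit_line_3d(points) -> Line3D:
    """Total-least-squares 3D line (first principal axis through the centroid).

    The direction sign is canonicalized so the largest-magnitude component is
    positive, making the result deterministic.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    uniq = np.unique(np.round(pts, 12), axis=0)
    if len(uniq) < 2:
        raise DegenerateGeometryError("line fit needs at least 2 distinct points")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    d = vt[0]
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    return Line3D(centroid, d)


def fit_line_2d(points) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares 2D line; returns (point_on_line, unit_direction)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    uniq = np.unique(np.round(pts, 12), axis=0)
    if len(uniq) < 2:
        raise DegenerateGeometryError("line fit needs at least 2 distinct points")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    d = vt[0]
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    return centroid, d / np.linalg.norm(d)


# --------------------------------------------------------------------------
# slice frame and plane sections
# --------------------------------------------------------------------------


def plane_basis(direction) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (e1, e2) of the plane normal to
    ``direction``, right-handed about it (e1 x e2 = n)."""
    n = np.asarray(direction, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)
    k = int(np.argmin(np.abs(n)))
    a = np.zeros(3)
    a[k] = 1.0
    e1 = a - np.dot(a, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _chain_segments(segments: np.ndarray, tol: float) -> list[tuple[np.ndarray, bool]]:
    """Chain unordered 2-point segments into polylines/loops.

    Returns a list of (points (k,2), closed_flag).
    """
    if len(segments) == 0:
        return []
    # quantized endpoint keys, vectorized
    q = np.round(np.asarray(segments) / tol).astype(np.int64)  # (k, 2, 2)
    keys = [[(int(a), int(b)) for a, b in seg] for seg in q]

    adjacency: dict = {}
    for i in range(len(segments)):
        for endpoint in (0, 1):
            adjacency.setdefault(keys[i][endpoint], []).append((i, endpoint))

    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        pts = [segments[start][0], segments[start][1]]
        head_key, tail_key = keys[start][0], keys[start][1]
        # extend forward from the tail, then (after reversal) from the head
        for _ in range(2):
            while True:
                nxt = None
                for j, endpoint in adjacency.get(tail_key, []):
                    if not used[j]:
                        nxt = (j, endpoint)
                        break
                if nxt is None:
                    break
                j, endpoint = nxt
                used[j] = True
                pts.append(segments[j][1 - endpoint])
                tail_key = keys[j][1 - endpoint]
            pts.reverse()
            head_key, tail_key = tail_key, head_key
        closed = head_key == tail_key and len(pts) > 3
        if closed:
            pts = pts[:-1]
        loops.append((np.asarray(pts), closed))
    return loops


def slice_mesh(
    model: SurfaceModel,
    axis: Line3D,
    station: float,
    basis: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[PlanarContour]:
    """Intersect the mesh with the plane normal to ``axis`` at ``station``.

    Returns one PlanarContour per intersection loop, in the 2D frame spanned
    by ``basis`` (default: :func:`plane_basis` of the axis direction), each
    ordered counter-clockwise, sorted by descending enclosed area. Open
    (non-loop) intersections are returned with ``open_warning`` set. An empty
    list means the plane misses the mesh.
    """
    n = axis.direction
    e1, e2 = basis if basis is not None else plane_basis(n)
    origin = axis.at(station)
    s = (model.vertices - origin) @ n
    # nudge exact-plane vertices off the plane for robust sign tests
    if np.any(np.abs(s) < 1e-9):
        origin = origin + 1e-6 * n
        s = (model.vertices - origin) @ n

    fs = s[model.faces]  # (m, 3)
    crossing = ~(np.all(fs > 0, axis=1) | np.all(fs < 0, axis=1))
    if not np.any(crossing):
        return []
    tris = model.faces[crossing]
    tvals = fs[crossing]

    # each crossing triangle has exactly two sign-change edges (vertices were
    # nudged off the plane above)
    v = model.vertices
    ia = tris  # edge starts: (v0,v1,v2)
    ib = tris[:, [1, 2, 0]]  # edge ends:   (v1,v2,v0)
    sa, sb = tvals, tvals[:, [1, 2, 0]]
    cross_edge = (sa > 0) != (sb > 0)  # (m, 3), two True per row
    rows_ok = cross_edge.sum(axis=1) == 2
    ia, ib, sa, sb, cross_edge = (
        ia[rows_ok],
        ib[rows_ok],
        sa[rows_ok],
        sb[rows_ok],
        cross_edge[rows_ok],
    )
    if len(ia) == 0:
        return []
    r, c = np.nonzero(cross_edge)  # row-major: pairs per triangle
    a_idx, b_idx = ia[r, c], ib[r, c]
    t = sa[r, c] / (sa[r, c] - sb[r, c])
    pts = v[a_idx] + t[:, None] * (v[b_idx] - v[a_idx])
    segs3 = pts.reshape(-1, 2, 3)  # (k, 2, 3)
    rel = segs3 - origin
    segs2 = np.stack([rel @ e1, rel @ e2], axis=-1)  # (k, 2, 2)

    scale = float(np.abs(segs2).max()) or 1.0
    loops = _chain_segments(segs2, tol=1e-6 * scale)

    contours = []
    for pts, closed in loops:
        if len(pts) < 3:
            continue
        if closed:
            # enforce CCW orientation
            x, y = pts[:, 0], pts[:, 1]
            area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
            if area2 < 0:
                pts = pts[::-1]
        contours.append(
            PlanarContour(station=station, points=pts, closed=closed, open_warning=not closed)
        )
    contours.sort(key=lambda c: c.area() if c.closed else 0.0, reverse=True)
    return contours


def outer_and_canal(contours: list[PlanarContour]):
    """Split a slice's contours into (outer periosteal, canal endosteal | None).

    The outer contour is the largest closed loop; the canal is the largest
    closed loop strictly contained in it.
    """
    closed = [c for c in contours if c.closed]
    if not closed:
        return None, None
    outer = closed[0]
    canal = None
    for c in closed[1:]:
        if outer.contains(c):
            canal = c
            break
    return outer, canal


# --------------------------------------------------------------------------
# anatomical axes
# --------------------------------------------------------------------------


def compute_knee_center(model: SurfaceModel) -> np.ndarray:
    """Midpoint of the transepicondylar axis (medial/lateral epicondyles)."""
    med = model.landmark(MED_EPICONDYLE)
    lat = model.landmark(LAT_EPICONDYLE)
    return (med + lat) / 2.0


def compute_faa(
    model: SurfaceModel,
    spacing: float = 1.0,
    span: tuple[float, float] = (0.10, 0.90),
    n_passes: int = 2,
    coarse_factor: float = 4.0,
) -> Line3D:
    """Femoral anatomical axis: best-fit 3D line through the centroids of
    best-fit circles to shaft cross-section outlines.

    Femoral length is the distance from the lesser-trochanter center (CLT) to
    the knee center (KC); sections are taken over 10-90% of it at ``spacing``
    mm. A first coarse pass slices normal to the CLT->KC chord to seed the
    axis; the final pass re-slices normal to the fitted line. The returned
    direction points distally (CLT toward KC).
    """
    clt = model.landmark(CLT)
    kc = compute_knee_center(model)
    chord = kc - clt
    length = np.linalg.norm(chord)
    if length < 1e-6:
        raise DegenerateGeometryError("CLT and knee center coincide")
    axis = Line3D(clt, chord)

    for ipass in range(n_passes):
        step = spacing * coarse_factor if ipass < n_passes - 1 else spacing
        lo = axis.station_of(clt + span[0] * chord)
        hi = axis.station_of(clt + span[1] * chord)
        stations = np.arange(min(lo, hi), max(lo, hi) + step / 2, step)
        e1, e2 = plane_basis(axis.direction)
        centers = []
        for st in stations:
            contours = slice_mesh(model, axis, st, basis=(e1, e2))
            outer, _ = outer_and_canal(contours)
            if outer is None:
                continue
            try:
                c = fit_circle(outer.points)
            except DegenerateGeometryError:
                continue
            centers.append(axis.at(st) + c.center[0] * e1 + c.center[1] * e2)
        if len(centers) < 10:
            raise InsufficientGeometryError(
                f"only {len(centers)} valid shaft sections (need >= 10)"
            )
        axis = fit_line_3d(np.asarray(centers))

    # orient distally
    if np.dot(axis.direction, chord) < 0:
        axis = Line3D(axis.origin, -axis.direction)
    return axis


def compute_pca_direction(
    model: SurfaceModel, axis: Line3D, basis=None
) -> np.ndarray:
    """Posterior condylar axis direction (medial -> lateral condyle) projected
    into the slice plane, as a unit 2-vector in the slice frame.

    Together with the model side this fixes the sign convention under which
    positive measured angles mean anteversion for left and right femurs alike
    (see :func:`signed_line_angle`).
    """
    med = model.landmark(MED_POST_CONDYLE)
    lat = model.landmark(LAT_POST_CONDYLE)
    e1, e2 = basis if basis is not None else plane_basis(axis.direction)
    d = lat - med
    v = np.array([np.dot(d, e1), np.dot(d, e2)])
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError("posterior condyle points coincide in projection")
    return v / n


def side_sign(side: str) -> float:
    """+1 for right femurs, -1 for left; applied to in-plane signed angles so
    that anteversion is positive on both sides."""
    return 1.0 if side == "right" else -1.0


def signed_line_angle(direction_2d, pca_dir: np.ndarray, side: str = "right") -> float:
    """Signed angle (degrees, in (-90, 90]) of an undirected in-plane line
    against the posterior condylar axis.

    The line direction is canonicalized to a non-negative PCA component; the
    counter-clockwise angle in the slice frame is then flipped for left-side
    femurs so that anteversion is positive for both sides.
    """
    u = np.asarray(direction_2d, dtype=float).reshape(2)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise DegenerateGeometryError("zero-length in-plane direction")
    u = u / nu
    a = float(np.dot(u, pca_dir))
    b = float(pca_dir[0] * u[1] - pca_dir[1] * u[0])  # cross(pca, u)
    if a < 0 or (a == 0 and b < 0):
        a, b = -a, -b
    ang = np.degrees(np.arctan2(b, a)) * side_sign(side)
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def projected_angle(subject_dir, reference_dir, axis: Line3D) -> float:
    """Signed angle in (-180, 180] from ``reference_dir`` to ``subject_dir``
    after projection onto the plane normal to ``axis``, counter-clockwise
    about the axis direction.

    2-vectors are interpreted in the deterministic slice frame of
    :func:`plane_basis`; 3-vectors are projected.
    """
    e1, e2 = plane_basis(axis.direction)

    def to_plane(v):
        v = np.asarray(v, dtype=float).ravel()
        if v.size == 2:
            return v.astype(float)
        if v.size == 3:
            return np.array([np.dot(v, e1), np.dot(v, e2)])
        raise ValueError("direction must be a 2- or 3-vector")

    u = to_plane(subject_dir)
    r = to_plane(reference_dir)
    nu, nr = np.linalg.norm(u), np.linalg.norm(r)
    full = np.linalg.norm(np.asarray(subject_dir, dtype=float).ravel())
    if nu < 1e-9 * max(full, 1.0):
        raise UndefinedProjectionError("subject direction is parallel to the axis")
    if nr < 1e-12:
        raise DegenerateGeometryError("reference direction has zero in-plane norm")
    ang = np.degrees(np.arctan2(r[0] * u[1] - r[1] * u[0], float(np.dot(u, r))))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# --------------------------------------------------------------------------
# rigid registration
# --------------------------------------------------------------------------


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iterations: int
    converged: bool


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def _principal_axis_inits(moving: np.ndarray, fixed: np.ndarray) -> list[RigidTransform]:
    """Centroid + principal-axes alignments (all four proper sign flips)."""
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    _, _, vtm = np.linalg.svd(moving - cm, full_matrices=False)
    _, _, vtf = np.linalg.svd(fixed - cf, full_matrices=False)
    inits = []
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([s1, s2, s1 * s2])  # keeps det = +1
        R = vtf.T @ S @ vtm
        if np.linalg.det(R) < 0:  # guard against reflective bases
            R = vtf.T @ (S @ np.diag([1, 1, -1])) @ vtm
        try:
            inits.append(RigidTransform(R, cf - R @ cm))
        except DegenerateGeometryError:
            continue
    return inits or [RigidTransform.identity()]


def icp_register(
    moving: SurfaceModel,
    fixed: SurfaceModel,
    exclude_label: str | None = STEM_NECK,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
    sample: int = 4000,
) -> ICPResult:
    """Rigid ICP aligning ``moving`` onto ``fixed``.

    Faces carrying ``exclude_label`` (the implant, absent preoperatively) are
    removed from both clouds before matching. Correspondences are nearest
    fixed vertices; iteration stops when the RMS improves by less than
    ``tolerance`` mm or at ``max_iterations`` (flagged, not fatal).
    Initialization: centroid + principal axes, best of the proper sign flips.
    """
    mv = moving.vertices_excluding_label(exclude_label)
    fx = fixed.vertices_excluding_label(exclude_label)
    if len(mv) == 0 or len(fx) == 0:
        raise RegistrationError("empty point set after label exclusion")
    if len(mv) > sample:
        idx = np.linspace(0, len(mv) - 1, sample).astype(int)
        mv = mv[idx]
    tree = cKDTree(fx)

    def rms_of(T):
        d, _ = tree.query(T.apply(mv))
        return float(np.sqrt(np.mean(d**2)))

    T = min(_principal_axis_inits(mv, fx), key=rms_of)
    prev = rms_of(T)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        cur = T.apply(mv)
        _, nn = tree.query(cur)
        T = _kabsch(mv, fx[nn])
        cur_rms = rms_of(T)
        if abs(prev - cur_rms) < tolerance:
            prev = cur_rms
            converged = True
            break
        prev = cur_rms
    if not converged:
        warnings.warn(
            f"ICP did not converge in {max_iterations} iterations (rms={prev:.3g} mm)",
            NonConvergenceWarning,
            stacklevel=2,
        )
    return ICPResult(transform=T, rms=prev, n_iterations=it, converged=converged)
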