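"""Slice-level determination and the six angle measurements.

Five preoperative parameters are measured on cross-sections normal to the
femoral anatomical axis (FAA), all against the posterior condylar axis (PCA):

* FA-MFN, FA-LFN — femoral anteversion at 33% and 66% of proximal femoral
  height H (GT to CLT), from the line bisecting the anterior and posterior
  cortex of the neck section;
* FA-CLT — canal major-axis torsion at the lesser-trochanter level, from the
  longest transverse (maximum Feret) diameter of the endosteal canal;
* CF-LFN, CF-CLT — orientation of the calcar femorale ridge on the canal
  boundary at the LFN and CLT levels (absent in some dysplastic hips).

Postoperative stem anteversion is measured after rigid registration of the
postoperative model into the preoperative frame, from a total-least-squares
axis through the labeled stem-neck surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point

from . import geometry as geo
from .errors import (
    DegenerateGeometryError,
    MissingStructureError,
    OrientationError,
    UndefinedProjectionError,
    UnstableMeasurementWarning,
)
from .geometry import (
    CLT,
    GT,
    STEM_NECK,
    Line3D,
    PlanarContour,
    RigidTransform,
    SurfaceModel,
    fit_line_2d,
    fit_line_3d,
    plane_basis,
    signed_line_angle,
    slice_mesh,
)

MFN_FRACTION = 0.33
LFN_FRACTION = 0.66

# detection thresholds for the calcar-femorale ridge (configurable per call)
CF_DEPTH_MM = 1.5
CF_MIN_LENGTH_MM = 3.0
NEAR_CIRCULAR_RATIO = 1.05
FERET_RATIO_WARN = 1.02


@dataclass(frozen=True)
class AnatomicalFrame:
    """Measurement frame of one femur: FAA anchored at the GT apex (stations
    increase distally), in-plane PCA direction, and the slice basis."""

    faa: Line3D  # origin at the GT projection, direction distal
    pca_dir: np.ndarray  # unit 2-vector in the slice basis (medial -> lateral)
    basis: tuple  # (e1, e2) slice basis, right-handed about faa.direction
    knee_center: np.ndarray
    side: str

    def station_of(self, point) -> float:
        return self.faa.station_of(point)

    def line_angle(self, direction_2d) -> float:
        """Signed anteversion-convention angle of an in-plane line vs PCA."""
        return signed_line_angle(direction_2d, self.pca_dir, self.side)

    def slice(self, model: SurfaceModel, station: float):
        return slice_mesh(model, self.faa, station, basis=self.basis)


@dataclass(frozen=True)
class SliceLevels:
    """The three measurement stations, mm distal to the GT apex along the FAA."""

    H: float
    mfn_station: float
    lfn_station: float
    clt_station: float


@dataclass
class MorphometryRecord:
    """Per-hip angle set (degrees) plus the calcar-femorale group flag."""

    hip_id: str
    side: str = "right"
    fa_mfn: float | None = None
    fa_lfn: float | None = None
    fa_clt: float | None = None
    cf_present_lfn: bool = False
    cf_lfn: float | None = None
    cf_clt: float | None = None
    stem_anteversion: float | None = None
    warnings: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "hip_id": self.hip_id,
            "side": self.side,
            "fa_mfn_deg": self.fa_mfn,
            "fa_lfn_deg": self.fa_lfn,
            "fa_clt_deg": self.fa_clt,
            "cf_present_lfn": self.cf_present_lfn,
            "cf_lfn_deg": self.cf_lfn,
            "cf_clt_deg": self.cf_clt,
            "stem_anteversion_deg": self.stem_anteversion,
            "warnings": ";".join(self.warnings),
        }


RECORD_COLUMNS = [
    "hip_id",
    "side",
    "fa_mfn_deg",
    "fa_lfn_deg",
    "fa_clt_deg",
    "cf_present_lfn",
    "cf_lfn_deg",
    "cf_clt_deg",
    "stem_anteversion_deg",
    "warnings",
]


# --------------------------------------------------------------------------
# frame and slice levels
# --------------------------------------------------------------------------


def build_frame(model: SurfaceModel, faa: Line3D | None = None) -> AnatomicalFrame:
    """Compute the anatomical frame (FAA anchored at GT, PCA, slice basis)."""
    if faa is None:
        faa = geo.compute_faa(model)
    gt = model.landmark(GT)
    # re-anchor at the GT projection so stations start at 0 there
    anchored = Line3D(faa.at(faa.station_of(gt)), faa.direction)
    basis = plane_basis(anchored.direction)
    pca = geo.compute_pca_direction(model, anchored, basis=basis)
    return AnatomicalFrame(
        faa=anchored,
        pca_dir=pca,
        basis=basis,
        knee_center=geo.compute_knee_center(model),
        side=model.side,
    )


def proximal_height(model: SurfaceModel, faa: Line3D) -> SliceLevels:
    """Proximal femoral height H = |station(CLT) - station(GT)| along the FAA
    and the MFN (33% H), LFN (66% H) and CLT measurement stations."""
    gt = model.landmark(GT)
    clt = model.landmark(CLT)
    s_gt = faa.station_of(gt)
    s_clt = faa.station_of(clt)
    h = s_clt - s_gt
    if h <= 0:
        raise OrientationError(
            "CLT is not distal to GT along the FAA (check landmarks/axis orientation)"
        )
    return SliceLevels(
        H=float(h),
        mfn_station=float(MFN_FRACTION * h),
        lfn_station=float(LFN_FRACTION * h),
        clt_station=float(h),
    )


# --------------------------------------------------------------------------
# neck bisector angle (FA-MFN, FA-LFN)
# --------------------------------------------------------------------------


def _principal_axes_2d(points: np.ndarray):
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    # eigh returns ascending order: v[:,1] is the long axis
    return c, v[:, 1], v[:, 0], np.sqrt(max(w[1], 0.0)), np.sqrt(max(w[0], 0.0))


def measure_fa_neck(
    contour: PlanarContour,
    pca_dir: np.ndarray,
    side: str = "right",
    n_samples: int = 41,
    near_circular_ratio: float = NEAR_CIRCULAR_RATIO,
) -> float:
    """Femoral anteversion from a neck cross-section.

    The cortical bisector is the total-least-squares line through midpoints of
    anterior/posterior boundary pairs sampled along the section's principal
    (long) direction; for an exact ellipse it coincides with the major axis.
    A near-circular section triggers UnstableMeasurementWarning but still
    returns the value.
    """
    pts = contour.resampled(512)
    c, long_ax, short_ax, s_long, s_short = _principal_axes_2d(pts)
    if s_short > 0 and s_long / s_short < near_circular_ratio:
        warnings.warn(
            f"near-circular neck section (axis ratio {s_long / max(s_short, 1e-12):.3f});"
            " bisector angle is unstable",
            UnstableMeasurementWarning,
            stacklevel=2,
        )
    t = (pts - c) @ long_ax
    t_lo, t_hi = np.quantile(t, [0.05, 0.95])
    boundary = LineString(np.vstack([pts, pts[:1]]))
    span = float(np.abs((pts - c) @ short_ax).max()) * 4 + 1.0
    midpoints = []
    for ti in np.linspace(t_lo, t_hi, n_samples):
        base = c + ti * long_ax
        probe = LineString([base - span * short_ax, base + span * short_ax])
        inter = probe.intersection(boundary)
        xs = _collect_points(inter)
        if len(xs) < 2:
            continue
        w = (np.asarray(xs) - base) @ short_ax
        midpoints.append(base + 0.5 * (w.min() + w.max()) * short_ax)
    if len(midpoints) < 2:
        raise DegenerateGeometryError("could not sample cortical midpoints")
    _, d = fit_line_2d(np.asarray(midpoints))
    return signed_line_angle(d, pca_dir, side)


def _collect_points(geom) -> list:
    if geom.is_empty:
        return []
    if isinstance(geom, Point):
        return [[geom.x, geom.y]]
    if isinstance(geom, MultiPoint):
        return [[p.x, p.y] for p in geom.geoms]
    if isinstance(geom, LineString):
        return [list(xy) for xy in geom.coords]
    if hasattr(geom, "geoms"):
        out = []
        for g in geom.geoms:
            out.extend(_collect_points(g))
        return out
    return []


# --------------------------------------------------------------------------
# canal major-axis torsion (FA-CLT)
# --------------------------------------------------------------------------


def max_feret_chord(points: np.ndarray) -> tuple[int, int, float]:
    """Indices and length of the maximum Feret (longest point-pair) chord.

    Uses the convex hull to restrict the candidate pairs; ties are broken by
    first occurrence in traversal order.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    if len(pts) >= 5:
        try:
            hull_idx = np.sort(ConvexHull(pts).vertices)
        except Exception:
            hull_idx = np.arange(len(pts))
    else:
        hull_idx = np.arange(len(pts))
    hp = pts[hull_idx]
    d2 = ((hp[:, None, :] - hp[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if i > j:
        i, j = j, i
    return int(hull_idx[i]), int(hull_idx[j]), float(np.sqrt(d2[i, j]))


def measure_fa_clt(
    canal_contour: PlanarContour,
    pca_dir: np.ndarray,
    side: str = "right",
    feret_ratio_warn: float = FERET_RATIO_WARN,
) -> float:
    """Canal torsion at the CLT level: signed angle of the canal's longest
    transverse diameter (maximum Feret chord) against the PCA."""
    pts = canal_contour.resampled(512)
    i, j, dmax = max_feret_chord(pts)
    chord = pts[j] - pts[i]
    # minimum caliper width via rotating the chord 90 deg is overkill here;
    # compare against the smallest principal extent for the stability check
    _, _, _, s_long, s_short = _principal_axes_2d(pts)
    if s_short > 0 and s_long / s_short < feret_ratio_warn:
        warnings.warn(
            "near-circular canal: maximum Feret diameter is nearly tied",
            UnstableMeasurementWarning,
            stacklevel=2,
        )
    return signed_line_angle(chord, pca_dir, side)


# --------------------------------------------------------------------------
# calcar femorale
# --------------------------------------------------------------------------


def detect_cf(
    contour: PlanarContour,
    min_ridge_length: float = CF_MIN_LENGTH_MM,
    depth_threshold: float = CF_DEPTH_MM,
) -> tuple[bool, tuple[np.ndarray, np.ndarray] | None]:
    """Detect the calcar-femorale ridge on an endosteal (canal) contour.

    The ridge reads as a tongue of bone protruding into the canal lumen, i.e.
    a run of boundary points deviating inward from the canal's convex hull.
    A candidate run needs deviation depth > ``depth_threshold`` (1.5 mm); the
    ridge is *present* when its extent into the canal — the maximum hull
    deviation — reaches ``min_ridge_length`` (3 mm). Returns the flag and,
    when present, the total-least-squares (point, direction) line through the
    ridge points. Absence is a valid result, never an error.
    """
    pts = contour.resampled(384)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    boundary = hull.exterior
    dev = np.array([boundary.distance(Point(p)) for p in pts])

    deep = dev > depth_threshold
    if not np.any(deep):
        return False, None
    # contiguous cyclic runs of deep deviation; take the deepest run
    idx = np.arange(len(pts))
    runs = _cyclic_runs(deep)
    best = max(runs, key=lambda r: dev[r].max())
    ridge_length = float(dev[best].max())
    if ridge_length < min_ridge_length:
        return False, None
    # fit the ridge line to the crest of the protrusion; the flanks near the
    # mouth follow the wall shape and would bias the orientation
    grown = _grow_run(dev > min(0.3, depth_threshold / 2), best, len(pts))
    deep_pts = pts[idx[grown]]
    deep_dev = dev[idx[grown]]
    for band in (0.35, 0.8, ridge_length):
        sel = deep_dev >= ridge_length - band
        if sel.sum() >= 6:
            break
    fit_pts = deep_pts[sel]
    line = fit_line_2d(fit_pts)
    for _ in range(3):  # trim off-crest stragglers (e.g. a notch side-wall)
        p0, d = line
        resid = np.abs((fit_pts - p0) @ np.array([-d[1], d[0]]))
        keep = resid <= 0.3
        if keep.sum() < 4 or keep.all():
            break
        fit_pts = fit_pts[keep]
        line = fit_line_2d(fit_pts)
    return True, line


def _cyclic_runs(mask: np.ndarray) -> list[np.ndarray]:
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    # rotate so position 0 is False, then split
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append((np.arange(i, j) + start) % n)
            i = j
        else:
            i += 1
    return runs


def _grow_run(mask: np.ndarray, run: np.ndarray, n: int) -> np.ndarray:
    lo, hi = int(run[0]), int(run[-1])
    steps = 0
    while mask[(lo - 1) % n] and (lo - 1) % n != hi and steps < n:
        lo = (lo - 1) % n
        steps += 1
    steps = 0
    while mask[(hi + 1) % n] and (hi + 1) % n != lo and steps < n:
        hi = (hi + 1) % n
        steps += 1
    if lo <= hi:
        return np.arange(lo, hi + 1)
    return np.concatenate([np.arange(lo, n), np.arange(0, hi + 1)])


def measure_cf_angle(cf_line, pca_dir: np.ndarray, side: str = "right") -> float:
    """Signed in-plane angle between the calcar-femorale line and the PCA."""
    if cf_line is None:
        raise MissingStructureError("no calcar-femorale line (ridge absent)")
    _, direction = cf_line
    return signed_line_angle(direction, pca_dir, side)


# --------------------------------------------------------------------------
# stem anteversion
# --------------------------------------------------------------------------


def measure_stem_anteversion(
    post_model: SurfaceModel,
    pre_frame: AnatomicalFrame,
    transform: RigidTransform,
) -> float:
    """Stem anteversion: signed projected angle between the stem neck axis and
    the PCA in the plane normal to the FAA.

    The stem neck axis is the total-least-squares 3D line through the
    STEM_NECK-labeled surface points mapped into the preoperative frame by
    ``transform`` (from registration)."""
    pts = transform.apply(post_model.labeled_vertices(STEM_NECK))
    axis3d = fit_line_3d(pts)
    e1, e2 = pre_frame.basis
    d2 = np.array([np.dot(axis3d.direction, e1), np.dot(axis3d.direction, e2)])
    if np.linalg.norm(d2) < 1e-6:
        raise UndefinedProjectionError("stem neck axis is parallel to the FAA")
    return pre_frame.line_angle(d2)


# --------------------------------------------------------------------------
# per-hip orchestration
# --------------------------------------------------------------------------


def measure_hip(
    pre_model: SurfaceModel,
    post_model: SurfaceModel | None = None,
    hip_id: str = "hip",
    cf_depth: float = CF_DEPTH_MM,
    cf_min_length: float = CF_MIN_LENGTH_MM,
    frame: AnatomicalFrame | None = None,
) -> MorphometryRecord:
    """Measure all parameters of one hip: the five preoperative angles, the
    CF-presence flag at LFN and, when a postoperative model is given,
    registration plus stem anteversion."""
    rec = MorphometryRecord(hip_id=hip_id, side=pre_model.side)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if frame is None:
            frame = build_frame(pre_model)
        levels = proximal_height(pre_model, frame.faa)

        for name, station in (("fa_mfn", levels.mfn_station), ("fa_lfn", levels.lfn_station)):
            outer, _ = geo.outer_and_canal(frame.slice(pre_model, station))
            if outer is None:
                raise DegenerateGeometryError(f"{hip_id}: no section at {name} station")
            setattr(rec, name, measure_fa_neck(outer, frame.pca_dir, frame.side))

        _, canal_clt = geo.outer_and_canal(frame.slice(pre_model, levels.clt_station))
        if canal_clt is None:
            raise DegenerateGeometryError(f"{hip_id}: no canal contour at the CLT station")
        rec.fa_clt = measure_fa_clt(canal_clt, frame.pca_dir, frame.side)

        _, canal_lfn = geo.outer_and_canal(frame.slice(pre_model, levels.lfn_station))
        if canal_lfn is not None:
            present, line = detect_cf(canal_lfn, cf_min_length, cf_depth)
            rec.cf_present_lfn = present
            if present:
                rec.cf_lfn = measure_cf_angle(line, frame.pca_dir, frame.side)
        present_clt, line_clt = detect_cf(canal_clt, cf_min_length, cf_depth)
        if present_clt:
            rec.cf_clt = measure_cf_angle(line_clt, frame.pca_dir, frame.side)

        if post_model is not None:
            icp = geo.icp_register(post_model, pre_model)
            rec.stem_anteversion = measure_stem_anteversion(post_model, frame, icp.transform)

        rec.warnings = [str(w.message) for w in caught]
    return rec
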