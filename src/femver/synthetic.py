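"""Parametric synthetic femurs, implants, and cohort tables with known truth.

The femur generator lofts analytic cross-sections along a straight anatomical
axis: an elliptical neck whose midline rotates to the requested anteversion at
the MFN and LFN stations, an elliptical endosteal canal with a specified
major-axis torsion at the lesser-trochanter (CLT) level, an optional
posteromedial calcar-femorale tongue at specified in-plane angles, a circular
diaphysis, and a condylar flare carrying the knee landmarks. Realism is
deliberately schematic: the downstream measurements depend only on section
shape at three stations, not on anatomical detail.

The cohort generator draws per-group predictor values from (truncated) normal
distributions and builds the stem-anteversion response from a group-specific
linear model plus noise, mirroring the statistical structure of a dysplastic-
hip arthroplasty cohort split by calcar-femorale presence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .errors import SpecError
from .geometry import (
    CLT,
    GT,
    LAT_EPICONDYLE,
    LAT_POST_CONDYLE,
    MED_EPICONDYLE,
    MED_POST_CONDYLE,
    STEM_NECK,
    RigidTransform,
    SurfaceModel,
)
from .morphometry import LFN_FRACTION, MFN_FRACTION, MorphometryRecord

ANGLE_BOUNDS = (-90.0, 90.0)


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass
class FemurSpec:
    """Ground-truth parameters of one synthetic femur (mm / degrees)."""

    H: float = 75.0  # proximal femoral height, GT to CLT
    shaft_length: float = 300.0  # femoral length, CLT to knee center
    shaft_radius: float = 13.5
    neck_anteversion_mfn: float = 18.5
    neck_anteversion_lfn: float = 37.6
    canal_torsion_clt: float = 52.0
    canal_axis_ratio: float = 1.6
    cf_present: bool = True
    cf_angle_lfn: float | None = 35.9
    cf_angle_clt: float | None = 51.5
    cf_depth: float = 5.0  # tongue extent into the canal lumen
    stem_anteversion: float | None = 26.7
    side: str = "right"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "neck_anteversion_mfn",
            "neck_anteversion_lfn",
            "canal_torsion_clt",
            "cf_angle_lfn",
            "cf_angle_clt",
            "stem_anteversion",
        ):
            v = getattr(self, name)
            if v is not None and not (ANGLE_BOUNDS[0] < v < ANGLE_BOUNDS[1]):
                raise SpecError(f"{name}={v} outside {ANGLE_BOUNDS}")
        if self.cf_present:
            if self.cf_angle_lfn is None or self.cf_angle_clt is None:
                raise SpecError("cf_present=True requires cf_angle_lfn and cf_angle_clt")
            if self.cf_depth <= 0:
                raise SpecError("cf_depth must be positive when cf_present")
        elif self.cf_angle_lfn is not None or self.cf_angle_clt is not None:
            raise SpecError("cf angles set while cf_present is False")
        if self.canal_axis_ratio < 1.05:
            raise SpecError("canal_axis_ratio must be >= 1.05 for recoverable torsion")
        if self.H <= 0 or self.shaft_length <= 0 or self.shaft_radius <= 0:
            raise SpecError("H, shaft_length and shaft_radius must be positive")
        if self.side not in ("left", "right"):
            raise SpecError("side must be 'left' or 'right'")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FemurSpec":
        return cls(**yaml.safe_load(text))


# Group-level defaults: predictor means/SDs and regression structure of a
# dysplastic cohort split by calcar-femorale presence at the LFN level.
CF_PREDICTOR_MEANS = {
    "fa_mfn_deg": 18.5,
    "fa_lfn_deg": 37.6,
    "fa_clt_deg": 52.0,
    "cf_lfn_deg": 35.9,
    "cf_clt_deg": 51.5,
}
CF_PREDICTOR_SDS = {
    "fa_mfn_deg": 9.5,
    "fa_lfn_deg": 12.6,
    "fa_clt_deg": 11.2,
    "cf_lfn_deg": 15.7,
    "cf_clt_deg": 11.6,
}
NONCF_PREDICTOR_MEANS = {"fa_mfn_deg": 33.5, "fa_lfn_deg": 39.2, "fa_clt_deg": 61.4}
NONCF_PREDICTOR_SDS = {"fa_mfn_deg": 13.1, "fa_lfn_deg": 17.3, "fa_clt_deg": 17.1}

CF_COEFFICIENTS = {
    "predictors": ["fa_clt_deg", "cf_lfn_deg"],
    "slopes": [0.464, 0.559],
    "intercept": -17.497,
}
NONCF_COEFFICIENTS = {
    "predictors": ["fa_lfn_deg"],
    "slopes": [0.749],
    "intercept": -1.433,
}
CF_MODEL_R = 0.870  # multiple R of the two-predictor group model
NONCF_MODEL_R = 0.864

CF_CROWE_COUNTS = {"I": 18, "II-III": 2, "IV": 1}
NONCF_CROWE_COUNTS = {"I": 4, "II-III": 6, "IV": 3}

TRUNCATION_BOUNDS = (-20.0, 100.0)  # anatomically plausible angle range


def _derived_noise_sd(sds: dict, coeffs: dict, model_r: float) -> float:
    """Noise SD implied by the group SDs, slopes, and target multiple R,
    assuming independent predictors."""
    signal_var = sum(
        s**2 * sds[p] ** 2 for s, p in zip(coeffs["slopes"], coeffs["predictors"])
    )
    r2 = model_r**2
    return float(np.sqrt(signal_var * (1.0 / r2 - 1.0)))


@dataclass
class CohortSpec:
    """Structure of a synthetic cohort table.

    ``noise_sd`` values default to the SDs implied by the group regression R
    (CF 0.870, non-CF 0.864) under independent predictor draws. A per-group
    predictor correlation matrix may be supplied; the default is independence
    because only predictor-response correlations are constrained by the
    published summaries.
    """

    n_cf: int = 21
    n_noncf: int = 13
    predictor_means: dict = field(
        default_factory=lambda: {"CF": dict(CF_PREDICTOR_MEANS), "nonCF": dict(NONCF_PREDICTOR_MEANS)}
    )
    predictor_sds: dict = field(
        default_factory=lambda: {"CF": dict(CF_PREDICTOR_SDS), "nonCF": dict(NONCF_PREDICTOR_SDS)}
    )
    coefficients: dict = field(
        default_factory=lambda: {"CF": dict(CF_COEFFICIENTS), "nonCF": dict(NONCF_COEFFICIENTS)}
    )
    noise_sd: dict | None = None  # {"CF": sd, "nonCF": sd}; None -> derived
    correlation: dict | None = None  # optional {"CF": matrix, "nonCF": matrix}
    seed: int = 0

    def __post_init__(self):
        if self.n_cf < 0 or self.n_noncf < 0:
            raise SpecError("group counts must be non-negative")
        if self.noise_sd is None:
            targets = {"CF": CF_MODEL_R, "nonCF": NONCF_MODEL_R}
            self.noise_sd = {
                g: _derived_noise_sd(self.predictor_sds[g], self.coefficients[g], r)
                for g, r in targets.items()
                if g in self.predictor_sds and g in self.coefficients
            }
        for v in self.noise_sd.values():
            if v < 0:
                raise SpecError("noise_sd must be >= 0")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls(**yaml.safe_load(text))


# --------------------------------------------------------------------------
# 2D section machinery (canonical right-femur frame: x anterior, y medial,
# z proximal; GT apex at z = 0, stations increase distally = -z)
# --------------------------------------------------------------------------

_E1 = np.array([0.0, -1.0])  # in-plane PCA direction, medial -> lateral
_E2 = np.array([-1.0, 0.0])  # posterior


def _angle_dir(theta_deg: float) -> np.ndarray:
    """In-plane direction of a line making the signed anteversion-convention
    angle ``theta`` with the PCA (canonical right femur)."""
    t = np.radians(theta_deg)
    return np.cos(t) * _E1 + np.sin(t) * _E2


def _ellipse(a: float, b: float, theta_deg: float, n: int = 256) -> Polygon:
    """Ellipse with semi-major ``a`` along the theta-convention direction."""
    u = _angle_dir(theta_deg)
    w = np.array([-u[1], u[0]])
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.outer(a * np.cos(t), u) + np.outer(b * np.sin(t), w)
    return Polygon(pts)


def _ellipse_radius(a, b, theta_deg, direction) -> float:
    u = _angle_dir(theta_deg)
    w = np.array([-u[1], u[0]])
    v = np.asarray(direction, float)
    v = v / np.linalg.norm(v)
    return 1.0 / np.sqrt((v @ u / a) ** 2 + (v @ w / b) ** 2)


def _smoothstep(u: float) -> float:
    u = min(max(u, 0.0), 1.0)
    return u * u * (3.0 - 2.0 * u)


_PM = np.array([-1.0, 1.0]) / np.sqrt(2.0)  # posteromedial direction


def _with_cf_spur(
    canal: Polygon, a, b, psi, cf_angle, depth, edge_length=8.0, embed=2.5
) -> Polygon:
    """Carve the calcar ridge into the canal lumen: a plate lying flat on the
    wall whose free edge runs along the cf_angle direction and protrudes
    ``depth`` mm into the canal.

    The plate is anchored at the ellipse point whose wall tangent is parallel
    to the ridge direction (taking the posteromedial of the two candidates),
    which keeps the notch clean for any angle and away from the canal
    major-axis endpoints so the maximum Feret diameter (FA-CLT) survives."""
    u_psi = _angle_dir(psi)
    w_psi = np.array([-u_psi[1], u_psi[0]])
    u = _angle_dir(cf_angle)
    cu, wu = float(u @ u_psi), float(u @ w_psi)
    # ellipse point with tangent parallel to u: tangent = -a sinT u_psi + b cosT w_psi
    T = np.arctan2(-b * cu, a * wu)
    cand = [
        a * np.cos(T) * u_psi + b * np.sin(T) * w_psi,
        -(a * np.cos(T) * u_psi + b * np.sin(T) * w_psi),
    ]
    q = max(cand, key=lambda p: float(p @ _PM))
    n_in = np.array([-u[1], u[0]])
    if float(n_in @ -q) < 0:
        n_in = -n_in  # perpendicular to the free edge, pointing into the lumen
    half = 0.5 * edge_length
    rect = Polygon(
        [
            q - half * u - embed * n_in,
            q + half * u - embed * n_in,
            q + half * u + depth * n_in,
            q - half * u + depth * n_in,
        ]
    )
    carved = canal.difference(rect)
    if carved.geom_type == "MultiPolygon":
        carved = max(carved.geoms, key=lambda g: g.area)
    return carved


def _resample_ring(poly: Polygon, n: int) -> np.ndarray:
    """Arc-length uniform resampling of a polygon boundary to ``n`` points,
    CCW, starting at the boundary point of polar angle closest to zero so that
    consecutive lofted rings stay index-aligned."""
    poly = orient(poly, sign=1.0)
    coords = np.asarray(poly.exterior.coords)  # closed (first == last)
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    m = 4 * n
    t = np.linspace(0.0, total, m, endpoint=False)
    dense = np.column_stack(
        [np.interp(t, s, coords[:, 0]), np.interp(t, s, coords[:, 1])]
    )
    ang = np.mod(np.arctan2(dense[:, 1], dense[:, 0]), 2.0 * np.pi)
    start = int(np.argmin(np.minimum(ang, 2.0 * np.pi - ang)))
    dense = np.roll(dense, -start, axis=0)
    return dense[::4]


# --------------------------------------------------------------------------
# femur generator
# --------------------------------------------------------------------------

# section-shape constants (mm)
NECK_SEMI_MAJOR = 16.0
NECK_SEMI_MINOR = 10.0
CANAL_SEMI_MAJOR = 8.5
SHAFT_CANAL_RADIUS = 5.0
CONDYLE_SEMI_AP = 22.0  # anterior-posterior semi-axis of the distal flare
CONDYLE_SEMI_ML = 35.0  # medial-lateral semi-axis
FLARE_LENGTH = 30.0
CANAL_BLEND_LENGTH = 20.0
CF_SPUR_OVERHANG = 6.0  # axial extension of the tongue beyond LFN/CLT


def _outer_section(z: float, spec: FemurSpec) -> Polygon:
    z_mfn = -MFN_FRACTION * spec.H
    z_lfn = -LFN_FRACTION * spec.H
    z_clt = -spec.H
    z_end = z_clt - spec.shaft_length
    z_flare = z_end + FLARE_LENGTH

    if z >= z_lfn:  # neck region: full ellipse, rotating midline
        if z >= z_mfn:
            phi = spec.neck_anteversion_mfn
        else:
            u = (z_mfn - z) / (z_mfn - z_lfn)
            phi = (1 - u) * spec.neck_anteversion_mfn + u * spec.neck_anteversion_lfn
        return _ellipse(NECK_SEMI_MAJOR, NECK_SEMI_MINOR, phi)
    if z >= z_clt:  # blend ellipse -> shaft circle
        u = _smoothstep((z_lfn - z) / (z_lfn - z_clt))
        a = (1 - u) * NECK_SEMI_MAJOR + u * spec.shaft_radius
        b = (1 - u) * NECK_SEMI_MINOR + u * spec.shaft_radius
        return _ellipse(a, b, spec.neck_anteversion_lfn)
    if z >= z_flare:  # diaphysis
        return _ellipse(spec.shaft_radius, spec.shaft_radius, 0.0)
    # condylar flare
    u = _smoothstep((z_flare - z) / (z_flare - z_end))
    a = (1 - u) * spec.shaft_radius + u * CONDYLE_SEMI_ML  # along PCA (y)
    b = (1 - u) * spec.shaft_radius + u * CONDYLE_SEMI_AP
    return _ellipse(a, b, 0.0)


def _canal_section(z: float, spec: FemurSpec) -> Polygon:
    z_lfn = -LFN_FRACTION * spec.H
    z_clt = -spec.H
    a = CANAL_SEMI_MAJOR
    b = a / spec.canal_axis_ratio
    psi = spec.canal_torsion_clt
    if z >= z_clt:
        canal = _ellipse(a, b, psi)
    else:
        u = _smoothstep((z_clt - z) / CANAL_BLEND_LENGTH)
        aa = (1 - u) * a + u * SHAFT_CANAL_RADIUS
        bb = (1 - u) * b + u * SHAFT_CANAL_RADIUS
        canal = _ellipse(aa, bb, psi)
    if spec.cf_present and (z_clt - CF_SPUR_OVERHANG) <= z <= (z_lfn + CF_SPUR_OVERHANG):
        zc = min(max(z, z_clt), z_lfn)
        u = (z_lfn - zc) / (z_lfn - z_clt)
        cf_angle = (1 - u) * spec.cf_angle_lfn + u * spec.cf_angle_clt
        canal = _with_cf_spur(canal, a, b, psi, cf_angle, spec.cf_depth)
    return canal


def _station_grid(spec: FemurSpec) -> np.ndarray:
    z_clt = -spec.H
    z_end = z_clt - spec.shaft_length
    z_flare = z_end + FLARE_LENGTH
    parts = [
        np.arange(0.0, z_clt, -1.5),
        # measurement stations on the grid so sections are exact there
        np.array([-MFN_FRACTION * spec.H, -LFN_FRACTION * spec.H]),
        np.arange(z_clt, z_clt - CANAL_BLEND_LENGTH, -2.5),
        np.arange(z_clt - CANAL_BLEND_LENGTH, z_flare, -6.0),
        np.arange(z_flare, z_end, -3.0),
        np.array([z_end]),
    ]
    z = np.concatenate(parts)
    return np.unique(np.round(z, 9))[::-1]  # descending from 0


def _loft(rings: list[np.ndarray], zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stack index-aligned rings into wall vertices and quad-strip faces."""
    n = rings[0].shape[0]
    verts = np.concatenate(
        [np.column_stack([r, np.full(n, z)]) for r, z in zip(rings, zs)]
    )
    faces = []
    for k in range(len(rings) - 1):
        a0 = k * n
        b0 = (k + 1) * n
        i = np.arange(n)
        j = (i + 1) % n
        faces.append(np.column_stack([a0 + i, a0 + j, b0 + i]))
        faces.append(np.column_stack([b0 + i, a0 + j, b0 + j]))
    return verts, np.concatenate(faces)


def _annulus_faces(outer0: int, inner0: int, n: int, flip: bool = False) -> np.ndarray:
    i = np.arange(n)
    j = (i + 1) % n
    f1 = np.column_stack([outer0 + i, outer0 + j, inner0 + i])
    f2 = np.column_stack([inner0 + i, outer0 + j, inner0 + j])
    f = np.concatenate([f1, f2])
    return f[:, ::-1] if flip else f


def generate_femur(
    spec: FemurSpec, n_boundary: int = 160
) -> tuple[SurfaceModel, MorphometryRecord]:
    """Build a watertight synthetic femur and its ground-truth record.

    The mesh is a hollow loft (outer cortex + endosteal canal joined by
    annular caps, torus topology), built in a canonical right-femur frame and
    mirrored afterwards for left-side specs. Deterministic given the spec.
    """
    zs = _station_grid(spec)
    outer_rings = [_resample_ring(_outer_section(z, spec), n_boundary) for z in zs]
    canal_rings = [_resample_ring(_canal_section(z, spec), n_boundary) for z in zs]

    v_out, f_out = _loft(outer_rings, zs)
    v_in, f_in = _loft(canal_rings, zs)
    n_out = len(v_out)
    verts = np.vstack([v_out, v_in])
    f_in = f_in[:, ::-1] + n_out  # reverse winding for the inner wall
    n = n_boundary
    top = _annulus_faces(0, n_out, n, flip=True)
    bottom = _annulus_faces((len(zs) - 1) * n, n_out + (len(zs) - 1) * n, n)
    faces = np.vstack([f_out, f_in, top, bottom])

    z_clt = -spec.H
    z_end = z_clt - spec.shaft_length
    gt_r = _ellipse_radius(
        NECK_SEMI_MAJOR, NECK_SEMI_MINOR, spec.neck_anteversion_mfn, np.array([0.0, -1.0])
    )
    clt_xy = spec.shaft_radius * _PM
    post_x = -CONDYLE_SEMI_AP * np.sqrt(1.0 - (20.0 / CONDYLE_SEMI_ML) ** 2)
    landmarks = {
        GT: np.array([0.0, -gt_r, 0.0]),
        CLT: np.array([clt_xy[0], clt_xy[1], z_clt]),
        MED_EPICONDYLE: np.array([0.0, CONDYLE_SEMI_ML, z_end]),
        LAT_EPICONDYLE: np.array([0.0, -CONDYLE_SEMI_ML, z_end]),
        MED_POST_CONDYLE: np.array([post_x, 20.0, z_end]),
        LAT_POST_CONDYLE: np.array([post_x, -20.0, z_end]),
    }
    model = SurfaceModel(verts, faces, landmarks, side="right")
    if spec.side == "left":
        model = model.mirrored()

    truth = MorphometryRecord(
        hip_id=f"synthetic-{spec.seed}",
        side=spec.side,
        fa_mfn=spec.neck_anteversion_mfn,
        fa_lfn=spec.neck_anteversion_lfn,
        fa_clt=spec.canal_torsion_clt,
        cf_present_lfn=spec.cf_present,
        cf_lfn=spec.cf_angle_lfn,
        cf_clt=spec.cf_angle_clt,
        stem_anteversion=spec.stem_anteversion,
    )
    return model, truth


# --------------------------------------------------------------------------
# postoperative model
# --------------------------------------------------------------------------

STEM_NECK_RADIUS = 5.5
STEM_NECK_HALF_LENGTH = 15.0
STEM_NECK_INCLINATION = 40.0  # elevation of the neck axis above the slice plane


def _stem_cylinder(center, direction, radius, half_length, n_around=48, n_axial=9):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    k = int(np.argmin(np.abs(d)))
    a = np.zeros(3)
    a[k] = 1.0
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    t = np.linspace(0, 2 * np.pi, n_around, endpoint=False)
    ring = radius * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2))
    hs = np.linspace(-half_length, half_length, n_axial)
    verts = np.concatenate([center + h * d + ring for h in hs])
    faces = []
    for kk in range(n_axial - 1):
        a0, b0 = kk * n_around, (kk + 1) * n_around
        i = np.arange(n_around)
        j = (i + 1) % n_around
        faces.append(np.column_stack([a0 + i, a0 + j, b0 + i]))
        faces.append(np.column_stack([b0 + i, a0 + j, b0 + j]))
    # cap fans
    nv = n_axial * n_around
    verts = np.vstack([verts, center - half_length * d, center + half_length * d])
    i = np.arange(n_around)
    j = (i + 1) % n_around
    faces.append(np.column_stack([np.full(n_around, nv), j, i]))
    base = (n_axial - 1) * n_around
    faces.append(np.column_stack([np.full(n_around, nv + 1), base + i, base + j]))
    return verts, np.concatenate(faces)


def generate_postop(
    pre_model: SurfaceModel,
    stem_anteversion: float,
    displacement: RigidTransform | None = None,
    seed: int = 0,
) -> SurfaceModel:
    """Postoperative model: the femur plus a labeled stem-neck cylinder whose
    axis makes ``stem_anteversion`` degrees with the PCA in the plane normal
    to the FAA, the whole model moved by ``displacement`` so downstream code
    must register it back. Deterministic given the inputs (seed kept for API
    symmetry)."""
    if displacement is None:
        displacement = RigidTransform.identity()
    work = pre_model.mirrored() if pre_model.side == "left" else pre_model

    gt = work.landmark(GT)
    clt = work.landmark(CLT)
    h = gt[2] - clt[2]
    # canonical generator frame: the anatomical axis is the z axis
    axis_up = np.array([0.0, 0.0, 1.0])
    inc = np.radians(STEM_NECK_INCLINATION)
    in_plane = -_angle_dir(stem_anteversion)  # medial-anterior end of the line
    d_neck = np.cos(inc) * np.array([in_plane[0], in_plane[1], 0.0]) + np.sin(inc) * axis_up
    center = np.array([0.0, 0.0, clt[2] + 0.55 * h]) + 12.0 * np.array(
        [in_plane[0], in_plane[1], 0.0]
    )

    cv, cf = _stem_cylinder(center, d_neck, STEM_NECK_RADIUS, STEM_NECK_HALF_LENGTH)
    n_v = len(work.vertices)
    n_f = len(work.faces)
    verts = np.vstack([work.vertices, cv])
    faces = np.vstack([work.faces, cf + n_v])
    labels = {STEM_NECK: np.arange(n_f, len(faces), dtype=np.int64)}
    post = SurfaceModel(verts, faces, dict(work.landmarks), "right", labels)
    if pre_model.side == "left":
        post = post.mirrored()
    return post.transformed(displacement)


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

COHORT_COLUMNS = [
    "hip_id",
    "group",
    "crowe_grade",
    "age_years",
    "bmi",
    "fa_mfn_deg",
    "fa_lfn_deg",
    "fa_clt_deg",
    "cf_lfn_deg",
    "cf_clt_deg",
    "stem_anteversion_deg",
]

_DEMOGRAPHICS = {  # (age mean, age sd, bmi mean, bmi sd)
    "CF": (64.9, 11.3, 24.4, 3.2),
    "nonCF": (64.9, 6.3, 23.0, 3.1),
}
_CROWE = {"CF": CF_CROWE_COUNTS, "nonCF": NONCF_CROWE_COUNTS}


def _matched_truncation_params(mean, sd, bounds=TRUNCATION_BOUNDS):
    """Underlying (mu, sigma) whose truncation to ``bounds`` has exactly the
    requested mean and SD (fixed-point on the truncated moments)."""
    from scipy.stats import truncnorm

    mu, sigma = float(mean), float(sd)
    for _ in range(40):
        a, b = (bounds[0] - mu) / sigma, (bounds[1] - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        mu_new = mu + (mean - float(m))
        sigma_new = sigma * sd / float(np.sqrt(v))
        if abs(mu_new - mu) < 1e-10 and abs(sigma_new - sigma) < 1e-10:
            mu, sigma = mu_new, sigma_new
            break
        mu, sigma = mu_new, sigma_new
    return mu, sigma


def _truncated_normal(rng, mean, sd, n, bounds=TRUNCATION_BOUNDS):
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = _matched_truncation_params(mean, sd, bounds)
    x = rng.normal(mu, sigma, size=n)
    bad = (x < bounds[0]) | (x > bounds[1])
    while np.any(bad):
        x[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (x < bounds[0]) | (x > bounds[1])
    return x


def _correlated_truncated(rng, means, sds, corr, n, bounds=TRUNCATION_BOUNDS):
    names = list(means)
    mu = np.array([means[k] for k in names])
    sd = np.array([sds[k] for k in names])
    C = np.asarray(corr, float)
    cov = np.outer(sd, sd) * C
    L = np.linalg.cholesky(cov)
    x = mu + rng.standard_normal((n, len(names))) @ L.T
    bad = np.any((x < bounds[0]) | (x > bounds[1]), axis=1)
    while np.any(bad):
        x[bad] = mu + rng.standard_normal((int(bad.sum()), len(names))) @ L.T
        bad = np.any((x < bounds[0]) | (x > bounds[1]), axis=1)
    return {k: x[:, i] for i, k in enumerate(names)}


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic cohort table with the group structure of a dysplastic-hip
    series: per-group predictor draws, a linear stem-anteversion response plus
    noise, Crowe grades, and demographics. Deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in (("CF", spec.n_cf), ("nonCF", spec.n_noncf)):
        if n == 0 or group not in spec.predictor_means:
            continue
        means = spec.predictor_means[group]
        sds = spec.predictor_sds[group]
        if spec.correlation is not None and group in spec.correlation:
            cols = _correlated_truncated(rng, means, sds, spec.correlation[group], n)
        else:
            cols = {k: _truncated_normal(rng, means[k], sds[k], n) for k in means}
        coef = spec.coefficients[group]
        y = np.full(n, float(coef["intercept"]))
        for slope, pred in zip(coef["slopes"], coef["predictors"]):
            y = y + slope * cols[pred]
        y = y + rng.normal(0.0, spec.noise_sd[group], size=n)

        crowe_counts = _CROWE[group]
        total = sum(crowe_counts.values())
        p = [c / total for c in crowe_counts.values()]
        age_m, age_s, bmi_m, bmi_s = _DEMOGRAPHICS[group]
        df = pd.DataFrame(
            {
                "group": group,
                "crowe_grade": rng.choice(list(crowe_counts), size=n, p=p),
                "age_years": rng.normal(age_m, age_s, size=n).round(1),
                "bmi": rng.normal(bmi_m, bmi_s, size=n).round(1),
            }
        )
        for k, v in cols.items():
            df[k] = v
        df["stem_anteversion_deg"] = y
        frames.append(df)

    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "hip_id", [f"hip{i + 1:03d}" for i in range(len(out))])
    for col in COHORT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[COHORT_COLUMNS]
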