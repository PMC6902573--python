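"""File-level orchestration: generate fixtures, measure meshes, analyze
cohorts, and predict stem anteversion — each stage reads and writes plain
files so stages are independently scriptable and testable."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import meshfiles, morphometry as mm, stats as st
from .errors import FemverError, SchemaError, SpecError
from .model import StemAnteversionModel
from .morphometry import RECORD_COLUMNS
from .stats import PUBLISHED_EQUATIONS, RegressionFit
from .synthetic import CohortSpec, FemurSpec, generate_cohort, generate_femur, generate_postop
from .geometry import RigidTransform

log = logging.getLogger("femver")

EXIT_CLEAN = 0
EXIT_PARTIAL = 1
EXIT_CONFIG = 2


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-mappable)."""

    seed: int = 0
    out: str = "femver_run"
    n_femurs: int = 1
    with_postop: bool = True
    mesh_format: str = "ply"
    n_boundary: int = 160  # mesh ring resolution of generated femurs
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    cf_depth_mm: float = mm.CF_DEPTH_MM
    cf_min_length_mm: float = mm.CF_MIN_LENGTH_MM
    near_circular_ratio: float = mm.NEAR_CIRCULAR_RATIO
    alpha_enter: float = st.ALPHA_ENTER
    log_level: str = "INFO"

    def __post_init__(self):
        if min(self.cf_depth_mm, self.cf_min_length_mm, self.near_circular_ratio) <= 0:
            raise SpecError("thresholds must be positive")
        if not 0 < self.alpha_enter <= 1:
            raise SpecError("alpha_enter must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise SchemaError(f"unknown config key: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _random_spec(rng: np.random.Generator, seed: int) -> FemurSpec:
    """A plausible dysplastic femur; CF angles track the canal torsion (the
    calcar forms the canal's posterior wall)."""
    torsion = float(rng.uniform(10.0, 60.0))
    cf_present = bool(rng.random() < 21 / 34)
    kw: dict = {}
    if cf_present:
        kw["cf_angle_lfn"] = float(np.clip(torsion + rng.uniform(-25, 25), 10.0, 70.0))
        kw["cf_angle_clt"] = float(np.clip(torsion + rng.uniform(-25, 25), 10.0, 70.0))
    else:
        kw["cf_angle_lfn"] = kw["cf_angle_clt"] = None
    mfn = float(rng.uniform(0.0, 50.0))
    return FemurSpec(
        H=float(rng.uniform(60.0, 90.0)),
        neck_anteversion_mfn=mfn,
        neck_anteversion_lfn=float(np.clip(mfn + rng.uniform(0.0, 25.0), 0.0, 60.0)),
        canal_torsion_clt=torsion,
        canal_axis_ratio=float(rng.uniform(1.4, 1.8)),
        cf_present=cf_present,
        stem_anteversion=float(rng.uniform(5.0, 50.0)),
        side="left" if rng.random() < 0.5 else "right",
        seed=seed,
        **kw,
    )


def run_generate(config: RunConfig) -> Path:
    """Write synthetic meshes + landmark files + truth table + cohort CSV."""
    out = Path(config.out)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "files": {}}
    truth_rows = []
    for i in range(config.n_femurs):
        spec = _random_spec(rng, seed=config.seed + i)
        model, truth = generate_femur(spec, n_boundary=config.n_boundary)
        hip_id = f"hip{i + 1:03d}"
        truth.hip_id = hip_id
        base = out / "meshes" / f"{hip_id}_pre"
        meshfiles.write_mesh(model, base.parent / f"{base.name}.{config.mesh_format}")
        meshfiles.write_landmarks(model, base.parent / f"{base.name}.landmarks.json")
        (out / "specs").mkdir(exist_ok=True)
        (out / "specs" / f"{hip_id}.yaml").write_text(spec.to_yaml())
        if config.with_postop:
            angle = float(rng.uniform(0.0, 15.0))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            a = np.radians(angle)
            R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K
            disp = RigidTransform(R, rng.uniform(-15.0, 15.0, 3))
            post = generate_postop(model, spec.stem_anteversion, disp)
            post_base = out / "meshes" / f"{hip_id}_post"
            meshfiles.write_mesh(post, post_base.parent / f"{post_base.name}.{config.mesh_format}")
            meshfiles.write_landmarks(post, post_base.parent / f"{post_base.name}.landmarks.json")
        truth_rows.append(truth.as_row())
    pd.DataFrame(truth_rows, columns=RECORD_COLUMNS).to_csv(out / "truth.csv", index=False)

    cohort = generate_cohort(CohortSpec(seed=config.seed, **config.cohort))
    cohort.to_csv(out / "cohort.csv", index=False)

    for f in sorted(out.rglob("*")):
        if f.is_file():
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_measure(config: RunConfig, mesh_dir=None) -> tuple[Path, int]:
    """Measure every ``*_pre.<fmt>`` mesh (+ optional ``*_post``) in a
    directory; returns (csv path, exit code). Per-hip failures are logged and
    skipped; all-fail gives a nonzero exit."""
    out = Path(config.out)
    mesh_dir = Path(mesh_dir) if mesh_dir else out / "meshes"
    rows, failures = [], 0
    pres = sorted(mesh_dir.glob(f"*_pre.{config.mesh_format}"))
    for pre_path in pres:
        hip_id = pre_path.name.rsplit("_pre", 1)[0]
        try:
            pre = meshfiles.read_mesh(
                pre_path, pre_path.with_name(f"{hip_id}_pre.landmarks.json")
            )
            post = None
            post_path = mesh_dir / f"{hip_id}_post.{config.mesh_format}"
            if post_path.exists():
                post = meshfiles.read_mesh(
                    post_path, post_path.with_name(f"{hip_id}_post.landmarks.json")
                )
            rec = mm.measure_hip(
                pre,
                post,
                hip_id=hip_id,
                cf_depth=config.cf_depth_mm,
                cf_min_length=config.cf_min_length_mm,
            )
            rows.append(rec.as_row())
        except (FemverError, ValueError, OSError) as exc:
            failures += 1
            log.error("measurement failed for %s: %s", hip_id, exc)
    out.mkdir(parents=True, exist_ok=True)
    csv = out / "measurements.csv"
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(csv, index=False)
    if not pres or (failures and not rows):
        return csv, EXIT_PARTIAL
    return csv, EXIT_PARTIAL if failures else EXIT_CLEAN


def run_analyze(config: RunConfig, cohort_csv=None) -> Path:
    """Fit the group models on a cohort CSV and write the analysis report."""
    out = Path(config.out)
    cohort_csv = Path(cohort_csv) if cohort_csv else out / "cohort.csv"
    try:
        df = pd.read_csv(cohort_csv)
    except Exception as exc:
        raise SchemaError(f"cannot read cohort CSV {cohort_csv}: {exc}") from exc
    results = StemAnteversionModel(df, alpha_enter=config.alpha_enter).fit()
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "analysis.json"
    report_path.write_text(json.dumps(results.to_report(), indent=1, sort_keys=True))
    (out / "analysis_summary.txt").write_text(results.summary() + "\n")
    fits = {g: f.to_dict() for g, f in results.group_fits.items()}
    (out / "fitted_equations.json").write_text(json.dumps(fits, indent=1))
    return report_path


def run_predict(config: RunConfig, measurements_csv=None, equations_json=None) -> tuple[Path, int]:
    """Apply fitted (or built-in published) equations to measured hips."""
    out = Path(config.out)
    measurements_csv = Path(measurements_csv) if measurements_csv else out / "measurements.csv"
    try:
        df = pd.read_csv(measurements_csv)
    except Exception as exc:
        raise SchemaError(f"cannot read measurements CSV {measurements_csv}: {exc}") from exc
    if equations_json:
        fits = {
            g: RegressionFit.from_dict(d)
            for g, d in json.loads(Path(equations_json).read_text()).items()
        }
        provenance = f"fitted:{equations_json}"
    else:
        fits = PUBLISHED_EQUATIONS
        provenance = "published-builtin"
    rows, failures = [], 0
    for _, row in df.iterrows():
        values = row.to_dict()
        try:
            res = st.predict_stem_anteversion(
                values, fits.get("CF", PUBLISHED_EQUATIONS["CF"]), fits.get("nonCF", PUBLISHED_EQUATIONS["nonCF"])
            )
            rows.append(
                {
                    "hip_id": res.hip_id,
                    "equation_used": res.equation_used,
                    "predicted_anteversion_deg": res.predicted_anteversion,
                    "observed_anteversion_deg": res.observed_anteversion,
                    "absolute_error_deg": res.absolute_error,
                    "equations": provenance,
                    "error": "",
                }
            )
        except FemverError as exc:
            failures += 1
            rows.append(
                {
                    "hip_id": values.get("hip_id", "hip"),
                    "equation_used": "",
                    "predicted_anteversion_deg": np.nan,
                    "observed_anteversion_deg": values.get("stem_anteversion_deg"),
                    "absolute_error_deg": np.nan,
                    "equations": provenance,
                    "error": str(exc),
                }
            )
    out.mkdir(parents=True, exist_ok=True)
    csv = out / "predictions.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    return csv, EXIT_PARTIAL if failures else EXIT_CLEAN
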