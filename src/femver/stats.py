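"""Group comparison, correlation, forward stepwise regression, prediction.

The cohort is split into a CF and a non-CF group by calcar-femorale presence
at the low-femoral-neck level. Group differences use the pooled-variance
Student t test (reproducing the published t statistics from printed summary
rows), categorical contrasts use Pearson's chi-squared without continuity
correction, associations use the Pearson product-moment R, and the
stem-anteversion predictors are chosen by pure forward selection with a
p < alpha entry criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegenerateGeometryError,
    IncompleteRecordError,
    SchemaError,
)
from .morphometry import MorphometryRecord

ALPHA_ENTER = 0.05

CF_PREDICTOR_CANDIDATES = [
    "fa_mfn_deg",
    "fa_lfn_deg",
    "fa_clt_deg",
    "cf_lfn_deg",
    "cf_clt_deg",
]
NONCF_PREDICTOR_CANDIDATES = ["fa_mfn_deg", "fa_lfn_deg", "fa_clt_deg"]
RESPONSE = "stem_anteversion_deg"


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        return cls(n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


@dataclass
class RegressionFit:
    """An ordinary-least-squares fit y = sum(coef * x) + intercept."""

    predictors: list
    coefficients: np.ndarray
    intercept: float
    R: float
    R2: float
    coefficient_p: np.ndarray
    n: int

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        self.coefficient_p = np.atleast_1d(np.asarray(self.coefficient_p, dtype=float))
        if len(self.coefficients) != len(self.predictors):
            raise ValueError("one coefficient per predictor required")
        if not np.isclose(self.R2, self.R**2, atol=1e-9):
            raise ValueError("R2 must equal R squared")

    def predict(self, values: dict) -> float:
        try:
            x = np.array([float(values[p]) for p in self.predictors])
        except (KeyError, TypeError, ValueError) as exc:
            raise IncompleteRecordError(f"missing predictor for equation: {exc}") from exc
        if np.any(~np.isfinite(x)):
            raise IncompleteRecordError(
                f"non-finite predictor among {self.predictors}"
            )
        return float(self.coefficients @ x + self.intercept)

    def equation(self) -> str:
        terms = " + ".join(
            f"{c:.3f}*{p}" for c, p in zip(self.coefficients, self.predictors)
        )
        return f"y = {terms} {self.intercept:+.3f}" if terms else f"y = {self.intercept:.3f}"

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "R": float(self.R),
            "R2": float(self.R2),
            "coefficient_p": [float(p) for p in self.coefficient_p],
            "n": int(self.n),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        return cls(
            predictors=list(d["predictors"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            R=float(d["R"]),
            R2=float(d["R2"]),
            coefficient_p=np.asarray(d.get("coefficient_p", [np.nan] * len(d["predictors"]))),
            n=int(d.get("n", 0)),
        )


# The published prediction equations. CF group: stem anteversion from FA-CLT
# and CF-LFN; non-CF group: from FA-LFN alone.
PUBLISHED_CF_EQUATION = RegressionFit(
    predictors=["fa_clt_deg", "cf_lfn_deg"],
    coefficients=np.array([0.464, 0.559]),
    intercept=-17.497,
    R=0.870,
    R2=0.870**2,
    coefficient_p=np.array([0.034, 0.001]),
    n=21,
)
PUBLISHED_NONCF_EQUATION = RegressionFit(
    predictors=["fa_lfn_deg"],
    coefficients=np.array([0.749]),
    intercept=-1.433,
    R=0.864,
    R2=0.864**2,
    coefficient_p=np.array([0.001]),
    n=13,
)
PUBLISHED_EQUATIONS = {"CF": PUBLISHED_CF_EQUATION, "nonCF": PUBLISHED_NONCF_EQUATION}


@dataclass
class PredictionResult:
    hip_id: str
    predicted_anteversion: float
    equation_used: str  # "CF" | "nonCF"
    observed_anteversion: float | None = None

    @property
    def absolute_error(self) -> float | None:
        if self.observed_anteversion is None:
            return None
        return abs(self.predicted_anteversion - self.observed_anteversion)


# --------------------------------------------------------------------------
# elementary tests
# --------------------------------------------------------------------------


def assign_group(record: MorphometryRecord | dict) -> str:
    """CF if the calcar femorale is present at the LFN level, else nonCF."""
    flag = (
        record.cf_present_lfn
        if isinstance(record, MorphometryRecord)
        else record.get("cf_present_lfn")
    )
    if flag is None or (isinstance(flag, float) and np.isnan(flag)):
        raise IncompleteRecordError("cf_present_lfn flag is not populated")
    return "CF" if bool(flag) else "nonCF"


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary):
    """Pooled-variance Student t test from per-group (n, mean, sd).

    Returns (t, df, p). Zero pooled variance: t = 0 for equal means, +-inf
    otherwise (flagged via the infinite value).
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("each group needs n >= 2")
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 <= 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return float(t), int(df), float(p)


def pooled_t_from_raw(x1, x2):
    """Pooled t from raw samples; identical to the summary form on the same data."""
    return pooled_t_from_summary(GroupSummary.from_values(x1), GroupSummary.from_values(x2))


def chi2_contingency(table):
    """Pearson chi-squared without continuity correction; (statistic, df, p)."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise DegenerateGeometryError("contingency table has a zero margin")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_r(x, y):
    """Sample Pearson correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateGeometryError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------


def _ols(X: np.ndarray, y: np.ndarray, names: list) -> RegressionFit:
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateGeometryError("rank-deficient design (collinear predictors)")
    res = sm.OLS(y, design).fit()
    fitted = res.fittedvalues
    if np.std(fitted) > 0 and np.std(y) > 0:
        R = float(np.corrcoef(fitted, y)[0, 1])
    else:
        R = 0.0
    return RegressionFit(
        predictors=list(names),
        coefficients=res.params[1:],
        intercept=float(res.params[0]),
        R=R,
        R2=R**2,
        coefficient_p=res.pvalues[1:],
        n=len(y),
    )


def ols_fit(predictor_columns: dict | pd.DataFrame, response) -> RegressionFit:
    """OLS of the response on the given predictor columns."""
    if isinstance(predictor_columns, pd.DataFrame):
        names = list(predictor_columns.columns)
        X = predictor_columns.to_numpy(dtype=float)
    else:
        names = list(predictor_columns)
        X = np.column_stack([np.asarray(predictor_columns[k], dtype=float) for k in names])
    y = np.asarray(response, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    return _ols(X, y, names)


def stepwise_forward(
    candidates: dict | pd.DataFrame,
    response,
    alpha_enter: float = ALPHA_ENTER,
) -> RegressionFit:
    """Pure forward selection: repeatedly add the candidate with the smallest
    entry p-value while it is below ``alpha_enter``; no removal step.

    Ties on the entry p-value are broken by the larger absolute partial
    correlation with the response. With no entering candidate the result is
    the intercept-only fit.
    """
    if isinstance(candidates, pd.DataFrame):
        cand = {k: candidates[k].to_numpy(dtype=float) for k in candidates.columns}
    else:
        cand = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    y = np.asarray(response, dtype=float)
    selected: list = []
    while True:
        remaining = [k for k in cand if k not in selected]
        if not remaining:
            break
        trials = []
        for k in remaining:
            names = selected + [k]
            X = np.column_stack([cand[c] for c in names])
            if len(y) <= X.shape[1] + 1:
                continue
            try:
                fit = _ols(X, y, names)
            except DegenerateGeometryError:
                continue
            p_enter = float(fit.coefficient_p[-1])
            trials.append((p_enter, -abs(_partial_corr(cand, y, selected, k)), k))
        if not trials:
            break
        trials.sort()
        p_best, _, k_best = trials[0]
        if p_best < alpha_enter:
            selected.append(k_best)
        else:
            break
    if not selected:
        ybar = float(np.mean(y))
        return RegressionFit(
            predictors=[],
            coefficients=np.empty(0),
            intercept=ybar,
            R=0.0,
            R2=0.0,
            coefficient_p=np.empty(0),
            n=len(y),
        )
    X = np.column_stack([cand[c] for c in selected])
    return _ols(X, y, selected)


def _partial_corr(cand, y, selected, k) -> float:
    """Partial correlation of candidate k with y given the selected set."""
    x = cand[k]
    if not selected:
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])
    Z = sm.add_constant(np.column_stack([cand[c] for c in selected]), has_constant="add")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def predict_stem_anteversion(
    record: MorphometryRecord | dict,
    cf_fit: RegressionFit = PUBLISHED_CF_EQUATION,
    noncf_fit: RegressionFit = PUBLISHED_NONCF_EQUATION,
) -> PredictionResult:
    """Apply the group-appropriate prediction equation to one hip."""
    if isinstance(record, MorphometryRecord):
        values = record.as_row()
        hip_id = record.hip_id
        observed = record.stem_anteversion
    else:
        values = dict(record)
        hip_id = str(values.get("hip_id", "hip"))
        observed = values.get("stem_anteversion_deg")
    group = assign_group(
        {"cf_present_lfn": values.get("cf_present_lfn")}
        if "cf_present_lfn" in values
        else {"cf_present_lfn": pd.notna(values.get("cf_lfn_deg"))}
    )
    fit = cf_fit if group == "CF" else noncf_fit
    predicted = fit.predict(values)
    if observed is not None and (isinstance(observed, float) and np.isnan(observed)):
        observed = None
    return PredictionResult(
        hip_id=hip_id,
        predicted_anteversion=predicted,
        equation_used=group,
        observed_anteversion=None if observed is None else float(observed),
    )


def prediction_errors(results: list[PredictionResult]) -> dict:
    """Per-group (n, mean, sd) of the absolute prediction error."""
    out = {}
    for group in ("CF", "nonCF"):
        errs = [
            r.absolute_error
            for r in results
            if r.equation_used == group and r.absolute_error is not None
        ]
        if not errs:
            continue
        e = np.asarray(errs, dtype=float)
        out[group] = {
            "n": int(len(e)),
            "mean": float(np.mean(e)),
            "sd": float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
        }
    if not out:
        raise ValueError("no predictions with observed values in any group")
    return out


# --------------------------------------------------------------------------
# measurement reliability
# --------------------------------------------------------------------------


def reliability(
    measurement_fn,
    models: list,
    repeats: int = 2,
    jitter_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Intra- and inter-observer reliability under landmark perturbation.

    Observer variation is emulated by jittering every landmark with isotropic
    Gaussian noise of ``jitter_sd`` mm before re-measurement.
    ``measurement_fn(model) -> {parameter: value}`` is called ``repeats``
    times per model for each of two simulated observers; intra-observer r is
    the Pearson correlation between an observer's first two repeat series,
    inter-observer r correlates the two observers' per-model means. Returns
    ({parameter: intra_r}, {parameter: inter_r}).
    """
    if len(models) < 3:
        raise ValueError("need at least 3 models for reliability estimation")
    if repeats < 2:
        raise ValueError("need at least 2 repeats")
    rng = np.random.default_rng(seed)

    def measure_once(model):
        jittered = _jitter_landmarks(model, rng, jitter_sd)
        return measurement_fn(jittered)

    series: dict = {}  # (observer, repeat) -> list of {param: value}
    for obs in range(2):
        for rep in range(repeats):
            series[(obs, rep)] = [measure_once(m) for m in models]

    params = sorted(series[(0, 0)][0])
    intra, inter = {}, {}
    for p in params:
        a = np.array([d[p] for d in series[(0, 0)]])
        b = np.array([d[p] for d in series[(0, 1)]])
        intra[p] = pearson_r(a, b)[0] if np.std(a) > 0 and np.std(b) > 0 else 1.0
        mean0 = np.mean(
            [[d[p] for d in series[(0, rep)]] for rep in range(repeats)], axis=0
        )
        mean1 = np.mean(
            [[d[p] for d in series[(1, rep)]] for rep in range(repeats)], axis=0
        )
        inter[p] = (
            pearson_r(mean0, mean1)[0] if np.std(mean0) > 0 and np.std(mean1) > 0 else 1.0
        )
    return intra, inter


def _jitter_landmarks(model, rng, sd: float):
    from .geometry import SurfaceModel

    return SurfaceModel(
        model.vertices,
        model.faces,
        {k: v + rng.normal(0.0, sd, 3) for k, v in model.landmarks.items()},
        model.side,
        model.face_labels,
    )


# --------------------------------------------------------------------------
# cohort-table helpers
# --------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = [
    "hip_id",
    "group",
    "fa_mfn_deg",
    "fa_lfn_deg",
    "fa_clt_deg",
    "stem_anteversion_deg",
]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing required columns: {missing}")
    bad = set(df["group"].dropna()) - {"CF", "nonCF"}
    if bad:
        raise SchemaError(f"unknown group labels: {sorted(bad)}")
    return df
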