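"""Cohort-level modelling of postoperative stem anteversion.

`StemAnteversionModel` is built from a cohort table (one row per hip with the
five proximal-femur angles, the group label, and — for fitting — the observed
stem anteversion). Its :meth:`fit` runs the full statistical stage and
returns a :class:`StemAnteversionResults` carrying group summaries, the
between-group tests, the per-predictor correlations/simple regressions, the
forward-stepwise group equations, and the in-sample prediction errors, with a
``summary()`` table in the statsmodels idiom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import stats as st
from .errors import SchemaError
from .stats import (
    CF_PREDICTOR_CANDIDATES,
    NONCF_PREDICTOR_CANDIDATES,
    RESPONSE,
    GroupSummary,
    PredictionResult,
    RegressionFit,
)

_CROWE_ORDER = ["I", "II-III", "IV"]


class StemAnteversionModel:
    """Group-specific prediction of postoperative stem anteversion.

    Parameters
    ----------
    cohort : DataFrame
        One row per hip. Required columns: ``hip_id``, ``group`` (``CF`` |
        ``nonCF``), ``fa_mfn_deg``, ``fa_lfn_deg``, ``fa_clt_deg``,
        ``stem_anteversion_deg``; CF rows additionally need ``cf_lfn_deg``
        and (when measured) ``cf_clt_deg``. ``crowe_grade`` is optional and
        only feeds the categorical group contrast.
    alpha_enter : float
        Entry p-value threshold of the forward selection.
    """

    def __init__(self, cohort: pd.DataFrame, alpha_enter: float = st.ALPHA_ENTER):
        self.cohort = st.validate_cohort(cohort.copy())
        if not 0 < alpha_enter <= 1:
            raise SchemaError("alpha_enter must be in (0, 1]")
        self.alpha_enter = float(alpha_enter)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StemAnteversionModel":
        return cls(pd.read_csv(path), **kwargs)

    @classmethod
    def from_records(cls, records, **kwargs) -> "StemAnteversionModel":
        """Build from MorphometryRecord objects (group from the CF flag)."""
        rows = []
        for rec in records:
            row = rec.as_row()
            row["group"] = st.assign_group(rec)
            rows.append(row)
        return cls(pd.DataFrame(rows), **kwargs)

    def _group(self, name: str) -> pd.DataFrame:
        return self.cohort[self.cohort["group"] == name]

    def fit(self) -> "StemAnteversionResults":
        res = StemAnteversionResults(model=self)
        candidates = {"CF": CF_PREDICTOR_CANDIDATES, "nonCF": NONCF_PREDICTOR_CANDIDATES}

        for group in ("CF", "nonCF"):
            df = self._group(group)
            if df.empty:
                continue
            res.group_summaries[group] = {
                col: GroupSummary.from_values(df[col])
                for col in candidates[group] + [RESPONSE]
                if col in df and df[col].notna().sum() >= 2
            }
            usable = [
                c for c in candidates[group] if c in df and df[c].notna().all()
            ]
            sub = df.dropna(subset=usable + [RESPONSE])
            if len(sub) >= 4 and usable:
                res.correlations[group] = {}
                res.simple_fits[group] = {}
                y = sub[RESPONSE].to_numpy(float)
                for c in usable:
                    x = sub[c].to_numpy(float)
                    try:
                        r, p = st.pearson_r(x, y)
                    except Exception:
                        continue
                    res.correlations[group][c] = {"R": r, "p": p}
                    res.simple_fits[group][c] = st.ols_fit({c: x}, y)
                res.group_fits[group] = st.stepwise_forward(
                    {c: sub[c].to_numpy(float) for c in usable}, y, self.alpha_enter
                )

        # between-group contrasts on the shared continuous parameters
        for col in ["stem_anteversion_deg", "fa_mfn_deg", "fa_lfn_deg", "fa_clt_deg"]:
            g1 = res.group_summaries.get("CF", {}).get(col)
            g2 = res.group_summaries.get("nonCF", {}).get(col)
            if g1 and g2:
                t, dfree, p = st.pooled_t_from_summary(g1, g2)
                res.t_tests[col] = {"t": t, "df": dfree, "p": p}
        if "crowe_grade" in self.cohort.columns and res.group_summaries.keys() >= {
            "CF",
            "nonCF",
        }:
            table = [
                [int((self._group(g)["crowe_grade"] == c).sum()) for c in _CROWE_ORDER]
                for g in ("CF", "nonCF")
            ]
            try:
                stat, dfree, p = st.chi2_contingency(table)
                res.crowe_test = {"table": table, "chi2": stat, "df": dfree, "p": p}
            except Exception:
                res.crowe_test = {"table": table}

        # in-sample predictions with the fitted equations
        if res.group_fits:
            preds = res.predict(self.cohort)
            observed = [p for p in preds if p.absolute_error is not None]
            if observed:
                res.prediction_error_summary = st.prediction_errors(observed)
        return res


@dataclass
class StemAnteversionResults:
    """Fitted group equations plus the descriptive/inferential side tables."""

    model: StemAnteversionModel
    group_fits: dict = field(default_factory=dict)  # group -> RegressionFit
    group_summaries: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    simple_fits: dict = field(default_factory=dict)
    t_tests: dict = field(default_factory=dict)
    crowe_test: dict | None = None
    prediction_error_summary: dict | None = None

    # -- prediction --------------------------------------------------------

    def equation_for(self, group: str) -> RegressionFit:
        if group not in self.group_fits:
            raise SchemaError(f"no fitted equation for group {group!r}")
        return self.group_fits[group]

    def predict(self, new: pd.DataFrame) -> list[PredictionResult]:
        """Apply the group-appropriate fitted equation to each row."""
        out = []
        for _, row in new.iterrows():
            group = row.get("group")
            if group not in self.group_fits:
                continue
            values = row.to_dict()
            predicted = self.group_fits[group].predict(values)
            obs = values.get(RESPONSE)
            out.append(
                PredictionResult(
                    hip_id=str(values.get("hip_id", "hip")),
                    predicted_anteversion=predicted,
                    equation_used=group,
                    observed_anteversion=None if pd.isna(obs) else float(obs),
                )
            )
        return out

    # -- reporting ---------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serializable analysis report."""
        rep: dict = {"groups": {}}
        for group in ("CF", "nonCF"):
            if group not in self.group_summaries:
                continue
            g: dict = {
                "summaries": {
                    k: {"n": s.n, "mean": s.mean, "sd": s.sd}
                    for k, s in self.group_summaries[group].items()
                }
            }
            if group in self.correlations:
                g["correlations"] = self.correlations[group]
                g["simple_regressions"] = {
                    k: f.to_dict() for k, f in self.simple_fits[group].items()
                }
            if group in self.group_fits:
                g["stepwise_fit"] = self.group_fits[group].to_dict()
                g["stepwise_equation"] = self.group_fits[group].equation()
            rep["groups"][group] = g
        rep["t_tests"] = self.t_tests
        if self.crowe_test is not None:
            rep["crowe_chi2"] = self.crowe_test
        if self.prediction_error_summary is not None:
            rep["prediction_errors"] = self.prediction_error_summary
        return rep

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = ["Stem anteversion prediction — group analysis", "=" * 52]
        for group in ("CF", "nonCF"):
            if group not in self.group_summaries:
                continue
            n = self.group_summaries[group].get(RESPONSE)
            lines.append(f"\n[{group} group]  n = {n.n if n else '?'}")
            for k, s in self.group_summaries[group].items():
                lines.append(f"  {k:22s} {s.mean:7.1f} ± {s.sd:.1f}")
            if group in self.group_fits:
                fit = self.group_fits[group]
                lines.append(f"  stepwise: {fit.equation()}")
                lines.append(f"            R = {fit.R:.3f}, R² = {fit.R2:.3f}")
        if self.t_tests:
            lines.append("\n[CF vs non-CF, pooled t]")
            for k, d in self.t_tests.items():
                lines.append(f"  {k:22s} t = {d['t']:6.3f}  p = {d['p']:.3f}")
        if self.crowe_test and "chi2" in self.crowe_test:
            c = self.crowe_test
            lines.append(f"\nCrowe grade chi² = {c['chi2']:.2f} (df {c['df']}), p = {c['p']:.3f}")
        if self.prediction_error_summary:
            lines.append("\n[absolute prediction error]")
            for g, d in self.prediction_error_summary.items():
                lines.append(f"  {g:6s} {d['mean']:.1f}° ± {d['sd']:.1f}° (n={d['n']})")
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Observed vs predicted stem anteversion, one marker per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        preds = self.predict(self.model.cohort)
        for group, marker in (("CF", "o"), ("nonCF", "s")):
            xs = [p.observed_anteversion for p in preds if p.equation_used == group]
            ys = [p.predicted_anteversion for p in preds if p.equation_used == group]
            if xs:
                ax.scatter(xs, ys, marker=marker, label=group, alpha=0.8)
        lo, hi = ax.get_xlim()
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("observed stem anteversion (°)")
        ax.set_ylabel("predicted stem anteversion (°)")
        ax.legend()
        return ax
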