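"""Time-to-multimorbidity survival analysis.

Derives incident multimorbidity (a second chronic condition) from panel
records, estimates group-wise Kaplan-Meier curves, fits a Cox proportional
hazards model (Efron-tie-corrected partial likelihood, via lifelines) and
tests proportionality with Schoenfeld residuals.

Event times sit on the wave offsets: the "second diagnosis" is dated by the
survey wave at which it is first reported, so ties are heavy and the Efron
correction is the default.  Participants already multimorbid at baseline
are excluded (incident-case analysis); deaths before multimorbidity censor
at the exact death time.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

__all__ = [
    "derive_time_to_multimorbidity",
    "kaplan_meier",
    "CoxPHModel",
    "CoxPHResults",
    "fit_cox",
    "schoenfeld_test",
]


def derive_time_to_multimorbidity(
    panel_dataset: pd.DataFrame,
    *,
    id_col: str = "id",
    time_col: str = "years_since_baseline",
    vital_col: str = "vital_status",
    disease_prefix: str = "disease_",
    count_col: str | None = None,
    keep_covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One survival record per at-risk participant.

    Multimorbidity onset is the first wave at which two or more conditions
    are reported.  Baseline-multimorbid participants are excluded; never
    reaching two conditions censors at the last observation alive, and death
    before multimorbidity censors at the exact death time.

    Disease counts come from the indicator columns named
    ``disease_<name>`` unless ``count_col`` names a precomputed count.
    """
    df = panel_dataset
    if count_col is None:
        disease_cols = [c for c in df.columns if c.startswith(disease_prefix)]
        if not disease_cols:
            raise ValueError(
                f"no columns with prefix {disease_prefix!r} and no count_col given"
            )
        counts = df[disease_cols].sum(axis=1)
    else:
        counts = df[count_col]
    work = df.assign(_n_cond=counts).sort_values([id_col, time_col], kind="mergesort")
    if keep_covariates is None:
        drop = {id_col, time_col, vital_col, "wave_index", "_n_cond", "state"}
        drop |= {c for c in work.columns if c.startswith(disease_prefix)}
        keep_covariates = [c for c in work.columns if c not in drop]
    rows = []
    for pid, grp in work.groupby(id_col, sort=False):
        alive = grp[grp[vital_col] != "dead"] if vital_col in grp.columns else grp
        if alive.empty or alive.iloc[0][time_col] != 0:
            raise ValueError(f"participant {pid!r} has no baseline record")
        if alive.iloc[0]["_n_cond"] >= 2:
            continue  # prevalent multimorbidity: not at risk
        onset = alive[alive["_n_cond"] >= 2]
        if len(onset):
            time, event = float(onset.iloc[0][time_col]), 1
        else:
            dead = grp[grp[vital_col] == "dead"] if vital_col in grp.columns else grp.iloc[:0]
            if len(dead):
                time, event = float(dead.iloc[0][time_col]), 0
            else:
                time, event = float(alive.iloc[-1][time_col]), 0
        if time <= 0:
            continue  # no follow-up beyond baseline
        rec = {id_col: pid, "time": time, "event": event}
        for c in keep_covariates:
            rec[c] = grp.iloc[0][c]
        rows.append(rec)
    return pd.DataFrame(rows)


def kaplan_meier(
    survival_records: pd.DataFrame,
    group_col: str | None = None,
    *,
    time_col: str = "time",
    event_col: str = "event",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Product-limit survival curves with exponential-Greenwood (log-log)
    confidence bands, tidy per group: (group, time, estimate, lower, upper)."""
    if survival_records.empty:
        raise ValueError("no survival records")
    groups = (
        [(str(g), d) for g, d in survival_records.groupby(group_col)]
        if group_col
        else [("all", survival_records)]
    )
    frames = []
    for label, d in groups:
        if d.empty:
            raise ValueError(f"empty group {label!r}")
        km = KaplanMeierFitter(alpha=alpha)
        km.fit(d[time_col], d[event_col])
        ci = km.confidence_interval_
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": km.survival_function_.index.to_numpy(dtype=float),
                    "estimate": km.survival_function_.iloc[:, 0].to_numpy(),
                    "lower": ci.iloc[:, 0].to_numpy(),
                    "upper": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class CoxPHModel:
    """Cox proportional hazards model on derived survival records.

    Thin statsmodels-style wrapper around lifelines' ``CoxPHFitter`` (Efron
    tie correction).  ``fit()`` returns a :class:`CoxPHResults`.
    """

    def __init__(
        self,
        survival_records: pd.DataFrame,
        covariate_names: Sequence[str],
        *,
        time_col: str = "time",
        event_col: str = "event",
    ):
        self.covariate_names = list(covariate_names)
        self.time_col = time_col
        self.event_col = event_col
        missing = [c for c in self.covariate_names if c not in survival_records.columns]
        if missing:
            raise KeyError(f"missing covariate column(s): {missing}")
        self.data = survival_records[[time_col, event_col] + self.covariate_names].copy()
        if (self.data[time_col] <= 0).any():
            raise ValueError("all survival times must be > 0")
        n_events = int(self.data[event_col].sum())
        if n_events < 1:
            raise ValueError("no events in the data")
        for c in self.covariate_names:
            if self.data[c].nunique() < 2:
                raise ValueError(f"covariate {c!r} is degenerate (constant)")
        self.n_events = n_events

    def fit(self, precision: float = 1e-14) -> "CoxPHResults":
        fitter = CoxPHFitter()
        try:
            fitter.fit(
                self.data,
                duration_col=self.time_col,
                event_col=self.event_col,
                fit_options={"precision": precision},
            )
            converged = True
            message = "converged"
        except Exception as err:  # monotone likelihood / separation
            raise RuntimeError(
                f"Cox partial-likelihood maximization failed: {err}"
            ) from err
        return CoxPHResults(self, fitter, converged, message)


class CoxPHResults:
    """Coefficients, covariance, hazard ratios and PH diagnostics."""

    def __init__(self, model: CoxPHModel, fitter: CoxPHFitter, converged: bool, message: str):
        self.model = model
        self._fitter = fitter
        self.converged = converged
        self.message = message
        self.params = fitter.params_.copy()
        self.bse = fitter.standard_errors_.copy()
        self.cov_params = fitter.variance_matrix_.to_numpy()
        self.loglike = float(fitter.log_likelihood_)

    def hazard_ratio_table(self) -> pd.DataFrame:
        s = self._fitter.summary
        return pd.DataFrame(
            {
                "covariate": s.index.to_list(),
                "coef": s["coef"].to_numpy(),
                "se": s["se(coef)"].to_numpy(),
                "hr": s["exp(coef)"].to_numpy(),
                "hr_lower": s["exp(coef) lower 95%"].to_numpy(),
                "hr_upper": s["exp(coef) upper 95%"].to_numpy(),
                "p": s["p"].to_numpy(),
            }
        )

    def schoenfeld_residuals(self) -> pd.DataFrame:
        """Unscaled Schoenfeld residuals at event rows, sorted by event time."""
        res = self._fitter.compute_residuals(self.model.data, kind="schoenfeld")
        times = self.model.data.loc[res.index, self.model.time_col]
        res = res.assign(_time=times.to_numpy()).sort_values("_time", kind="mergesort")
        return res

    def proportional_hazards_test(self, time_transform: str = "rank") -> pd.DataFrame:
        return schoenfeld_test(self, time_transform=time_transform)

    def summary(self) -> str:
        lines = [
            "Cox proportional hazards (Efron ties, partial likelihood)",
            f"records: {len(self.model.data)}   events: {self.model.n_events}"
            f"   log partial likelihood: {self.loglike:.4f}",
            "",
            self.hazard_ratio_table().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "covariates": list(self.params.index),
            "coef": [float(v) for v in self.params],
            "se": [float(v) for v in self.bse],
            "log_partial_likelihood": self.loglike,
            "converged": self.converged,
            "n_events": self.model.n_events,
            "n_records": int(len(self.model.data)),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def fit_cox(
    survival_records: pd.DataFrame,
    covariate_names: Sequence[str],
    **kwargs,
) -> CoxPHResults:
    """Convenience: build a :class:`CoxPHModel` and fit it."""
    return CoxPHModel(survival_records, covariate_names, **kwargs).fit()


def schoenfeld_test(
    cox_results: CoxPHResults, time_transform: str = "rank"
) -> pd.DataFrame:
    """Grambsch-Therneau test of proportional hazards.

    Per-covariate score tests of zero slope of the Schoenfeld residuals on
    the transformed event time (chi-square, 1 df; computed by lifelines) plus
    a global test on all covariates jointly (chi-square, p df), which
    lifelines does not provide and is computed here from the unscaled
    residuals and the average information matrix.
    """
    model = cox_results.model
    p = len(model.covariate_names)
    m = model.n_events
    if m <= p:
        raise ValueError(
            f"need more events ({m}) than covariates ({p}) to test proportionality"
        )
    per_cov = proportional_hazard_test(
        cox_results._fitter, model.data, time_transform=time_transform
    ).summary

    res = cox_results.schoenfeld_residuals()
    times = res["_time"].to_numpy()
    U = res[model.covariate_names].to_numpy()
    if time_transform == "rank":
        g = stats.rankdata(times, method="average")
    elif time_transform == "identity":
        g = times.astype(float)
    elif time_transform == "log":
        g = np.log(times.astype(float))
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    gc = g - g.mean()
    z = U.T @ gc
    info = np.linalg.inv(cox_results.cov_params)  # observed information at the MLE
    var_z = float(gc @ gc) * info / m
    global_stat = float(z @ np.linalg.solve(var_z, z))
    global_p = float(stats.chi2.sf(global_stat, df=p))

    rows = []
    for c in model.covariate_names:
        stat = float(per_cov.loc[c, "test_statistic"])
        rows.append(
            {
                "covariate": c,
                "statistic": stat,
                "df": 1,
                "p": float(stats.chi2.sf(stat, df=1)),
            }
        )
    rows.append({"covariate": "GLOBAL", "statistic": global_stat, "df": p, "p": global_p})
    return pd.DataFrame(rows)
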