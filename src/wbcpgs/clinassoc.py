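"""Clinical association stages.

Logistic models (odds ratio per score s.d., with a Hosmer-Lemeshow
calibration check on 8 deciles of risk), linear models on log-scale
counts, exposure-cohort assembly under the stated censoring rules, Cox
proportional-hazards fits with residual diagnostics, and Kaplan-Meier
curves over Low / Middle / High score strata.

Logistic and linear stages are fitted with statsmodels, survival stages
with lifelines (Efron handling of tied event times, lifelines' default).
Confidence intervals are Wald intervals on the log scale for odds and
hazard ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (ConfigError, DegenerateInputError, FitError,
                     InsufficientDataError, ValidationError)

_Z975 = stats.norm.ppf(0.975)


@dataclass
class FitResult:
    """One association estimate: OR/HR per s.d. or slope per s.d."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    coef: float
    se: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("confidence interval does not bracket estimate")


def _design(score, covariates):
    s = np.asarray(score, dtype=float)
    cols = [np.ones(len(s)), s]
    names = ["const", "score"]
    if covariates is not None:
        C = covariates
        if isinstance(C, pd.DataFrame):
            names += list(C.columns)
            C = C.to_numpy(dtype=float)
        else:
            C = np.asarray(C, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            names += [f"x{i}" for i in range(C.shape[1])]
        cols.append(C)
        X = np.column_stack(cols)
    else:
        X = np.column_stack(cols)
    return X, names


def logistic_fit(outcome, score, covariates=None) -> FitResult:
    """Maximum-likelihood logistic regression; OR per score s.d. with Wald CI.

    Raises :class:`FitError` on separation or non-convergence and
    :class:`InsufficientDataError` if only one outcome class is present.
    """
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise InsufficientDataError("outcome has a single class")
    X, names = _design(score, covariates)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise FitError(f"logistic fit failed: {exc}",
                       {"n": len(y), "events": int(y.sum())}) from exc
    if not res.mle_retvals.get("converged", False) or np.any(np.abs(res.params) > 25):
        raise FitError("logistic fit did not converge (possible separation)",
                       {"params": dict(zip(names, res.params))})
    b, se = res.params[1], res.bse[1]
    return FitResult(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - _Z975 * se)),
        ci_high=float(np.exp(b + _Z975 * se)),
        p=float(res.pvalues[1]), n=len(y), events=int(y.sum()),
        coef=float(b), se=float(se),
        diagnostics={"llf": float(res.llf), "converged": True,
                     "fitted": res.predict(X)})


@dataclass
class HLResult:
    statistic: float
    p: float
    df: int
    n_bins: int
    table: pd.DataFrame


def hosmer_lemeshow(fitted_probs, outcomes, n_bins: int = 8) -> HLResult:
    """Hosmer-Lemeshow goodness-of-fit on deciles of risk.

    Observations are ranked by fitted probability and split into
    ``n_bins`` near-equal-count groups with tied probabilities kept in
    one group; the chi-square statistic has ``n_bins - 2`` degrees of
    freedom (recomputed if ties collapse groups).
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be at least 2")
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(p)) < n_bins:
        raise DegenerateInputError(
            f"only {len(np.unique(p))} distinct probabilities for {n_bins} bins")
    try:
        bins = pd.qcut(p, n_bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise DegenerateInputError(f"cannot form risk bins: {exc}") from exc
    groups = pd.DataFrame({"bin": bins, "p": p, "y": y}).groupby("bin")
    tab = groups.agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"),
                     mean_p=("p", "mean")).reset_index()
    used = len(tab)
    if used < 3:
        raise DegenerateInputError("ties collapsed the risk bins below 3")
    o1, e1, n = tab["obs"].to_numpy(), tab["exp"].to_numpy(), tab["n"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((o1 - e1) ** 2 / (e1 * (1.0 - e1 / n)))
    df = used - 2
    return HLResult(float(chi2), float(stats.chi2.sf(chi2, df)), df, used, tab)


def linear_log_fit(outcome, score, covariates=None) -> FitResult:
    """Least-squares slope of a log-scale outcome on the standardized score."""
    y = np.asarray(outcome, dtype=float)
    X, names = _design(score, covariates)
    if len(y) < X.shape[1] + 2:
        raise InsufficientDataError("too few complete cases for linear fit")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design (collinear covariates)",
                       {"columns": names})
    res = sm.OLS(y, X).fit()
    b, se = res.params[1], res.bse[1]
    return FitResult(
        estimate=float(b), ci_low=float(b - _Z975 * se),
        ci_high=float(b + _Z975 * se), p=float(res.pvalues[1]),
        n=len(y), events=0, coef=float(b), se=float(se),
        diagnostics={"r2": float(res.rsquared),
                     "resid_sd": float(np.sqrt(res.scale))})


@dataclass
class CensoringRules:
    """Outcome and censoring rules for assembling an exposure cohort.

    Defaults encode the chemotherapy first-cycle design: incident WBC
    count < 3000 cells/uL, censoring at the earlier of the event, the
    start of the second treatment cycle, or 30 days ('1 month') after
    initiation, with a baseline count floor of > 1000 cells/uL.
    Alternative thresholds (3500/4000 for WBC, 1500 for neutrophils) and
    a 730-day ('24 months') horizon without a second-cycle rule cover
    the immunosuppressant designs.
    """

    outcome_threshold: float = 3000.0
    horizon_days: float = 30.0
    use_second_cycle: bool = True
    baseline_floor: float = 1000.0


def build_exposure_cohort(persons: pd.DataFrame, measures: pd.DataFrame,
                          rules: CensoringRules = CensoringRules()
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One time-to-event record per person under the stated rules.

    ``persons`` needs baseline_wbc, second_cycle_day, last_encounter_day
    (either may be inf) and any covariates; ``measures`` holds
    (person_id, day, count) with day 0 = treatment start.  The event is
    the first post-baseline day with count below the outcome threshold;
    otherwise the person is censored at the earliest of second cycle,
    horizon, or last encounter.  Persons failing the baseline floor are
    excluded and returned in the log.  Returns ``(records, excluded)``.
    """
    meas = measures.sort_values(["person_id", "day"], kind="mergesort")
    below = meas.loc[(meas["day"] > 0)
                     & (meas["count"].to_numpy() < rules.outcome_threshold)]
    first_event = below.groupby("person_id")["day"].min()
    records, excluded = [], []
    for _, row in persons.iterrows():
        pid = row["person_id"]
        if not row["baseline_wbc"] > rules.baseline_floor:
            excluded.append({"person_id": pid, "reason": "baseline_floor",
                             "baseline_wbc": row["baseline_wbc"]})
            continue
        censors = {"window_end": rules.horizon_days,
                   "last_encounter": row.get("last_encounter_day", np.inf)}
        if rules.use_second_cycle:
            censors["second_cycle"] = row.get("second_cycle_day", np.inf)
        censor_reason = min(censors, key=censors.get)
        censor_day = censors[censor_reason]
        ev_day = first_event.get(pid, np.inf)
        if ev_day <= 0:
            raise ValidationError(f"event before start for {pid}")
        if ev_day <= censor_day:
            time, event, reason = ev_day, True, "event"
        else:
            time, event, reason = censor_day, False, censor_reason
        rec = dict(row)
        rec.update({"time": float(time), "event": bool(event),
                    "censor_reason": reason})
        records.append(rec)
    rec_df = pd.DataFrame(records)
    if len(rec_df) and (rec_df["time"] <= 0).any():
        raise ValidationError("non-positive follow-up time",
                              rows=rec_df.loc[rec_df["time"] <= 0,
                                              "person_id"].tolist())
    return rec_df, pd.DataFrame(excluded, columns=["person_id", "reason",
                                                   "baseline_wbc"])


def cox_fit(records: pd.DataFrame, score_col: str = "score",
            covariate_cols=(), duration_col: str = "time",
            event_col: str = "event") -> FitResult:
    """Cox proportional-hazards fit; HR per score s.d. with Wald CI.

    Partial likelihood with Efron handling of ties (lifelines default).
    Diagnostics summarize Schoenfeld (proportional hazards), martingale
    (non-linearity) and deviance (outlier) residuals.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test
    if records[event_col].sum() < 1:
        raise InsufficientDataError("no events in exposure cohort")
    cols = [duration_col, event_col, score_col, *covariate_cols]
    df = records[cols].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    b = float(cph.params_[score_col])
    se = float(cph.standard_errors_[score_col])
    try:
        ph = proportional_hazard_test(cph, df, time_transform="rank")
        ph_p = float(ph.summary.loc[score_col, "p"].min()
                     if hasattr(ph.summary.loc[score_col, "p"], "min")
                     else ph.summary.loc[score_col, "p"])
    except Exception:
        ph_p = np.nan
    mart = cph.compute_residuals(df, "martingale")["martingale"]
    dev = cph.compute_residuals(df, "deviance")["deviance"]
    diagnostics = {
        "schoenfeld_ph_p": ph_p,
        "martingale_score_corr": float(np.corrcoef(
            mart.to_numpy(), df.loc[mart.index, score_col].to_numpy())[0, 1]),
        "deviance_max_abs": float(dev.abs().max()),
        "deviance_frac_gt2": float((dev.abs() > 2).mean()),
    }
    return FitResult(
        estimate=float(np.exp(b)), ci_low=float(np.exp(b - _Z975 * se)),
        ci_high=float(np.exp(b + _Z975 * se)),
        p=float(cph.summary.loc[score_col, "p"]),
        n=len(df), events=int(df[event_col].sum()),
        coef=b, se=se, diagnostics=diagnostics)


def km_strata(scores, records: pd.DataFrame, duration_col: str = "time",
              event_col: str = "event") -> tuple[pd.Series, dict]:
    """Kaplan-Meier curves over score strata.

    Strata: Low (score < -1), Middle (-1 <= score <= 1), High (score > 1).
    Returns ``(labels, {stratum: survival DataFrame})``.
    """
    from lifelines import KaplanMeierFitter
    s = np.asarray(scores, dtype=float)
    labels = pd.Series(np.select([s < -1.0, s > 1.0], ["Low", "High"],
                                 default="Middle"), index=records.index)
    curves = {}
    for name in ("Low", "Middle", "High"):
        member = labels == name
        if not member.any():
            continue
        km = KaplanMeierFitter()
        km.fit(records.loc[member, duration_col],
               records.loc[member, event_col], label=name)
        curves[name] = km.survival_function_
    return labels, curves
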