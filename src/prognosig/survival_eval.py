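"""Survival evaluation: Kaplan-Meier, log-rank, Cox PH, CPE, sens/spec.

Thin, typed wrappers around lifelines with the conventions fixed once for the
whole pipeline: Greenwood log-log confidence intervals for Kaplan-Meier,
Efron handling of tied event times in Cox fits (follow-up recorded in whole
months produces heavy ties), and the Gonen-Heller concordance probability
estimate (CPE) as the censoring-independent concordance summary of a fitted
Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .core_data import ClinicalTable, DataError, HIGH_RISK, dichotomize


@dataclass
class KMEstimate:
    """Product-limit survival curve with Greenwood (log-log) 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("empty survival input")
    if (times < 0).any():
        raise DataError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    return KMEstimate(times=sf.index.to_numpy(dtype=float),
                      survival=sf.iloc[:, 0].to_numpy(),
                      ci_low=ci.iloc[:, 0].to_numpy(),
                      ci_high=ci.iloc[:, 1].to_numpy())


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]
            ) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; returns (chi2, df, p)."""
    if len(groups) < 2:
        raise DataError("log-rank test needs >= 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise DataError(f"group {i} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(np.concatenate(times), np.concatenate(labels),
                                    np.concatenate(events))
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


@dataclass
class CoxFitResult:
    """Cox proportional-hazards fit summary plus per-sample risk."""

    summary: pd.DataFrame          # coef, hazard_ratio, ci_low, ci_high, p
    linear_predictor: pd.Series    # per-sample log partial hazard

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


def cox_fit(covariates: pd.DataFrame, times, events,
            categorical: dict[str, str] | None = None) -> CoxFitResult:
    """Multivariate Cox PH fit with Efron tie handling.

    ``categorical`` maps column names to their reference level; such columns
    are expanded to treatment-coded indicators named ``col[level]``.
    Continuous columns (e.g. a risk score used as a covariate) pass through.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise DataError("no observed events; Cox model is not identifiable")
    design = pd.DataFrame(index=covariates.index)
    categorical = categorical or {}
    for col in covariates.columns:
        if col in categorical:
            ref = categorical[col]
            levels = [ref] + sorted(set(covariates[col].astype(str)) - {ref})
            cat = pd.Categorical(covariates[col].astype(str), categories=levels)
            dummies = pd.get_dummies(cat, prefix=col, prefix_sep="=",
                                     drop_first=True, dtype=float)
            dummies.index = covariates.index
            design = design.join(dummies)
        else:
            design[col] = pd.to_numeric(covariates[col])
    const = design.nunique() <= 1
    if const.any():
        raise DataError(f"constant covariate(s): {list(design.columns[const])}")
    if events.sum() < design.shape[1]:
        raise DataError("fewer events than covariates")
    df = design.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise DataError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hazard_ratio": s["exp(coef)"],
        "ci_low": np.exp(s["coef lower 95%"]),
        "ci_high": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    lp = cph.predict_log_partial_hazard(design)
    return CoxFitResult(summary=summary,
                        linear_predictor=pd.Series(np.asarray(lp, dtype=float).ravel(),
                                                   index=design.index))


def cpe(fit_or_lp: CoxFitResult | pd.Series | np.ndarray) -> float:
    """Gonen-Heller concordance probability estimate.

    K = (2 / n(n-1)) * sum_{i<j} 1 / (1 + exp(-|eta_i - eta_j|)) with eta the
    Cox linear predictors: under proportional hazards the member of a pair
    with the higher linear predictor fails first with exactly that
    probability, so the estimate needs no censoring correction.  Identical
    predictors give exactly 0.5.
    """
    lp = fit_or_lp.linear_predictor if isinstance(fit_or_lp, CoxFitResult) else fit_or_lp
    eta = np.asarray(lp, dtype=float)
    n = eta.size
    if n < 2:
        raise DataError("CPE needs >= 2 samples")
    if np.ptp(eta) == 0:
        return 0.5
    diff = np.abs(eta[:, None] - eta[None, :])
    iu = np.triu_indices(n, k=1)
    return float(np.mean(1.0 / (1.0 + np.exp(-diff[iu]))))


def horizon_sens_spec(predicted: pd.Series, clinical: ClinicalTable,
                      horizon_months: float = 60.0
                      ) -> tuple[float, float, dict[str, int]]:
    """Sensitivity/specificity of predicted risk labels at a survival horizon.

    Truth comes from dichotomizing the clinical table at the horizon; samples
    censored before the horizon carry no usable truth and are excluded from
    both denominators.  Sensitivity is the fraction of true high-risk
    (death within horizon) patients predicted high-risk; specificity the
    fraction of true low-risk patients predicted low-risk.
    """
    truth = dichotomize(clinical, horizon_months)
    common = [s for s in truth.sample_ids if s in set(predicted.index)]
    if not common:
        raise DataError("no labeled samples overlap the predictions")
    t = truth.labels.loc[common]
    p = predicted.loc[common]
    tp = int(((t == HIGH_RISK) & (p == HIGH_RISK)).sum())
    fn = int(((t == HIGH_RISK) & (p != HIGH_RISK)).sum())
    tn = int(((t != HIGH_RISK) & (p != HIGH_RISK)).sum())
    fp = int(((t != HIGH_RISK) & (p == HIGH_RISK)).sum())
    if tp + fn == 0 and tn + fp == 0:
        raise DataError("no evaluable samples at this horizon")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    counts = {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
              "excluded": len(truth.excluded_ids)}
    return sens, spec, counts
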