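"""Survival analysis: Kaplan-Meier with landmark reads, log-rank tests and
stratified Cox proportional-hazards models.

Wraps lifelines. Cox models use Efron's tie correction and can stratify the
baseline hazard by a cohort variable, matching the analysis design where
heterogeneous sub-cohorts are merged but each keeps its own baseline
hazard. Landmark survival (e.g. 5-year PFS at 60 months) is read from the
right-continuous product-limit step function: the value at t includes any
jump at exactly t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMResult:
    """Per-group product-limit estimates with log-log 95% CIs."""
    survival: dict[str, pd.DataFrame]      # group -> [S, ci_low, ci_high] by time
    landmark: pd.DataFrame                 # groups x landmark months, S(t) in [0,1]
    n_per_group: dict[str, int]
    skipped_groups: list[str] = field(default_factory=list)


def km_estimate(time: pd.Series, event: pd.Series, groups: pd.Series,
                landmarks: tuple[float, ...] = (60.0,)) -> KMResult:
    """Kaplan-Meier estimator per group with Greenwood-based log-log CIs and
    landmark survival read from the step function."""
    df = pd.DataFrame({"time": time, "event": event, "group": groups}).dropna()
    surv: dict[str, pd.DataFrame] = {}
    land_rows = {}
    n_per = {}
    skipped = []
    for group, grp in df.groupby("group", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empties
            skipped.append(str(group))
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(group))
        ci = kmf.confidence_interval_
        out = pd.DataFrame({
            "S": kmf.survival_function_.iloc[:, 0],
            "ci_low": ci.iloc[:, 0],
            "ci_high": ci.iloc[:, 1],
        })
        surv[str(group)] = out
        land_rows[str(group)] = [float(kmf.predict(t)) for t in landmarks]
        n_per[str(group)] = len(grp)
    landmark = pd.DataFrame.from_dict(land_rows, orient="index",
                                      columns=[f"S({t})" for t in landmarks])
    return KMResult(surv, landmark, n_per, skipped)


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


def logrank(time: pd.Series, event: pd.Series, groups: pd.Series) -> LogrankResult:
    """Standard k-group log-rank test (chi-square on k-1 df)."""
    df = pd.DataFrame({"time": time, "event": event, "group": groups}).dropna()
    k = df["group"].nunique()
    if k < 2:
        raise ValueError(f"log-rank needs >= 2 groups (got {k})")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return LogrankResult(float(res.test_statistic), k - 1, float(res.p_value))


@dataclass
class CoxFit:
    summary: pd.DataFrame      # covariate -> HR, ci_low, ci_high, p, coef, se
    n: int
    n_events: int
    strata: list[str] | None
    log_likelihood: float
    fitter: CoxPHFitter


def _check_collinearity(X: pd.DataFrame) -> None:
    cols = [c for c in X.columns if X[c].nunique() > 1]
    if len(cols) < 2:
        return
    corr = X[cols].corr().abs()
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if corr.at[a, b] > 0.999:
                raise ValueError(
                    f"covariates {a!r} and {b!r} are collinear (|r| > 0.999); "
                    "drop one or fit them in separate models")


def cox_fit(data: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str], strata: list[str] | str | None = None) -> CoxFit:
    """Multivariate Cox regression (Efron ties), optionally stratified.

    ``data`` rows with missing values in the model columns are dropped.
    Collinear covariate pairs are detected and reported before fitting;
    non-convergence surfaces lifelines' error with its iteration advice.
    """
    if isinstance(strata, str):
        strata = [strata]
    cols = [duration_col, event_col] + list(covariates) + (strata or [])
    df = data[cols].dropna().copy()
    _check_collinearity(df[list(covariates)])
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lifelines' convergence chatter
        cph.fit(df, duration_col=duration_col, event_col=event_col,
                strata=strata, robust=False)
    s = cph.summary
    summary = pd.DataFrame({
        "HR": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
        "coef": s["coef"],
        "se": s["se(coef)"],
    })
    return CoxFit(summary=summary, n=len(df),
                  n_events=int(df[event_col].sum()),
                  strata=strata, log_likelihood=float(cph.log_likelihood_),
                  fitter=cph)


def model_design(cohort: pd.DataFrame, labels: pd.Series,
                 t1q13: pd.Series | None = None,
                 model: int = 1,
                 extra_covariates: list[str] | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Design frame for the two prognostic Cox models.

    Model 1 codes the 1q&13 classes as dummies against the 1q&13- baseline;
    model 2 codes the single t&1q&13+ flag. Extra clinical covariates are
    passed through unchanged.
    """
    df = cohort.copy()
    covs: list[str] = []
    if model == 1:
        df["cls_1q13_pos"] = (labels.reindex(df.index) == "1q&13+").astype(float)
        df["cls_1q13_single"] = (labels.reindex(df.index) == "1q/13").astype(float)
        covs += ["cls_1q13_pos", "cls_1q13_single"]
    elif model == 2:
        if t1q13 is None:
            raise ValueError("model 2 needs the t&1q&13 flag")
        df["t1q13_pos"] = t1q13.reindex(df.index).astype(float)
        covs += ["t1q13_pos"]
    else:
        raise ValueError("model must be 1 or 2")
    covs += list(extra_covariates or [])
    return df, covs
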