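"""Survival utilities: Kaplan-Meier curves, log-rank tests, Cox proportional
hazards, and the maximally selected optimal cutpoint.

KM estimation and Cox fitting delegate to lifelines (Efron tie handling);
the standardized two-sample log-rank statistic and the cutpoint scan are
implemented here.  The p-value reported at a selected cutpoint is the naive
log-rank p: it is anti-conservative because the cutpoint maximizes the
statistic, and is labelled exploratory in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "logrank_standardized",
    "CutpointResult",
    "optimal_cutpoint",
    "km_logrank",
    "cox_fit",
]


def _check_surv(surv: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"} <= set(surv.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if (surv["time"] < 0).any():
        raise ValueError("negative survival time")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return surv


def logrank_standardized(
    time: np.ndarray, event: np.ndarray, in_group: np.ndarray
) -> float:
    """Standardized two-sample log-rank statistic U / sqrt(V).

    Positive when the flagged group has fewer events than expected (better
    survival); the squared value is the usual log-rank chi-square.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_group = np.asarray(in_group, dtype=bool)
    if event.sum() == 0:
        raise ValueError("log-rank undefined: no events")
    order = np.argsort(time, kind="stable")
    time, event, in_group = time[order], event[order], in_group[order]
    n = time.size
    U = 0.0
    V = 0.0
    i = 0
    n_at_risk = n
    n1_at_risk = int(in_group.sum())
    while i < n:
        j = i
        d = d1 = 0
        removed = removed1 = 0
        while j < n and time[j] == time[i]:
            d += event[j]
            d1 += event[j] * in_group[j]
            removed += 1
            removed1 += int(in_group[j])
            j += 1
        if d > 0 and n_at_risk > 1:
            e1 = d * n1_at_risk / n_at_risk
            U += d1 - e1
            V += (
                d
                * (n1_at_risk / n_at_risk)
                * (1 - n1_at_risk / n_at_risk)
                * (n_at_risk - d)
                / (n_at_risk - 1)
            )
        n_at_risk -= removed
        n1_at_risk -= removed1
        i = j
    if V <= 0:
        raise ValueError("log-rank variance is zero (degenerate grouping)")
    return float(U / np.sqrt(V))


@dataclass
class CutpointResult:
    variable: str
    cutpoint: float
    statistic: float  # |standardized log-rank| at the cutpoint
    n_low: int
    n_high: int
    min_prop: float
    exploratory_p: float  # naive, selection-unadjusted


def optimal_cutpoint(
    values: pd.Series,
    surv: pd.DataFrame,
    min_prop: float = 0.10,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous variable.

    Every unique value is a candidate threshold (low: value <= t, high:
    value > t) provided both sides hold at least ``min_prop`` of the
    samples; the threshold maximizing |standardized log-rank| wins, ties
    resolved toward the lower threshold.  The attached p-value is the naive
    chi-square p of the selected statistic and is exploratory only -- the
    selection makes it anti-conservative.
    """
    surv = _check_surv(surv)
    common = values.index.intersection(surv.index)
    values = values[common].astype(float)
    surv = surv.loc[common]
    n = len(values)
    if n < 10:
        raise ValueError("need at least 10 samples for a cutpoint scan")
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    v = values.to_numpy()
    candidates = np.unique(v)[:-1]  # top value cannot define a non-empty 'high'
    best: CutpointResult | None = None
    for t in candidates:
        high = v > t
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < min_prop * n:
            continue
        try:
            z = logrank_standardized(time, event, high)
        except ValueError:
            continue
        stat = abs(z)
        if best is None or stat > best.statistic + 1e-12:
            best = CutpointResult(
                variable=str(values.name or "value"),
                cutpoint=float(t),
                statistic=float(stat),
                n_low=n_low,
                n_high=n_high,
                min_prop=min_prop,
                exploratory_p=float(stats.chi2.sf(stat**2, df=1)),
            )
    if best is None:
        raise ValueError(
            f"no candidate cutpoint satisfies min_prop = {min_prop} with a "
            "computable log-rank statistic"
        )
    return best


def km_logrank(groups: pd.Series, surv: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group and the two-sided log-rank test.

    Returns ``{'curves': {group: DataFrame(time, survival)}, 'statistic',
    'p'}``.  Requires >= 2 groups and >= 1 event overall.
    """
    surv = _check_surv(surv)
    common = groups.index.intersection(surv.index)
    groups = groups[common]
    surv = surv.loc[common]
    names = groups.dropna().unique()
    if len(names) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    if surv["event"].sum() == 0:
        raise ValueError("log-rank undefined: no events in the table")
    curves = {}
    for g in names:
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "time"], surv.loc[mask, "event"], label=str(g))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[g] = curve
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
    }


def cox_fit(
    surv: pd.DataFrame,
    covariates: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) over the named covariates.

    Categorical covariates are dummy-encoded (first level dropped).  Returns
    a per-coefficient table with HR, 95% CI bounds and the Wald p.  Constant
    or linearly dependent covariates raise before fitting; a guideline
    warning fires when events < covariates + 1.
    """
    surv = _check_surv(surv)
    missing = [c for c in covariates if c not in surv.columns]
    if missing:
        raise KeyError(f"covariates absent from table: {missing}")
    design = pd.get_dummies(
        surv[covariates], drop_first=True, dtype=float
    )
    const = design.columns[design.nunique() <= 1]
    if len(const):
        raise ValueError(f"constant covariate(s): {list(const)}")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    n_events = int(surv["event"].sum())
    if n_events < len(design.columns) + 1:
        warnings.warn(
            f"only {n_events} events for {len(design.columns)} coefficient(s); "
            "estimates may be unstable",
            stacklevel=2,
        )
    frame = pd.concat([surv[["time", "event"]], design], axis=1)
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError and others
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    out = pd.DataFrame(
        {
            "coef": summary["coef"],
            "HR": summary["exp(coef)"],
            "HR_lower": np.exp(summary["coef lower 95%"]),
            "HR_upper": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out
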