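"""Survival machinery: Kaplan-Meier, log-rank and Cox regression.

Kaplan-Meier estimation and the two-group log-rank test are implemented
natively (the optimal-cutoff scan calls log-rank once per grid candidate,
so its inner loop must stay light); Cox proportional-hazards fitting
delegates to lifelines with Efron tie handling.  pT/pN stage covariates
are dummy-encoded with the lowest category as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import FitError, StatisticsError

ENDPOINTS = ("OS", "CSS", "PFS")


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit estimate of survival.

    ``event_times`` are the distinct times with at least one event;
    ``survival`` the estimate just after each.  ``S(t) = 1`` before the
    first event; the curve is non-increasing.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate S(t) (right-continuous step function, S(0)=1)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float),
                              side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimate from times and event flags."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one record")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq = np.unique(t_sorted[e_sorted == 1])
    n = len(times)
    surv = []
    at_risk = []
    d_list = []
    s = 1.0
    for t in uniq:
        r = int((t_sorted >= t).sum())
        d = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        d_list.append(d)
    return KaplanMeierCurve(
        event_times=uniq,
        survival=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(d_list, dtype=int),
    )


def logrank_statistic(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df, pooled risk tables).

    Returns ``(chi_square, p_value)``.  Requires both groups non-empty
    and at least one event overall.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise StatisticsError("both groups must be non-empty")
    if ea.sum() + eb.sum() < 1:
        raise StatisticsError("log-rank requires at least one event")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        if abs(o_minus_e) < 1e-12:
            return 0.0, 1.0
        raise StatisticsError("log-rank variance is zero but O-E is not")
    chi2 = o_minus_e**2 / var
    p = float(sstats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class CovariateEffect:
    name: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary."""

    endpoint: str
    covariates: list[str]
    effects: dict[str, CovariateEffect]
    n: int
    n_events: int
    log_likelihood: float

    def effect(self, name: str) -> CovariateEffect:
        return self.effects[name]


def encode_stage_covariates(
    df: pd.DataFrame, columns: Sequence[str] = ("pT", "pN")
) -> pd.DataFrame:
    """Dummy-encode ordinal stage columns, lowest category as reference."""
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            continue
        cats = sorted(out[col].astype(str).unique())
        dummies = pd.get_dummies(
            pd.Categorical(out[col].astype(str), categories=cats), prefix=col
        ).iloc[:, 1:]
        out = pd.concat([out.drop(columns=[col]), dummies.astype(float)], axis=1)
    return out


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    endpoint: str = "OS",
) -> CoxResult:
    """Fit a Cox model (Efron ties) and summarize HRs with 95% CIs.

    ``covariates`` are columns of ``df`` (already numeric / dummy
    encoded).  Raises :class:`FitError` for degenerate designs (constant
    covariate, fewer events than covariates) or non-convergence.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates)
    data = df[[duration_col, event_col] + covariates].copy().astype(float)
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        raise FitError(
            f"{n_events} events for {len(covariates)} covariates; underdetermined"
        )
    for c in covariates:
        if data[c].nunique() < 2:
            raise FitError(f"covariate {c!r} is constant across the cohort")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, Exception) as exc:  # lifelines raises various types
        raise FitError(f"Cox fit failed: {exc}") from exc

    summ = cph.summary
    effects = {}
    for name in covariates:
        row = summ.loc[name]
        effects[name] = CovariateEffect(
            name=name,
            hazard_ratio=float(row["exp(coef)"]),
            ci_lower=float(row["exp(coef) lower 95%"]),
            ci_upper=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        )
    return CoxResult(
        endpoint=endpoint,
        covariates=covariates,
        effects=effects,
        n=len(data),
        n_events=n_events,
        log_likelihood=float(cph.log_likelihood_),
    )
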