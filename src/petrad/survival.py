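"""Kaplan-Meier estimation, log-rank tests and Cox proportional-hazards
modelling of PFS/OS by RadScore group (lifelines backend, Efron ties)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KMResult", "km_estimate", "logrank", "HazardResult", "cox_hr"]


@dataclass
class KMResult:
    """Product-limit survival curve with median and fixed-time rates."""

    curve: pd.DataFrame          # index: time; column: survival
    median: float | None         # None = not reached
    n: int
    n_events: int

    def rate_at(self, t: float) -> float:
        s = self.curve["survival"]
        prior = s[s.index <= t]
        return float(prior.iloc[-1]) if len(prior) else 1.0


def km_estimate(times, events) -> KMResult:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    curve = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return KMResult(curve=curve, median=median, n=len(times), n_events=int(events.sum()))


def logrank(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square and p across groups (1 df for two groups)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class HazardResult:
    """Hazard ratio of the high vs low group with Wald CI and p."""

    hr: float
    ci: tuple[float, float]
    p: float
    n_high: int
    n_low: int

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("HR must be positive")
        if not (self.ci[0] <= self.hr <= self.ci[1]):
            raise ValueError("CI must bracket the HR")


def cox_hr(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    group_col: str,
) -> HazardResult:
    """Cox partial-likelihood fit on a binary group covariate (Efron ties)."""
    data = df[[duration_col, event_col, group_col]].copy()
    g = data[group_col].astype(int)
    n_high, n_low = int((g == 1).sum()), int((g == 0).sum())
    events_by_group = df.groupby(g)[event_col].sum()
    if len(events_by_group) < 2 or (events_by_group == 0).any():
        raise ValueError("events required in both groups for a Cox fit")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"Cox fit failed (monotone likelihood / no overlap?): {exc}") from exc
    row = cph.summary.loc[group_col]
    return HazardResult(
        hr=float(row["exp(coef)"]),
        ci=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        p=float(row["p"]),
        n_high=n_high,
        n_low=n_low,
    )
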