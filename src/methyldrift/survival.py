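"""Kaplan-Meier survival estimation and trial response-rate arithmetic.

The product-limit estimator, Greenwood variance and log-log (exponential
Greenwood) confidence bands come from lifelines; the median is the smallest
time at which the survival curve reaches 0.5 or below, with its 95% CI read
off the band crossings (Brookmeyer-Crowley style). An upper limit the data
never pin down is reported as not reached ("NR"). Ties between events and
censorings at the same time follow the standard convention: events first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times


@dataclass
class KMEstimate:
    """Product-limit survival estimate for one group."""

    times: np.ndarray              # distinct observed times
    survival: np.ndarray           # S(t) just after each time
    at_risk: np.ndarray
    n: int
    n_events: int
    median: float                  # inf when never reached
    median_ci: tuple[float, float]

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, alpha: float = 0.05) -> KMEstimate:
    """Kaplan-Meier estimate with Greenwood log-log median CI.

    ``times`` are positive durations (days); ``events`` flags death/
    progression (1) versus censoring (0).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]
    # drop the t=0 anchor row for the step representation
    step = sf[sf.index > 0]
    event_table = kmf.event_table
    at_risk = event_table.loc[event_table.index > 0, "at_risk"]
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return KMEstimate(
        times=step.index.to_numpy(dtype=float),
        survival=step.to_numpy(dtype=float),
        at_risk=at_risk.to_numpy(dtype=int),
        n=len(t),
        n_events=int(e.sum()),
        median=median,
        median_ci=(lo, hi),
    )


def km_by_group(table: pd.DataFrame, group_col: str = "group") -> dict[str, KMEstimate]:
    """Fit one KM estimate per group of a survival table."""
    return {str(g): km_estimate(sub["time_days"], sub["event"])
            for g, sub in table.groupby(group_col, sort=True)}


def format_median_ci(est: KMEstimate) -> str:
    def fmt(x: float) -> str:
        return "NR" if not math.isfinite(x) else f"{x:g}"
    return f"{fmt(est.median)} (95% CI {fmt(est.median_ci[0])}-{fmt(est.median_ci[1])})"


RESPONSE_CATEGORIES = ("complete_response", "partial_response",
                       "stable_disease", "progressive_disease")


def response_rates(counts: dict[str, int], n: int | None = None) -> dict[str, int]:
    """Integer percentages (half-up rounding) for trial response categories.

    ``counts`` maps category -> patient count; counts must sum to ``n``
    (inferred when omitted). Returns category -> percent.
    """
    for cat in counts:
        if cat not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown response category {cat!r}")
    total = sum(counts.values())
    if n is None:
        n = total
    if total != n:
        raise ValueError(f"counts sum to {total}, expected n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return {cat: rate_percent(counts.get(cat, 0), n) for cat in RESPONSE_CATEGORIES}


def rate_percent(count: int, n: int) -> int:
    """100 * count / n, rounded half-up to the nearest integer percent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(math.floor(100.0 * count / n + 0.5))
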