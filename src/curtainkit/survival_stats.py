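"""Censoring-aware survival statistics for processivities and dwell times.

Compaction processivities and DNA-binding times are right-censored
(barrier contact, protein dissociation, DNA breakage, end of record),
so plain medians are biased; the Kaplan-Meier product-limit estimator
handles the censoring, and the reported "half-life" is its median: the
smallest observed event time at which the survival probability drops
to 0.5 or below.  Group comparisons use the log-rank test (censored)
and the Mann-Whitney U test (uncensored values, e.g. velocities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = ["SurvivalCurve", "km_estimate", "half_life", "logrank_test",
           "mann_whitney_u"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate with a Greenwood 95% confidence band.

    Arrays are aligned on the sorted unique observed times; ``survival``
    is right-continuous (value just after each time).  ``median`` is
    None when the curve never reaches 0.5.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    median: Optional[float]
    n: int
    n_censored: int

    def survival_at(self, t: float) -> float:
        """S(t) with S(t)=1 for t before the first observed time."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(values: Sequence[float], censored_flags: Sequence[bool],
                alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``censored_flags[i]`` is True when the i-th value is right-censored
    (the true value exceeds the observed one).  Ties are grouped at
    identical times with censored observations processed after deaths;
    the confidence band is Greenwood's with the log(-log) transform.
    """
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored_flags, dtype=bool)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != censored.shape:
        raise ValueError("values and censored flags must be aligned")
    if np.any(values <= 0):
        raise ValueError("survival values must be > 0")

    observed = ~censored
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(values, event_observed=observed)

    times = np.unique(values)
    surv = np.array([float(kmf.predict(t)) for t in times])
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())

    at_risk = np.array([(values >= t).sum() for t in times])
    d = np.array([((values == t) & observed).sum() for t in times])
    c = np.array([((values == t) & censored).sum() for t in times])

    event_times = times[(d > 0) & (surv <= 0.5)]
    median = float(event_times[0]) if event_times.size else None

    return SurvivalCurve(times=times, at_risk=at_risk, events=d, censored=c,
                         survival=surv, lo95=lo, hi95=hi, median=median,
                         n=int(values.size), n_censored=int(censored.sum()))


def half_life(curve: SurvivalCurve) -> Optional[float]:
    """Median survival: smallest observed event time with S <= 0.5,
    or None when the survival curve never reaches 0.5."""
    return curve.median


def logrank_test(a: tuple[Sequence[float], Sequence[bool]],
                 b: tuple[Sequence[float], Sequence[bool]]) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 df); returns (statistic, p)."""
    va, ca = np.asarray(a[0], float), np.asarray(a[1], bool)
    vb, cb = np.asarray(b[0], float), np.asarray(b[1], bool)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(va, vb, event_observed_A=~ca, event_observed_B=~cb)
    return float(res.test_statistic), float(res.p_value)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact p by enumeration when both samples have at most 8 untied
    observations, otherwise the normal approximation with tie
    correction (no continuity correction, so U at its null mean gives
    p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= 8 and b.size <= 8
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))
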