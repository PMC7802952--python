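"""Kaplan-Meier estimation and the two-group log-rank test.

The product-limit estimator carries a Greenwood variance and an
exponential-Greenwood (log(-log)) confidence envelope, which stays inside
[0, 1] by construction.  The curve records the Q3 survival time: the first
event time at which the estimated survival falls to 0.75 or below, the
marker drawn on the package's survival plots.

Ties between events and censorings at the same time follow the standard
convention: events precede censorings, so samples censored at t are still
at risk for the event at t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["SurvivalCurve", "LogRankResult", "km_curve", "logrank"]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with confidence envelope.

    ``survival[i]`` is the estimate just after ``event_times[i]``; the
    curve is 1 before the first event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    q3_time: float | None = None
    conf_level: float = 0.95

    def evaluate(self, t: float) -> float:
        """S(t): the step-function value at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, int] = field(default=(0, 0))
    events_per_group: tuple[int, int] = field(default=(0, 0))


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("survival input is empty")
    if times.shape != events.shape:
        raise ValueError("times and events have different lengths")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isin(events, [0, 1])):
        raise ValueError("event flags must be 0/1")
    return times, events


def km_curve(times, events, conf: float = 0.95) -> SurvivalCurve:
    """Product-limit survival estimate with exponential-Greenwood envelope.

    Parameters
    ----------
    times, events
        Observed durations and 0/1 event indicators (0 = censored).
    conf
        Two-sided confidence level of the envelope.
    """
    times, events = _check_times(times, events)
    event_times = np.unique(times[events == 1])

    surv = []
    at_risk = []
    var_sum = 0.0  # running sum of d / (n (n - d)) for Greenwood
    lo, hi = [], []
    z = stats.norm.ppf(0.5 + conf / 2.0)
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))  # censored-at-t still at risk
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            var_sum += d_i / (n_i * (n_i - d_i))
        surv.append(s)
        at_risk.append(n_i)
        if 0.0 < s < 1.0:
            # log(-log S) transform keeps the envelope inside [0, 1]
            theta = np.log(-np.log(s))
            se = np.sqrt(var_sum) / abs(np.log(s))
            lo.append(np.exp(-np.exp(theta + z * se)))
            hi.append(np.exp(-np.exp(theta - z * se)))
        else:
            lo.append(s)
            hi.append(s)

    surv_arr = np.array(surv)
    below = np.nonzero(surv_arr <= 0.75)[0] if surv_arr.size else np.array([], dtype=int)
    q3 = float(event_times[below[0]]) if below.size else None
    return SurvivalCurve(
        event_times=event_times,
        survival=surv_arr,
        ci_lower=np.array(lo),
        ci_upper=np.array(hi),
        at_risk=np.array(at_risk, dtype=int),
        q3_time=q3,
        conf_level=conf,
    )


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Unstratified two-group log-rank test.

    Sums observed-minus-expected events in group A over the pooled distinct
    event times, with the hypergeometric variance at each time; the
    statistic is referred to a chi-square with one degree of freedom.
    Raises if either group is empty — callers that need a sentinel (e.g.
    degenerate predictors during model selection) implement it themselves.
    """
    times_a, events_a = _check_times(times_a, events_a)
    times_b, events_b = _check_times(times_b, events_b)

    pooled_times = np.concatenate([times_a, times_b])
    pooled_events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(times_a.size), np.ones(times_b.size)])
    event_times = np.unique(pooled_times[pooled_events == 1])

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = pooled_times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 0)).sum())
        died = (pooled_times == t) & (pooled_events == 1)
        d = int(died.sum())
        d1 = int((died & (group == 0)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))

    if var == 0.0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e**2 / var
        p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        n_per_group=(times_a.size, times_b.size),
        events_per_group=(int(events_a.sum()), int(events_b.sum())),
    )
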