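"""Univariate statistics for response and survival endpoints.

Implements the small-cohort exploratory program used downstream of feature
extraction: Welch's t-test with a mean-difference CI and Hedges' g
(bias-corrected standardized mean difference), chi-square / Fisher tests
with odds ratios for binary covariates, Kaplan-Meier product-limit curves
with Greenwood variance (log-transformed 95% bands clipped to [0, 1]), the
two-group log-rank test, hazard ratios approximated as event-rate ratios,
and median dichotomization of continuous markers.

No multiple-testing correction is applied anywhere: with dozens of
correlated imaging features on a small cohort the p-values are descriptive
and meant to be read together with the effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "TwoSampleResult",
    "ContingencyResult",
    "KaplanMeierFit",
    "welch_test",
    "contingency_test",
    "km_fit",
    "logrank",
    "event_rate_hr",
    "dichotomize_median",
]


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


@dataclass
class TwoSampleResult:
    mean_diff: float
    ci95: tuple[float, float]
    t_stat: float
    df: float
    p_two_sided: float
    hedges_g: float
    g_ci95: tuple[float, float]
    n_x: int
    n_y: int
    n_dropped: int = 0


def welch_test(x, y) -> TwoSampleResult:
    """Welch's unequal-variance t-test plus Hedges' g with 95% CIs.

    Missing values are dropped per sample (count reported).  The g CI uses
    the usual large-sample normal approximation
    SE^2 = (nx+ny)/(nx*ny) + g^2 / (2*(nx+ny-2)).
    """
    x_raw, y_raw = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    x, y = _clean(x_raw), _clean(y_raw)
    n_dropped = (len(x_raw) - len(x)) + (len(y_raw) - len(y))
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise StatsError(f"welch_test needs >=2 values per group, got {nx} and {ny}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        # identical constant samples: define the degenerate null result
        return TwoSampleResult(0.0, (0.0, 0.0), 0.0, float(nx + ny - 2), 1.0, 0.0,
                               (0.0, 0.0), nx, ny, n_dropped)
    res = sps.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    diff = float(x.mean() - y.mean())
    df_w = nx + ny - 2
    s_pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df_w)
    j = 1.0 - 3.0 / (4.0 * df_w - 1.0)
    g = j * diff / s_pooled if s_pooled > 0 else 0.0
    se_g = np.sqrt((nx + ny) / (nx * ny) + g**2 / (2.0 * df_w))
    return TwoSampleResult(
        mean_diff=diff,
        ci95=(float(ci.low), float(ci.high)),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
        hedges_g=float(g),
        g_ci95=(float(g - 1.96 * se_g), float(g + 1.96 * se_g)),
        n_x=nx,
        n_y=ny,
        n_dropped=n_dropped,
    )


@dataclass
class ContingencyResult:
    odds_ratio: float
    or_ci95: tuple[float, float]
    p: float
    method: str


def contingency_test(table, method: str = "auto") -> ContingencyResult:
    """2x2 association test with an odds ratio and Woolf-logit 95% CI.

    Chi-square (no continuity correction) by default; Fisher's exact test
    when any expected cell count is below 5 (or when forced).  Zero cells
    get the Haldane-Anscombe +0.5 correction for the OR and its CI.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise StatsError("contingency_test needs a 2x2 table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsError("contingency table has an all-zero margin")
    expected = sps.contingency.expected_freq(t)
    use_fisher = method == "fisher" or (method == "auto" and (expected < 5).any())
    if use_fisher:
        p = float(sps.fisher_exact(t.astype(int))[1])
        chosen = "fisher"
    else:
        p = float(sps.chi2_contingency(t, correction=False)[1])
        chosen = "chi_square"
    c = t + 0.5 if (t == 0).any() else t
    oratio = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
    se = np.sqrt((1.0 / c).sum())
    lo, hi = np.exp(np.log(oratio) + np.array([-1.96, 1.96]) * se)
    return ContingencyResult(float(oratio), (float(lo), float(hi)), p, chosen)


@dataclass
class KaplanMeierFit:
    """Product-limit survival estimate with Greenwood 95% bands."""

    event_times: np.ndarray  # distinct times with >=1 event, sorted
    survival: np.ndarray  # S(t) just after each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    @property
    def median(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if len(below) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


def km_fit(times, events) -> KaplanMeierFit:
    """Kaplan-Meier estimate with Greenwood variance.

    The 95% band is computed on the log scale, ``S * exp(+/- 1.96 *
    sqrt(sum d/(n(n-d))))``, and clipped to [0, 1].  With no censoring the
    estimate equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise StatsError("km_fit needs at least one observation")
    if np.any(times < 0):
        raise StatsError("survival times must be nonnegative")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    ev_times = np.unique(times[events])
    surv, lo, hi, at_risk, n_ev = [], [], [], [], []
    s = 1.0
    greenwood = 0.0
    for t in ev_times:
        n = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n
        at_risk.append(n)
        n_ev.append(d)
        surv.append(s)
        if d < n:
            greenwood += d / (n * (n - d))
            half = 1.96 * np.sqrt(greenwood)
            lo.append(min(max(s * np.exp(-half), 0.0), 1.0))
            hi.append(min(s * np.exp(half), 1.0))
        else:  # S hit zero; variance of log S undefined
            lo.append(0.0)
            hi.append(0.0 if s == 0 else 1.0)
    return KaplanMeierFit(
        ev_times,
        np.array(surv),
        np.array(lo),
        np.array(hi),
        np.array(at_risk),
        np.array(n_ev),
    )


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, two-sided p) on 1 df.

    With zero events in both groups the test is undefined and (nan, nan)
    is returned with a warning.
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a = np.asarray(events_a).astype(bool)
    events_b = np.asarray(events_b).astype(bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise StatsError("logrank needs both groups nonempty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("logrank: no events in either group; p undefined")
        return float("nan"), float("nan")
    from lifelines.statistics import logrank_test

    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def event_rate_hr(
    times_a, events_a, times_b, events_b, method: str = "person_time"
) -> tuple[float, tuple[float, float]]:
    """Hazard ratio approximated as the ratio of event rates A / B.

    ``person_time`` (default): rate = events / summed follow-up time, so on
    exponential data the ratio converges to the true hazard ratio.
    ``proportion``: rate = events / n.  The 95% CI is
    ``exp(log HR +/- 1.96 * sqrt(1/dA + 1/dB))``; zero event counts get a
    +0.5 continuity correction with a warning.
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    d_a = float(np.asarray(events_a).astype(bool).sum())
    d_b = float(np.asarray(events_b).astype(bool).sum())
    if method == "person_time":
        t_a, t_b = times_a.sum(), times_b.sum()
    elif method == "proportion":
        t_a, t_b = float(len(times_a)), float(len(times_b))
    else:
        raise StatsError(f"unknown event_rate_hr method {method!r}")
    if t_a <= 0 or t_b <= 0:
        raise StatsError("event_rate_hr needs positive person-time in both groups")
    if d_a == 0 or d_b == 0:
        warnings.warn("event_rate_hr: zero events in a group; +0.5 continuity applied")
        d_a += 0.5
        d_b += 0.5
    hr = (d_a / t_a) / (d_b / t_b)
    half = 1.96 * np.sqrt(1.0 / d_a + 1.0 / d_b)
    return float(hr), (float(hr * np.exp(-half)), float(hr * np.exp(half)))


def dichotomize_median(values) -> pd.Series:
    """Split at the cohort median: 'high' if value > median, else 'low'.

    Ties at the median go low; missing values stay missing (excluded from
    the median).  A constant vector produces an empty 'high' group, which
    downstream survival comparisons must treat as degenerate.
    """
    s = pd.Series(values, dtype=float)
    if s.notna().sum() < 2:
        raise StatsError("dichotomize_median needs >=2 non-missing values")
    med = s.median(skipna=True)
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s.notna()] = np.where(s[s.notna()] > med, "high", "low")
    if (out == "high").sum() == 0:
        warnings.warn("dichotomize_median: empty 'high' group (constant or highly tied values)")
    return out
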