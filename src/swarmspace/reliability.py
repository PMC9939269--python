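"""How many events are needed before a metric's cumulative mean stabilizes.

For each metric the cumulative mean over chronologically ordered events is
tracked; a *broken-line* model — a sloped segment joined continuously to a
slope-0 plateau at an unknown event index tau — is fitted by profiled least
squares, with a likelihood-ratio test against the flat-mean null and a
profile-likelihood confidence set for tau. A bootstrap over event order
checks that conclusions do not hinge on chronology, and a KPSS test
distinguishes genuinely level-stationary series (where any change-point is
uninformative) from series with a real trend-to-plateau transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import kpss as sm_kpss


@dataclass
class ChangePointResult:
    tau_hat: int
    ci95: tuple[int, int]
    ci90: tuple[int, int]
    p_value: float
    slope_pre: float
    intercept: float
    significant: bool
    informative: bool
    rss: float
    n: int


@dataclass
class KPSSResult:
    statistic: float
    p_value: float
    lags: int
    stationary_at_5pct: bool


def cumulative_means(values) -> np.ndarray:
    """Running mean of event metric values ordered {1, 2, ..., n}."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 events")
    return np.cumsum(values) / np.arange(1, len(values) + 1)


def cumulative_mean_table(event_metrics: pd.DataFrame,
                          metrics: list, order_by: str = "start_t") -> pd.DataFrame:
    """Cumulative-mean series per metric, events in chronological order."""
    df = event_metrics.sort_values(order_by) if order_by else event_metrics
    return pd.DataFrame({m: cumulative_means(df[m].to_numpy()) for m in metrics},
                        index=np.arange(1, len(df) + 1))


def _broken_line_rss(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RSS, intercept and slope of the broken-line fit at every candidate tau.

    Model: y_k = a + b * (min(k, tau) - tau); slope b before tau, exactly
    flat at level a after, continuous at the join. tau ranges over the
    integer grid 2..n-2 (1-based event index).
    """
    n = len(y)
    taus = np.arange(2, n - 1)
    k = np.arange(1, n + 1, dtype=float)
    rss = np.empty(len(taus))
    a_hat = np.empty(len(taus))
    b_hat = np.empty(len(taus))
    for i, tau in enumerate(taus):
        r = np.minimum(k, tau) - tau
        rbar = r.mean()
        srr = np.sum((r - rbar) ** 2)
        b = np.sum((r - rbar) * (y - y.mean())) / srr if srr > 0 else 0.0
        a = y.mean() - b * rbar
        rss[i] = np.sum((y - a - b * r) ** 2)
        a_hat[i], b_hat[i] = a, b
    return taus, rss, np.column_stack([a_hat, b_hat])


class BrokenLineChangePoint(BaseEstimator):
    """Trend-to-plateau change-point estimator for a cumulative-mean series.

    ``fit(y)`` profiles the join index tau over the integer grid 2..n-2,
    minimizing the residual sum of squares of the continuous broken-line
    model. Significance against the flat-mean null uses the likelihood-ratio
    statistic ``n * log(RSS0 / RSS1)`` with a chi-square(1) reference, and
    the confidence set for tau collects every grid point within the
    chi-square(1) profile-likelihood cutoff (endpoints rounded outward by
    construction of the integer grid).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n < 8:
            raise ValueError("need at least 8 points for a change-point fit")
        taus, rss, coefs = _broken_line_rss(y)
        i = int(np.argmin(rss))
        rss1 = rss[i]
        rss0 = float(np.sum((y - y.mean()) ** 2))

        informative = True
        if rss0 <= 1e-300 or (rss0 - rss1) <= 1e-12 * max(rss0, 1e-300):
            # flat series: no RSS improvement, the fit carries no information
            informative = False
            p = 1.0
            i = len(taus) - 1  # pin tau at the end of the grid (n-2)
            rss1 = rss[i]
        else:
            lr = n * np.log(rss0 / max(rss1, 1e-300))
            p = float(stats.chi2.sf(lr, df=1))

        def ci(level: float) -> tuple[int, int]:
            if rss1 <= 1e-300:
                return int(taus[i]), int(taus[i])
            cut = stats.chi2.ppf(level, df=1)
            inside = n * np.log(rss / rss1) <= cut
            # the continuous-tau confidence boundary falls between grid
            # points; round the integer endpoints outward
            lo = max(int(taus[0]), int(taus[inside].min()) - 1)
            hi = min(int(taus[-1]), int(taus[inside].max()) + 1)
            return lo, hi

        self.result_ = ChangePointResult(
            tau_hat=int(taus[i]), ci95=ci(0.95), ci90=ci(0.90), p_value=p,
            slope_pre=float(coefs[i, 1]), intercept=float(coefs[i, 0]),
            significant=bool(informative and p < self.alpha),
            informative=informative, rss=float(rss1), n=n)
        self.tau_hat_ = self.result_.tau_hat
        return self

    def predict(self, k=None) -> np.ndarray:
        """Fitted broken line at event indices ``k`` (default 1..n)."""
        r = self.result_
        if k is None:
            k = np.arange(1, r.n + 1)
        k = np.asarray(k, dtype=float)
        return r.intercept + r.slope_pre * (np.minimum(k, r.tau_hat) - r.tau_hat)


def broken_line_changepoint(series, alpha: float = 0.05) -> ChangePointResult:
    """Fit the broken-line change-point model to a cumulative-mean series."""
    return BrokenLineChangePoint(alpha=alpha).fit(series).result_


def bootstrap_changepoint(event_values, B: int = 10_000, seed: int = 0,
                          alpha: float = 0.05) -> dict:
    """Bootstrap tau over event order.

    Events are resampled i.i.d. with replacement (destroying chronology), the
    cumulative mean rebuilt and the change-point refitted per replicate —
    a check that the estimated sample size does not depend on the particular
    order events happened to occur in.
    """
    event_values = np.asarray(event_values, dtype=float)
    n = len(event_values)
    if n < 8:
        raise ValueError("need at least 8 events")
    rng = np.random.default_rng(seed)
    taus = np.empty(B, dtype=int)
    sig = np.zeros(B, dtype=bool)
    for b in range(B):
        res = broken_line_changepoint(
            cumulative_means(event_values[rng.integers(0, n, n)]), alpha)
        taus[b] = res.tau_hat
        sig[b] = res.significant
    return {"tau_median": float(np.median(taus)),
            "tau_ci": (float(np.percentile(taus, 2.5)),
                       float(np.percentile(taus, 97.5))),
            "prop_significant": float(sig.mean()),
            "taus": taus, "B": B, "seed": seed}


def kpss_test(series, lags="short") -> KPSSResult:
    """KPSS level-stationarity test of a (cumulative-mean) series.

    Null hypothesis: the series is stationary around a constant level. Uses a
    Bartlett-window long-run variance with ``lags = floor(4 (n/100)^0.25)``
    by default; the p-value is interpolated from the standard critical-value
    table and clamped to its [0.01, 0.1] range. A zero-variance series is
    stationary by convention.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 10:
        raise ValueError("need at least 10 points for a KPSS test")
    if lags == "short":
        lags = int(np.floor(4 * (n / 100.0) ** 0.25))
    if np.ptp(series) == 0.0:
        return KPSSResult(statistic=0.0, p_value=0.1,
                          lags=lags if isinstance(lags, int) else 0,
                          stationary_at_5pct=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, p, nlags, _ = sm_kpss(series, regression="c", nlags=lags)
    return KPSSResult(statistic=float(stat), p_value=float(p), lags=int(nlags),
                      stationary_at_5pct=bool(p > 0.05))


def reliability_report(event_metrics_by_dataset: dict, metrics: list,
                       alpha: float = 0.05, lags="short",
                       order_by: str = "start_t") -> pd.DataFrame:
    """Change-point / stationarity classification per metric and dataset.

    Each cell reports whether a significant trend-to-plateau change-point is
    present in the cumulative mean and whether the series is KPSS-stationary,
    the grid used to judge which metrics are reliably estimated at a given
    number of events.
    """
    rows = []
    for dataset, df in event_metrics_by_dataset.items():
        cum = cumulative_mean_table(df, metrics, order_by)
        for metric in metrics:
            series = cum[metric].to_numpy()
            cp = broken_line_changepoint(series, alpha)
            kp = kpss_test(series, lags)
            if cp.significant and not kp.stationary_at_5pct:
                cls = "change-point"
            elif cp.significant:
                # a change-point inside a stationary series is uninformative
                cls = "change-point (stationary)"
            elif kp.stationary_at_5pct:
                cls = "stationary"
            else:
                cls = "no change-point"
            rows.append({"dataset": dataset, "metric": metric,
                         "tau_hat": cp.tau_hat, "ci_low": cp.ci95[0],
                         "ci_high": cp.ci95[1], "p_changepoint": cp.p_value,
                         "kpss_stat": kp.statistic, "kpss_p": kp.p_value,
                         "stationary": kp.stationary_at_5pct,
                         "significant_changepoint": cp.significant,
                         "classification": cls})
    return pd.DataFrame(rows)
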