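"""Deviation-from-scan-mean (DFSM), Poisson references and overdispersion.

The central quantities:

* ``DFSM_i = |C_i - lambda| / lambda * 100%`` — the percentage deviation
  of the count ``C_i`` in the i-th equivalent blood sample from the
  scan-mean count ``lambda`` for that sample size.  The fraction of
  samples with DFSM below a threshold (25%, 50%) measures how often a
  single randomly-timed blood draw would enumerate the cells to within
  that error.
* Poisson reference distributions of the same mean, against which the
  empirical count distributions and DFSM fractions are compared.
* The variance-to-mean relation of window counts: a Poisson (well-mixed,
  steady-state) stream is equidispersed (variance = mean); a stream
  whose underlying rate moves on the scan timescale is overdispersed,
  which a zero-intercept variance-vs-mean fit exposes as a slope > 1.

Overlapping ("sliding") windows reuse the same events many times, which
biases the plain sample variance of their counts downward: with ``n``
window starts of length ``w`` at stride ``s``, neighbouring counts share
``max(0, 1 - d*s/w)`` of their window, and for a stationary stream

    E[S^2] = sigma^2 * (n/(n-1)) * (1 - g/n),
    g = 1 + 2 * sum_d (1 - d/n) * max(0, 1 - d*s/w),

so :func:`variance_mean_point` divides the sample variance by this
factor in sliding mode.  The factor tends to 1 as ``w/duration -> 0``
(many effectively independent windows), recovering the known property
that the sliding variance converges to the non-overlapping variance on
long streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import EventSeries
from .intervals import IntervalCounts, scan_mean

__all__ = [
    "DfsmResult",
    "VarianceMeanPoint",
    "dfsm",
    "dfsm_threshold_fraction",
    "poisson_reference_pmf",
    "poisson_dfsm_fraction",
    "sliding_variance_factor",
    "variance_mean_point",
    "zero_intercept_fit",
    "maxmin_rate_ratio",
    "split_scan_ratio",
    "ks_two_sample",
]

_EPS = 1e-9


@dataclass(frozen=True)
class DfsmResult:
    """Per-window DFSM percentages and the scan mean they refer to."""

    values: np.ndarray
    lam: float
    source_label: str = ""

    def threshold_fraction(self, threshold_pct: float) -> float:
        return dfsm_threshold_fraction(self, threshold_pct)

    def threshold_fractions(self, thresholds=(25.0, 50.0)) -> dict[float, float]:
        return {float(t): dfsm_threshold_fraction(self, t) for t in thresholds}


@dataclass(frozen=True)
class VarianceMeanPoint:
    """Sample mean and variance of window counts for one scan."""

    mean: float
    variance: float
    window: float
    n_windows: int
    source_label: str = ""


def dfsm(counts: IntervalCounts, lam: float | None = None) -> DfsmResult:
    """Deviation from the scan mean, in percent, for every window.

    ``lam`` defaults to the scan mean of ``counts`` and must be
    positive (the statistic is undefined for an empty scan).
    """
    if lam is None:
        lam = scan_mean(counts)
    if not lam > 0:
        raise ValueError(f"DFSM undefined for scan mean {lam}")
    values = np.abs(counts.counts - lam) / lam * 100.0
    return DfsmResult(values, float(lam), counts.source_label)


def dfsm_threshold_fraction(result: DfsmResult, threshold_pct: float) -> float:
    """Fraction of windows with DFSM <= threshold (inclusive)."""
    if threshold_pct < 0:
        raise ValueError("threshold must be non-negative")
    if result.values.size == 0:
        raise ValueError("no DFSM values")
    return float(np.mean(result.values <= threshold_pct + _EPS))


def poisson_reference_pmf(lam: float, k_max: int) -> tuple[np.ndarray, float]:
    """Poisson pmf over ``k = 0..k_max`` plus the tail mass beyond ``k_max``."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    k = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(k, lam)
    tail = float(stats.poisson.sf(k_max, lam))
    return pmf, tail


def poisson_dfsm_fraction(lam: float, threshold_pct: float) -> float:
    """Expected fraction of Poisson(λ) counts with DFSM <= threshold.

    Sums the pmf over the integers ``k`` with ``|k - lam| <= lam*thr/100``
    — the reference curve a steady, well-mixed stream would follow.
    """
    if not lam > 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if threshold_pct < 0:
        raise ValueError("threshold must be non-negative")
    half = lam * threshold_pct / 100.0
    lo = int(math.ceil(lam - half - _EPS))
    hi = int(math.floor(lam + half + _EPS))
    if hi < max(lo, 0):
        return 0.0
    lo = max(lo, 0)
    return float(stats.poisson.cdf(hi, lam) - stats.poisson.cdf(lo - 1, lam))


def sliding_variance_factor(n_windows: int, window: float, stride: float) -> float:
    """Expected shrinkage ``E[S^2]/sigma^2`` of the overlapping-window
    sample variance (n-1 divisor) for a stationary stream."""
    n = int(n_windows)
    if n < 2:
        raise ValueError("need at least 2 windows")
    d_max = min(n - 1, int(math.ceil(window / stride)) - 1)
    if d_max < 1:
        return 1.0
    d = np.arange(1, d_max + 1)
    rho = 1.0 - d * stride / window
    g = 1.0 + 2.0 * float(np.sum((1.0 - d / n) * rho))
    return (n / (n - 1.0)) * (1.0 - g / n)


def variance_mean_point(
    counts: IntervalCounts, overlap_correction: str | bool = "auto"
) -> VarianceMeanPoint:
    """Sample mean and variance (n-1 divisor) of window counts.

    ``overlap_correction`` — "auto" (default) divides the sample
    variance by :func:`sliding_variance_factor` when the counts came
    from sliding windows, making the estimator unbiased for stationary
    streams; ``False`` always returns the raw sample variance;
    ``True`` forces the correction.
    """
    if counts.n_windows < 2:
        raise ValueError("need at least 2 windows")
    m = float(np.mean(counts.counts))
    v = float(np.var(counts.counts, ddof=1))
    apply = (
        overlap_correction is True
        or (overlap_correction == "auto" and counts.spec.mode == "sliding")
    )
    if apply:
        v /= sliding_variance_factor(counts.n_windows, counts.spec.window, counts.spec.stride)
    return VarianceMeanPoint(m, v, counts.spec.window, counts.n_windows, counts.source_label)


def zero_intercept_fit(points) -> float:
    """Least-squares slope of variance on mean through the origin.

    ``slope = sum(m_i * v_i) / sum(m_i^2)``; slope 1 is the Poisson
    (equidispersion) signature, slope > 1 indicates overdispersion.
    """
    pts = list(points)
    means = np.array([p.mean for p in pts])
    varis = np.array([p.variance for p in pts])
    if means.size == 0 or np.all(means == 0):
        raise ValueError("need at least one point with positive mean")
    return float(np.sum(means * varis) / np.sum(means**2))


def maxmin_rate_ratio(rates, zero_floor: float | None = None) -> float:
    """Max/min ratio of a set of detection rates.

    A zero minimum yields ``inf`` (flagged-infinite) unless
    ``zero_floor`` substitutes a positive floor rate for zeros.
    """
    r = np.asarray(list(rates), dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 rates")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    if zero_floor is not None:
        r = np.maximum(r, zero_floor)
    mx, mn = float(np.max(r)), float(np.min(r))
    if mn == 0:
        return math.inf
    return mx / mn


def split_scan_ratio(series: EventSeries, zero_floor: float | None = None) -> float:
    """Max/min rate ratio of the first and last 15 min of a >=35-min scan.

    The two segments ``[0, 15 min)`` and ``[20 min, 35 min)`` are
    separated by a 5-min guard gap; this is the short-timescale
    counterpart of the 24-h session ratio.
    """
    if series.duration < 2100.0:
        raise ValueError(
            f"scan must last at least 35 min, got {series.duration / 60.0:.1f} min"
        )
    first = series.restricted(0.0, 900.0).n_events / 15.0
    last = series.restricted(1200.0, 2100.0).n_events / 15.0
    return maxmin_rate_ratio([first, last], zero_floor=zero_floor)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    Returns ``(D, p)`` with ``D = sup |ECDF_a - ECDF_b|``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
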