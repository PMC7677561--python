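"""Equivalent-blood-sample interval counting and detection summaries.

A scan interval of length ``w`` seconds is an equivalent blood sample of
``w/60 * sampling_rate`` microlitres; counting events in families of
such windows turns one continuous scan into the count distribution a
repeated blood draw of that size would have produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EventSeries, IntervalSpec

__all__ = [
    "IntervalCounts",
    "count_in_windows",
    "detection_fraction",
    "expected_detection_fraction",
    "count_histogram",
    "scan_mean",
    "inclusion_filter",
]


@dataclass(frozen=True)
class IntervalCounts:
    """Event counts over a family of windows on one series."""

    spec: IntervalSpec
    starts: np.ndarray
    counts: np.ndarray
    source_label: str = ""
    source_duration: float = 0.0

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.counts):
            raise ValueError("starts and counts must have equal length")

    @property
    def n_windows(self) -> int:
        return int(len(self.counts))


def count_in_windows(series: EventSeries, spec: IntervalSpec) -> IntervalCounts:
    """Tally events in half-open windows ``[t, t+w)``, ``t = 0, stride, ...``.

    Window starts run while ``t + w <= duration``; a trailing partial
    window is discarded (a fixed-size blood sample is all or nothing).
    An event exactly at ``t + w`` belongs to the next window.
    """
    w, s = spec.window, spec.stride
    if w > series.duration:
        raise ValueError(
            f"window {w} s exceeds scan duration {series.duration} s"
        )
    # number of starts with t + w <= duration, robust to float stride
    n = int(np.floor((series.duration - w) / s + 1e-9)) + 1
    starts = np.arange(n) * s
    hi = np.searchsorted(series.times, starts + w, side="left")
    lo = np.searchsorted(series.times, starts, side="left")
    return IntervalCounts(spec, starts, (hi - lo).astype(np.int64), series.label, series.duration)


def detection_fraction(counts: IntervalCounts) -> float:
    """Fraction of windows (equivalent blood samples) with at least one event."""
    if counts.n_windows == 0:
        raise ValueError("no windows")
    return float(np.mean(counts.counts >= 1))


def expected_detection_fraction(rate_per_min: float, window_s: float) -> float:
    """Analytic ``P(>= 1 event)`` for a homogeneous Poisson stream.

    ``1 - exp(-rate * window)`` — the closed-form limit that the
    empirical detection fraction converges to as windows accumulate.
    """
    if rate_per_min < 0 or window_s < 0:
        raise ValueError("rate and window must be non-negative")
    return float(-np.expm1(-(rate_per_min / 60.0) * window_s))


def count_histogram(counts: IntervalCounts) -> dict[int, int]:
    """Mapping count value -> number of windows; frequencies sum to n_windows."""
    if counts.n_windows == 0:
        raise ValueError("no windows")
    vals, freq = np.unique(counts.counts, return_counts=True)
    return {int(v): int(f) for v, f in zip(vals, freq)}


def scan_mean(counts: IntervalCounts) -> float:
    """Mean events per window over the whole scan (the DFSM reference λ)."""
    if counts.n_windows == 0:
        raise ValueError("no windows")
    return float(np.mean(counts.counts))


def inclusion_filter(series: EventSeries, rule: str, min_rate_per_min: float = 0.5) -> bool:
    """Cohort inclusion rules.

    ``"any_detection"`` passes iff the scan recorded at least one event;
    ``"min_rate"`` passes iff the scan-mean rate strictly exceeds
    ``min_rate_per_min`` (default 0.5 events/min, the abundant-CTC
    cohort threshold).
    """
    if rule == "any_detection":
        return series.n_events >= 1
    if rule == "min_rate":
        return series.rate_per_min > min_rate_per_min
    raise ValueError(f"unknown inclusion rule {rule!r}")
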