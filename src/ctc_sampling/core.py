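"""Domain types and the interval <-> blood-volume conversion layer.

An in vivo flow cytometry scan produces a stream of timestamped
detection events (one per fluorescent cell passing the probe).  Because
the instrument interrogates a known volumetric blood flow (about
50 ul of peripheral blood per minute in the mouse), any *time interval*
of the scan corresponds to an *equivalent blood sample* of proportional
volume: a 24 s interval corresponds to ~20 ul of blood, i.e. roughly 1%
of the ~2 ml mouse peripheral blood volume (PBV).  The equivalence is
taken at face value here — the count of events in a scan interval is
treated as the count of cells that a drawn blood sample of the
corresponding volume would have contained; no dilution or mixing
correction is applied.

Canonical units throughout the package:

* event times and window lengths: seconds
* detection rates: events per minute
* blood volumes: microlitres (the %-of-PBV figure is display only)
* cell concentrations: events per millilitre of blood
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "EventSeries",
    "IntervalSpec",
    "validate_event_series",
    "rate_to_concentration",
    "concentration_to_rate",
    "interval_to_volume",
    "volume_to_pbv_fraction",
]


@dataclass(frozen=True)
class ScanConfig:
    """Physiological conversion constants for a scan.

    Parameters
    ----------
    sampling_rate_ul_per_min:
        Blood volume optically sampled per unit time, in ul/min.
        Default 50 (the instrument's conservative estimate for the
        mouse ventral caudal vessel bundle).
    pbv_ml:
        Total peripheral blood volume of the animal, in ml.  Default
        2.0 (adult mouse).  Used for display-level %PBV labels only.
    """

    sampling_rate_ul_per_min: float = 50.0
    pbv_ml: float = 2.0

    def __post_init__(self) -> None:
        if not self.sampling_rate_ul_per_min > 0:
            raise ValueError(
                f"sampling rate must be positive, got {self.sampling_rate_ul_per_min}"
            )
        if not self.pbv_ml > 0:
            raise ValueError(f"peripheral blood volume must be positive, got {self.pbv_ml}")


DEFAULT_CONFIG = ScanConfig()


@dataclass(frozen=True)
class EventSeries:
    """One scan: sorted detection timestamps within a known duration.

    ``times`` are seconds from scan start, each in ``[0, duration)``.
    The series may be empty.  Exact duplicate timestamps are permitted
    (two cells can pass within one clock tick) but are logged.
    """

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if times.size:
            if np.any(~np.isfinite(times)):
                raise ValueError("event times must be finite")
            times = np.sort(times)
            if times[0] < 0 or times[-1] >= self.duration:
                bad = times[0] if times[0] < 0 else times[-1]
                raise ValueError(
                    f"event time {bad!r} outside [0, {self.duration}) in series {self.label!r}"
                )
            if np.any(np.diff(times) == 0):
                logger.warning(
                    "series %r contains duplicate timestamps (kept)", self.label
                )
        object.__setattr__(self, "times", times)

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    @property
    def rate_per_min(self) -> float:
        """Mean detection rate over the scan, events/min."""
        return self.n_events / (self.duration / 60.0)

    def restricted(self, start: float, stop: float) -> "EventSeries":
        """Events in ``[start, stop)`` re-referenced to a new origin."""
        if not 0 <= start < stop <= self.duration:
            raise ValueError(f"invalid restriction [{start}, {stop})")
        lo, hi = np.searchsorted(self.times, [start, stop], side="left")
        return EventSeries(self.times[lo:hi] - start, stop - start, self.label)


def validate_event_series(series: EventSeries) -> EventSeries:
    """Return a validated copy of ``series`` (sorted, range-checked).

    ``EventSeries`` already validates on construction; this re-runs the
    checks so externally deserialized objects can be funnelled through
    a single audited entry point.
    """
    return replace(series)


@dataclass(frozen=True)
class IntervalSpec:
    """A family of counting windows of fixed length.

    ``sliding`` mode places a window start every ``stride`` seconds
    (default 1 s — effectively "all possible intervals");
    ``nonoverlapping`` mode tiles the scan with abutting windows
    (stride forced equal to the window).  Windows are half-open
    ``[t, t + window)`` and trailing partial windows are discarded.
    """

    window: float
    mode: str = "sliding"
    stride: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise ValueError(f"window must be positive, got {self.window}")
        if self.mode not in ("sliding", "nonoverlapping"):
            raise ValueError(f"unknown mode {self.mode!r}")
        stride = self.stride
        if self.mode == "nonoverlapping":
            if stride is not None and stride != self.window:
                raise ValueError("nonoverlapping mode requires stride == window")
            stride = self.window
        elif stride is None:
            stride = 1.0
        if not stride > 0:
            raise ValueError(f"stride must be positive, got {stride}")
        object.__setattr__(self, "stride", float(stride))


# ---------------------------------------------------------------------------
# Interval <-> volume <-> concentration conversions
# ---------------------------------------------------------------------------

def rate_to_concentration(rate_per_min: float, config: ScanConfig = DEFAULT_CONFIG) -> float:
    """Convert a detection rate (events/min) to a blood concentration (events/ml).

    With the default 50 ul/min sampling rate one minute of scan time
    samples 0.05 ml, so concentration = rate / 0.05 = 20 * rate.
    """
    if rate_per_min < 0:
        raise ValueError(f"rate must be non-negative, got {rate_per_min}")
    ml_per_min = config.sampling_rate_ul_per_min / 1000.0
    return rate_per_min / ml_per_min


def concentration_to_rate(conc_per_ml: float, config: ScanConfig = DEFAULT_CONFIG) -> float:
    """Inverse of :func:`rate_to_concentration`."""
    if conc_per_ml < 0:
        raise ValueError(f"concentration must be non-negative, got {conc_per_ml}")
    ml_per_min = config.sampling_rate_ul_per_min / 1000.0
    return conc_per_ml * ml_per_min


def interval_to_volume(window_s: float, config: ScanConfig = DEFAULT_CONFIG) -> float:
    """Equivalent blood volume (ul) of a scan interval of ``window_s`` seconds."""
    if not window_s > 0:
        raise ValueError(f"window must be positive, got {window_s}")
    return window_s / 60.0 * config.sampling_rate_ul_per_min


def volume_to_pbv_fraction(volume_ul: float, config: ScanConfig = DEFAULT_CONFIG) -> float:
    """Fraction of the peripheral blood volume represented by ``volume_ul``.

    Display-level only: the fraction is never fed back into any
    computation (volumes in ul stay canonical).
    """
    if volume_ul < 0:
        raise ValueError(f"volume must be non-negative, got {volume_ul}")
    return volume_ul / (config.pbv_ml * 1000.0)
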