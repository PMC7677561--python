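"""Synthetic detection-event streams.

Every generator realizes a point process with piecewise-constant rate by
exponential inter-arrival sampling (the memoryless property makes
restarting the clock at a rate change exact, so no thinning is needed).
All randomness flows through :class:`numpy.random.Generator`; a stream
battery derives one child seed per stream from a master seed via
``numpy.random.SeedSequence.spawn`` in a fixed order, so any replicate
is reproducible in isolation.

The stream kinds mirror the study designs this package analyzes:

* ``homogeneous`` — constant-rate Poisson process (the well-mixed,
  steady-state null; also the statistical role of a well-mixed
  microsphere flow phantom).
* ``changepoint`` — rate doubles (generally: jumps) at a fixed time, the
  minimal model of a mean CTC level that changes mid-scan.
* ``merged`` — superposition of two independent Poisson streams, e.g.
  two concurrent shedding sources.  By the superposition theorem this
  is itself Poisson at the summed rate — the point of the comparison.
* ``switching`` — two-state Markov-modulated Poisson process, the
  verbal "high/low shedding state" hypothesis made concrete.
* ``diurnal_session`` — four spaced scans in a 24-h window whose
  per-scan rates vary by a session-level multiplier law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import EventSeries
from .io import write_event_series

__all__ = [
    "SimSpec",
    "DiurnalSession",
    "simulate_homogeneous_poisson",
    "simulate_changepoint_poisson",
    "simulate_merged_poisson",
    "simulate_switching_shedding",
    "simulate_diurnal_session",
    "generate_fixture_suite",
    "MM_RATE_RANGE_PER_MIN",
    "DEFAULT_MULTIPLIER_BOUNDS",
]

#: Detection-rate envelope (events/min) of the abundant-CTC cohort the
#: simulated batteries emulate.
MM_RATE_RANGE_PER_MIN = (0.6, 19.6)

#: Default bounds of the log-uniform per-scan rate multiplier for
#: diurnal sessions.  Chosen so that session max/min rate ratios span
#: roughly 3-100 across a 14-session battery, emulating the observed
#: order-of-magnitude (up to ~150x) within-day variability.
DEFAULT_MULTIPLIER_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic stream (or session)."""

    kind: str
    rate1: float
    rate2: float = 0.0
    change_time: float = 0.0
    duration: float = 2100.0
    seed: int = 0
    n_replicates: int = 1

    _KINDS = ("homogeneous", "changepoint", "merged", "switching", "diurnal_session")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.rate1 < 0 or self.rate2 < 0:
            raise ValueError("rates must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.kind == "changepoint" and not 0 < self.change_time < self.duration:
            raise ValueError(
                f"change_time must lie in (0, {self.duration}), got {self.change_time}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class DiurnalSession:
    """An ordered battery of equal-length scans spanning <= 24 h.

    ``start_hours`` are hours since the session began (monotone, within
    [0, 24]); ``clock_start_hour`` anchors the first scan to wall-clock
    hours-of-day for display.
    """

    scans: tuple
    start_hours: tuple
    session_id: str = ""
    clock_start_hour: float = 7.0

    def __post_init__(self) -> None:
        if len(self.scans) != len(self.start_hours):
            raise ValueError("scans and start_hours length mismatch")
        hrs = np.asarray(self.start_hours, dtype=float)
        if hrs.size and (np.any(np.diff(hrs) <= 0) or hrs[0] < 0 or hrs[-1] > 24):
            raise ValueError("start_hours must be strictly increasing within [0, 24]")
        durs = {s.duration for s in self.scans}
        if len(durs) > 1:
            raise ValueError("scan durations must be equal within a session")

    @property
    def scan_duration(self) -> float:
        return self.scans[0].duration

    @property
    def scan_rates_per_min(self) -> np.ndarray:
        return np.array([s.rate_per_min for s in self.scans])

    @property
    def pooled_rate_per_min(self) -> float:
        """24-h reference rate: pooled events over pooled scanned time."""
        total = sum(s.n_events for s in self.scans)
        return total / (len(self.scans) * self.scan_duration / 60.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _exp_arrivals(rate_per_min: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Arrival times in [0, duration) via exponential inter-arrivals."""
    if rate_per_min < 0:
        raise ValueError(f"rate must be non-negative, got {rate_per_min}")
    if rate_per_min == 0:
        return np.empty(0)
    lam = rate_per_min / 60.0  # events per second
    times = []
    t = 0.0
    # draw in chunks to keep the loop cheap at high rates
    chunk = max(16, int(1.5 * lam * duration_s) + 16)
    while True:
        gaps = rng.exponential(1.0 / lam, size=chunk)
        arr = t + np.cumsum(gaps)
        inside = arr[arr < duration_s]
        times.append(inside)
        if inside.size < arr.size:
            return np.concatenate(times)
        t = arr[-1]
        chunk = max(16, chunk // 4)


def simulate_homogeneous_poisson(
    rate_per_min: float, duration_s: float, seed, label: str = ""
) -> EventSeries:
    """Constant-rate Poisson stream; expected count = rate x duration."""
    rng = _as_rng(seed)
    return EventSeries(_exp_arrivals(rate_per_min, duration_s, rng), duration_s, label)


def simulate_changepoint_poisson(
    rate1: float, rate2: float, change_time_s: float, duration_s: float, seed, label: str = ""
) -> EventSeries:
    """Poisson stream whose rate jumps from ``rate1`` to ``rate2`` at ``change_time_s``."""
    if not 0 < change_time_s < duration_s:
        raise ValueError(
            f"change_time must lie in (0, {duration_s}), got {change_time_s}"
        )
    rng = _as_rng(seed)
    first = _exp_arrivals(rate1, change_time_s, rng)
    second = _exp_arrivals(rate2, duration_s - change_time_s, rng) + change_time_s
    return EventSeries(np.concatenate([first, second]), duration_s, label)


def simulate_merged_poisson(
    rate1: float, rate2: float, duration_s: float, seed, label: str = ""
) -> EventSeries:
    """Union of two independent homogeneous streams (superposed sources)."""
    rng = _as_rng(seed)
    a = _exp_arrivals(rate1, duration_s, rng)
    b = _exp_arrivals(rate2, duration_s, rng)
    return EventSeries(np.sort(np.concatenate([a, b])), duration_s, label)


def simulate_switching_shedding(
    rate_low: float,
    rate_high: float,
    mean_dwell_low_min: float,
    mean_dwell_high_min: float,
    duration_s: float,
    seed,
    label: str = "",
) -> EventSeries:
    """Two-state Markov-modulated Poisson stream (high/low shedding states).

    Dwell times in each state are exponential with the given means; the
    initial state is drawn from the stationary distribution (dwell-time
    weighted).  Long-run mean rate is the time-weighted average
    ``(r_lo*d_lo + r_hi*d_hi) / (d_lo + d_hi)``.
    """
    if rate_low < 0 or rate_high < 0:
        raise ValueError("rates must be non-negative")
    if not (mean_dwell_low_min > 0 and mean_dwell_high_min > 0):
        raise ValueError("dwell means must be positive")
    rng = _as_rng(seed)
    dwell_s = (mean_dwell_low_min * 60.0, mean_dwell_high_min * 60.0)
    rates = (rate_low, rate_high)
    p_low = dwell_s[0] / (dwell_s[0] + dwell_s[1])
    state = 0 if rng.random() < p_low else 1
    t = 0.0
    pieces = []
    while t < duration_s:
        dwell = rng.exponential(dwell_s[state])
        stop = min(t + dwell, duration_s)
        if stop > t:
            pieces.append(t + _exp_arrivals(rates[state], stop - t, rng))
        t = stop
        state = 1 - state
    times = np.concatenate(pieces) if pieces else np.empty(0)
    return EventSeries(times, duration_s, label)


def _draw_multipliers(rng: np.random.Generator, n: int, bounds: tuple) -> np.ndarray:
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"multiplier bounds must satisfy 0 < lo < hi, got {bounds}")
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def simulate_diurnal_session(
    base_rate_per_min: float,
    scan_multipliers: Sequence[float] | str = "loguniform",
    scan_duration_s: float = 3000.0,
    start_hours: Sequence[float] = (0.0, 6.0, 12.0, 18.0),
    seed=0,
    session_id: str = "",
    multiplier_bounds: tuple = DEFAULT_MULTIPLIER_BOUNDS,
    clock_start_hour: float = 7.0,
) -> DiurnalSession:
    """A session of spaced scans with scan-level rate variability.

    Each scan is homogeneous Poisson at ``base_rate * multiplier``.
    Multipliers are either given explicitly (one per scan) or drawn
    log-uniformly from ``multiplier_bounds`` (the default emulates the
    observed within-day spread of mean detection rates).
    """
    rng = _as_rng(seed)
    n = len(start_hours)
    if isinstance(scan_multipliers, str):
        if scan_multipliers != "loguniform":
            raise ValueError(f"unknown multiplier law {scan_multipliers!r}")
        mult = _draw_multipliers(rng, n, multiplier_bounds)
    else:
        mult = np.asarray(scan_multipliers, dtype=float)
        if mult.size != n:
            raise ValueError(f"need {n} multipliers, got {mult.size}")
        if np.any(mult <= 0):
            raise ValueError("multipliers must be positive")
    scans = tuple(
        simulate_homogeneous_poisson(
            base_rate_per_min * m, scan_duration_s, rng, f"{session_id}/scan{i}"
        )
        for i, m in enumerate(mult)
    )
    return DiurnalSession(scans, tuple(float(h) for h in start_hours), session_id, clock_start_hour)


# ---------------------------------------------------------------------------
# Fixture battery
# ---------------------------------------------------------------------------

def battery_specs(
    n_each: int = 54,
    n_sessions: int = 14,
    rate_range: tuple = MM_RATE_RANGE_PER_MIN,
    duration_s: float = 2100.0,
) -> list[SimSpec]:
    """The default simulated study design.

    ``n_each`` 35-min streams per kind with base rates log-spaced across
    the abundant-CTC envelope: homogeneous at r, change-point with
    rate doubling (r -> 2r) at mid-scan, and merged (r + 2r) streams;
    plus ``n_sessions`` 24-h sessions of four 50-min scans.
    """
    rates = np.geomspace(rate_range[0], rate_range[1], n_each)
    specs = [SimSpec("homogeneous", rate1=float(r), duration=duration_s) for r in rates]
    specs += [
        SimSpec(
            "changepoint",
            rate1=float(r),
            rate2=2.0 * float(r),
            change_time=duration_s / 2.0,
            duration=duration_s,
        )
        for r in rates
    ]
    specs += [
        SimSpec("merged", rate1=float(r), rate2=2.0 * float(r), duration=duration_s)
        for r in rates
    ]
    session_rates = np.geomspace(rate_range[0], rate_range[1], n_sessions)
    specs += [
        SimSpec("diurnal_session", rate1=float(r), duration=3000.0) for r in session_rates
    ]
    return specs


def realize(spec: SimSpec, seed, label: str = ""):
    """Instantiate one stream (or session) from its spec with an explicit seed."""
    if spec.kind == "homogeneous":
        return simulate_homogeneous_poisson(spec.rate1, spec.duration, seed, label)
    if spec.kind == "changepoint":
        return simulate_changepoint_poisson(
            spec.rate1, spec.rate2, spec.change_time, spec.duration, seed, label
        )
    if spec.kind == "merged":
        return simulate_merged_poisson(spec.rate1, spec.rate2, spec.duration, seed, label)
    if spec.kind == "diurnal_session":
        return simulate_diurnal_session(
            spec.rate1, scan_duration_s=spec.duration, seed=seed, session_id=label
        )
    raise ValueError(f"cannot realize kind {spec.kind!r}")


def generate_fixture_suite(
    output_dir: str | Path,
    master_seed: int,
    n_each: int = 54,
    n_sessions: int = 14,
) -> dict:
    """Write the deterministic stream battery and return its manifest.

    One child seed per battery entry is spawned from ``master_seed`` in
    a fixed order, so the suite (and any single entry) is byte-for-byte
    reproducible.  The manifest records every spec and realized count.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    specs = battery_specs(n_each=n_each, n_sessions=n_sessions)
    children = np.random.SeedSequence(master_seed).spawn(len(specs))
    entries = []
    for i, (spec, child) in enumerate(zip(specs, children)):
        rng = np.random.default_rng(child)
        if spec.kind == "diurnal_session":
            label = f"{spec.kind}_{i:03d}"
            session = realize(spec, rng, label)
            paths, counts = [], []
            for j, scan in enumerate(session.scans):
                p = output_dir / f"{label}_scan{j}.csv"
                write_event_series(
                    scan, p, {"start_hour": session.start_hours[j], "session_id": label}
                )
                paths.append(p.name)
                counts.append(scan.n_events)
            entry = {
                "kind": spec.kind,
                "label": label,
                "paths": paths,
                "start_hours": list(session.start_hours),
                "rate1": spec.rate1,
                "duration": spec.duration,
                "n_events": counts,
            }
        else:
            label = f"{spec.kind}_{i:03d}"
            series = realize(spec, rng, label)
            p = output_dir / f"{label}.csv"
            write_event_series(series, p, {"kind": spec.kind})
            entry = {
                "kind": spec.kind,
                "label": label,
                "paths": [p.name],
                "rate1": spec.rate1,
                "rate2": spec.rate2,
                "change_time": spec.change_time,
                "duration": spec.duration,
                "n_events": series.n_events,
            }
        entries.append(entry)
    manifest = {
        "master_seed": int(master_seed),
        "n_each": n_each,
        "n_sessions": n_sessions,
        "entries": entries,
    }
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
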