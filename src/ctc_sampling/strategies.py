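"""Blood-sampling strategy evaluation on 24-h sessions.

A *strategy* draws ``n_samples`` equivalent blood samples of a fixed
window length from a session of spaced scans and estimates the session
mean count as the average of the per-sample counts.  Its *accuracy* at
a threshold is the fraction of possible draws whose estimate falls
within that DFSM threshold of the session's pooled 24-h mean.  The
comparison of interest: many small samples spread over the day versus a
single contiguous sample of the same total volume.

Sample separation is measured at scan granularity: two samples from
different scans are separated by the difference of the scan clock
starts; two samples from the same scan by their offset difference.  A
6-h minimum separation on a session of four scans 6 h apart therefore
forces one sample per scan.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .simulate import DiurnalSession

__all__ = [
    "StrategySpec",
    "enumerate_strategy_draws",
    "strategy_accuracy",
    "paired_strategy_comparison",
]


@dataclass(frozen=True)
class StrategySpec:
    """One sampling strategy.

    ``n_samples`` samples of ``sample_window`` seconds each, pairwise at
    least ``min_separation_h`` hours apart.  ``mode`` selects exhaustive
    enumeration over the offset grid (``stride`` seconds, default one
    window length) or seeded random draws (``n_draws`` of them).
    """

    n_samples: int
    sample_window: float
    min_separation_h: float = 6.0
    mode: str = "exhaustive"
    stride: float | None = None
    n_draws: int = 200

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.sample_window > 0:
            raise ValueError("sample_window must be positive")
        if self.mode not in ("exhaustive", "random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.stride is not None and not self.stride > 0:
            raise ValueError("stride must be positive")

    @property
    def total_window(self) -> float:
        return self.n_samples * self.sample_window

    def grid_stride(self) -> float:
        return self.stride if self.stride is not None else self.sample_window


def _offsets(session: DiurnalSession, spec: StrategySpec) -> np.ndarray:
    dur = session.scan_duration
    if spec.sample_window > dur:
        raise ValueError(
            f"sample window {spec.sample_window} s does not fit inside a "
            f"{dur} s scan"
        )
    s = spec.grid_stride()
    n = int(math.floor((dur - spec.sample_window) / s + 1e-9)) + 1
    return np.arange(n) * s


def _separation_ok(session: DiurnalSession, draw, min_sep_h: float) -> bool:
    for (i, oi), (j, oj) in itertools.combinations(draw, 2):
        if i == j:
            sep = abs(oi - oj) / 3600.0
        else:
            sep = abs(session.start_hours[i] - session.start_hours[j])
        if sep < min_sep_h - 1e-9:
            return False
    return True


def _scan_combos(session: DiurnalSession, spec: StrategySpec) -> list[tuple]:
    """Multisets of scan indices whose pairwise separation can be met."""
    n_scans = len(session.scans)
    combos = []
    for combo in itertools.combinations_with_replacement(range(n_scans), spec.n_samples):
        # same-scan pairs need within-scan offsets >= min_sep apart
        ok = True
        for a, b in itertools.combinations(combo, 2):
            if a == b:
                need = spec.min_separation_h * 3600.0
                if need > session.scan_duration - spec.sample_window:
                    ok = False
                    break
            elif abs(session.start_hours[a] - session.start_hours[b]) < spec.min_separation_h - 1e-9:
                ok = False
                break
        if ok:
            combos.append(combo)
    return combos


def enumerate_strategy_draws(
    session: DiurnalSession,
    spec: StrategySpec,
    seed=None,
    max_draws: int = 200_000,
) -> list[tuple]:
    """All draws (mode ``exhaustive``) or seeded random draws of window positions.

    A draw is a tuple of ``(scan_index, offset_s)`` pairs, every pair of
    samples satisfying the separation constraint and every window lying
    fully inside its scan.
    """
    offsets = _offsets(session, spec)
    combos = _scan_combos(session, spec)
    if not combos:
        raise ValueError(
            f"cannot place {spec.n_samples} samples at least "
            f"{spec.min_separation_h} h apart in session {session.session_id!r}"
        )
    if spec.mode == "random":
        rng = np.random.default_rng(seed)
        draws = []
        while len(draws) < spec.n_draws:
            combo = combos[rng.integers(len(combos))]
            draw = tuple((int(i), float(offsets[rng.integers(len(offsets))])) for i in combo)
            if _separation_ok(session, draw, spec.min_separation_h):
                draws.append(draw)
        return draws

    total = 0
    draws = []
    for combo in combos:
        for offs in itertools.product(offsets, repeat=spec.n_samples):
            draw = tuple((int(i), float(o)) for i, o in zip(combo, offs))
            if _separation_ok(session, draw, spec.min_separation_h):
                draws.append(draw)
                total += 1
                if total > max_draws:
                    raise ValueError(
                        f"exhaustive enumeration exceeds {max_draws} draws; "
                        "use mode='random' or a coarser stride"
                    )
    return draws


def _draw_counts(session: DiurnalSession, spec: StrategySpec, draws) -> np.ndarray:
    """Mean event count per sample window for each draw."""
    w = spec.sample_window
    est = np.empty(len(draws))
    for k, draw in enumerate(draws):
        c = 0
        for i, off in draw:
            t = session.scans[i].times
            c += np.searchsorted(t, off + w, side="left") - np.searchsorted(t, off, side="left")
        est[k] = c / len(draw)
    return est


def strategy_accuracy(
    session: DiurnalSession,
    spec: StrategySpec,
    threshold_pct: float = 25.0,
    seed=None,
) -> float:
    """Fraction of draws whose estimate is within the DFSM threshold of
    the session's pooled 24-h mean (per window of the strategy's size)."""
    lam = session.pooled_rate_per_min / 60.0 * spec.sample_window
    if not lam > 0:
        raise ValueError("session 24-h mean is zero; accuracy undefined")
    draws = enumerate_strategy_draws(session, spec, seed=seed)
    est = _draw_counts(session, spec, draws)
    dev = np.abs(est - lam) / lam * 100.0
    if math.isinf(threshold_pct):
        return 1.0
    return float(np.mean(dev <= threshold_pct + 1e-9))


def paired_strategy_comparison(
    session: DiurnalSession,
    multi: StrategySpec,
    single: StrategySpec,
    threshold_pct: float = 25.0,
    seed=None,
) -> float:
    """``accuracy(multi) - accuracy(single)`` on the same session.

    Both strategies must commit the same total blood volume
    (``n_samples * sample_window`` equal); a positive value means the
    spread-out strategy estimated the 24-h mean more reliably.
    """
    if not math.isclose(multi.total_window, single.total_window, rel_tol=1e-9):
        raise ValueError(
            f"strategies sample unequal total volumes: "
            f"{multi.total_window} s vs {single.total_window} s"
        )
    acc_m = strategy_accuracy(session, multi, threshold_pct, seed=seed)
    acc_s = strategy_accuracy(session, single, threshold_pct, seed=seed)
    return acc_m - acc_s
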