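"""End-to-end analysis pipeline over a directory of event-series files.

This is the library behind the ``analyze`` CLI subcommand and the
numbered analysis drivers: load scans (and 24-h sessions) from disk,
apply cohort inclusion rules, count windows at the standard equivalent
blood-sample sizes, compute detection fractions, DFSM threshold
fractions with Poisson references, variance-mean points and
zero-intercept slopes per cohort, 24-h and split-scan ratio metrics
with a KS comparison, and the sampling-strategy grid.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EventSeries, IntervalSpec
from .dispersion import (
    dfsm,
    ks_two_sample,
    maxmin_rate_ratio,
    poisson_dfsm_fraction,
    split_scan_ratio,
    variance_mean_point,
    zero_intercept_fit,
)
from .intervals import count_in_windows, detection_fraction, inclusion_filter, scan_mean
from .io import read_event_series
from .simulate import DiurnalSession
from .strategies import StrategySpec, paired_strategy_comparison, strategy_accuracy

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
SUMMARY_REQUIRED_KEYS = (
    "schema_version",
    "windows_s",
    "thresholds_pct",
    "n_scans",
    "n_sessions",
    "n_parse_errors",
    "cohorts",
    "ratios",
    "strategies",
)

#: Standard equivalent-blood-sample window lengths (seconds):
#: 24 s, 2 min, 4 min, 8 min = 20, 100, 200, 400 ul at 50 ul/min.
STANDARD_WINDOWS_S = (24.0, 120.0, 240.0, 480.0)

#: The standard strategy grid: fraction-of-PBV labels -> (n_samples,
#: window seconds).  1% of a 2-ml PBV = 20 ul = 24 s of scan time.
STANDARD_STRATEGY_GRID = {
    "1%": (1, 24.0),
    "2%": (1, 48.0),
    "two 1%": (2, 24.0),
    "4%": (1, 96.0),
    "four 1%": (4, 24.0),
    "20%": (1, 480.0),
    "80%": (1, 1920.0),
    "four 20%": (4, 480.0),
}

#: Paired comparisons: spread-out strategy vs contiguous equal volume.
STANDARD_PAIRINGS = (("two 1%", "2%"), ("four 1%", "4%"), ("four 20%", "80%"))


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    input_dir: str = "."
    output_dir: str = "results"
    windows_s: tuple = STANDARD_WINDOWS_S
    stride_s: float = 1.0
    thresholds_pct: tuple = (25.0, 50.0)
    min_rate_per_min: float = 0.5
    n_draws: int = 50
    seed: int = 0
    figures: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["windows_s"] = list(self.windows_s)
        d["thresholds_pct"] = list(self.thresholds_pct)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "windows_s" in known:
            known["windows_s"] = tuple(float(w) for w in known["windows_s"])
        if "thresholds_pct" in known:
            known["thresholds_pct"] = tuple(float(t) for t in known["thresholds_pct"])
        return cls(**known)


def load_inputs(input_dir: str | Path):
    """Load scans and sessions from a directory.

    If a ``manifest.json`` (from the fixture generator) is present it
    drives the loading and provides cohort kinds; otherwise every
    ``*.csv`` with a sidecar is read as a standalone scan of kind
    ``"unknown"``.  Returns ``(scans, sessions, n_errors)`` where
    ``scans`` is a list of ``(kind, EventSeries)``.
    """
    input_dir = Path(input_dir)
    scans: list[tuple[str, EventSeries]] = []
    sessions: list[DiurnalSession] = []
    n_errors = 0
    manifest_path = input_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for entry in manifest["entries"]:
            try:
                if entry["kind"] == "diurnal_session":
                    scan_list = [read_event_series(input_dir / p) for p in entry["paths"]]
                    sessions.append(
                        DiurnalSession(
                            tuple(scan_list),
                            tuple(entry["start_hours"]),
                            entry["label"],
                        )
                    )
                else:
                    scans.append((entry["kind"], read_event_series(input_dir / entry["paths"][0])))
            except Exception as exc:  # noqa: BLE001 - skip-and-log contract
                logger.warning("skipping %s: %s", entry.get("label"), exc)
                n_errors += 1
    else:
        for csv in sorted(input_dir.glob("*.csv")):
            try:
                scans.append(("unknown", read_event_series(csv)))
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping %s: %s", csv.name, exc)
                n_errors += 1
    return scans, sessions, n_errors


def per_scan_table(scans, config: RunConfig) -> pd.DataFrame:
    """Tidy per-scan, per-window summary rows."""
    rows = []
    for kind, series in scans:
        include_dfsm = inclusion_filter(series, "min_rate", config.min_rate_per_min)
        for w in config.windows_s:
            if w > series.duration:
                continue
            spec = IntervalSpec(window=w, mode="sliding", stride=config.stride_s)
            counts = count_in_windows(series, spec)
            lam = scan_mean(counts)
            row = {
                "label": series.label,
                "kind": kind,
                "window_s": w,
                "n_windows": counts.n_windows,
                "mean": lam,
                "detection_fraction": detection_fraction(counts),
                "included_any_detection": inclusion_filter(series, "any_detection"),
                "included_min_rate": include_dfsm,
            }
            point = variance_mean_point(counts)
            row["variance"] = point.variance
            for t in config.thresholds_pct:
                if lam > 0:
                    row[f"dfsm_le_{t:g}"] = dfsm(counts, lam).threshold_fraction(t)
                    row[f"poisson_le_{t:g}"] = poisson_dfsm_fraction(lam, t)
                else:
                    row[f"dfsm_le_{t:g}"] = math.nan
                    row[f"poisson_le_{t:g}"] = math.nan
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_slopes(per_scan: pd.DataFrame) -> pd.DataFrame:
    """Zero-intercept variance-mean slope per cohort and window size."""
    from .dispersion import VarianceMeanPoint

    rows = []
    if per_scan.empty:
        return pd.DataFrame(rows)
    for (kind, w), grp in per_scan.groupby(["kind", "window_s"]):
        pts = [
            VarianceMeanPoint(r["mean"], r["variance"], w, int(r["n_windows"]), r["label"])
            for _, r in grp.iterrows()
            if r["mean"] > 0
        ]
        if not pts:
            continue
        rows.append(
            {"kind": kind, "window_s": w, "n_scans": len(pts), "slope": zero_intercept_fit(pts)}
        )
    return pd.DataFrame(rows)


def ratio_tables(scans, sessions) -> pd.DataFrame:
    """Max/min rate ratios: per-session (24-h) and per-scan (split 15-min)."""
    rows = []
    for session in sessions:
        rows.append(
            {
                "group": "24h_session",
                "label": session.session_id,
                "ratio": maxmin_rate_ratio(session.scan_rates_per_min),
            }
        )
    for kind, series in scans:
        if series.duration >= 2100.0 and series.n_events > 0:
            rows.append(
                {"group": "35min_split", "label": series.label, "ratio": split_scan_ratio(series)}
            )
    return pd.DataFrame(rows)


def ratio_ks(ratios: pd.DataFrame) -> dict:
    """KS comparison of 24-h session ratios vs 35-min split-scan ratios."""
    if ratios.empty:
        return {}
    a = ratios.loc[(ratios.group == "24h_session") & np.isfinite(ratios.ratio), "ratio"]
    b = ratios.loc[(ratios.group == "35min_split") & np.isfinite(ratios.ratio), "ratio"]
    if len(a) == 0 or len(b) == 0:
        return {}
    d, p = ks_two_sample(a, b)
    return {"groups": ["24h_session", "35min_split"], "D": d, "p": p, "n": [len(a), len(b)]}


def strategy_tables(sessions, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy of the standard strategy grid and the paired differences."""
    acc_rows, diff_rows = [], []
    rng = np.random.SeedSequence(config.seed)
    for session, child in zip(sessions, rng.spawn(max(len(sessions), 1))):
        if session.pooled_rate_per_min <= 0:
            continue
        seeds = child.spawn(len(STANDARD_STRATEGY_GRID) + len(STANDARD_PAIRINGS))
        specs = {}
        for (name, (n, w)), s in zip(STANDARD_STRATEGY_GRID.items(), seeds):
            spec = StrategySpec(n, w, mode="random", n_draws=config.n_draws)
            specs[name] = spec
            for t in config.thresholds_pct:
                acc_rows.append(
                    {
                        "session": session.session_id,
                        "strategy": name,
                        "threshold_pct": t,
                        "accuracy": strategy_accuracy(session, spec, t, seed=s),
                    }
                )
        for (multi, single), s in zip(STANDARD_PAIRINGS, seeds[len(STANDARD_STRATEGY_GRID):]):
            diff_rows.append(
                {
                    "session": session.session_id,
                    "multi": multi,
                    "single": single,
                    "threshold_pct": 25.0,
                    "paired_difference": paired_strategy_comparison(
                        session, specs[multi], specs[single], 25.0, seed=s
                    ),
                }
            )
    return pd.DataFrame(acc_rows), pd.DataFrame(diff_rows)


def build_summary(config: RunConfig, per_scan, slopes, ratios, ks, acc, diffs, n_errors) -> dict:
    cohorts: dict = {}
    for _, r in slopes.iterrows():
        cohorts.setdefault(r["kind"], {"slopes": {}})["slopes"][f"{r['window_s']:g}"] = r["slope"]
        cohorts[r["kind"]]["n_scans"] = int(r["n_scans"])
    summary = {
        "schema_version": SCHEMA_VERSION,
        "windows_s": list(config.windows_s),
        "thresholds_pct": list(config.thresholds_pct),
        "n_scans": int(per_scan["label"].nunique()) if not per_scan.empty else 0,
        "n_sessions": int(acc["session"].nunique()) if not acc.empty else 0,
        "n_parse_errors": int(n_errors),
        "cohorts": cohorts,
        "ratios": {} if not ks else ks,
        "strategies": {
            "accuracy": acc.to_dict(orient="records"),
            "paired_differences": diffs.to_dict(orient="records"),
        },
        # paths are run-local, not part of the scientific record
        "config": {k: v for k, v in config.to_dict().items()
                   if k not in ("input_dir", "output_dir")},
    }
    return summary


def validate_summary(summary: dict) -> None:
    """Raise ``ValueError`` if the summary does not match the schema."""
    missing = [k for k in SUMMARY_REQUIRED_KEYS if k not in summary]
    if missing:
        raise ValueError(f"summary missing keys: {missing}")
    if summary["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"summary schema_version {summary['schema_version']} != {SCHEMA_VERSION}"
        )


def run_analysis(config: RunConfig) -> dict:
    """Full pipeline: load, analyze, write CSVs + summary JSON; return summary."""
    scans, sessions, n_errors = load_inputs(config.input_dir)
    if not scans and not sessions:
        raise ValueError(f"no readable event-series inputs in {config.input_dir}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_scan = per_scan_table(scans, config)
    slopes = cohort_slopes(per_scan)
    ratios = ratio_tables(scans, sessions)
    ks = ratio_ks(ratios)
    acc, diffs = strategy_tables(sessions, config)
    per_scan.to_csv(out / "per_scan.csv", index=False, float_format="%.10g")
    slopes.to_csv(out / "slopes.csv", index=False, float_format="%.10g")
    ratios.to_csv(out / "ratios.csv", index=False, float_format="%.10g")
    acc.to_csv(out / "strategy_accuracy.csv", index=False, float_format="%.10g")
    diffs.to_csv(out / "strategy_differences.csv", index=False, float_format="%.10g")
    summary = build_summary(config, per_scan, slopes, ratios, ks, acc, diffs, n_errors)
    validate_summary(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if config.figures:
        _write_figures(scans, config, out / "figures")
    if n_errors:
        logger.warning("%d input file(s) were skipped due to parse errors", n_errors)
    return summary


def _write_figures(scans, config: RunConfig, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import plots

    fig_dir.mkdir(parents=True, exist_ok=True)
    for kind, series in scans[:8]:  # a representative handful
        fig, axes = plt.subplots(1, 2, figsize=(9, 3))
        plots.raster_plot(series, axes[0])
        spec = IntervalSpec(window=config.windows_s[0], mode="sliding", stride=config.stride_s)
        counts = count_in_windows(series, spec)
        if counts.counts.max() > 0:
            plots.count_histogram_plot(counts, axes[1])
        fig.tight_layout()
        fig.savefig(fig_dir / f"{series.label or kind}.png", dpi=120)
        plt.close(fig)
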