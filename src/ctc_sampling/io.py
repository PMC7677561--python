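"""Reading and writing event-series files.

On disk an event series is a two-column CSV (``scan_id, time_s``) plus a
JSON sidecar carrying the scan duration, label and free-form acquisition
metadata.  The pair round-trips losslessly: timestamps are written with
``repr``-level precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EventSeries, validate_event_series

__all__ = ["write_event_series", "read_event_series", "sidecar_path"]

_SIDE_SUFFIX = ".meta.json"


def sidecar_path(csv_path: str | Path) -> Path:
    p = Path(csv_path)
    return p.with_suffix("").with_suffix(_SIDE_SUFFIX) if p.suffix == ".csv" else p.parent / (p.name + _SIDE_SUFFIX)


def write_event_series(series: EventSeries, csv_path: str | Path, metadata: dict | None = None) -> Path:
    """Write ``series`` to ``csv_path`` and its sidecar; return the CSV path."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    scan_id = series.label or csv_path.stem
    df = pd.DataFrame({"scan_id": scan_id, "time_s": series.times})
    df.to_csv(csv_path, index=False, float_format="%.17g")
    side = {
        "duration_s": series.duration,
        "label": series.label,
        "metadata": metadata or {},
    }
    sidecar_path(csv_path).write_text(json.dumps(side, indent=1, sort_keys=True))
    return csv_path


def read_event_series(csv_path: str | Path) -> EventSeries:
    """Load an event series written by :func:`write_event_series`."""
    csv_path = Path(csv_path)
    side = json.loads(sidecar_path(csv_path).read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    times = np.asarray(df["time_s"], dtype=float) if len(df) else np.empty(0)
    series = EventSeries(times, float(side["duration_s"]), str(side.get("label", "")))
    return validate_event_series(series)
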