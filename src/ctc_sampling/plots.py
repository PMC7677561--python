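"""Figure helpers: raster plots, count histograms with Poisson overlays,
variance-mean scatter with zero-intercept fits.

Figures are presentation artifacts; every number they show comes from
the analysis modules.
"""

from __future__ import annotations

import numpy as np

from .dispersion import poisson_reference_pmf
from .intervals import IntervalCounts, count_histogram, scan_mean

__all__ = ["raster_plot", "count_histogram_plot", "variance_mean_plot"]


def raster_plot(series, ax, **kwargs):
    """Temporal raster: one vertical line per detection event."""
    kwargs.setdefault("colors", "black")
    kwargs.setdefault("linewidths", 0.5)
    ax.vlines(series.times / 60.0, 0, 1, **kwargs)
    ax.set_xlim(0, series.duration / 60.0)
    ax.set_yticks([])
    ax.set_xlabel("time (min)")
    ax.set_title(series.label)
    return ax


def count_histogram_plot(counts: IntervalCounts, ax, poisson_overlay: bool = True):
    """Window-count histogram with the same-mean Poisson pmf overlaid."""
    hist = count_histogram(counts)
    lam = scan_mean(counts)
    ks = np.arange(max(hist) + 1)
    freq = np.array([hist.get(int(k), 0) for k in ks]) / counts.n_windows
    ax.bar(ks, freq, width=0.9, color="#7f9fc4", label="measured")
    if poisson_overlay and lam > 0:
        pmf, _ = poisson_reference_pmf(lam, int(max(hist)))
        ax.plot(ks, pmf, "k--", label=f"Poisson(λ={lam:.2f})")
    ax.axvline(lam, color="k", lw=1)
    ax.set_xlabel(f"events per {counts.spec.window:g} s window")
    ax.set_ylabel("fraction of windows")
    ax.legend(frameon=False)
    return ax


def variance_mean_plot(points, ax, slope: float | None = None):
    """Variance vs mean scatter with 1:1 line and optional fitted slope."""
    m = np.array([p.mean for p in points])
    v = np.array([p.variance for p in points])
    ax.loglog(m, v, "o", ms=4, alpha=0.7)
    lim = (min(m[m > 0].min(), v[v > 0].min()), max(m.max(), v.max()))
    xs = np.geomspace(*lim)
    ax.plot(xs, xs, "k--", lw=1, label="variance = mean")
    if slope is not None:
        ax.plot(xs, slope * xs, "r-", lw=1, label=f"fit: var = {slope:.2f} · mean")
    ax.set_xlabel("mean events per window")
    ax.set_ylabel("variance of events per window")
    ax.legend(frameon=False)
    return ax
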