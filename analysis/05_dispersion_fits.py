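#!/usr/bin/env python
"""Variance-to-mean analysis: which stream models are overdispersed?

For the three 54-stream batteries (steady, rate-doubling, merged) and
every equivalent sample size, plots variance of sliding-window counts
against the mean and fits a zero-intercept line.  Steady and merged
(superposed) streams sit on the 1:1 Poisson line; change-point streams
show slopes well above 1 — the overdispersion signature of a mean cell
number that moves during the scan.  Writes the per-scan points, the
slope table and a four-panel figure.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ctc_sampling import IntervalSpec, count_in_windows, variance_mean_point, zero_intercept_fit
from ctc_sampling.simulate import battery_specs, realize

WINDOWS_S = (24.0, 120.0, 240.0, 480.0)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--figures", action="store_true")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    specs = [s for s in battery_specs() if s.kind != "diurnal_session"]
    children = np.random.SeedSequence(args.seed).spawn(len(specs))
    points = []
    for spec, child in zip(specs, children):
        series = realize(spec, np.random.default_rng(child))
        for w in WINDOWS_S:
            p = variance_mean_point(count_in_windows(series, IntervalSpec(w, stride=1.0)))
            points.append({"kind": spec.kind, "window_s": w, "mean": p.mean,
                           "variance": p.variance, "n_windows": p.n_windows})
    df = pd.DataFrame(points)
    df.to_csv(args.outdir / "variance_mean_points.csv", index=False, float_format="%.6g")

    from ctc_sampling import VarianceMeanPoint

    slope_rows = []
    for (kind, w), grp in df.groupby(["kind", "window_s"]):
        pts = [VarianceMeanPoint(r.mean, r.variance, w, int(r.n_windows))
               for r in grp.itertuples()]
        slope_rows.append({"kind": kind, "window_s": w, "slope": zero_intercept_fit(pts)})
    slopes = pd.DataFrame(slope_rows).pivot(index="kind", columns="window_s", values="slope")
    slopes.to_csv(args.outdir / "variance_mean_slopes.csv", float_format="%.4f")
    print("zero-intercept variance-mean slopes (1 = Poisson equidispersion):")
    print(slopes.to_string(float_format=lambda v: f"{v:.3f}"))
    print("\nsteady and merged batteries stay near 1; "
          "rate-doubling streams are clearly overdispersed at every sample size")

    if args.figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from ctc_sampling.plots import variance_mean_plot

        fig, axes = plt.subplots(1, len(WINDOWS_S), figsize=(16, 4))
        for ax, w in zip(axes, WINDOWS_S):
            grp = df[(df.window_s == w) & (df.kind == "changepoint")]
            pts = [VarianceMeanPoint(r.mean, r.variance, w, int(r.n_windows))
                   for r in grp.itertuples()]
            variance_mean_plot(pts, ax, slope=zero_intercept_fit(pts))
            ax.set_title(f"{w:g} s windows")
        fig.tight_layout()
        fig.savefig(args.outdir / "variance_mean_changepoint.png", dpi=120)
        print(f"figure written to {args.outdir}/variance_mean_changepoint.png")


if __name__ == "__main__":
    main()
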