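#!/usr/bin/env python
"""Pair-correlation analysis of the preset ensemble.

For 20 replicate preset scenes: estimates the translation-corrected PCF of
(a) bead-cluster centroids, whose dominant peak above 40 nm recovers the
~85 nm inter-bead repeat, and (b) raw label positions, whose short-range
peak reflects multiple labels per bead region.  Writes the seed-0 curves
and a per-seed peak table to results/, plus a two-panel figure.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import goldpcf as gp

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

R_GRID = np.arange(5.0, 200.25, 0.5)

rows = []
for seed in range(20):
    scene = gp.simulate_scene(gp.SimulationConfig(), seed=seed)
    win = scene.config.window
    labels = scene.labels[["x_nm", "y_nm"]].to_numpy()
    clusters = gp.cluster_labels(labels, cutoff=25.0)

    cent = gp.estimate_pcf(clusters.cluster_centroids, win, R_GRID, 5.0)
    lab = gp.estimate_pcf(labels, win, R_GRID, 5.0)
    p_long = gp.find_pcf_peaks(cent, r_min=40.0)
    p_short = gp.find_pcf_peaks(lab, r_min=5.0, r_max=40.0)
    rows.append(
        {
            "seed": seed,
            "long_peak_nm": p_long[0].r_peak if p_long else np.nan,
            "long_peak_g": p_long[0].g_peak if p_long else np.nan,
            "short_peak_nm": p_short[0].r_peak if p_short else np.nan,
            "short_peak_g": p_short[0].g_peak if p_short else np.nan,
        }
    )
    if seed == 0:
        pd.DataFrame({"r_nm": R_GRID, "g_centroids": cent.g, "g_labels": lab.g}).to_csv(
            OUT / "pcf_curves_seed0.csv", index=False
        )
        curves0 = (cent, lab)

table = pd.DataFrame(rows)
table.to_csv(OUT / "pcf_peaks_by_seed.csv", index=False)
print(table.describe().loc[["50%", "min", "max"]].to_string())
print(
    f"\nMedian inter-cluster peak: {table.long_peak_nm.median():.1f} nm "
    "(generator repeat 85 nm); median short-range peak: "
    f"{table.short_peak_nm.median():.1f} nm (labels on a 9 nm shell; the "
    "kernel-smoothed estimate sits below the 18 nm chord mode, see "
    "docs/methods.md)."
)

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(1, 2, figsize=(9, 3.4))
cent, lab = curves0
axes[0].plot(cent.r_grid, cent.g, lw=1.2)
axes[0].axvline(85, color="crimson", ls=":", lw=1)
axes[0].set(xlabel="r (nm)", ylabel="g(r)", title="cluster centroids")
axes[1].plot(lab.r_grid, lab.g, lw=1.2)
axes[1].axvline(18, color="crimson", ls=":", lw=1)
axes[1].set(xlabel="r (nm)", ylabel="g(r)", title="raw labels", xlim=(5, 60))
for ax in axes:
    ax.axhline(1, color="gray", lw=0.8, ls="--")
fig.tight_layout()
fig.savefig(OUT / "pcf_seed0.png", dpi=150)
print(f"wrote {OUT/'pcf_peaks_by_seed.csv'} and {OUT/'pcf_seed0.png'}")
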