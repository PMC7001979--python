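#!/usr/bin/env python
"""Along-fibril spacing of bead clusters on the preset ensemble.

Projects recovered cluster centroids onto the ground-truth fibril
polylines, pools successive arc-length spacings over 20 replicate scenes,
and reports the histogram mode (5 nm bins) together with the arc-vs-chord
contrast for curved fibrils.  Writes the pooled spacings and a summary to
results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import goldpcf as gp

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

pooled = []
for seed in range(20):
    scene = gp.simulate_scene(gp.SimulationConfig(), seed=seed)
    clusters = gp.cluster_labels(
        scene.labels[["x_nm", "y_nm"]].to_numpy(), cutoff=25.0
    )
    for fid, fib in enumerate(scene.fibrils):
        try:
            stats = gp.successive_spacings(clusters, fib.polyline)
        except ValueError:
            continue
        pooled.append(
            pd.DataFrame(
                {
                    "seed": seed,
                    "fibril_id": fid,
                    "spacing_nm": stats.spacings,
                    "chord_nm": stats.chord_distances,
                }
            )
        )

df = pd.concat(pooled, ignore_index=True)
df.to_csv(OUT / "spacings_pooled.csv", index=False)

mode = gp.spacing_mode(df["spacing_nm"].to_numpy(), bin_width=5.0)
summary = {
    "n_spacings": int(len(df)),
    "spacing_mode_nm": mode,
    "spacing_median_nm": float(df["spacing_nm"].median()),
    "spacing_sd_nm": float(df["spacing_nm"].std()),
    "chord_median_nm": float(df["chord_nm"].median()),
    "fraction_chord_below_arc": float((df["chord_nm"] < df["spacing_nm"]).mean()),
    "bin_width_nm": 5.0,
}
with open(OUT / "spacing_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print(json.dumps(summary, indent=2))
print(
    f"\nMost common successive inter-cluster distance along fibrils: "
    f"{mode:.0f} nm (generator repeat 85 nm, jitter sd 4 nm). Chord "
    "distances sit slightly below arc-length spacings on curved fibrils."
)
print(f"wrote {OUT/'spacings_pooled.csv'} and {OUT/'spacing_summary.json'}")
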