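# goldpcf

Quantitative spatial analysis of immunogold labels in cryo-STEM tomograms
of extracellular matrix, built around the beaded-microfibril geometry of
collagen VI.

Collagen VI assembles into "beads-on-a-string" microfibrils: globular bead
regions joined by triple-helical segments at a regular repeat (~85 nm in
situ). After immunogold labeling, each bead region carries several 6 nm
gold particles, and single-axis tomography (tilt range ±60°) leaves a
missing wedge in Fourier space that smears each gold bead along the beam
axis, so one physical bead can appear as several detections in successive
slices. `goldpcf` implements the measurement chain that turns such volumes
into repeat-distance statistics, and a ground-truthed synthetic generator
so every stage is testable without microscope data:

- **`goldpcf.simulate`** — synthetic scenes: curved fibrils (persistent
  random walk) carrying bead clusters at a jittered 85 nm repeat, three
  labels per bead on a 9 nm shell, Poisson background, and rendering into
  3D volumes with missing-wedge elongation.
- **`goldpcf.detect`** — gold-bead candidates as local brightness maxima in
  2D slices at the known bead scale, with per-slice auto-thresholding.
- **`goldpcf.merge`** — nearest-neighbor linking of detections in
  successive slices closer than the bead diameter; connected components
  collapse to intensity-weighted 3D centroids ("centers of mass").
- **`goldpcf.pcf`** — kernel-smoothed 2D pair correlation function with
  translation (set-covariance) edge correction:

  ĝ(r) = 1/(2πr λ̂²) · Σ_{i≠j} k_h(r − d_ij) / A(Δx_ij, Δy_ij),

  with λ̂ = n/|W|, Epanechnikov kernel k_h (bandwidth h = 5 nm by
  default), and A(Δ) = (a−|Δx|)(b−|Δy|) the area over which a pair with
  displacement Δ could have been observed in the a×b window. g ≡ 1 under
  complete spatial randomness; peaks flag preferred distances. Includes a
  brute-force double-loop oracle and a Monte-Carlo CSR envelope test.
- **`goldpcf.fibril`** — single-linkage grouping of labels into bead
  clusters, arc-length spacings of successive clusters along a fibril
  polyline, and the triple-helix span helper (n_residues/3 × rise).

## Worked example

Run the full synthetic pipeline (simulate → render → detect → merge →
select flat subset → PCF → peaks → spacings) on a 1.5 × 1.5 µm field:

```sh
goldpcf run-all --seed 3 --out-dir out/
```

prints (abridged):

```json
{
  "n_labels_planted": 260,
  "n_slice_peaks": 1460,
  "n_merged_centroids": 209,
  "n_recovered_clusters": 78,
  "n_planted_clusters": 84,
  "pcf_short_range_peak_nm": 15.0,
  "pcf_long_range_peak_nm": 82.0,
  "spacing_mode_nm": 80.0,
  "truth_repeat_nm": 85.0
}
```

Reading this: 260 planted gold labels became 1460 per-slice detections
(the missing wedge duplicates each bead across ~5–7 slices), which merged
back to 209 centroids (labels of one bead closer than the 6 nm merge
radius fuse, as in real data). The pair correlation of the cluster-level
pattern peaks at 82 nm — the bead repeat — and the label-level pattern
adds a short-range peak near 15 nm from multiple labels on one bead. The
along-fibril spacing mode (80 nm, 5 nm bins) agrees with the 85 nm truth
to within one histogram bin. Individual stages are available as
`goldpcf simulate|detect|merge|pcf|fibril-stats` on plain CSV/MRC/JSON
files; `analysis/01…04_*.py` run the same computations as scripted
analyses over a 20-scene ensemble and write tables under `results/`.

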