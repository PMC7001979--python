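# Methods

## The measurement problem

Immunogold labeling marks a target protein with colloidal gold (6 nm
here), which images as a high-contrast point-like feature in cryo-STEM
tomograms. Two obstacles stand between raw volumes and distance
statistics:

1. **Missing-wedge duplication.** Single-axis tilting over ±60° leaves a
   wedge of Fourier space unsampled, elongating each bead's image along
   the beam axis; the elongated image can break into several local maxima
   in successive slices, so naive detection overcounts beads.
2. **Bounded-window bias.** Pair-distance statistics computed in a finite
   field of view undercount large separations (both endpoints must fall
   inside the window), biasing density estimates down at large r unless
   edge-corrected.

The package addresses (1) by detecting in 2D slices and merging along the
wedge axis, and (2) with the translation (set-covariance) edge correction
of the pair correlation function.

## Pipeline stages

**Slice detection.** Slices are taken perpendicular to the wedge axis.
A candidate is a strict intensity maximum within a square neighborhood of
side ≈ bead_diameter/voxel_size (rounded up to odd voxels) above a
threshold; `auto` thresholding uses per-slice mean + k·sd (k = 5 default,
since tomogram intensity statistics vary slice to slice). Plateaus of
equal value count once (the plateau must strictly dominate its border;
its lexicographically smallest index represents it), so constant regions
yield nothing. Dark-polarity volumes (bright-field) are inverted first.
Coordinates follow the voxel-center convention, physical = (index + 0.5)
× voxel_size, with 0-based indices; the default voxel size 2.4 nm
corresponds to 1.2 nm/pixel acquisition binned by two.

**Wedge merging.** Each detection links to its single nearest neighbor in
the next slice (strictly consecutive by default; a gap parameter exists)
when their in-plane separation is below the bead diameter (6 nm default;
exposed, since "bead size" could also be read as the point-spread
footprint). Distance ties break toward lower x, then y, keeping the
linking deterministic. Connected components of the link graph become one
centroid: the intensity-weighted mean position (mass = intensity). A
z-band filter then selects the subpopulation lying flat against the
carbon support (e.g. the distal-side labels) and projects it to 2D;
identifying the carbon plane is left to the user, as in practice it is
read off the tomogram directly.

**Pair correlation.** For n points in a rectangular a×b window W,

    ĝ(r) = 1/(2πr λ̂²) · Σ_{i≠j} k_h(r − d_ij) / A(Δx_ij, Δy_ij),
    λ̂ = n/|W|,   A(Δ) = (a − |Δx|)(b − |Δy|),

with the Epanechnikov kernel k_h(u) = (3/4h)(1 − (u/h)²) on |u| ≤ h
(Gaussian and box kernels are options; Epanechnikov is the point-pattern
standard). A(Δ) is the area of W ∩ W_Δ — the region where a pair with
displacement Δ could have been observed — which removes boundary bias
exactly for rectangular windows; non-rectangular windows are refused
rather than approximated. Pairs whose overlap area falls below 1% of |W|
are excluded (logged) to cap single-pair weights. The default r grid runs
from max(h, 5) nm to a quarter of the shorter window side in 2 nm steps;
the estimator variance grows quickly beyond that. The biased λ̂² = (n/|W|)²
denominator is the default, with the unbiased n(n−1)/|W|² variant as a
switch. The grid must start at or above h to stay clear of the 1/r
singularity, and bandwidth 5 nm is the default smoothing scale throughout.
A brute-force double-loop implementation of the same estimator (capped at
500 points) serves as the oracle in tests, and a periodic (torus-metric)
variant cross-validates the edge correction on CSR patterns.

**Peak calling.** Local maxima of ĝ with prominence ≥ 0.2 (peak height
minus the higher flanking minimum), sorted by prominence. The pipeline
report additionally requires a peak to clear a pointwise Monte-Carlo CSR
envelope (maximum ĝ over 39 binomial patterns of the same n, pointwise
level 1/40): sparse patterns produce spurious kernel bumps from a handful
of chance pairs, with large nominal prominence because the flanking
baseline is near zero, and the envelope is the standard significance
guard against reporting them.

**Along-fibril spacings.** Labels are grouped into bead clusters by
single linkage at a 25 nm cutoff — between the ~18 nm intra-cluster label
scale and the ~85 nm inter-bead repeat — and centroids within 30 nm of a
fibril polyline are projected to arc-length positions; successive
differences are the spacings. Fibril paths are explicit inputs (synthetic
ground truth, or a user-traced polyline); automatic fibril tracing is out
of scope. The mode is the center of the fullest 5 nm histogram bin, ties
toward smaller r, with bin edges at (k − ½)·width so centers fall on
multiples of the bin width — a symmetric distribution centered on a round
repeat value then maps onto a single bin instead of splitting across an
edge. Chord (straight-line) distances between the same successive
clusters are reported alongside; for curved fibrils chord < arc, the
circular-arc relation being chord = 2R sin(s/2R).

**Triple-helix span.** span = (n_residues/3) × rise_per_triplet. With 335
residues per strand and 0.87 nm per Gly-X-Y triplet this gives 97.15 nm,
a little above the ~85 nm in-situ repeat — consistent with supercoiling
of the assembled microfibril shortening the axial span. The function
returns the exact arithmetic.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not image formation. Defaults (the "collagen-VI preset") are: 4 × 4 µm
window, 50 fibrils of 1 µm length (typical uninterrupted fibril length),
persistent random walk with 10 nm steps and ≤10° turn per step — gently
curved paths whose 6-bead segments arc well below the ~120° observed for
strongly curved fibrils (tested property) — bead repeat 85 nm with 4 nm
Gaussian jitter, first bead inset half a repeat from the fibril start
(fixes the end-inclusion convention), 3 labels per bead at a fixed 9 nm
offset radius with uniform direction, background 5 labels/µm², bead
diameter 6 nm. The walk reflects off window edges so arc length is
preserved and all labels stay inside the observation window; shell labels
pushed outside by an edge-adjacent bead are dropped, as for a hard
detector field of view. The label-offset distribution (antibody + gold
geometry) is not known; the fixed-radius shell is a modeling choice whose
2D chord-length distribution has its mode at twice the shell radius
(18 nm), matching the observed short-range pair-distance scale by
construction.

Rendering places each label as a unit Gaussian blob (σ = 2.5 nm in-plane,
FWHM ≈ the bead diameter) stretched by an elongation factor (default 2)
along the wedge axis, plus optional Gaussian noise, in bright- or
dark-label polarity. This reproduces the elongation/duplication
phenomenon the merge stage must undo; it is not a tilt-projection or
CTF-accurate simulator, and passing tests on it demonstrate correctness
of the analysis chain, not robustness to reconstruction artifacts,
contrast variation, or crowded non-fibril features of real tomograms.
Every stochastic operation takes an explicit seed or Generator; given
(config, seed) all outputs are bit-reproducible.

## Known estimator biases and numerical choices

- **Short-range peak location.** For labels on a ρ = 9 nm shell the
  pair-distance density is one-sidedly singular at 2ρ = 18 nm (chords
  cannot exceed the diameter). Smoothing with h = 5 nm spreads that edge
  mass symmetrically while the 1/(2πr) factor weights the left side up,
  so the interior local maximum of ĝ sits near 14.5 nm — about 3.5 nm
  below the raw chord mode. Independent quadrature of the smoothed
  density confirms 14.5 nm; the pipeline measures 14–15 nm. The raw
  pairwise-distance histogram mode remains at 17–18 nm (tested). Reported
  peak locations should therefore be read as smoothed-estimate locations,
  biased left wherever the underlying density is strongly asymmetric.
- **Inter-cluster peak.** Cluster centroids inherit shot noise from
  averaging 3 shell labels, and curved fibrils make straight-line
  distances slightly shorter than the arc repeat, so the centroid-level
  PCF peaks at ~83–85 nm for an 85 nm generator repeat.
- **Peak-location resolution.** The acceptance and analysis scripts use a
  0.5 nm r-grid step so reported peak locations are not
  quantization-limited (the library default step is 2 nm for generic
  curves).
- **Merging conventions.** "Successive slices" means strictly consecutive
  (gap 0); nearest-neighbor-only linking rather than radius-linking all
  pairs; both follow the two-step slice-then-merge design. Chains
  spanning many slices collapse to a single centroid (components are
  maximal). Merging is idempotent on its own output when no consecutive
  slices coincide.
- **Degenerate inputs.** Constant slices yield no detections; empty
  z-band selections warn rather than fail; clustering of an empty point
  set returns an empty assignment; PCF estimation requires ≥ 2 points, a
  grid within the window's usable range, and refuses non-rectangular
  windows.

## Problem sizes

The test suite and acceptance script run 20-replicate ensembles of the
default 4 × 4 µm preset (~1 900 labels, ~600 clusters per scene),
256³-voxel rendered volumes for detection/merge recovery, 500-point
patterns against the brute-force PCF oracle, and ~2 000-point CSR
patterns for calibration; the end-to-end rendered pipeline uses a
1.5 × 1.5 µm field at the same fibril density, chosen so the rendered
volume (64 × 625 × 625 voxels at 2.4 nm) stays comfortably in memory.
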