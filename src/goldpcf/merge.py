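"""Merging of missing-wedge duplicate detections into 3D centroids.

Single-axis tomography leaves a wedge of Fourier space unsampled, so a
point-like gold bead is smeared along the beam axis and its image can break
into several local maxima in successive slices.  Detections in consecutive
slices whose in-plane separation is below the bead size are therefore taken
to be the same bead: each detection is linked to its single nearest neighbor
in the next slice when that neighbor lies closer than the bead diameter, and
connected components of the resulting graph collapse to one intensity-
weighted centroid ("center of mass", mass = intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .detect import SlicePeaks, peaks_to_nm

CENTROID_COLUMNS = [
    "x_nm",
    "y_nm",
    "z_nm",
    "total_intensity",
    "n_member_peaks",
    "slice_min",
    "slice_max",
]


@dataclass
class MergedCentroids:
    centroids: pd.DataFrame  # columns CENTROID_COLUMNS

    def __len__(self) -> int:
        return len(self.centroids)


def _nearest_in_next(
    xy_s: np.ndarray, xy_t: np.ndarray, threshold: float
) -> np.ndarray:
    """Index in ``xy_t`` of each ``xy_s`` point's nearest neighbor (or -1).

    Ties on distance are broken toward lower x, then lower y, so the linking
    is deterministic on symmetric inputs.
    """
    out = np.full(len(xy_s), -1, dtype=int)
    if len(xy_t) == 0:
        return out
    # candidate ordering implements the tie-break: sort targets by (x, y)
    order = np.lexsort((xy_t[:, 1], xy_t[:, 0]))
    tgt = xy_t[order]
    for i, p in enumerate(xy_s):
        d2 = np.sum((tgt - p) ** 2, axis=1)
        j = int(np.argmin(d2))  # argmin returns the first, i.e. lowest (x, y)
        if d2[j] < threshold**2:
            out[i] = order[j]
    return out


def merge_along_wedge(
    peaks: SlicePeaks,
    bead_diameter: float | None = None,
    voxel_size: float | None = None,
    gap: int = 0,
) -> MergedCentroids:
    """Merge per-slice detections along the wedge axis into 3D centroids.

    ``gap`` is the number of empty slices tolerated between linked
    detections; the default 0 links strictly consecutive slices.
    """
    bead = peaks.bead_diameter_nm if bead_diameter is None else bead_diameter
    vs = peaks.voxel_size if voxel_size is None else voxel_size
    if not (bead > 0 and vs > 0):
        raise ValueError("bead_diameter and voxel_size must be > 0")
    df = peaks.peaks
    if (df["intensity"] < 0).any():
        raise ValueError("negative peak intensities")
    if not df["slice_index"].is_monotonic_increasing:
        warnings.warn("peaks were not sorted by slice; sorting internally")
        df = df.sort_values(["slice_index", "y_vox", "x_vox"], kind="stable")
        df = df.reset_index(drop=True)

    n = len(df)
    if n == 0:
        return MergedCentroids(pd.DataFrame(columns=CENTROID_COLUMNS))

    xy = df[["x_vox", "y_vox"]].to_numpy(dtype=float) * vs
    slices = df["slice_index"].to_numpy()
    by_slice = {s: np.flatnonzero(slices == s) for s in np.unique(slices)}

    rows, cols = [], []
    for s, idx_s in by_slice.items():
        for dz in range(1, gap + 2):
            idx_t = by_slice.get(s + dz)
            if idx_t is None:
                continue
            nn = _nearest_in_next(xy[idx_s], xy[idx_t], bead)
            hit = nn >= 0
            rows.extend(idx_s[hit])
            cols.extend(idx_t[nn[hit]])

    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)

    nm = peaks_to_nm(peaks)
    if len(nm) != n:  # peaks were re-sorted above
        nm = pd.DataFrame(
            {
                "x_nm": (df["x_vox"] + 0.5) * vs,
                "y_nm": (df["y_vox"] + 0.5) * vs,
                "z_nm": (df["slice_index"] + 0.5) * vs,
                "intensity": df["intensity"],
            }
        )
    w = df["intensity"].to_numpy(dtype=float)
    # guard against all-zero weights within a component
    records = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        wm = w[members]
        if wm.sum() <= 0:
            wm = np.ones(len(members))
        wm = wm / wm.sum()
        records.append(
            (
                float(nm["x_nm"].to_numpy()[members] @ wm),
                float(nm["y_nm"].to_numpy()[members] @ wm),
                float(nm["z_nm"].to_numpy()[members] @ wm),
                float(w[members].sum()),
                int(len(members)),
                int(slices[members].min()),
                int(slices[members].max()),
            )
        )
    out = pd.DataFrame(records, columns=CENTROID_COLUMNS)
    out = out.sort_values(["z_nm", "y_nm", "x_nm"], kind="stable").reset_index(
        drop=True
    )
    return MergedCentroids(out)


def select_flat_subset(
    centroids: MergedCentroids, z_band: tuple[float, float]
) -> pd.DataFrame:
    """Project centroids within a z band to 2D (x_nm, y_nm).

    Used to isolate the labels lying flat against the carbon support (e.g.
    the distal-side population), which can then be analyzed as a 2D point
    pattern.  The band is in nm relative to the volume origin; identifying
    the carbon plane is up to the caller.
    """
    z_lo, z_hi = z_band
    if not z_lo < z_hi:
        raise ValueError(f"invalid z band: ({z_lo}, {z_hi})")
    df = centroids.centroids
    sel = df[(df["z_nm"] >= z_lo) & (df["z_nm"] <= z_hi)]
    if len(sel) == 0:
        warnings.warn("z band selected no centroids")
    return sel[["x_nm", "y_nm"]].reset_index(drop=True)
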