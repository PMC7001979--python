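"""Gold-bead candidate detection in 2D slices of a tomogram.

Detection works slice by slice perpendicular to the missing-wedge (beam)
axis: gold beads appear as local brightness maxima at the known bead scale
(6 nm colloidal gold by default).  A bead elongated by the missing wedge
shows up as maxima in several successive slices; merging those is the job
of :mod:`goldpcf.merge`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import TomogramVolume

PEAK_COLUMNS = ["slice_index", "y_vox", "x_vox", "intensity"]


@dataclass
class SlicePeaks:
    """Per-slice 2D detections (voxel coordinates within each slice)."""

    peaks: pd.DataFrame  # columns PEAK_COLUMNS
    bead_diameter_nm: float
    voxel_size: float
    wedge_axis: int = 0

    def __len__(self) -> int:
        return len(self.peaks)


def _slice_peaks_2d(img: np.ndarray, size: int, threshold: float) -> list[tuple]:
    """Regional maxima of one slice above threshold.

    A point qualifies if it is strictly greater than everything else in a
    size x size square around it.  Plateaus of equal value count once: the
    plateau must dominate its border strictly, and the lexicographically
    smallest index represents it.  A constant slice therefore yields nothing.
    """
    neigh_max = ndimage.maximum_filter(img, size=size, mode="nearest")
    footprint = np.ones((size, size), dtype=bool)
    footprint[size // 2, size // 2] = False
    excl_max = ndimage.maximum_filter(img, footprint=footprint, mode="nearest")

    strict = (img > excl_max) & (img > threshold)
    out = [(int(r), int(c), float(img[r, c])) for r, c in zip(*np.nonzero(strict))]

    plateau = (img == neigh_max) & (img == excl_max) & (img > threshold)
    if plateau.any():
        lab, n = ndimage.label(plateau)
        for comp_id in range(1, n + 1):
            mask = lab == comp_id
            border = ndimage.binary_dilation(mask, iterations=size // 2) & ~mask
            if not border.any():
                continue  # plateau fills the slice: no strict dominance
            val = img[mask][0]
            if val > img[border].max():
                rr, cc = np.nonzero(mask)
                order = np.lexsort((cc, rr))
                out.append((int(rr[order[0]]), int(cc[order[0]]), float(val)))
    return out


def detect_slice_peaks(
    volume: TomogramVolume,
    bead_diameter: float = 6.0,
    threshold: float | str = "auto",
    auto_k: float = 5.0,
) -> SlicePeaks:
    """Find bead candidates as neighborhood maxima per slice.

    Parameters
    ----------
    bead_diameter : nm; sets the square neighborhood (side rounded up to an
        odd number of voxels) within which a detection must be the maximum.
    threshold : absolute intensity, or ``"auto"`` for per-slice
        mean + auto_k * sd (dark-polarity volumes are inverted first, so an
        absolute threshold refers to the inverted intensities).
    """
    if volume.grid.size == 0:
        raise ValueError("empty volume")
    vs = volume.voxel_size
    if bead_diameter < vs:
        raise ValueError(
            f"bead_diameter {bead_diameter} nm is below one voxel ({vs} nm); "
            "resample the volume or adjust the diameter"
        )
    size = int(np.ceil(bead_diameter / vs))
    if size % 2 == 0:
        size += 1

    data = np.moveaxis(volume.grid, volume.wedge_axis, 0)
    if volume.polarity == "dark":
        data = -data

    records = []
    excl2 = (size // 2) ** 2
    for s in range(data.shape[0]):
        img = np.asarray(data[s], dtype=float)
        thr = (
            img.mean() + auto_k * img.std() if threshold == "auto" else float(threshold)
        )
        found = _slice_peaks_2d(img, size, thr)
        # enforce the exclusion radius among same-slice detections
        found.sort(key=lambda t: (-t[2], t[0], t[1]))
        kept: list[tuple] = []
        for r, c, v in found:
            if all((r - kr) ** 2 + (c - kc) ** 2 > excl2 for kr, kc, _ in kept):
                kept.append((r, c, v))
        records.extend((s, r, c, v) for r, c, v in kept)

    peaks = pd.DataFrame(records, columns=PEAK_COLUMNS)
    peaks = peaks.sort_values(
        ["slice_index", "y_vox", "x_vox"], kind="stable"
    ).reset_index(drop=True)
    return SlicePeaks(
        peaks=peaks,
        bead_diameter_nm=bead_diameter,
        voxel_size=vs,
        wedge_axis=volume.wedge_axis,
    )


def peaks_to_nm(peaks: SlicePeaks, volume: TomogramVolume | None = None) -> pd.DataFrame:
    """Convert slice/voxel detections to physical nm coordinates.

    Voxel-center convention: physical = (index + 0.5) * voxel_size, 0-based
    indices.  The slice index runs along the wedge axis and becomes z.
    """
    vs = volume.voxel_size if volume is not None else peaks.voxel_size
    if not (vs and vs > 0):
        raise ValueError("voxel size unavailable")
    df = peaks.peaks
    return pd.DataFrame(
        {
            "x_nm": (df["x_vox"] + 0.5) * vs,
            "y_nm": (df["y_vox"] + 0.5) * vs,
            "z_nm": (df["slice_index"] + 0.5) * vs,
            "intensity": df["intensity"],
        }
    )


def peaks_table_nm(peaks: SlicePeaks) -> pd.DataFrame:
    """Combined voxel + nm table, as written by the CLI."""
    nm = peaks_to_nm(peaks)
    out = peaks.peaks.copy()
    for col in ("x_nm", "y_nm", "z_nm"):
        out[col] = nm[col]
    return out
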