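"""Tomographic volume container and MRC map I/O (via gemmi).

Axis order is (z, y, x) with z conventionally the beam / missing-wedge axis.
Voxel sizes are stored in nm; MRC headers record the cell in angstroms
(1 nm = 10 A), so files interoperate with standard map viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np


@dataclass
class TomogramVolume:
    """A 3D intensity grid with physical voxel size and wedge axis.

    ``polarity`` says whether gold labels are brighter ('bright', e.g.
    dark-field STEM) or darker ('dark', bright-field) than background.
    """

    grid: np.ndarray
    voxel_size: float
    wedge_axis: int = 0
    polarity: str = "bright"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if self.grid.size == 0:
            raise ValueError("grid is empty")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        if not np.isfinite(self.grid).all():
            raise ValueError("grid contains non-finite values")
        if self.wedge_axis not in (0, 1, 2):
            raise ValueError("wedge_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def write_mrc(volume: TomogramVolume, path) -> None:
    """Write a 32-bit float MRC map; voxel size goes into the cell header."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.grid, dtype=np.float32))
    a = volume.voxel_size * 10.0  # nm -> A
    s = volume.grid.shape
    m.grid.unit_cell = gemmi.UnitCell(s[0] * a, s[1] * a, s[2] * a, 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path, wedge_axis: int = 0, polarity: str = "bright") -> TomogramVolume:
    """Read an MRC map; voxel size is recovered from the header cell (A -> nm)."""
    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    spacings = np.array([cell.a, cell.b, cell.c]) / np.array(grid.shape)
    if not np.allclose(spacings, spacings[0], rtol=1e-3):
        raise ValueError(f"anisotropic voxel sizes not supported: {spacings} A")
    return TomogramVolume(
        grid=grid,
        voxel_size=float(spacings[0]) / 10.0,
        wedge_axis=wedge_axis,
        polarity=polarity,
    )
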