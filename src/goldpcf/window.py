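"""Rectangular observation windows for 2D point patterns.

All coordinates throughout the package are physical lengths in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Window2D:
    """Axis-aligned rectangular observation window, bounds in nm."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.x_max, self.y_min, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("window bounds must be finite")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: x [{self.x_min}, {self.x_max}], "
                f"y [{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) lying inside the closed window."""
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Window2D":
        return cls(d["x_min"], d["x_max"], d["y_min"], d["y_max"])
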