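"""Discretized rectangular state space (habitat mask) for SCR integration.

The mask is the detector bounding box expanded by a buffer width on every
side and gridded at a fixed spacing; activity centres are integrated (or
sampled) over cell centres with exact area bookkeeping
(``total_area = n_cells * cell_area``).  A buffer of at least 3 sigma of
the half-normal detection function is required for unbiased density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from opencamscr.capture_data import DetectorArray


@dataclass
class StateSpaceMask:
    cell_centres: np.ndarray      # (n_cells, 2), metres
    spacing: float                # metres
    buffer_width: float           # metres
    bounds: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    def __post_init__(self):
        self.cell_centres = np.asarray(self.cell_centres, dtype=float)
        if self.cell_centres.ndim != 2 or self.cell_centres.shape[1] != 2:
            raise ValueError("cell_centres must be (n, 2)")
        xmin, xmax, ymin, ymax = self.bounds
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("mask bounds must enclose positive area")

    @property
    def n_cells(self) -> int:
        return self.cell_centres.shape[0]

    @property
    def cell_area(self) -> float:
        """Cell area in km^2."""
        return (self.spacing / 1000.0) ** 2

    @property
    def total_area(self) -> float:
        """Total mask area in km^2 (= n_cells * cell_area)."""
        return self.n_cells * self.cell_area

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        xmin, xmax, ymin, ymax = self.bounds
        return (
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
            & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cell_centres, columns=["x_m", "y_m"])

    def write(self, path) -> None:
        """CSV export of cell centres with a header declaring spacing/area."""
        with open(path, "w") as fh:
            fh.write(f"# spacing_m={self.spacing} cell_area_km2={self.cell_area} "
                     f"total_area_km2={self.total_area}\n")
            self.to_frame().to_csv(fh, index=False)


def build_mask(
    array: DetectorArray,
    buffer_width: float = 18_000.0,
    spacing: float = 1_000.0,
) -> StateSpaceMask:
    """Grid the buffered detector bounding box into a habitat mask.

    The rectangle is the detector bounding box expanded by ``buffer_width``
    (m) on every side; cell centres are placed on a lattice of pitch
    ``spacing`` starting at the rectangle corner, so a single detector with
    buffer == spacing yields a 3 x 3 mask.
    """
    if buffer_width <= 0:
        raise ValueError("buffer_width must be > 0")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if spacing > buffer_width:
        warnings.warn(
            "mask spacing exceeds buffer width; the mask will be coarse",
            stacklevel=2,
        )
    bxmin, bxmax, bymin, bymax = array.bounding_box()
    xmin, xmax = bxmin - buffer_width, bxmax + buffer_width
    ymin, ymax = bymin - buffer_width, bymax + buffer_width
    nx = int(np.floor((xmax - xmin) / spacing + 1e-9)) + 1
    ny = int(np.floor((ymax - ymin) / spacing + 1e-9)) + 1
    gx = xmin + spacing * np.arange(nx)
    gy = ymin + spacing * np.arange(ny)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    centres = np.column_stack([xx.ravel(), yy.ravel()])
    return StateSpaceMask(
        cell_centres=centres, spacing=spacing, buffer_width=buffer_width,
        bounds=(xmin, xmax, ymin, ymax),
    )


def check_buffer_rule(mask: StateSpaceMask, sigma: float) -> tuple[bool, str]:
    """Check the buffer-width >= 3 sigma rule (boundary inclusive)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ok = mask.buffer_width >= 3.0 * sigma
    msg = (
        f"buffer {mask.buffer_width / 1000:.1f} km "
        f"{'meets' if ok else 'violates'} the 3-sigma rule "
        f"(3 sigma = {3 * sigma / 1000:.1f} km)"
    )
    return ok, msg
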