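"""Porosity metrology on voxel masks and the design-to-printed correction.

Printed porosity is measured by voxel counting inside a cubic region of
interest (ROI) centered in the porous band — the standard 3 mm cube
convention for these specimens. Because selective laser melting sinters
extra material onto the struts, printed porosity is systematically lower
than designed porosity; the deficit is unit-cell specific and is captured
by an ordinary-least-squares affine map fitted per cell type, which is then
used to predict the printed porosity of new designs and to derive adjusted
design targets that compensate the manufacturing deviation.

Porosity is always a fraction in (0, 1) internally; percent only at I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CellType, SampleDesign, VoxelGrid

__all__ = [
    "Cube",
    "PorosityRecord",
    "CorrectionModel",
    "binarize_global",
    "central_roi",
    "measure_porosity",
    "fit_porosity_correction",
    "adjusted_design_porosity",
    "records_to_frame",
]


@dataclass(frozen=True)
class Cube:
    """Axis-aligned cube: center (mm triple) and edge length (mm)."""

    center: tuple[float, float, float]
    edge: float

    def __post_init__(self):
        if self.edge <= 0:
            raise ValueError("cube edge must be positive")


@dataclass
class PorosityRecord:
    """One design's designed vs measured (printed) porosity."""

    design_id: str
    cell_type: CellType
    design_porosity: float
    printed_porosity: float
    roi: Cube | None = None

    def __post_init__(self):
        self.cell_type = CellType(self.cell_type)
        for name in ("design_porosity", "printed_porosity"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class CorrectionModel:
    """Affine design->printed porosity map for one unit-cell type."""

    cell_type: CellType
    slope: float
    intercept: float
    n_points: int
    r2: float

    def predict(self, design_porosity) -> np.ndarray | float:
        """Predicted printed porosity, clamped to the open unit interval."""
        p = self.slope * np.asarray(design_porosity, dtype=float) + self.intercept
        out = np.clip(p, 1e-3, 1.0 - 1e-3)
        return out if out.ndim else float(out)


def binarize_global(
    intensity: np.ndarray,
    threshold: float,
    voxel_size: float,
    origin=(0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Segment a grayscale volume with a global threshold (solid = value >= t).

    An empty or full result is legal (it happens with a badly chosen
    threshold) and only triggers a warning.
    """
    intensity = np.asarray(intensity)
    if not intensity.min() <= threshold <= intensity.max():
        warnings.warn(
            "threshold outside the grayscale range; mask will be empty or full",
            stacklevel=2,
        )
    solid = intensity >= threshold
    if not solid.any():
        warnings.warn("global threshold produced an empty mask", stacklevel=2)
    elif solid.all():
        warnings.warn("global threshold produced an all-solid mask", stacklevel=2)
    return VoxelGrid(solid, voxel_size, origin)


def central_roi(design: SampleDesign, edge: float = 3.0) -> Cube:
    """Cubic ROI centered on the specimen axis at the porous-band center.

    The cube must fit axially inside the band and laterally inside the
    cylinder cross-section (edge <= diameter / sqrt(2), cube inscribed in
    the circle).
    """
    if edge > design.porous_band_height:
        raise ValueError(
            f"ROI edge {edge} mm exceeds porous band height "
            f"{design.porous_band_height} mm"
        )
    if edge > design.diameter / np.sqrt(2.0) + 1e-12:
        raise ValueError(
            f"ROI edge {edge} mm does not fit inside the {design.diameter} mm "
            "diameter cylinder cross-section"
        )
    return Cube((0.0, 0.0, design.porous_band_center), edge)


def _roi_slices(grid: VoxelGrid, roi: Cube) -> tuple[slice, slice, slice]:
    """Snap the cube to the voxel lattice: lower bound rounds to the nearest
    voxel boundary, extent is round(edge / voxel_size) voxels, half-open."""
    slices = []
    n = int(round(roi.edge / grid.voxel_size))
    if n < 1:
        raise ValueError("ROI smaller than one voxel")
    for axis in range(3):
        lo_mm = roi.center[axis] - roi.edge / 2.0
        i0 = int(round((lo_mm - grid.origin[axis]) / grid.voxel_size))
        if i0 < 0 or i0 + n > grid.shape[axis]:
            raise ValueError(
                f"ROI exceeds grid bounds along axis {axis}: "
                f"[{i0}, {i0 + n}) not within [0, {grid.shape[axis]})"
            )
        slices.append(slice(i0, i0 + n))
    return tuple(slices)


def measure_porosity(grid: VoxelGrid, roi: Cube) -> float:
    """Void fraction = 1 - solid fraction, counted in the snapped ROI."""
    sub = grid.solid[_roi_slices(grid, roi)]
    return float(1.0 - sub.mean())


def fit_porosity_correction(
    records: list[PorosityRecord], cell_type: CellType | str
) -> CorrectionModel:
    """OLS of printed on designed porosity for one cell type.

    Requires at least two distinct design porosities for that cell type.
    """
    cell_type = CellType(cell_type)
    recs = [r for r in records if r.cell_type is cell_type]
    if len(recs) < 2:
        raise ValueError(f"need >= 2 records for cell type {cell_type.value}")
    x = np.array([r.design_porosity for r in recs])
    y = np.array([r.printed_porosity for r in recs])
    if np.ptp(x) < 1e-12:
        raise ValueError("all design porosities identical; slope is undefined")
    res = stats.linregress(x, y)
    return CorrectionModel(
        cell_type=cell_type,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(recs),
        r2=float(res.rvalue**2),
    )


def adjusted_design_porosity(printed_estimate: float) -> float:
    """Porosity target for the adjusted (printing-compensated) design.

    The adjusted model simply targets the estimated printed porosity; the
    nontrivial step is estimating it upstream via :class:`CorrectionModel`.
    """
    if not 0.0 < printed_estimate < 1.0:
        raise ValueError(f"printed porosity estimate {printed_estimate} not in (0, 1)")
    return float(printed_estimate)


def records_to_frame(records: list[PorosityRecord]) -> pd.DataFrame:
    """Porosity table in the standard CSV layout."""
    return pd.DataFrame(
        {
            "design_id": [r.design_id for r in records],
            "cell_type": [r.cell_type.value for r in records],
            "design_porosity": [r.design_porosity for r in records],
            "printed_porosity": [r.printed_porosity for r in records],
            "roi_center_z_mm": [r.roi.center[2] if r.roi else np.nan for r in records],
            "roi_edge_mm": [r.roi.edge if r.roi else np.nan for r in records],
        }
    )
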