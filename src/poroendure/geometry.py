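"""Voxelized porous specimen geometry from TPMS unit-cell implicit fields.

The specimens are simplified ISO 14801 test cylinders: a 4.5 mm diameter
shaft with a hemispherical tip 11 mm above the embedding plane, carrying a
fully porous band built from a triply periodic minimal surface (TPMS) unit
cell. Two skeletal unit-cell families are supported, Schwarz Primitive (SP)
and Schwarz W (SW), realised as trigonometric level sets. The porosity of a
design is controlled by resolving the level threshold with bisection until
the voxel-counted void fraction of one unit cell matches the target.

Solid convention: a point is solid iff ``f(x) >= level_threshold``.
All lengths are in millimetres; the cylinder axis is z with z = 0 at the
embedding plane.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "CellType",
    "UnitCellSpec",
    "SampleDesign",
    "VoxelGrid",
    "implicit_field",
    "voxelize_unit_cell",
    "threshold_for_porosity",
    "generate_sample",
    "export_surface",
    "ConvergenceError",
]


class CellType(str, Enum):
    """Skeletal TPMS unit-cell family."""

    SP = "SP"  # Schwarz Primitive
    SW = "SW"  # Schwarz W


class ConvergenceError(RuntimeError):
    """Bisection on the level threshold failed to reach its tolerance."""


def implicit_field(cell_type: CellType | str, points, cell_length: float):
    """Evaluate the unit-cell implicit field at ``points``.

    Parameters
    ----------
    cell_type : CellType or str
        ``SP`` uses ``cos X + cos Y + cos Z``; ``SW`` uses
        ``cos X cos Y + cos Y cos Z + cos Z cos X`` with
        ``X = 2 pi x / cell_length`` etc.
    points : array-like, shape (..., 3)
        Coordinates in mm.
    cell_length : float
        Period of the cell in mm, > 0.

    Returns
    -------
    ndarray or scalar of the field value(s); periodic with period
    ``cell_length`` along each axis.
    """
    if cell_length <= 0:
        raise ValueError("cell_length must be positive")
    cell_type = CellType(cell_type)
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("points must have trailing dimension 3")
    w = 2.0 * np.pi / cell_length
    cx, cy, cz = (np.cos(w * pts[..., i]) for i in range(3))
    if cell_type is CellType.SP:
        out = cx + cy + cz
    else:
        out = cx * cy + cy * cz + cz * cx
    return out if out.ndim else out.item()


def _field_on_axes(cell_type: CellType, x, y, z, cell_length: float):
    """Field on the separable grid x × y × z (1-D coordinate arrays).

    Broadcasting the three cosine vectors avoids materialising an (n, 3)
    coordinate array for large grids.
    """
    w = 2.0 * np.pi / cell_length
    cx = np.cos(w * np.asarray(x, dtype=float))[:, None, None]
    cy = np.cos(w * np.asarray(y, dtype=float))[None, :, None]
    cz = np.cos(w * np.asarray(z, dtype=float))[None, None, :]
    if CellType(cell_type) is CellType.SP:
        return cx + cy + cz
    return cx * cy + cy * cz + cz * cx


@dataclass
class UnitCellSpec:
    """A TPMS unit cell with a porosity target.

    ``level_threshold`` is resolved by :func:`threshold_for_porosity`,
    not set by the user.
    """

    cell_type: CellType
    cell_length: float
    target_porosity: float
    level_threshold: float | None = None

    def __post_init__(self):
        self.cell_type = CellType(self.cell_type)
        if self.cell_length <= 0:
            raise ValueError("cell_length must be positive")
        if not 0.0 < self.target_porosity < 1.0:
            raise ValueError("target_porosity must be in (0, 1)")


@dataclass
class SampleDesign:
    """ISO 14801-style cylindrical test specimen with a porous band.

    The porous band must contain an integer number of unit cells along z.
    """

    cell: UnitCellSpec
    design_id: str = ""
    diameter: float = 4.5
    lever_arm: float = 11.0
    porous_band_height: float = 4.5
    porous_band_center: float = 3.0

    def __post_init__(self):
        if self.diameter <= 0 or self.lever_arm <= 0:
            raise ValueError("diameter and lever_arm must be positive")
        if self.porous_band_height < 0:
            raise ValueError("porous_band_height must be >= 0")
        if self.porous_band_height > 0:
            ratio = self.porous_band_height / self.cell.cell_length
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"porous band height {self.porous_band_height} mm does not fit an "
                    f"integer number of {self.cell.cell_length} mm cells"
                )

    @property
    def n_cells_along_band(self) -> int:
        return int(round(self.porous_band_height / self.cell.cell_length))


@dataclass
class VoxelGrid:
    """Binary solid mask on an isotropic lattice.

    ``solid[i, j, k]`` covers the voxel whose lower corner is at
    ``origin + (i, j, k) * voxel_size`` (axis order x, y, z).
    """

    solid: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.ndim != 3:
            raise ValueError("solid mask must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    def solid_fraction(self) -> float:
        return float(self.solid.mean())

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write the mask as ``<path>.npz`` plus a JSON sidecar header."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), solid=self.solid)
        header = {
            "shape": list(self.shape),
            "voxel_size_mm": self.voxel_size,
            "origin_mm": list(self.origin),
            "axis_order": "xyz",
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        solid = np.load(path.with_suffix(".npz"))["solid"]
        return cls(solid, header["voxel_size_mm"], tuple(header["origin_mm"]))

    def to_tiff(self, path) -> None:
        """Write as a TIFF stack, one page per z slice (page axes y, x)."""
        import tifffile

        stack = np.transpose(self.solid, (2, 1, 0)).astype(np.uint8) * 255
        tifffile.imwrite(path, stack)

    @classmethod
    def from_tiff(cls, path, voxel_size: float, origin=(0.0, 0.0, 0.0)) -> "VoxelGrid":
        import tifffile

        stack = tifffile.imread(path)
        solid = np.transpose(stack > 0, (2, 1, 0))
        return cls(solid, voxel_size, origin)


def voxelize_unit_cell(cell: UnitCellSpec, n_voxels: int) -> np.ndarray:
    """Solid mask of one unit cell sampled at ``n_voxels`` per edge.

    The cell's ``level_threshold`` must already be resolved. Sampling is at
    voxel centers, so the mask tiles periodically without seams.
    """
    if cell.level_threshold is None:
        raise ValueError("resolve level_threshold first (threshold_for_porosity)")
    x = (np.arange(n_voxels) + 0.5) * (cell.cell_length / n_voxels)
    f = _field_on_axes(cell.cell_type, x, x, x, cell.cell_length)
    return f >= cell.level_threshold


def threshold_for_porosity(
    cell: UnitCellSpec,
    voxel_size: float | None = None,
    tolerance: float = 1e-3,
    max_iter: int = 80,
) -> float:
    """Resolve the level threshold giving the target void fraction.

    Bisection on the threshold over one voxelized unit cell until the
    voxel-counted void fraction is within ``tolerance`` (fraction, default
    0.001 = 0.1 porosity point) of ``cell.target_porosity``. The resolved
    threshold is stored on the spec and returned.

    ``voxel_size`` defaults to ``cell_length / 64``.
    """
    if not 0.05 < cell.target_porosity < 0.95:
        raise ValueError("target porosity outside supported range (0.05, 0.95)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if voxel_size is None:
        voxel_size = cell.cell_length / 64
    n = int(round(cell.cell_length / voxel_size))
    if n < 8:
        raise ValueError("voxel_size too coarse for threshold resolution")
    x = (np.arange(n) + 0.5) * (cell.cell_length / n)
    f = _field_on_axes(cell.cell_type, x, x, x, cell.cell_length).ravel()

    lo, hi = -3.5, 3.5  # both families take values in [-3, 3]
    void = lambda t: float(np.mean(f < t))  # noqa: E731  solid is f >= t
    if not (void(lo) <= cell.target_porosity <= void(hi)):
        raise ConvergenceError("initial interval does not bracket the target")
    t = 0.0
    for _ in range(max_iter):
        t = 0.5 * (lo + hi)
        v = void(t)
        if abs(v - cell.target_porosity) <= tolerance:
            cell.level_threshold = t
            return t
        if v < cell.target_porosity:
            lo = t
        else:
            hi = t
    raise ConvergenceError(
        f"bisection did not reach |void - target| <= {tolerance} in {max_iter} "
        "iterations; the voxel grid may be too coarse for this tolerance"
    )


def generate_sample(
    design: SampleDesign,
    voxel_size: float,
    stock_below: float = 2.0,
    threshold_voxel_size: float | None = None,
) -> VoxelGrid:
    """Voxelize a full specimen: solid shaft + hemispherical tip + porous band.

    The region ``z < 0`` (below the embedding plane) is included as solid
    stock of depth ``stock_below``. Within the porous band the solid is
    intersected with the thresholded unit-cell field tiled periodically,
    phase-aligned with the bottom of the band.
    """
    cell = design.cell
    if voxel_size > cell.cell_length / 16 + 1e-12:
        raise ValueError("voxel_size too coarse: must be <= cell_length / 16")
    if design.porous_band_height > 0 and cell.level_threshold is None:
        threshold_for_porosity(cell, threshold_voxel_size)

    radius = design.diameter / 2.0
    pad = voxel_size
    z_lo, z_hi = -stock_below, design.lever_arm + radius + pad
    nx = int(np.ceil((design.diameter + 2 * pad) / voxel_size))
    nz = int(np.ceil((z_hi - z_lo) / voxel_size))
    origin = (-nx * voxel_size / 2.0, -nx * voxel_size / 2.0, z_lo)

    x = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    z = origin[2] + (np.arange(nz) + 0.5) * voxel_size
    r2 = x[:, None] ** 2 + x[None, :] ** 2  # axis at (0, 0)

    in_circle = r2 <= radius**2
    solid = np.zeros((nx, nx, nz), dtype=bool)
    shaft = z <= design.lever_arm
    solid[:, :, shaft] = in_circle[:, :, None]
    # hemispherical tip centered at (0, 0, lever_arm)
    tip = z > design.lever_arm
    if tip.any():
        dz2 = (z[tip] - design.lever_arm) ** 2
        solid[:, :, tip] = r2[:, :, None] + dz2[None, None, :] <= radius**2

    if design.porous_band_height > 0:
        b_lo = design.porous_band_center - design.porous_band_height / 2.0
        b_hi = design.porous_band_center + design.porous_band_height / 2.0
        band = (z >= b_lo) & (z < b_hi)
        if band.any():
            f = _field_on_axes(
                cell.cell_type, x, x, z[band] - b_lo, cell.cell_length
            )
            solid[:, :, band] &= f >= cell.level_threshold
    return VoxelGrid(solid, voxel_size, origin)


def _write_binary_stl(path, triangles: np.ndarray) -> None:
    """Minimal binary STL writer; ``triangles`` has shape (n, 3, 3), mm units."""
    tris = np.asarray(triangles, dtype=np.float32)
    n = len(tris)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    normals = np.cross(e1, e2)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norm, out=np.zeros_like(normals), where=norm > 0)
    with open(path, "wb") as fh:
        fh.write(b"poroendure voxel surface".ljust(80, b"\0"))
        fh.write(struct.pack("<I", n))
        rec = np.zeros(n, dtype=[("n", "<3f4"), ("v", "<3,3f4"), ("attr", "<u2")])
        rec["n"] = normals
        rec["v"] = tris
        fh.write(rec.tobytes())


def export_surface(grid: VoxelGrid, path) -> int:
    """Export a marching-cubes triangulation of the solid surface as binary STL.

    The mask is zero-padded so the surface closes at the grid boundary.
    Returns the number of triangles written. Vertex coordinates are in mm in
    the grid's frame.
    """
    from skimage import measure

    if not grid.solid.any():
        raise ValueError("cannot export surface of an empty grid")
    padded = np.pad(grid.solid.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # voxel (i,j,k) center sits at origin + (i + 0.5) * vs; padding shifts by 1
    verts = (verts - 0.5) * grid.voxel_size + np.asarray(grid.origin)
    tris = verts[faces]
    _write_binary_stl(path, tris)
    return len(tris)


def surface_area(grid: VoxelGrid) -> float:
    """Marching-cubes surface area of the solid phase, mm^2."""
    from skimage import measure

    if not grid.solid.any():
        raise ValueError("empty grid has no surface")
    padded = np.pad(grid.solid.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(grid.voxel_size,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))
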