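"""Synthetic studies with the statistical structure the workflow assumes.

Everything the analysis modules consume — printed voxel masks, monotonic
force-displacement curves, tensile stress-strain records, fatigue tables —
can be generated here from a small set of ground-truth parameters, so the
whole pipeline is testable without laboratory data or an FE solver. The
generator enforces, by construction, the two empirical structures the
analysis is built on:

* a systematic, cell-type-specific porosity deficit after printing,
  modelled as morphological dilation of the solid phase (extra sintered
  material) plus optional surface-voxel noise;
* a single normalized S-N power law ``F_cyclic / F_ult = a N_f^b`` shared
  by all designs, with lognormal lifetime scatter and censoring at five
  million cycles.

Monotonic response comes from a parametric "virtual tester" producing
bilinear force-displacement curves whose stiffness and knee force scale
with relative density as power laws; bilinearity keeps every downstream
quantity (stiffness fit, plastic offset crossing, ultimate load) available
in closed form for oracle tests. Printed specimens additionally carry
specimen-level strength/stiffness factors that are shared between a
specimen's experimental curve and its scan-based virtual test — the scan
sees the same physical geometry — which is what makes the offset-threshold
calibration identifiable.

Every public generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fatigue import (
    CENSOR_LIMIT,
    FatigueObservation,
    LoadPlan,
    observations_to_frame,
    plan_load_levels,
)
from .geometry import CellType, UnitCellSpec, VoxelGrid, threshold_for_porosity, voxelize_unit_cell
from .metrology import Cube, PorosityRecord, fit_porosity_correction, measure_porosity, records_to_frame
from .monotonic import Curve, CurveSource

__all__ = [
    "PrintModel",
    "VirtualTesterConfig",
    "FatigueNoiseModel",
    "StudyConfig",
    "DesignData",
    "SyntheticStudy",
    "simulate_printing",
    "virtual_monotonic_test",
    "closed_form_offset_load",
    "sample_fatigue_lifetimes",
    "make_tensile_curve",
    "synthetic_grayscale_scan",
    "generate_study",
]


# ---------------------------------------------------------------------------
# printing model


@dataclass(frozen=True)
class PrintModel:
    """Morphological model of selective-laser-melting material gain.

    The solid phase is dilated with a spherical structuring element
    (realised exactly via a Euclidean distance transform, so non-integer
    radii are meaningful); radius 0 is the identity. Radii are expressed in
    voxels of the grid they are applied to; ``surface_noise`` is the
    probability of toggling a surface voxel (both solid-surface voxels
    turning void and void voxels adjacent to solid turning solid),
    emulating partially fused particles and local lack of fusion.
    """

    radius_voxels: tuple[tuple[str, float], ...] = (("SP", 1.5), ("SW", 2.5))
    surface_noise: float = 0.02

    def radius_for(self, cell_type: CellType | str) -> float:
        d = dict(self.radius_voxels)
        r = d[CellType(cell_type).value]
        if r < 0:
            raise ValueError("dilation radius must be >= 0")
        return r


def _spherical_dilation(solid: np.ndarray, radius_voxels: float) -> np.ndarray:
    if radius_voxels == 0:
        return solid.copy()
    dist = ndimage.distance_transform_edt(~solid)
    return dist <= radius_voxels


def simulate_printing(
    grid: VoxelGrid,
    model: PrintModel,
    cell_type: CellType | str,
    rng: np.random.Generator | None = None,
    periodic: bool = False,
) -> VoxelGrid:
    """Apply the printing model to a mask: dilation, then surface noise.

    ``periodic=True`` treats the mask as one period of an infinite tiling
    (the dilation wraps), which is exact for unit-cell and band-block
    grids. Porosity strictly decreases for any positive radius.
    """
    r = model.radius_for(cell_type)
    if r >= min(grid.shape):
        raise ValueError("dilation radius exceeds the grid extent")
    if periodic and r > 0:
        n = grid.shape
        tiled = np.tile(grid.solid, (3, 3, 3))
        dil = _spherical_dilation(tiled, r)
        solid = dil[n[0] : 2 * n[0], n[1] : 2 * n[1], n[2] : 2 * n[2]]
    else:
        solid = _spherical_dilation(grid.solid, r)
    if model.surface_noise > 0 and rng is not None:
        solid = _toggle_surface(solid, model.surface_noise, rng)
    return VoxelGrid(solid, grid.voxel_size, grid.origin)


def _surface_shells(solid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of solid-surface voxels and void voxels touching solid."""
    core = ndimage.binary_erosion(solid)
    shell_solid = np.flatnonzero(solid & ~core)
    shell_void = np.flatnonzero(ndimage.binary_dilation(solid) & ~solid)
    return shell_solid, shell_void


def _toggle_surface(
    solid: np.ndarray,
    p: float,
    rng: np.random.Generator,
    shells: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Randomly toggle surface voxels (6-connectivity boundary) with prob p.

    ``shells`` may carry precomputed shell indices of ``solid`` so repeated
    scans of the same printed mask skip the morphology passes.
    """
    shell_solid, shell_void = shells if shells is not None else _surface_shells(solid)
    out = solid.copy()
    flat = out.ravel()
    flat[shell_solid[rng.random(shell_solid.size) < p]] = False
    flat[shell_void[rng.random(shell_void.size) < p]] = True
    return out


# ---------------------------------------------------------------------------
# virtual monotonic tester


@dataclass(frozen=True)
class VirtualTesterConfig:
    """Parametric stand-in for the elasto-plastic FE bending simulation.

    Stiffness and knee (yield) force scale with relative density
    ``(1 - porosity)`` as power laws, Gibson-Ashby style; the curve is
    bilinear with hardening ratio ``h`` (tangent slope ``h * k`` past the
    knee). ``failure_offset`` is the ground-truth plastic displacement at
    which printed specimens actually fail, i.e. where experimental curves
    peak. Scales are plausible magnitudes for these specimens (hundreds of
    newtons), not claims about any particular laboratory's parts; the
    anchor is ~200 N of ultimate load per 10 porosity points.
    """

    k0: float = 6000.0  # N/mm at zero porosity
    F0: float = 3000.0  # N at zero porosity
    n_k: float = 1.5
    n_F: float = 2.2
    strength_multiplier: tuple[tuple[str, float], ...] = (("SP", 1.0), ("SW", 0.9))
    stiffness_multiplier: tuple[tuple[str, float], ...] = (("SP", 1.0), ("SW", 1.4))
    hardening_ratio: float = 0.30
    failure_offset: float = 0.07  # mm, ground truth for threshold calibration
    noise_sd_experiment: float = 0.005  # load-cell/readout noise, multiplicative
    noise_sd_virtual: float = 0.002  # segmentation/discretisation noise of a solve
    n_points: int = 300

    def multiplier_for(self, cell_type) -> float:
        return dict(self.strength_multiplier)[CellType(cell_type).value]

    def stiffness(self, porosity: float, cell_type) -> float:
        mult = dict(self.stiffness_multiplier)[CellType(cell_type).value]
        return self.k0 * (1.0 - porosity) ** self.n_k * mult

    def knee_force(self, porosity: float, cell_type) -> float:
        return self.F0 * (1.0 - porosity) ** self.n_F * self.multiplier_for(cell_type)

    def noise_for(self, source: CurveSource) -> float:
        if CurveSource(source) is CurveSource.EXPERIMENT:
            return self.noise_sd_experiment
        return self.noise_sd_virtual


def closed_form_offset_load(
    k: float, F_y: float, h: float, threshold: float
) -> float:
    """Offset-criterion ultimate load of an exact bilinear curve.

    On the hardening branch ``u_pl = (1 - h) (u - u_y)``, so the plastic
    displacement reaches ``threshold`` at
    ``F = F_y + h k threshold / (1 - h)``.
    """
    return F_y + h * k * threshold / (1.0 - h)


def virtual_monotonic_test(
    porosity: float,
    cell_type: CellType | str,
    config: VirtualTesterConfig | None = None,
    rng: np.random.Generator | None = None,
    strength_factor: float = 1.0,
    stiffness_factor: float = 1.0,
    softening: bool = False,
    source: CurveSource = CurveSource.VIRTUAL_TEST,
) -> Curve:
    """Bilinear force-displacement curve for one (porosity, cell type).

    With ``softening=True`` the curve peaks at the ground-truth failure
    offset and then falls — the shape of an experimental record, whose
    max-force ultimate therefore equals the closed-form offset load at the
    generator's ``failure_offset``. Without it the curve keeps hardening
    well past the offset, like an FE solve pushed beyond the ultimate
    state. Multiplicative measurement noise applies to k and F_y when an
    ``rng`` is supplied; its sd depends on ``source`` (experimental load
    trains are noisier than a repeated solve on fixed geometry).
    """
    config = config or VirtualTesterConfig()
    if not 0.0 <= porosity < 1.0:
        raise ValueError("porosity must be in [0, 1)")
    h = config.hardening_ratio
    if not 0.0 <= h < 1.0:
        raise ValueError("hardening ratio must be in [0, 1)")
    k = config.stiffness(porosity, cell_type) * stiffness_factor
    F_y = config.knee_force(porosity, cell_type) * strength_factor
    noise_sd = config.noise_for(source)
    if rng is not None and noise_sd > 0:
        k *= float(np.exp(rng.normal(0.0, noise_sd)))
        F_y *= float(np.exp(rng.normal(0.0, noise_sd)))
    u_y = F_y / k
    u_fail = u_y + config.failure_offset / (1.0 - h) if h < 1 else u_y
    n = max(config.n_points, 200)

    if softening:
        F_peak = closed_form_offset_load(k, F_y, h, config.failure_offset)
        u_rise = np.linspace(0.0, u_fail, n)
        F_rise = np.where(u_rise <= u_y, k * u_rise, F_y + h * k * (u_rise - u_y))
        drop = 0.25 * F_peak
        u_soft = u_fail + np.linspace(0.0, drop / (0.5 * k), 40)[1:]
        F_soft = F_peak - 0.5 * k * (u_soft - u_fail)
        u = np.concatenate([u_rise, u_soft])
        F = np.concatenate([F_rise, F_soft])
    else:
        # push well past the ultimate state so any calibration threshold on
        # the default 0.01-0.20 mm grid is reachable
        u_end = u_y + 3.0 * config.failure_offset / (1.0 - h)
        u = np.linspace(0.0, u_end, n)
        F = np.where(u <= u_y, k * u, F_y + h * k * (u - u_y))
    return Curve(u, F, source)


# ---------------------------------------------------------------------------
# fatigue lifetimes


@dataclass(frozen=True)
class FatigueNoiseModel:
    """Ground-truth S-N law with lognormal lifetime scatter and censoring."""

    a: float = 3.22
    b: float = -0.20
    scatter_sd: float = 0.3  # decades of life (log10 cycles)
    censor_limit: float = CENSOR_LIMIT

    def __post_init__(self):
        if self.b >= 0:
            raise ValueError("exponent b must be negative")
        if self.scatter_sd < 0:
            raise ValueError("scatter sd must be >= 0")

    def median_life(self, normalized_load: float) -> float:
        return (normalized_load / self.a) ** (1.0 / self.b)


def sample_fatigue_lifetimes(
    F_ult: float,
    plan: LoadPlan,
    noise: FatigueNoiseModel,
    rng: np.random.Generator,
    design_id: str = "",
) -> list[FatigueObservation]:
    """Draw one fatigue campaign: all plan levels x replicates.

    Lifetimes invert the S-N law at each level and multiply by
    ``10^eps, eps ~ N(0, scatter_sd)``; draws at or beyond the censor
    limit become runouts.
    """
    observations = []
    for _fraction, load in plan.levels:
        for _ in range(plan.replicates_per_level):
            n_median = noise.median_life(load / F_ult)
            n_f = n_median * 10.0 ** rng.normal(0.0, noise.scatter_sd)
            if n_f >= noise.censor_limit:
                obs = FatigueObservation(
                    design_id, load, float(noise.censor_limit), True, F_ult
                )
            else:
                obs = FatigueObservation(
                    design_id, load, max(1.0, round(n_f)), False, F_ult
                )
            observations.append(obs)
    return observations


# ---------------------------------------------------------------------------
# tensile fixture


def make_tensile_curve(
    E_gpa: float = 104.8,
    sigma_y: float = 820.6,
    uts: float = 914.6,
    a_percent: float = 4.41,
    proportional_limit: float = 750.0,
    offset_strain: float = 0.002,
    n_points: int = 600,
):
    """Piecewise-linear stress-strain fixture with analytic properties.

    Elastic up to the proportional limit, then a hardening segment whose
    slope ``H`` is solved so the 0.2 % offset line intersects it exactly at
    ``sigma_y`` (``1/H = 1/E + offset / (sigma_y - sigma_0)``), then a
    shallower segment peaking exactly at (``a_percent``/100, ``uts``),
    then a short post-peak drop. Returns ``(strain, stress, truth)`` with
    the construction constants recorded in ``truth``.
    """
    E = E_gpa * 1000.0  # MPa
    s0 = proportional_limit
    if not 0 < s0 < sigma_y < uts:
        raise ValueError("need 0 < proportional limit < sigma_y < UTS")
    H = 1.0 / (1.0 / E + offset_strain / (sigma_y - s0))
    e0 = s0 / E
    s_mid = sigma_y + 0.25 * (uts - sigma_y)
    e_mid = e0 + (s_mid - s0) / H
    e_uts = a_percent / 100.0
    if e_mid >= e_uts:
        raise ValueError("inconsistent fixture: hardening segment passes the UTS strain")
    n1 = n_points // 2
    n2 = n_points // 4
    n3 = n_points - n1 - n2
    strain = np.concatenate(
        [
            np.linspace(0.0, e0, n1, endpoint=False),
            np.linspace(e0, e_mid, n2, endpoint=False),
            np.linspace(e_mid, e_uts, n3),
            e_uts + np.linspace(0.002, 0.004, 5),
        ]
    )
    stress = np.empty_like(strain)
    m1 = strain < e0
    m2 = (strain >= e0) & (strain < e_mid)
    m3 = (strain >= e_mid) & (strain <= e_uts)
    m4 = strain > e_uts
    stress[m1] = E * strain[m1]
    stress[m2] = s0 + H * (strain[m2] - e0)
    stress[m3] = s_mid + (uts - s_mid) / (e_uts - e_mid) * (strain[m3] - e_mid)
    stress[m4] = uts - 5000.0 * (strain[m4] - e_uts)
    truth = {
        "E_gpa": E_gpa,
        "sigma_y_mpa": sigma_y,
        "uts_mpa": uts,
        "a_percent": a_percent,
        "proportional_limit_mpa": s0,
        "hardening_modulus_mpa": H,
    }
    return strain, stress, truth


def synthetic_grayscale_scan(
    grid: VoxelGrid,
    rng: np.random.Generator,
    blur_sigma_voxels: float = 1.0,
    noise_sd: float = 0.05,
    solid_value: float = 100.0,
) -> np.ndarray:
    """Blurred, noisy grayscale rendering of a mask (a crude uCT look)."""
    img = grid.solid.astype(float) * solid_value
    img = ndimage.gaussian_filter(img, blur_sigma_voxels)
    img += rng.normal(0.0, noise_sd * solid_value, img.shape)
    return img


# ---------------------------------------------------------------------------
# full study


@dataclass(frozen=True)
class StudyConfig:
    """The stated world of the default synthetic study.

    Six designs (50/60/70 % porosity x SP/SW), calibration on the 60 % and
    70 % designs, validation on the 50 % ones. Geometry is generated as
    periodic band blocks around the metrology ROI. ``voxels_per_cell``
    and the print radii together set the printed-porosity deficit
    (~4.5 points for SP, ~11 for SW at the 70 % level with the defaults,
    preserving the strong SP/SW printability asymmetry).
    """

    porosity_levels: tuple[float, ...] = (0.5, 0.6, 0.7)
    cell_lengths: tuple[tuple[str, float], ...] = (("SP", 0.75), ("SW", 1.125))
    voxels_per_cell: tuple[tuple[str, int], ...] = (("SP", 64), ("SW", 64))
    roi_edge: float = 3.0
    block_margin: float = 0.3
    print_model: PrintModel = field(default_factory=PrintModel)
    tester: VirtualTesterConfig = field(default_factory=VirtualTesterConfig)
    fatigue_noise: FatigueNoiseModel = field(default_factory=FatigueNoiseModel)
    n_specimens: int = 4  # monotonic specimens = uCT scan replicates per design
    quality_mean: float = 0.95  # printed strut quality vs ideal CAD geometry
    quality_sd: float = 0.05  # specimen-level strength scatter (shared exp/scan)
    stiffness_factor_sd: float = 0.04  # specimen-level stiffness scatter
    calibration_levels: tuple[float, ...] = (0.6, 0.7)
    validation_levels: tuple[float, ...] = (0.5,)

    def design_ids(self) -> list[str]:
        return [
            f"{int(round(p * 100))}{ct}"
            for ct, _ in self.cell_lengths
            for p in self.porosity_levels
        ]

    def cell_length_for(self, cell_type) -> float:
        return dict(self.cell_lengths)[CellType(cell_type).value]

    def voxels_for(self, cell_type) -> int:
        return dict(self.voxels_per_cell)[CellType(cell_type).value]


def reduced_config() -> StudyConfig:
    """Coarse, fast variant for multi-seed testing.

    Half the voxels per cell with print radii rescaled to keep the dilation
    thickness approximately constant in millimetres, so the printed
    porosity deficits stay close to the default study's.
    """
    return StudyConfig(
        voxels_per_cell=(("SP", 32), ("SW", 32)),
        print_model=PrintModel(radius_voxels=(("SP", 1.0), ("SW", 1.5))),
    )


@dataclass
class DesignData:
    """Everything generated for one design."""

    design_id: str
    cell_type: CellType
    design_porosity: float
    printed_porosity: float
    scan_porosities: list[float]
    adjusted_target: float | None = None
    exp_curves: list[Curve] = field(default_factory=list)
    exp_ultimates: list[float] = field(default_factory=list)
    virtual_curves: dict = field(default_factory=dict)  # strategy -> [Curve]
    masks: dict = field(default_factory=dict)  # optional: name -> VoxelGrid

    @property
    def F_ult_exp(self) -> float:
        return float(np.mean(self.exp_ultimates))


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    designs: dict[str, DesignData]
    calibration_ids: list[str]
    validation_ids: list[str]
    observations: list[FatigueObservation]
    tensile_strain: np.ndarray
    tensile_stress: np.ndarray
    truth: dict

    def porosity_records(self, design_ids=None) -> list[PorosityRecord]:
        """One record per scan replicate (per-specimen convention)."""
        ids = self.designs if design_ids is None else design_ids
        roi = Cube((0.0, 0.0, 0.0), self.config.roi_edge)
        return [
            PorosityRecord(d.design_id, d.cell_type, d.design_porosity, p, roi)
            for i in ids
            for d in [self.designs[i]]
            for p in d.scan_porosities
        ]

    def ultimates(self) -> dict[str, float]:
        return {i: d.F_ult_exp for i, d in self.designs.items()}

    def save(self, out_dir) -> None:
        """Emit the study directory tree in the standard text formats."""
        out = Path(out_dir)
        (out / "curves").mkdir(parents=True, exist_ok=True)
        (out / "tensile").mkdir(exist_ok=True)
        observations_to_frame(self.observations).to_csv(
            out / "fatigue.csv", index=False
        )
        records_to_frame(self.porosity_records()).to_csv(
            out / "porosity.csv", index=False
        )
        for did, d in self.designs.items():
            for j, c in enumerate(d.exp_curves):
                c.to_frame().to_csv(out / "curves" / f"{did}_exp{j}.csv", index=False)
            for strat, curves in d.virtual_curves.items():
                for j, c in enumerate(curves):
                    name = f"{did}_{strat}{j if strat == 'scan' else ''}.csv"
                    c.to_frame().to_csv(out / "curves" / name, index=False)
            if d.masks:
                (out / "masks").mkdir(exist_ok=True)
                for name, grid in d.masks.items():
                    grid.save(out / "masks" / f"{did}_{name}")
        import pandas as pd

        pd.DataFrame(
            {"strain": self.tensile_strain, "stress_MPa": self.tensile_stress}
        ).to_csv(out / "tensile" / "tensile.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


@lru_cache(maxsize=32)
def _printed_unit_cell(cell_type: str, cell_length: float, porosity: float,
                       n_vox: int, radius_voxels: float):
    """Designed and printed (dilated) masks of one unit cell, cached.

    Dilation wraps periodically, so tiling the printed cell equals printing
    the tiled structure. Returned arrays are shared: treat as read-only.
    """
    cell = UnitCellSpec(cell_type, cell_length, porosity)
    threshold_for_porosity(cell, cell_length / n_vox)
    designed = voxelize_unit_cell(cell, n_vox)
    n = n_vox
    tiled = np.tile(designed, (3, 3, 3))
    printed = _spherical_dilation(tiled, radius_voxels)[n : 2 * n, n : 2 * n, n : 2 * n]
    designed.setflags(write=False)
    printed.setflags(write=False)
    return designed, printed, cell.level_threshold


def _band_block(cell_mask: np.ndarray, voxel_size: float, block_mm: float) -> VoxelGrid:
    n_block = int(round(block_mm / voxel_size))
    reps = -(-n_block // cell_mask.shape[0])  # ceil
    tiled = np.tile(cell_mask, (reps, reps, reps))[:n_block, :n_block, :n_block]
    return VoxelGrid(tiled, voxel_size)


def generate_study(
    seed: int = 0,
    config: StudyConfig | None = None,
    keep_masks: bool = False,
    out_dir=None,
) -> SyntheticStudy:
    """Generate a complete six-design study from one master seed.

    The master seed fans out through named ``SeedSequence`` children (scan
    noise, monotonic curves, fatigue) so each stage is independently
    reproducible. The deterministic geometry stage (thresholding and
    dilation of unit cells) is cached across calls, so regenerating with a
    new seed only redraws the stochastic stages.
    """
    config = config or StudyConfig()
    root = np.random.SeedSequence(seed)
    ss_scan, ss_curves, ss_fatigue = root.spawn(3)
    rng_scan = np.random.default_rng(ss_scan)
    rng_curves = np.random.default_rng(ss_curves)
    rng_fatigue = np.random.default_rng(ss_fatigue)

    block_mm = config.roi_edge + 2 * config.block_margin
    designs: dict[str, DesignData] = {}
    truth_designs: dict[str, dict] = {}

    cal_ids, val_ids = [], []
    for ct_name, cell_length in config.cell_lengths:
        ct = CellType(ct_name)
        n_vox = config.voxels_for(ct)
        vs = cell_length / n_vox
        radius = config.print_model.radius_for(ct)
        for p in config.porosity_levels:
            did = f"{int(round(p * 100))}{ct.value}"
            designed_cell, printed_cell, threshold = _printed_unit_cell(
                ct.value, cell_length, p, n_vox, radius
            )
            designed = _band_block(designed_cell, vs, block_mm)
            printed = _band_block(printed_cell, vs, block_mm)
            center = tuple([printed.shape[0] * vs / 2.0] * 3)
            roi = Cube(center, config.roi_edge)
            printed_porosity = measure_porosity(printed, roi)

            shells = _surface_shells(printed.solid)
            scan_porosities, scans = [], []
            for _ in range(config.n_specimens):
                noisy = _toggle_surface(
                    printed.solid, config.print_model.surface_noise, rng_scan, shells
                )
                scan = VoxelGrid(noisy, vs)
                scan_porosities.append(measure_porosity(scan, roi))
                if keep_masks:
                    scans.append(scan)

            d = DesignData(
                design_id=did,
                cell_type=ct,
                design_porosity=p,
                printed_porosity=printed_porosity,
                scan_porosities=scan_porosities,
            )
            if keep_masks:
                d.masks = {"designed": designed, "printed": printed}
                d.masks.update({f"scan{j}": s for j, s in enumerate(scans)})
            designs[did] = d
            truth_designs[did] = {
                "cell_type": ct.value,
                "design_porosity": p,
                "level_threshold": threshold,
                "printed_porosity": printed_porosity,
                "scan_porosities": scan_porosities,
            }
            (cal_ids if p in config.calibration_levels else val_ids).append(did)

    # adjusted design targets: measured for calibration designs, predicted via
    # the per-cell-type correction for validation designs (prospective use)
    roi0 = Cube((0.0, 0.0, 0.0), config.roi_edge)
    cal_records = [
        PorosityRecord(i, designs[i].cell_type, designs[i].design_porosity, sp, roi0)
        for i in cal_ids
        for sp in designs[i].scan_porosities
    ]
    corrections = {
        ct_name: fit_porosity_correction(cal_records, ct_name)
        for ct_name, _ in config.cell_lengths
    }
    for did, d in designs.items():
        if did in cal_ids:
            d.adjusted_target = float(np.mean(d.scan_porosities))
        else:
            d.adjusted_target = corrections[d.cell_type.value].predict(
                d.design_porosity
            )
        truth_designs[did]["adjusted_target"] = d.adjusted_target

    # monotonic curves: experimental + the three virtual-test strategies
    tester = config.tester
    for did, d in designs.items():
        qs = config.quality_mean * np.exp(
            rng_curves.normal(0.0, config.quality_sd, config.n_specimens)
        )
        ws = np.exp(
            rng_curves.normal(0.0, config.stiffness_factor_sd, config.n_specimens)
        )
        exp_curves, scan_curves = [], []
        for j in range(config.n_specimens):
            p_j = d.scan_porosities[j]
            exp_curves.append(
                virtual_monotonic_test(
                    p_j, d.cell_type, tester, rng_curves,
                    strength_factor=qs[j], stiffness_factor=ws[j],
                    softening=True, source=CurveSource.EXPERIMENT,
                )
            )
            scan_curves.append(
                virtual_monotonic_test(
                    p_j, d.cell_type, tester, rng_curves,
                    strength_factor=qs[j], stiffness_factor=ws[j],
                )
            )
        d.exp_curves = exp_curves
        d.exp_ultimates = [float(c.F.max()) for c in exp_curves]
        d.virtual_curves = {
            "original": [virtual_monotonic_test(d.design_porosity, d.cell_type, tester)],
            "adjusted": [virtual_monotonic_test(d.adjusted_target, d.cell_type, tester)],
            "scan": scan_curves,
        }
        truth_designs[did]["specimen_strength_factors"] = qs.tolist()
        truth_designs[did]["specimen_stiffness_factors"] = ws.tolist()
        truth_designs[did]["F_ult_exp_mean"] = d.F_ult_exp

    # fatigue campaigns
    observations = []
    for did, d in designs.items():
        plan = plan_load_levels(d.F_ult_exp)
        observations.extend(
            sample_fatigue_lifetimes(
                d.F_ult_exp, plan, config.fatigue_noise, rng_fatigue, did
            )
        )

    strain, stress, tensile_truth = make_tensile_curve()

    truth = {
        "seed": seed,
        "seed_children": ["scan_noise", "monotonic_curves", "fatigue"],
        "sn_law": {
            "a": config.fatigue_noise.a,
            "b": config.fatigue_noise.b,
            "scatter_sd_log10": config.fatigue_noise.scatter_sd,
            "censor_limit": config.fatigue_noise.censor_limit,
        },
        "tester": asdict(tester),
        "print_model": asdict(config.print_model),
        "failure_offset_mm": tester.failure_offset,
        "quality_mean": config.quality_mean,
        "tensile": tensile_truth,
        "designs": truth_designs,
        "schema_version": 1,
    }
    study = SyntheticStudy(
        config=config,
        seed=seed,
        designs=designs,
        calibration_ids=cal_ids,
        validation_ids=val_ids,
        observations=observations,
        tensile_strain=strain,
        tensile_stress=stress,
        truth=truth,
    )
    if out_dir is not None:
        study.save(out_dir)
    return study
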