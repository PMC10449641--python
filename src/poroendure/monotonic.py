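"""Monotonic force-displacement and tensile stress-strain post-processing.

Two ultimate-load criteria coexist, mirroring how experiments and
simulations are read in this workflow:

* experimental bending-compression curves use the **maximum force**;
* virtual-test (FE stand-in) curves use the **plastic-displacement offset**
  criterion: the ultimate load is the force at which the plastic
  displacement ``u_pl = u - F/k`` first reaches a calibrated threshold
  (0.07 mm by default). The threshold is calibrated by scanning a grid and
  maximizing the Pearson R^2 between offset-criterion loads of simulated
  curves and paired experimental ultimates.

Tensile stress-strain curves yield the printed material's elastic modulus
(least-squares slope over the 0-400 MPa window), 0.2 % plastic-strain
offset yield stress, ultimate tensile strength and elongation at break.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Curve",
    "CurveSource",
    "UltimateMethod",
    "MonotonicResult",
    "OffsetCriterion",
    "MaterialProperties",
    "NoFailureError",
    "estimate_stiffness",
    "plastic_displacement",
    "ultimate_load_max",
    "ultimate_load_offset",
    "calibrate_offset_threshold",
    "tensile_properties",
]

DEFAULT_OFFSET_GRID = np.round(np.arange(0.01, 0.2001, 0.005), 6)


class CurveSource(str, Enum):
    EXPERIMENT = "experiment"
    VIRTUAL_TEST = "virtual_test"


class UltimateMethod(str, Enum):
    MAX_FORCE = "max_force"
    PLASTIC_OFFSET = "plastic_offset"


class NoFailureError(RuntimeError):
    """The curve never reaches the plastic-displacement threshold."""


@dataclass
class Curve:
    """A preprocessed monotone force-displacement record.

    ``u`` (mm) is non-decreasing with ``u[0] = 0`` and ``F[0] = 0`` (N).
    Use :meth:`from_raw` to zero a raw machine record and drop the settling
    toe (initial samples with F below 1 % of the maximum).
    """

    u: np.ndarray
    F: np.ndarray
    source: CurveSource = CurveSource.EXPERIMENT

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.source = CurveSource(self.source)
        if self.u.shape != self.F.shape or self.u.ndim != 1:
            raise ValueError("u and F must be 1-D arrays of equal length")
        if len(self.u) < 10:
            raise ValueError("curve needs at least 10 points")
        if np.isnan(self.u).any() or np.isnan(self.F).any():
            raise ValueError("curve contains NaN")
        if np.any(np.diff(self.u) < 0):
            raise ValueError("displacement must be non-decreasing")
        if abs(self.u[0]) > 1e-12 or abs(self.F[0]) > 1e-12:
            raise ValueError("curve must start at (0, 0); use Curve.from_raw")

    @classmethod
    def from_raw(cls, u, F, source=CurveSource.EXPERIMENT, toe_fraction=0.01):
        """Zero a raw record and trim the settling toe region."""
        u = np.asarray(u, dtype=float)
        F = np.asarray(F, dtype=float)
        keep = F >= toe_fraction * F.max()
        start = int(np.argmax(keep))  # first sample above the toe
        start = max(start - 1, 0)  # retain one anchor sample below it
        u, F = u[start:] - u[start], F[start:] - F[start]
        return cls(u, F, source)

    def __len__(self):
        return len(self.u)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u_mm": self.u, "F_N": self.F})


@dataclass
class MonotonicResult:
    F_ult: float  # N
    method: UltimateMethod
    u_at_ult: float  # mm
    stiffness: float | None = None  # N/mm; not part of the max-force criterion
    flagged: bool = False  # True when no interior maximum existed

    def __post_init__(self):
        if self.F_ult <= 0:
            raise ValueError("F_ult must be positive")
        if self.stiffness is not None and self.stiffness <= 0:
            raise ValueError("stiffness must be positive when provided")


@dataclass
class OffsetCriterion:
    """Calibrated plastic-displacement threshold for the offset criterion."""

    u_ult_pl: float = 0.07  # mm

    def __post_init__(self):
        if self.u_ult_pl < 0:
            raise ValueError("u_ult_pl must be non-negative")


@dataclass
class MaterialProperties:
    E: float  # GPa
    sigma_y: float  # MPa
    UTS: float  # MPa
    A_percent: float
    poisson: float = 0.3

    def __post_init__(self):
        if self.E <= 0 or self.A_percent <= 0:
            raise ValueError("E and A_percent must be positive")
        if not 0 < self.sigma_y < self.UTS:
            raise ValueError("need 0 < sigma_y < UTS")


def estimate_stiffness(curve: Curve, fit_window: float = 0.3) -> float:
    """Elastic stiffness (N/mm): origin-anchored OLS slope on the window
    ``F <= fit_window * max(F)``.

    The 30 % window keeps the fit below the knee of typical specimen
    curves; it is configurable because the appropriate window depends on
    how early the structure yields.
    """
    mask = curve.F <= fit_window * curve.F.max()
    u, F = curve.u[mask], curve.F[mask]
    if len(u) < 5:
        raise ValueError("fewer than 5 points inside the stiffness window")
    denom = float(np.dot(u, u))
    if denom == 0:
        raise ValueError("degenerate window: zero displacement")
    k = float(np.dot(u, F) / denom)  # least squares through the origin
    if k <= 0:
        raise ValueError(f"non-positive stiffness estimate {k}")
    return k


def plastic_displacement(curve: Curve, k: float) -> np.ndarray:
    """Pointwise plastic displacement ``u_pl = u - F / k`` (mm).

    Small negative values are measurement noise and are permitted; they are
    reported as-is so callers can inspect them.
    """
    if k <= 0:
        raise ValueError("stiffness k must be positive")
    return curve.u - curve.F / k


def ultimate_load_max(curve: Curve) -> MonotonicResult:
    """Ultimate load as the maximum recorded force.

    On a curve with no interior maximum (still rising at the end of the
    record) the last force is returned with ``flagged=True``. Ties resolve
    to the first index of the maximum.
    """
    i = int(np.argmax(curve.F))
    flagged = i == len(curve) - 1
    return MonotonicResult(
        F_ult=float(curve.F[i]),
        method=UltimateMethod.MAX_FORCE,
        u_at_ult=float(curve.u[i]),
        flagged=flagged,
    )


def ultimate_load_offset(
    curve: Curve, k: float | None = None, criterion: OffsetCriterion | None = None
) -> MonotonicResult:
    """Ultimate load at the first crossing of the plastic-displacement offset.

    The crossing is linearly interpolated in (u, F) between the bracketing
    samples. Raises :class:`NoFailureError` when the plastic displacement
    never reaches the threshold (a purely elastic record, distinct from an
    invalid input).
    """
    if criterion is None:
        criterion = OffsetCriterion()
    if k is None:
        k = estimate_stiffness(curve)
    upl = plastic_displacement(curve, k)
    threshold = criterion.u_ult_pl
    eps = 1e-12
    above = upl > threshold + eps
    if not above.any():
        raise NoFailureError(
            f"plastic displacement never exceeds {threshold} mm (max "
            f"{upl.max():.4g} mm)"
        )
    i = int(np.argmax(above))
    if i == 0:
        u_c, F_c = float(curve.u[0]), float(curve.F[0])
    else:
        d0, d1 = upl[i - 1], upl[i]
        t = 0.0 if d1 == d0 else (threshold - d0) / (d1 - d0)
        u_c = float(curve.u[i - 1] + t * (curve.u[i] - curve.u[i - 1]))
        F_c = float(curve.F[i - 1] + t * (curve.F[i] - curve.F[i - 1]))
    return MonotonicResult(
        F_ult=F_c,
        method=UltimateMethod.PLASTIC_OFFSET,
        u_at_ult=u_c,
        stiffness=k,
    )


def calibrate_offset_threshold(
    sim_curves: list[Curve],
    exp_ult: list[float],
    grid=None,
) -> tuple[OffsetCriterion, pd.DataFrame]:
    """Pick the offset threshold maximizing Pearson R^2 against experiments.

    ``sim_curves`` and ``exp_ult`` are paired. For each grid value the
    offset-criterion ultimate load is computed for every simulated curve
    that reaches that threshold; pairs whose curve does not reach it are
    excluded at that grid point, and grid points with fewer than 3
    surviving pairs are dropped. Ties in R^2 (to 1e-10) break toward the
    smaller threshold. Returns the criterion and the full (threshold, R^2,
    n_pairs) trace.
    """
    if len(sim_curves) != len(exp_ult):
        raise ValueError("sim_curves and exp_ult must be paired")
    if len(sim_curves) < 3:
        raise ValueError("need at least 3 simulation/experiment pairs")
    grid = DEFAULT_OFFSET_GRID if grid is None else np.asarray(grid, dtype=float)
    exp_ult = np.asarray(exp_ult, dtype=float)
    ks = [estimate_stiffness(c) for c in sim_curves]

    rows = []
    for thr in grid:
        crit = OffsetCriterion(float(thr))
        sim_vals, exp_vals = [], []
        for c, k, fe in zip(sim_curves, ks, exp_ult):
            try:
                sim_vals.append(ultimate_load_offset(c, k, crit).F_ult)
                exp_vals.append(fe)
            except NoFailureError:
                continue
        if len(sim_vals) < 3:
            continue
        r = stats.pearsonr(sim_vals, exp_vals)
        rows.append((float(thr), float(r.statistic**2), len(sim_vals)))
    if not rows:
        raise ValueError("fewer than 3 pairs survive at every grid threshold")
    trace = pd.DataFrame(rows, columns=["threshold_mm", "r2", "n_pairs"])
    best_r2 = trace["r2"].max()
    best = trace.loc[trace["r2"] >= best_r2 - 1e-10, "threshold_mm"].min()
    return OffsetCriterion(float(best)), trace


def tensile_properties(
    strain,
    stress,
    modulus_window: tuple[float, float] = (0.0, 400.0),
    offset_strain: float = 0.002,
) -> MaterialProperties:
    """Elastic and plastic properties from a tensile stress-strain curve.

    * ``E``: OLS slope of stress (MPa) on strain over the
      ``modulus_window`` stress band, reported in GPa.
    * ``sigma_y``: intersection of the curve with the offset line
      ``sigma = E * (strain - offset_strain)`` (0.2 % offset method).
    * ``UTS``: maximum stress; ``A_percent``: strain at maximum stress
      in percent.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.shape != stress.shape or strain.ndim != 1:
        raise ValueError("strain and stress must be 1-D arrays of equal length")
    if np.any(np.diff(strain) < 0):
        raise ValueError("strain must be non-decreasing")
    lo, hi = modulus_window
    if stress.max() < hi:
        raise ValueError(f"stress range must span the {lo}-{hi} MPa window")
    win = (stress >= lo) & (stress <= hi)
    if win.sum() < 2:
        raise ValueError("modulus window contains fewer than 2 samples")
    res = stats.linregress(strain[win], stress[win])
    E_mpa = float(res.slope)
    if E_mpa <= 0:
        raise ValueError("non-positive modulus estimate")

    # 0.2 % offset: first sign change of stress - E * (strain - offset)
    diff = stress - E_mpa * (strain - offset_strain)
    below = diff <= 0
    if not below.any():
        raise NoFailureError("curve never crosses the 0.2% offset line (no yield)")
    j = int(np.argmax(below))
    if j == 0:
        sigma_y = float(stress[0])
    else:
        d0, d1 = diff[j - 1], diff[j]
        t = d0 / (d0 - d1)
        sigma_y = float(stress[j - 1] + t * (stress[j] - stress[j - 1]))

    i_max = int(np.argmax(stress))
    return MaterialProperties(
        E=E_mpa / 1000.0,
        sigma_y=sigma_y,
        UTS=float(stress[i_max]),
        A_percent=float(strain[i_max] * 100.0),
    )
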