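"""End-to-end endurance-limit prediction: calibration and validation loops.

The workflow chains three calibrated relationships:

1. a per-cell-type affine porosity correction (design -> printed),
2. the plastic-displacement offset criterion turning a virtual-test curve
   into an ultimate load, with an affine map ``F_ult_exp = c F_ult_FE + d``
   (per cell type) from virtual to experimental ultimates,
3. the normalized S-N power law ``F_cyclic / F_ult = a N_f^b``.

Composed, they predict a design's endurance load directly from a virtual
test: ``F_endurance = a (c F_ult_FE + d) (5e6)^b``. All components are
fitted on the calibration design set only; validation designs are kept
disjoint and a leakage guard enforces it.

Three geometry strategies feed the virtual tests: ``original`` (as-designed
porosity), ``adjusted`` (design regenerated at the estimated printed
porosity) and ``scan`` (per-specimen scanned geometry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fatigue import CENSOR_LIMIT, SNFit, endurance_ci, endurance_fraction, fit_sn
from .geometry import CellType
from .metrology import CorrectionModel, fit_porosity_correction
from .monotonic import (
    Curve,
    OffsetCriterion,
    calibrate_offset_threshold,
    estimate_stiffness,
    ultimate_load_max,
    ultimate_load_offset,
)

__all__ = [
    "STRATEGIES",
    "LinearMap",
    "CalibrationBundle",
    "PredictionResult",
    "fit_linear_map",
    "predict_ultimate",
    "predict_endurance",
    "validate_prediction",
    "pearson_r2_pvalue",
    "run_calibration",
    "run_validation",
]

STRATEGIES = ("original", "adjusted", "scan")


@dataclass
class LinearMap:
    """Affine virtual-to-experimental ultimate-load map for one cell type."""

    cell_type: CellType | None  # None for a pooled (ablation) map
    c: float
    d: float  # N
    r2: float
    p_value: float
    n_pairs: int = 0

    def __post_init__(self):
        if self.cell_type is not None:
            self.cell_type = CellType(self.cell_type)

    def predict(self, F_ult_FE: float, cell_type=None) -> float:
        if (
            self.cell_type is not None
            and cell_type is not None
            and CellType(cell_type) is not self.cell_type
        ):
            raise ValueError(
                f"map fitted on {self.cell_type.value} applied to "
                f"{CellType(cell_type).value} design"
            )
        return self.c * float(F_ult_FE) + self.d


def pearson_r2_pvalue(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)


def fit_linear_map(pairs, cell_type: CellType | str | None) -> LinearMap:
    """OLS of experimental on virtual-test ultimate load.

    ``pairs`` is a sequence of ``(F_ult_FE, F_ult_exp)`` tuples; at least 3
    are required. Significance of the slope is reported, not enforced.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 (F_ult_FE, F_ult_exp) pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError("zero variance in F_ult_FE; slope is undefined")
    res = stats.linregress(x, y)
    return LinearMap(
        cell_type=None if cell_type is None else CellType(cell_type),
        c=float(res.slope),
        d=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=len(pairs),
    )


def predict_ultimate(F_ult_FE: float, linear_map: LinearMap, cell_type=None) -> float:
    """Experimental-scale ultimate load predicted from a virtual test."""
    return linear_map.predict(F_ult_FE, cell_type)


@dataclass
class PredictionResult:
    design_id: str
    F_ult_FE: float
    F_ult_pred: float
    endurance_load: float  # N
    endurance_fraction: float  # of the predicted ultimate
    band: tuple[float, float] = (0.10, 0.15)


def predict_endurance(
    F_ult_FE: float,
    linear_map: LinearMap,
    sn: SNFit,
    n_cycles: float = CENSOR_LIMIT,
    design_id: str = "",
    cell_type=None,
    band: tuple[float, float] = (0.10, 0.15),
) -> PredictionResult:
    """Full chain: virtual ultimate -> predicted ultimate -> endurance load."""
    frac = endurance_fraction(sn, n_cycles)
    F_pred = predict_ultimate(F_ult_FE, linear_map, cell_type)
    return PredictionResult(
        design_id=design_id,
        F_ult_FE=float(F_ult_FE),
        F_ult_pred=F_pred,
        endurance_load=frac * F_pred,
        endurance_fraction=frac,
        band=band,
    )


def validate_prediction(
    result: PredictionResult, exp_F_ult: float, exp_band=(0.10, 0.15)
) -> dict:
    """Compare a prediction with the experimental ultimate.

    Reports the relative ultimate-load error and whether the predicted
    endurance load falls inside the experimental survival band (a fraction
    of the experimental ultimate).
    """
    if exp_F_ult <= 0:
        raise ValueError("experimental ultimate must be positive")
    frac_of_exp = result.endurance_load / exp_F_ult
    return {
        "design_id": result.design_id,
        "F_ult_FE": result.F_ult_FE,
        "F_ult_pred": result.F_ult_pred,
        "F_ult_exp": float(exp_F_ult),
        "rel_error": abs(result.F_ult_pred - exp_F_ult) / exp_F_ult,
        "endurance_load_N": result.endurance_load,
        "endurance_frac_of_exp": frac_of_exp,
        "in_band": bool(exp_band[0] <= frac_of_exp <= exp_band[1]),
    }


@dataclass
class CalibrationBundle:
    """Everything needed to run the prediction chain prospectively."""

    corrections: dict[str, CorrectionModel]  # cell type -> porosity correction
    offset: OffsetCriterion
    maps: dict[str, dict[str, LinearMap]]  # strategy -> cell type -> map
    sn: SNFit
    provenance: dict = field(default_factory=dict)
    schema_version: int = 1

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": self.schema_version,
            "corrections": {
                ct: {
                    "slope": m.slope,
                    "intercept": m.intercept,
                    "n_points": m.n_points,
                    "r2": m.r2,
                }
                for ct, m in self.corrections.items()
            },
            "offset_u_ult_pl_mm": self.offset.u_ult_pl,
            "maps": {
                strat: {
                    ct: {
                        "c": m.c,
                        "d": m.d,
                        "r2": m.r2,
                        "p_value": m.p_value,
                        "n_pairs": m.n_pairs,
                    }
                    for ct, m in by_ct.items()
                }
                for strat, by_ct in self.maps.items()
            },
            "sn": {
                "a": self.sn.a,
                "b": self.sn.b,
                "n_failures": self.sn.n_failures,
                "residual_sd": self.sn.residual_sd,
                "endurance_fraction_at_5M": self.sn.endurance_fraction_at_5M,
                "ci95": list(self.sn.ci95) if self.sn.ci95 else None,
            },
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationBundle":
        """Load a bundle from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        corrections = {
            ct: CorrectionModel(CellType(ct), m["slope"], m["intercept"],
                                m["n_points"], m["r2"])
            for ct, m in doc["corrections"].items()
        }
        maps = {
            strat: {
                ct: LinearMap(CellType(ct), m["c"], m["d"], m["r2"], m["p_value"],
                              m["n_pairs"])
                for ct, m in by_ct.items()
            }
            for strat, by_ct in doc["maps"].items()
        }
        sn_doc = doc["sn"]
        sn = SNFit(
            a=sn_doc["a"],
            b=sn_doc["b"],
            n_failures=sn_doc["n_failures"],
            residual_sd=sn_doc["residual_sd"],
            endurance_fraction_at_5M=sn_doc["endurance_fraction_at_5M"],
            ci95=tuple(sn_doc["ci95"]) if sn_doc["ci95"] else None,
        )
        return cls(
            corrections=corrections,
            offset=OffsetCriterion(doc["offset_u_ult_pl_mm"]),
            maps=maps,
            sn=sn,
            provenance=doc.get("provenance", {}),
            schema_version=doc.get("schema_version", 1),
        )


def _offset_load(curve: Curve, criterion: OffsetCriterion) -> float:
    return ultimate_load_offset(curve, estimate_stiffness(curve), criterion).F_ult


def run_calibration(
    study,
    offset_grid=None,
    n_boot: int = 1000,
    seed: int = 0,
    pooled_map: bool = False,
) -> CalibrationBundle:
    """Fit every component of the prediction chain on the calibration set.

    Steps: (i) per-cell-type porosity corrections from the scan porosity
    records; (ii) offset-threshold calibration maximizing R^2 between
    scan-based virtual ultimates and the paired experimental ultimates;
    (iii) per-strategy, per-cell-type linear maps (per-specimen pairing);
    (iv) the pooled S-N fit with a bootstrap CI. Provenance (design ids,
    seeds) is recorded in the bundle.
    """
    cal_ids = list(study.calibration_ids)
    cal = [study.designs[i] for i in cal_ids]
    for d in cal:
        if not d.exp_curves or not d.virtual_curves:
            raise ValueError(f"design {d.design_id} is missing curve inputs")
    required_cts = {study.designs[i].cell_type for i in study.designs}
    cal_cts = {d.cell_type for d in cal}
    missing = required_cts - cal_cts
    if missing:
        raise ValueError(
            "calibration set missing cell type(s) "
            + ", ".join(ct.value for ct in missing)
            + ": cannot fit their linear maps"
        )

    corrections = {
        ct.value: fit_porosity_correction(study.porosity_records(cal_ids), ct)
        for ct in cal_cts
    }

    # offset threshold: scan-based virtual curves vs paired experimental
    # ultimates (max-force criterion on the experimental side)
    sim_curves, exp_ults = [], []
    for d in cal:
        exp_u = [ultimate_load_max(c).F_ult for c in d.exp_curves]
        for c, fe in zip(d.virtual_curves["scan"], exp_u):
            sim_curves.append(c)
            exp_ults.append(fe)
    offset, offset_trace = calibrate_offset_threshold(sim_curves, exp_ults, offset_grid)

    maps: dict[str, dict[str, LinearMap]] = {}
    for strat in STRATEGIES:
        pairs_by_ct: dict[str, list] = {}
        for d in cal:
            exp_u = [ultimate_load_max(c).F_ult for c in d.exp_curves]
            curves = d.virtual_curves[strat]
            if strat == "scan":
                fe_vals = [_offset_load(c, offset) for c in curves]
                new = list(zip(fe_vals, exp_u))
            else:
                v = _offset_load(curves[0], offset)
                new = [(v, e) for e in exp_u]
            pairs_by_ct.setdefault(d.cell_type.value, []).extend(new)
        if pooled_map:
            all_pairs = [p for ps in pairs_by_ct.values() for p in ps]
            maps[strat] = {"pooled": fit_linear_map(all_pairs, None)}
        else:
            maps[strat] = {
                ct: fit_linear_map(ps, ct) for ct, ps in pairs_by_ct.items()
            }

    cal_obs = [o for o in study.observations if o.design_id in cal_ids]
    sn = fit_sn(cal_obs)
    sn.ci95 = endurance_ci(cal_obs, n_boot=n_boot, seed=seed)

    bundle = CalibrationBundle(
        corrections=corrections,
        offset=offset,
        maps=maps,
        sn=sn,
        provenance={
            "calibration_ids": cal_ids,
            "study_seed": study.seed,
            "bootstrap_seed": seed,
            "offset_trace_best_r2": float(offset_trace["r2"].max()),
        },
    )
    return bundle


def run_validation(
    bundle: CalibrationBundle,
    study,
    strategy: str = "adjusted",
    band: tuple[float, float] = (0.10, 0.15),
) -> pd.DataFrame:
    """Predict and score every validation design under one geometry strategy.

    The validation set must be disjoint from the bundle's calibration
    provenance (leakage guard). Scan-strategy virtual ultimates average the
    per-specimen curves. Returns one row per design with the prediction,
    the experimental reference, the relative error and band membership.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    val_ids = list(study.validation_ids)
    overlap = set(val_ids) & set(bundle.provenance.get("calibration_ids", []))
    if overlap:
        raise ValueError(
            f"leakage: validation design(s) {sorted(overlap)} appear in the "
            "calibration provenance"
        )
    rows = []
    for did in val_ids:
        d = study.designs[did]
        curves = d.virtual_curves.get(strategy)
        if not curves:
            raise ValueError(f"no {strategy!r} virtual curves for design {did}")
        F_fe = float(np.mean([_offset_load(c, bundle.offset) for c in curves]))
        by_ct = bundle.maps[strategy]
        lmap = by_ct.get("pooled") or by_ct.get(d.cell_type.value)
        if lmap is None:
            raise ValueError(f"no linear map for cell type {d.cell_type.value}")
        result = predict_endurance(
            F_fe, lmap, bundle.sn, design_id=did, cell_type=d.cell_type
            if lmap.cell_type is not None else None, band=band,
        )
        record = validate_prediction(result, d.F_ult_exp, band)
        record["strategy"] = strategy
        rows.append(record)
    return pd.DataFrame(rows)


def strategy_comparison(
    bundle: CalibrationBundle, study, band=(0.10, 0.15)
) -> pd.DataFrame:
    """Validation report for all three strategies, concatenated."""
    return pd.concat(
        [run_validation(bundle, study, s, band) for s in STRATEGIES],
        ignore_index=True,
    )
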