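"""Normalized S-N power-law fatigue fitting with runout censoring.

The workflow's core fatigue assumption is that the normalized cyclic load
``F_cyclic / F_ult_exp`` follows one power law for all porous designs:

    F_cyclic / F_ult_exp = a * N_f ** b                       (S-N law)

with ``N_f`` the number of cycles to failure. Specimens enduring five
million cycles are runouts (right-censored per the ISO 14801 survival
definition) and are excluded from the fit; the fit itself is ordinary
least squares of ``ln(normalized load)`` on ``ln(N_f)`` over failures.
The endurance limit is the extrapolated normalized load at 5e6 cycles,
``a * (5e6) ** b``, with a percentile-bootstrap confidence interval
(stratified by load level) and a delta-method alternative for
cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CENSOR_LIMIT",
    "DEFAULT_LEVEL_FRACTIONS",
    "FatigueObservation",
    "LoadPlan",
    "SNFit",
    "plan_load_levels",
    "normalize",
    "fit_sn",
    "endurance_fraction",
    "endurance_ci",
    "endurance_ci_delta",
    "classify_survival",
    "observations_to_frame",
]

CENSOR_LIMIT = 5_000_000  # cycles; ISO 14801 survival definition
DEFAULT_LEVEL_FRACTIONS = (0.50, 0.35, 0.25, 0.20, 0.15, 0.10)


@dataclass
class FatigueObservation:
    """One fatigue test: peak cyclic load, cycles, and censoring status."""

    design_id: str
    F_cyclic: float  # N, peak of the cyclic load
    N_f: float  # cycles (to failure, or censor limit for runouts)
    runout: bool
    F_ult_exp: float | None = None  # design's monotonic ultimate, N

    def __post_init__(self):
        if self.F_cyclic <= 0:
            raise ValueError("F_cyclic must be positive")
        if self.N_f < 1:
            raise ValueError("N_f must be >= 1")
        if self.runout and self.N_f < CENSOR_LIMIT:
            raise ValueError("a runout must have N_f at the censor limit")

    @property
    def normalized_load(self) -> float:
        if self.F_ult_exp is None:
            raise ValueError(f"no ultimate load attached for {self.design_id}")
        return self.F_cyclic / self.F_ult_exp


@dataclass
class LoadPlan:
    """ISO-style fatigue load plan: levels as fractions of the ultimate."""

    levels: list[tuple[float, float]]  # (fraction, load N rounded to 10 N)
    R_ratio: float = 0.1
    frequency_hz: float = 15.0
    replicates_per_level: int = 4


@dataclass
class SNFit:
    """Fitted power-law parameters with diagnostics."""

    a: float
    b: float
    n_failures: int
    residual_sd: float  # natural-log scale
    endurance_fraction_at_5M: float = field(default=np.nan)
    ci95: tuple[float, float] | None = None

    def __post_init__(self):
        if self.b >= 0:
            warnings.warn(
                f"fitted exponent b = {self.b:.3g} is non-negative; fatigue "
                "life should decrease with load",
                stacklevel=3,
            )
        if np.isnan(self.endurance_fraction_at_5M):
            self.endurance_fraction_at_5M = float(self.a * CENSOR_LIMIT**self.b)


def _round_to_10(x: float) -> float:
    """Nearest 10 N, halves away from zero."""
    return float(np.floor(x / 10.0 + 0.5) * 10.0)


def plan_load_levels(F_ult: float, fractions=DEFAULT_LEVEL_FRACTIONS) -> LoadPlan:
    """Load levels as fractions of the ultimate, rounded to the nearest 10 N."""
    if F_ult <= 0:
        raise ValueError("F_ult must be positive")
    levels = [(float(f), _round_to_10(f * F_ult)) for f in fractions]
    if any(load <= 0 for _, load in levels):
        raise ValueError("degenerate load plan: a level rounded to 0 N")
    return LoadPlan(levels=levels)


def normalize(
    observations: list[FatigueObservation], ultimates: dict[str, float]
) -> list[FatigueObservation]:
    """Attach each design's experimental ultimate so loads pool across designs."""
    out = []
    for obs in observations:
        if obs.design_id not in ultimates:
            raise KeyError(f"no ultimate load for design {obs.design_id!r}")
        out.append(
            FatigueObservation(
                design_id=obs.design_id,
                F_cyclic=obs.F_cyclic,
                N_f=obs.N_f,
                runout=obs.runout,
                F_ult_exp=float(ultimates[obs.design_id]),
            )
        )
    return out


def classify_survival(obs: FatigueObservation) -> str:
    """'runout' iff the specimen endured the censor limit, else 'failure'."""
    if obs.N_f > CENSOR_LIMIT and not obs.runout:
        raise ValueError(
            f"inconsistent observation: N_f = {obs.N_f} exceeds the censor "
            "limit but is not flagged as a runout"
        )
    return "runout" if obs.runout or obs.N_f >= CENSOR_LIMIT else "failure"


def _failures(observations: list[FatigueObservation]):
    fails = [o for o in observations if classify_survival(o) == "failure"]
    x = np.array([np.log(o.N_f) for o in fails])
    y = np.array([np.log(o.normalized_load) for o in fails])
    return fails, x, y


def fit_sn(
    observations: list[FatigueObservation], direction: str = "life_on_load"
) -> SNFit:
    """Failures-only log-log least-squares fit of the S-N power law.

    Runouts are censored: they never enter the fit (but callers keep them
    for plotting and validation). Requires >= 3 failures spanning >= 2
    distinct normalized load levels.

    ``direction`` selects which variable carries the residuals:

    * ``"life_on_load"`` (default): regress ln(N_f) on ln(normalized load)
      and invert to (a, b). Load is the controlled variable and life the
      random one, so this is the standard fatigue-analysis convention
      (ASTM E739 style) and is unbiased under lognormal life scatter.
    * ``"load_on_life"``: regress ln(normalized load) on ln(N_f) directly.
      With scatter in life this attenuates |b| (errors-in-variables), but
      it is the literal reading of the power law with load on the left;
      provided for comparison.
    """
    fails, x, y = _failures(observations)
    if len(fails) < 3:
        raise ValueError(f"need >= 3 failures to fit, got {len(fails)}")
    if len(np.unique(np.round(y, 9))) < 2:
        raise ValueError("failures span a single load level; slope is undefined")
    if direction == "life_on_load":
        res = stats.linregress(y, x)  # ln N = alpha + beta ln S
        if res.slope == 0:
            raise ValueError("degenerate fit: zero slope of life on load")
        b = float(1.0 / res.slope)
        a = float(np.exp(-res.intercept / res.slope))
        resid = x - (res.intercept + res.slope * y)  # residuals in ln N
    elif direction == "load_on_life":
        res = stats.linregress(x, y)
        a = float(np.exp(res.intercept))
        b = float(res.slope)
        resid = y - (res.intercept + b * x)
    else:
        raise ValueError(f"unknown fit direction {direction!r}")
    dof = max(len(fails) - 2, 1)
    fit = SNFit(
        a=a,
        b=b,
        n_failures=len(fails),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    fit.endurance_fraction_at_5M = endurance_fraction(fit, CENSOR_LIMIT)
    return fit


def endurance_fraction(fit: SNFit, n_cycles: float = CENSOR_LIMIT) -> float:
    """Normalized endurance load ``a * n_cycles ** b``."""
    return float(fit.a * n_cycles**fit.b)


def _strata(observations):
    """Group observation indices by normalized load level."""
    keys = np.round([o.normalized_load for o in observations], 9)
    strata = {}
    for i, key in enumerate(keys):
        strata.setdefault(key, []).append(i)
    return [np.asarray(v) for v in strata.values()]


def endurance_ci(
    observations: list[FatigueObservation],
    n_cycles: float = CENSOR_LIMIT,
    n_boot: int = 2000,
    seed=None,
    max_retries: int = 100,
    direction: str = "life_on_load",
) -> tuple[float, float]:
    """95 % percentile-bootstrap CI for the endurance fraction.

    Observations are resampled with replacement within each normalized load
    level (stratified bootstrap), refit, and the endurance fraction
    re-evaluated; replicates whose failures collapse onto fewer than two
    levels are redrawn a bounded number of times and then skipped.
    """
    fit_sn(observations, direction)  # validate the data once up front
    rng = np.random.default_rng(seed)
    strata = _strata(observations)
    obs_arr = np.array(observations, dtype=object)
    estimates = []
    for _ in range(n_boot):
        for _retry in range(max_retries):
            idx = np.concatenate(
                [rng.choice(s, size=len(s), replace=True) for s in strata]
            )
            try:
                fit = fit_sn(list(obs_arr[idx]), direction)
            except ValueError:
                continue
            estimates.append(endurance_fraction(fit, n_cycles))
            break
    if not estimates:
        raise RuntimeError("no valid bootstrap replicate obtained")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def endurance_ci_delta(
    observations: list[FatigueObservation], n_cycles: float = CENSOR_LIMIT
) -> tuple[float, float]:
    """Delta-method 95 % CI on the endurance fraction (cross-check).

    In the life-on-load parameterisation ``ln N = alpha + beta ln S`` the
    log endurance fraction is ``ln S* = (ln n_cycles - alpha) / beta``; the
    prediction variance of the regression line at ``ln S*`` is mapped
    through the inverse slope (classical inverse-prediction delta
    approximation) and the interval exponentiated.
    """
    _, x, y = _failures(observations)  # x = ln N, y = ln S
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 failures")
    res = stats.linregress(y, x)  # ln N = alpha + beta ln S
    if res.slope == 0:
        raise ValueError("degenerate fit: zero slope")
    alpha, beta = res.intercept, res.slope
    resid = x - (alpha + beta * y)
    s2 = np.sum(resid**2) / (n - 2)
    syy = np.sum((y - y.mean()) ** 2)
    ln_n = np.log(n_cycles)
    ln_s = (ln_n - alpha) / beta
    # variance of the fitted mean ln N at ln S*, divided by slope^2
    var_mean = s2 * (1.0 / n + (ln_s - y.mean()) ** 2 / syy)
    sd_ln_s = np.sqrt(var_mean) / abs(beta)
    t = stats.t.ppf(0.975, n - 2)
    return float(np.exp(ln_s - t * sd_ln_s)), float(np.exp(ln_s + t * sd_ln_s))


def observations_to_frame(observations: list[FatigueObservation]) -> pd.DataFrame:
    """Fatigue table in the standard CSV layout."""
    rows = {
        "design_id": [o.design_id for o in observations],
        "F_cyclic_N": [o.F_cyclic for o in observations],
        "N_cycles": [o.N_f for o in observations],
        "runout": [int(o.runout) for o in observations],
    }
    if all(o.F_ult_exp is not None for o in observations):
        rows["F_ult_exp_N"] = [o.F_ult_exp for o in observations]
        rows["normalized_load"] = [o.normalized_load for o in observations]
    return pd.DataFrame(rows)
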