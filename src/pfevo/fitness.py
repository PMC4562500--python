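"""Cellular and population fitness of the PF stress-response circuit.

The division rate of a single cell is modelled as the product of two
relative factors applied to a drug-free maximal rate gamma0:

* ``gamma1(F, Z)`` -- zeocin toxicity.  External zeocin ``Z`` is taken up
  at rate ``k_in`` and cleared at ``k_out``; free internal zeocin
  ``Z_i`` binds the yEGFP::ZeoR protein (total ``F``, unbound ``R``,
  bound ``B``) at rate ``k_on``; complex turnover at ``k_off`` recycles
  the protein and neutralizes the bound antibiotic.  The steady-state
  free internal zeocin sets the kill term through a Hill function with
  constant ``K_z`` and coefficient ``h_z``.
* ``gamma2(F, C)`` -- inducer (doxycycline, ``C``) toxicity from rtTA
  squelching.  rtTA level is taken equal to the reporter level ``F``;
  its doxycycline-bound activity saturates with half-constant ``K_C``
  and poisons growth through a Hill term with constant ``K_d`` and
  coefficient ``h_d``.

Both algebraic forms are the package defaults calibrated to reproduce
the qualitative landscape shapes of the circuit (monotone decreasing in
inducer-only conditions, monotone increasing in zeocin-only conditions,
peaked when both drugs are present); they can be swapped for other
published forms by subclassing or replacing the ``gamma_*`` callables.

Expression ``F`` is in arbitrary fluorescence units; landscapes are
tabulated on a log10(F) grid over [0, 4].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .environment import Environment

__all__ = [
    "FitnessParams",
    "ExpressionModes",
    "BindingState",
    "bound_zeocin_steady_state",
    "gamma_zeocin",
    "gamma_dox",
    "cellular_fitness",
    "population_fitness",
    "expression_grid",
    "ExpressionGrid",
    "fit_fitness_params",
    "FitDiagnostics",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FitnessParams:
    """Parameters of the fitness landscape model (rates per hour)."""

    gamma0: float = 0.25       # maximal division rate, /h (galactose medium)
    # zeocin submodel
    k_in: float = 1.0          # uptake, /h per external unit
    k_out: float = 1.0         # clearance, /h
    k_on: float = 1.0          # binding, /h per protein unit
    k_off: float = 1.0         # complex turnover (protein recycling), /h
    K_z: float = 0.1           # kill half-constant, internal zeocin units
    h_z: float = 2.0           # kill Hill coefficient
    # doxycycline submodel
    K_C: float = 0.6           # dox half-saturation, ug/ml
    K_d: float = 500.0         # squelching toxicity constant, protein units
    h_d: float = 2.0           # squelching Hill coefficient

    def __post_init__(self) -> None:
        for name in ("gamma0", "k_in", "k_out", "k_on", "k_off", "K_z", "K_C", "K_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.h_z < 1 or self.h_d < 1:
            raise ValueError("Hill coefficients must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessParams":
        return cls(**d)


@dataclass(frozen=True)
class ExpressionModes:
    """Locations of the Off/On fluorescence modes, log10 arbitrary units."""

    off_log10: float = 1.0
    on_log10: float = 3.0
    sd_log10: float = 0.25

    @property
    def f_off(self) -> float:
        return 10.0 ** self.off_log10

    @property
    def f_on(self) -> float:
        return 10.0 ** self.on_log10


@dataclass(frozen=True)
class BindingState:
    """Steady state of the zeocin uptake/binding submodel."""

    Z_ext: float
    Z_int: float   # free internal zeocin
    B: float       # bound yEGFP::ZeoR
    R: float       # unbound yEGFP::ZeoR

    @property
    def F(self) -> float:
        return self.B + self.R


def _check_finite_nonneg(**kwargs: float) -> None:
    for name, val in kwargs.items():
        arr = np.asarray(val, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite, got {val!r}")
        if np.any(arr < 0):
            raise ValueError(f"{name} must be >= 0, got {val!r}")


def steady_state_internal_zeocin(F, Z, params: FitnessParams):
    """Free internal zeocin at the uptake/binding steady state.

    Solves the unique non-negative root of
    ``k_out*k_on*Zi^2 + (k_off*(k_out + k_on*F) - k_in*k_on*Z)*Zi
    - k_in*k_off*Z = 0``.  Vectorized over F and Z.
    """
    F = np.asarray(F, dtype=float)
    Z = np.asarray(Z, dtype=float)
    p = params
    a = p.k_out * p.k_on
    b = p.k_off * (p.k_out + p.k_on * F) - p.k_in * p.k_on * Z
    c = -p.k_in * p.k_off * Z
    disc = b * b - 4.0 * a * c
    # c <= 0 guarantees disc >= b^2 >= 0 and a single non-negative root
    zi = (-b + np.sqrt(disc)) / (2.0 * a)
    return np.maximum(zi, 0.0)


def bound_zeocin_steady_state(F: float, Z: float, params: FitnessParams) -> BindingState:
    """Steady state of internal zeocin and bound/unbound protein.

    Satisfies dZ_int/dt = dB/dt = 0 for the uptake/binding model and
    conserves protein (B + R = F).
    """
    _check_finite_nonneg(F=F, Z=Z)
    zi = float(steady_state_internal_zeocin(F, Z, params))
    if not math.isfinite(zi):
        raise ArithmeticError(f"steady-state solve failed for F={F}, Z={Z}")
    B = params.k_on * zi * F / (params.k_off + params.k_on * zi)
    return BindingState(Z_ext=float(Z), Z_int=zi, B=B, R=float(F) - B)


def gamma_zeocin(F, Z, params: FitnessParams, resistance_multiplier=1.0):
    """Relative fitness factor gamma1 in (0, 1] from zeocin toxicity.

    ``resistance_multiplier`` scales the kill half-constant K_z upward
    (generic-resistance mutations); 1 for the ancestral genotype.
    """
    _check_finite_nonneg(F=F, Z=Z)
    zi = steady_state_internal_zeocin(F, Z, params)
    kz = params.K_z * np.asarray(resistance_multiplier, dtype=float)
    return 1.0 / (1.0 + (zi / kz) ** params.h_z)


def gamma_dox(F, C, params: FitnessParams):
    """Relative fitness factor gamma2 in (0, 1] from rtTA squelching."""
    _check_finite_nonneg(F=F, C=C)
    F = np.asarray(F, dtype=float)
    C = np.asarray(C, dtype=float)
    activity = F * np.divide(C, C + params.K_C, out=np.zeros_like(C + F, dtype=float),
                             where=(C + params.K_C) > 0)
    return 1.0 / (1.0 + (activity / params.K_d) ** params.h_d)


def cellular_fitness(F, env: Environment, params: FitnessParams,
                     resistance_multiplier=1.0):
    """Single-cell division rate (per hour) at expression level F in env.

    Equals ``gamma0 * gamma1 * gamma2``; gamma0 exactly when both drug
    factors are 1 (e.g. the D0Z0 control).
    """
    if not isinstance(env, Environment):
        raise TypeError("env must be an Environment")
    g1 = gamma_zeocin(F, env.zeo, params, resistance_multiplier)
    g2 = gamma_dox(F, env.dox, params)
    return params.gamma0 * g1 * g2


def population_fitness(expr_sample, env: Environment, params: FitnessParams) -> float:
    """Mean division rate over a sample of log10-fluorescence values."""
    x = np.asarray(expr_sample, dtype=float)
    if x.size == 0:
        raise ValueError("expression sample must be non-empty")
    return float(np.mean(cellular_fitness(10.0 ** x, env, params)))


@dataclass(frozen=True)
class ExpressionGrid:
    """Cellular fitness tabulated on an ascending log10-expression grid."""

    log10_F: np.ndarray
    fitness: np.ndarray

    def argmax_log10(self) -> float:
        return float(self.log10_F[int(np.argmax(self.fitness))])


def expression_grid(env: Environment, params: FitnessParams,
                    lo: float = 0.0, hi: float = 4.0, n: int = 201) -> ExpressionGrid:
    """Evaluate the cellular fitness landscape on a log10(F) grid."""
    x = np.linspace(lo, hi, n)
    fit = cellular_fitness(10.0 ** x, env, params)
    return ExpressionGrid(log10_F=x, fitness=np.asarray(fit, dtype=float))


def landscape_table(envs: Sequence[Environment], params: FitnessParams,
                    **grid_kw) -> pd.DataFrame:
    """Tidy landscape export: condition, log10_F, fitness_per_h."""
    rows = []
    for env in envs:
        g = expression_grid(env, params, **grid_kw)
        rows.append(pd.DataFrame({
            "condition": env.label, "log10_F": g.log10_F, "fitness_per_h": g.fitness,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

@dataclass
class FitDiagnostics:
    cost: float
    n_conditions: int
    success: bool
    message: str
    unidentifiable: tuple[str, ...] = ()
    rates: pd.DataFrame | None = None


_FIT_NAMES = ("gamma0", "K_z", "h_z", "K_C", "K_d", "h_d")
_FIT_BOUNDS_LO = np.array([1e-3, 1e-4, 1.0, 1e-3, 1.0, 1.0])
_FIT_BOUNDS_HI = np.array([5.0, 1e2, 6.0, 1e2, 1e6, 6.0])

# fixed multi-start grid (log-spaced perturbations of a nominal guess)
_START_SCALES = [
    (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    (0.5, 0.3, 1.0, 0.3, 0.2, 1.0),
    (2.0, 3.0, 1.0, 3.0, 5.0, 1.0),
    (1.0, 0.1, 1.5, 1.0, 1.0, 0.75),
    (1.0, 10.0, 0.75, 1.0, 0.1, 1.5),
    (0.7, 1.0, 1.25, 0.1, 10.0, 1.0),
    (1.5, 0.3, 1.0, 10.0, 0.3, 1.25),
    (1.0, 3.0, 1.25, 0.5, 2.0, 0.6),
]


def _pack(params: FitnessParams) -> np.ndarray:
    vec = np.array([getattr(params, n) for n in _FIT_NAMES], dtype=float)
    return np.log(vec)


def _unpack(logvec: np.ndarray, template: FitnessParams) -> FitnessParams:
    vals = np.exp(logvec)
    vals[[2, 5]] = np.maximum(vals[[2, 5]], 1.0)  # Hill coefficients >= 1
    return replace(template, **dict(zip(_FIT_NAMES, vals)))


def growth_rates_from_curves(curves: pd.DataFrame) -> pd.DataFrame:
    """Exponential growth rate per condition from a growth-curve table.

    Expects columns time_h, od (or cell_count), dox_ug_ml, zeo_mg_ml and
    optionally replicate; rates are max-R2 sliding-window log-linear
    slopes averaged over replicates.
    """
    from .phenotyping import growth_rate_from_curve

    dens_col = "od" if "od" in curves.columns else "cell_count"
    required = {"time_h", dens_col, "dox_ug_ml", "zeo_mg_ml"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"growth-curve table missing columns: {sorted(missing)}")
    group_cols = ["dox_ug_ml", "zeo_mg_ml"]
    if "replicate" in curves.columns:
        group_cols.append("replicate")
    rows = []
    for key, grp in curves.groupby(group_cols, sort=True):
        rate, _, r2 = growth_rate_from_curve(
            grp.rename(columns={dens_col: "density"})[["time_h", "density"]])
        rows.append(dict(zip(group_cols, np.atleast_1d(key))) | {"rate_per_h": rate, "r2": r2})
    df = pd.DataFrame(rows)
    return (df.groupby(["dox_ug_ml", "zeo_mg_ml"], as_index=False)["rate_per_h"]
              .mean())


def fit_fitness_params(
    curves: pd.DataFrame,
    expr: pd.DataFrame,
    template: FitnessParams | None = None,
    weights: np.ndarray | None = None,
    max_cells_per_condition: int = 2000,
) -> tuple[FitnessParams, FitDiagnostics]:
    """Fit landscape parameters to growth rates across a drug grid.

    Parameters
    ----------
    curves : DataFrame
        Growth curves with columns time_h, od (or cell_count),
        dox_ug_ml, zeo_mg_ml, replicate.
    expr : DataFrame
        Expression samples with columns condition_label and
        log10_fluorescence (timepoint_day ignored here); one sample per
        condition present in ``curves``.

    The observed rate per condition is compared with the population
    fitness predicted from the condition's expression sample; weighted
    least squares with 8 fixed multi-starts (deterministic).
    """
    template = template or FitnessParams()
    rates = growth_rates_from_curves(curves)
    n_zeo = rates["zeo_mg_ml"].nunique()
    n_dox = rates["dox_ug_ml"].nunique()
    if len(rates) < 2 or (n_zeo < 2 and n_dox < 2):
        raise ValueError("degenerate design: need >= 2 dox or zeocin levels")

    unident = []
    if (rates["zeo_mg_ml"] == 0).all():
        unident += ["k_in", "k_out", "k_on", "k_off", "K_z", "h_z"]
    if (rates["dox_ug_ml"] == 0).all():
        unident += ["K_C", "K_d", "h_d"]

    samples = {}
    for _, row in rates.iterrows():
        label = Environment(row["dox_ug_ml"], row["zeo_mg_ml"]).label
        sub = expr.loc[expr["condition_label"] == label, "log10_fluorescence"].to_numpy()
        if sub.size == 0:
            raise ValueError(f"no expression sample for condition {label}")
        if sub.size > max_cells_per_condition:
            # deterministic thinning keeps the fit reproducible
            idx = np.linspace(0, sub.size - 1, max_cells_per_condition).astype(int)
            sub = np.sort(sub)[idx]
        samples[label] = 10.0 ** sub

    obs = rates["rate_per_h"].to_numpy()
    envs = [Environment(d, z) for d, z in rates[["dox_ug_ml", "zeo_mg_ml"]].to_numpy()]
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)

    def residuals(logvec: np.ndarray) -> np.ndarray:
        p = _unpack(logvec, template)
        pred = np.array([
            np.mean(cellular_fitness(samples[e.label], e, p)) for e in envs
        ])
        return np.sqrt(w) * (pred - obs)

    x0 = _pack(template)
    best = None
    for scales in _START_SCALES:
        start = x0 + np.log(np.asarray(scales))
        start = np.clip(start, np.log(_FIT_BOUNDS_LO), np.log(_FIT_BOUNDS_HI))
        try:
            sol = least_squares(residuals, start, method="trf",
                                bounds=(np.log(_FIT_BOUNDS_LO), np.log(_FIT_BOUNDS_HI)),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ArithmeticError("landscape fit failed from every start")

    fitted = _unpack(best.x, template)
    diag = FitDiagnostics(cost=float(best.cost), n_conditions=len(rates),
                          success=bool(best.success), message=str(best.message),
                          unidentifiable=tuple(unident), rates=rates)
    return fitted, diag
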