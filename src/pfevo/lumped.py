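"""Lumped constant-population ODE model of the first evolutionary steps.

The population is split into the ancestral class and three lumped mutant
classes -- knockout (K), tweaking (T) and generic-resistance (G) -- each
characterized only by a fitness (exponential growth rate).  Fractions
evolve under replicator dynamics with a constant mutational influx from
the ancestral class:

    dx_anc/dt = (g_anc - gbar) x_anc - mu_h x_anc
    dx_i/dt   = (g_i   - gbar) x_i   + mu_h p_i x_anc

where gbar is the population mean fitness and mu_h converts the
per-genome per-generation beneficial-mutation rate to per hour through
the ancestral division rate (generations per hour = g_anc / ln 2).
Mutant classes neither back-mutate nor mutate further (single-step
model of the initial adaptation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .environment import Environment
from .fitness import FitnessParams, ExpressionModes, cellular_fitness
from .switching import SwitchingParams, dominant_growth_rate

__all__ = [
    "MutationSpec",
    "class_fitness",
    "ancestral_fitness",
    "simulate_lumped",
    "ancestral_half_life",
    "HALF_LIFE_NOT_REACHED",
]

LN2 = math.log(2.0)

#: Sentinel for trajectories whose ancestral fraction never drops below 0.5.
HALF_LIFE_NOT_REACHED = float("inf")

CLASSES = ("anc", "K", "T", "G")


@dataclass(frozen=True)
class MutationSpec:
    """Beneficial-mutation rate and type probabilities.

    ``p_K`` is derived from the normalization P(K) = 1 - P(G) - P(T).
    """

    mu: float = 10.0 ** -6.2   # per genome per generation
    p_T: float = 0.025
    p_G: float = 0.75

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0 <= self.p_T <= 1 and 0 <= self.p_G <= 1 and self.p_T + self.p_G <= 1):
            raise ValueError("type probabilities must lie in [0,1] and sum to <= 1")

    @property
    def p_K(self) -> float:
        return 1.0 - self.p_G - self.p_T

    @property
    def probabilities(self) -> dict[str, float]:
        return {"K": self.p_K, "T": self.p_T, "G": self.p_G}


def ancestral_fitness(env: Environment, params: FitnessParams,
                      switching: SwitchingParams,
                      modes: ExpressionModes | None = None) -> float:
    """Long-run ancestral growth rate: dominant eigenvalue of the
    two-state system with environment-specific state fitnesses."""
    modes = modes or ExpressionModes()
    g_L = float(cellular_fitness(modes.f_off, env, params))
    r = switching.r_of_dox(env.dox)
    if r <= 0:
        # cultures start Off; without induction the On state is unreachable
        return g_L
    g_H = float(cellular_fitness(modes.f_on, env, params))
    p = SwitchingParams(g_L=g_L, g_H=g_H, r=r, f=switching.f, r_max=None)
    return dominant_growth_rate(p)


def class_fitness(mut_type: str, env: Environment, params: FitnessParams,
                  switching: SwitchingParams,
                  modes: ExpressionModes | None = None,
                  rng: np.random.Generator | None = None,
                  n_expectation: int = 201) -> float:
    """Fitness of a lumped mutant class in an environment (per hour).

    * ``K`` -- deterministic: cellular fitness at null (basal Off-mode)
      expression; a knockout cannot switch On.
    * ``T`` -- a draw (``rng`` given) or the expectation (default) of
      cellular fitness over the intermediate-expression range, uniform
      in log10 F between the Off and On modes.  Without inducer the
      circuit cannot express, so the range collapses to the Off mode.
    * ``G`` -- a draw or expectation uniform between the ancestral
      fitness and the fitness the same genotype would have with zeocin
      removed.
    """
    modes = modes or ExpressionModes()
    g_anc = ancestral_fitness(env, params, switching, modes)
    if mut_type == "anc":
        return g_anc
    if mut_type == "K":
        return float(cellular_fitness(modes.f_off, env, params))
    if mut_type == "T":
        if switching.r_of_dox(env.dox) <= 0:
            # no induction: a tweaked circuit stays basal, like the ancestor
            return float(cellular_fitness(modes.f_off, env, params))
        lo, hi = modes.off_log10, modes.on_log10
        if rng is not None:
            x = rng.uniform(lo, hi)
            return float(cellular_fitness(10.0 ** x, env, params))
        xs = np.linspace(lo, hi, n_expectation)
        return float(np.mean(cellular_fitness(10.0 ** xs, env, params)))
    if mut_type == "G":
        hi = ancestral_fitness(env.without_zeocin(), params, switching, modes)
        hi = max(hi, g_anc)
        if rng is not None:
            return float(rng.uniform(g_anc, hi))
        return 0.5 * (g_anc + hi)
    raise ValueError(f"unknown mutation type: {mut_type!r}")


def class_fitnesses(env: Environment, params: FitnessParams,
                    switching: SwitchingParams,
                    modes: ExpressionModes | None = None) -> dict[str, float]:
    """Expectation-mode fitness of every class in ``env``."""
    return {c: class_fitness(c, env, params, switching, modes) for c in CLASSES}


def simulate_lumped(
    spec: MutationSpec,
    fitnesses: dict[str, float],
    duration_days: float = 20.0,
    dt_out_h: float = 1.0,
    x0: dict[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate the lumped replicator/mutation ODE.

    Returns a tidy trajectory with columns time_day, x_anc, x_K, x_T,
    x_G; fractions sum to 1 at every output time.
    """
    if duration_days <= 0:
        raise ValueError("duration must be > 0")
    g = np.array([fitnesses[c] for c in CLASSES], dtype=float)
    p = np.array([0.0, spec.p_K, spec.p_T, spec.p_G], dtype=float)
    mu_h = spec.mu * fitnesses["anc"] / LN2  # per hour, via ancestral divisions

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        gbar = float(g @ x)
        dx = (g - gbar) * x
        influx = mu_h * x[0]
        dx[0] -= influx
        dx[1:] += influx * p[1:]
        return dx

    x_init = np.array([1.0, 0.0, 0.0, 0.0]) if x0 is None else \
        np.array([x0.get(c, 0.0) for c in CLASSES], dtype=float)
    x_init = x_init / x_init.sum()

    t_end = duration_days * 24.0
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out_h, dt_out_h)
    t_eval[-1] = min(t_eval[-1], t_end)
    sol = solve_ivp(rhs, (0.0, t_end), x_init, t_eval=t_eval,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise ArithmeticError(f"lumped-model integration failed: {sol.message}")
    x = np.clip(sol.y.T, 0.0, 1.0)
    x = x / x.sum(axis=1, keepdims=True)
    return pd.DataFrame({
        "time_day": sol.t / 24.0,
        "x_anc": x[:, 0], "x_K": x[:, 1], "x_T": x[:, 2], "x_G": x[:, 3],
    })


def ancestral_half_life(trajectory: pd.DataFrame) -> float:
    """Days until the ancestral fraction first drops below 0.5.

    Linear interpolation between output times; returns
    ``HALF_LIFE_NOT_REACHED`` (inf) when x_anc stays >= 0.5 throughout.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    t = trajectory["time_day"].to_numpy(dtype=float)
    x = trajectory["x_anc"].to_numpy(dtype=float)
    below = np.nonzero(x < 0.5)[0]
    if below.size == 0:
        return HALF_LIFE_NOT_REACHED
    i = below[0]
    if i == 0:
        return float(t[0])
    # linear crossing between samples i-1 and i
    frac = (x[i - 1] - 0.5) / (x[i - 1] - x[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
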