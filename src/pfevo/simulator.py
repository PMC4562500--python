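"""Detailed stochastic simulation of PF-circuit experimental evolution.

Allele-level population dynamics with Off/On phenotype switching,
gradual drug uptake, mutation entry as single cells, and periodic
resuspension bottlenecks:

* Every mutational lineage (allele) carries Off/On cell counts.  Large
  lineages (>= ``stochastic_size_threshold`` cells) advance by the
  exact two-state matrix exponential; small lineages advance by
  per-step binomial division / death / switch events, so single-cell
  establishment and loss experience genuine drift.
* Division and death rates decompose the landscape product
  ``gamma0 * gamma1 * gamma2``: squelching toxicity (gamma2) slows
  division, unbound zeocin (1 - gamma1) kills, so the net rate equals
  the cellular fitness.
* Mutations enter the ancestral background as single cells at rate mu
  per genome per generation (Poisson in the realized ancestral
  divisions); mu is condition dependent (higher with zeocin).  Types:
  K (knockout; cannot switch On, collapses to basal expression),
  T (tweaking; a single parameter theta in (0,1) scales the Off->On
  rate and proportionally lowers the On-state expression, i.e. a
  partial loss of rtTA activity and toxicity), and
  G (generic resistance; the zeocin kill constant is scaled up so the
  drawn fitness gain is uniform between the current and the
  zeocin-free fitness, never exceeding the latter).
* Every ``resuspension_interval_h`` hours the culture is diluted
  multinomially back to the bottleneck size into fresh medium;
  internalized drug persists through resuspension.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environment import Environment
from .fitness import (FitnessParams, ExpressionModes, gamma_dox,
                      steady_state_internal_zeocin)
from .lumped import MutationSpec, ancestral_half_life, HALF_LIFE_NOT_REACHED
from .switching import SwitchingParams, expm2_entries as _expm2_entries

__all__ = [
    "SimConfig", "SummaryStats", "EnsembleSummary", "PopulationState",
    "Simulator", "stochastic_step", "summarize_ensemble",
]

LN2 = math.log(2.0)

MUT_ANC, MUT_K, MUT_T, MUT_G = 0, 1, 2, 3
TYPE_NAMES = {MUT_ANC: "ancestral", MUT_K: "K", MUT_T: "T", MUT_G: "G"}


@dataclass(frozen=True)
class SimConfig:
    """Run settings of the detailed simulator."""

    mu_no_z: float = 10.0 ** -6.2    # beneficial-mutation rate, no zeocin
    mu_with_z: float = 10.0 ** -5.4  # with zeocin (DNA damage)
    p_T: float = 0.025
    p_G: float = 0.75
    bottleneck: float = 1e6          # resuspension target size, cells
    resuspension_interval_h: float = 12.0
    duration_days: float = 20.0
    n_replicates: int = 100
    established_threshold: float = 0.05   # day-20 frequency for "established"
    stochastic_size_threshold: float = 1000.0  # cells; below -> stochastic
    dt_h: float = 0.1
    initial_population: float = 1e6
    dox_uptake_rate: float = 1.0     # /h, internal relaxation to external
    zeo_uptake_rate: float = 0.5     # /h
    zeocin_death_share: float = 0.0  # fraction of zeocin toxicity as death
    resistance_cap_epsilon: float = 0.01  # G cap: gamma1 reaches 1 - epsilon
    deterministic_resuspension: bool = False  # exact scaling instead of sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_T <= 1 and 0 <= self.p_G <= 1
                and self.p_T + self.p_G <= 1):
            raise ValueError("type probabilities must lie in [0,1], sum <= 1")
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")
        if not (0 < self.established_threshold < 1):
            raise ValueError("established threshold must be in (0,1)")

    @property
    def p_K(self) -> float:
        return 1.0 - self.p_G - self.p_T

    def mu(self, env: Environment) -> float:
        return self.mu_with_z if env.zeo > 0 else self.mu_no_z

    def mutation_spec(self, env: Environment) -> MutationSpec:
        return MutationSpec(mu=self.mu(env), p_T=self.p_T, p_G=self.p_G)


class PopulationState:
    """Structure-of-arrays population: one row per surviving allele.

    Row 0 is always the ancestral lineage.  ``n_L``/``n_H`` hold Off/On
    cell counts (floats; integer-valued for stochastic lineages).
    """

    __slots__ = ("ids", "mut_type", "r_mult", "res_u", "res_mult",
                 "log10_f_on", "t_origin", "preexisting", "n_L", "n_H",
                 "stoch", "C_int", "Z_int", "t_h", "divisions", "next_id",
                 "extinct", "_cache")

    def __init__(self, n0_off: float, n0_on: float = 0.0,
                 on_log10: float = 3.0) -> None:
        self.ids = np.array([0], dtype=np.int64)
        self.mut_type = np.array([MUT_ANC], dtype=np.int8)
        self.r_mult = np.array([1.0])
        self.res_u = np.array([0.0])
        self.res_mult = np.array([1.0])
        self.log10_f_on = np.array([on_log10])
        self.t_origin = np.array([0.0])
        self.preexisting = np.array([False])
        self.n_L = np.array([float(n0_off)])
        self.n_H = np.array([float(n0_on)])
        self.stoch = np.array([False])
        self.C_int = 0.0    # internal effective doxycycline, ug/ml
        self.Z_int = 0.0    # internal effective zeocin, mg/ml
        self.t_h = 0.0
        self.divisions = 0.0
        self.next_id = 1
        self.extinct = False
        self._cache = None   # per-allele rate cache, managed by Simulator

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_alleles(self) -> int:
        return len(self.ids)

    @property
    def totals(self) -> np.ndarray:
        return self.n_L + self.n_H

    @property
    def total(self) -> float:
        return float(self.totals.sum())

    def frequencies(self) -> np.ndarray:
        tot = self.total
        return self.totals / tot if tot > 0 else np.zeros(self.n_alleles)

    def ancestral_fraction(self) -> float:
        tot = self.total
        return float(self.totals[0] / tot) if tot > 0 else 0.0

    def append(self, **rows) -> None:
        n = len(rows["ids"])
        self._cache = None
        self.ids = np.concatenate([self.ids, rows["ids"]])
        self.mut_type = np.concatenate([self.mut_type, rows["mut_type"]])
        self.r_mult = np.concatenate([self.r_mult, rows["r_mult"]])
        self.res_u = np.concatenate([self.res_u, rows["res_u"]])
        self.res_mult = np.concatenate([self.res_mult, rows["res_mult"]])
        self.log10_f_on = np.concatenate([self.log10_f_on, rows["log10_f_on"]])
        self.t_origin = np.concatenate([self.t_origin, np.full(n, self.t_h)])
        self.preexisting = np.concatenate([self.preexisting, rows["preexisting"]])
        self.n_L = np.concatenate([self.n_L, rows["n_L"]])
        self.n_H = np.concatenate([self.n_H, rows["n_H"]])
        self.stoch = np.concatenate([self.stoch, np.ones(n, dtype=bool)])

    def prune(self) -> None:
        """Drop extinct mutant lineages (ancestral row always kept)."""
        keep = self.totals > 0
        keep[0] = True
        if not keep.all():
            self._cache = None
            for name in ("ids", "mut_type", "r_mult", "res_u", "res_mult",
                         "log10_f_on", "t_origin", "preexisting",
                         "n_L", "n_H", "stoch"):
                setattr(self, name, getattr(self, name)[keep])


def stochastic_step(rng: np.random.Generator, n_L, n_H,
                    b_L, d_L, b_H, d_H, r, f, dt: float):
    """One binomial division/death/switch step for small lineages.

    Counts are integers; deaths first (per-cell probability
    1 - exp(-d*dt)), then divisions among survivors (probability
    exp(b*dt) - 1, which makes the mean growth factor exactly
    exp((b-d)*dt)), then switching.  Returns the updated (n_L, n_H) and
    the number of divisions realized per lineage.
    """
    n_L = np.asarray(n_L, dtype=np.int64)
    n_H = np.asarray(n_H, dtype=np.int64)
    p = lambda rate: -np.expm1(-np.asarray(rate, dtype=float) * dt)
    pdiv = lambda rate: np.minimum(np.expm1(np.asarray(rate, dtype=float) * dt), 1.0)

    die_L = rng.binomial(n_L, np.broadcast_to(p(d_L), n_L.shape))
    die_H = rng.binomial(n_H, np.broadcast_to(p(d_H), n_H.shape))
    sur_L = n_L - die_L
    sur_H = n_H - die_H
    div_L = rng.binomial(sur_L, np.broadcast_to(pdiv(b_L), n_L.shape))
    div_H = rng.binomial(sur_H, np.broadcast_to(pdiv(b_H), n_H.shape))
    n_L2 = sur_L + div_L
    n_H2 = sur_H + div_H
    sw_up = rng.binomial(n_L2, np.broadcast_to(p(r), n_L.shape))
    sw_dn = rng.binomial(n_H2, np.broadcast_to(p(f), n_H.shape))
    n_L2 = n_L2 - sw_up + sw_dn
    n_H2 = n_H2 + sw_up - sw_dn
    return n_L2, n_H2, div_L + div_H


@dataclass
class SummaryStats:
    """Per-replicate outcome of 20 days of simulated evolution."""

    half_life_days: float
    n_established: int
    type_fractions: dict[str, float]           # of total population, day 20
    mutant_fraction: float                     # 1 - ancestral, day 20
    preexisting_fraction: float = float("nan")  # mass-based, of mutant mass
    preexisting_allele_fraction: float = float("nan")  # count-based diagnostic
    extinct: bool = False


@dataclass
class EnsembleSummary:
    n_replicates: int
    half_life_mean: float
    half_life_sem: float
    fraction_half_life_reached: float
    n_established_mean: float
    n_established_sem: float
    type_fraction_mean: dict[str, float]
    type_fraction_sem: dict[str, float]
    preexisting_mean: float = float("nan")
    preexisting_sem: float = float("nan")


class Simulator:
    """Detailed evolutionary simulator for one parameterization."""

    def __init__(self, params: FitnessParams | None = None,
                 switching: SwitchingParams | None = None,
                 modes: ExpressionModes | None = None,
                 config: SimConfig | None = None) -> None:
        self.params = params or FitnessParams()
        self.switching = switching or SwitchingParams()
        self.modes = modes or ExpressionModes()
        self.config = config or SimConfig()

    # -- elementary operations -------------------------------------------

    def new_population(self, n0: float | None = None) -> PopulationState:
        n0 = self.config.initial_population if n0 is None else n0
        return PopulationState(n0_off=n0, on_log10=self.modes.on_log10)

    #: relative drug-level change that triggers a rate refresh
    _DRUG_TOL = 1e-3

    def update_drug_uptake(self, state: PopulationState, env: Environment,
                           dt: float) -> None:
        """Relax internal effective drug levels toward the external ones."""
        if dt < 0:
            raise ValueError("dt must be >= 0")
        cfg = self.config
        state.C_int = env.dox + (state.C_int - env.dox) * math.exp(-cfg.dox_uptake_rate * dt)
        state.Z_int = env.zeo + (state.Z_int - env.zeo) * math.exp(-cfg.zeo_uptake_rate * dt)
        cache = state._cache
        if cache is not None:
            scale_c = max(env.dox, 1e-12)
            scale_z = max(env.zeo, 1e-12)
            if (abs(state.C_int - cache["C"]) > self._DRUG_TOL * scale_c
                    or abs(state.Z_int - cache["Z"]) > self._DRUG_TOL * scale_z):
                state._cache = None

    def _rates(self, state: PopulationState):
        """Per-allele per-state birth/death/switch rates at current drugs.

        Squelching toxicity (gamma2) slows division.  Zeocin toxicity
        (1 - gamma1) is cell-cycle arrest first and death second: a
        configurable share ``zeocin_death_share`` of it acts as a death
        rate, the remainder reduces the division rate.  The net growth
        rate is always the cellular fitness gamma0*gamma1*gamma2.
        """
        p = self.params
        f_off = self.modes.f_off
        f_on = 10.0 ** state.log10_f_on
        C, Z = state.C_int, state.Z_int
        zi_off = float(steady_state_internal_zeocin(f_off, Z, p))
        zi_on = steady_state_internal_zeocin(f_on, Z, p)
        kz = p.K_z * state.res_mult
        g1_L = 1.0 / (1.0 + (zi_off / kz) ** p.h_z)
        g1_H = 1.0 / (1.0 + (zi_on / kz) ** p.h_z)
        act_off = f_off * C / (C + p.K_C)
        g2_L = 1.0 / (1.0 + (act_off / p.K_d) ** p.h_d)
        act_on = f_on * C / (C + p.K_C)
        g2_H = 1.0 / (1.0 + (act_on / p.K_d) ** p.h_d)
        q = self.config.zeocin_death_share
        b_L = p.gamma0 * g2_L * (1.0 - (1.0 - q) * (1.0 - g1_L))
        b_L = np.asarray(b_L, dtype=float) + np.zeros(state.n_alleles)
        b_H = p.gamma0 * g2_H * (1.0 - (1.0 - q) * (1.0 - g1_H))
        b_H = np.asarray(b_H, dtype=float) + np.zeros(state.n_alleles)
        d_L = p.gamma0 * g2_L * q * (1.0 - g1_L)
        d_L = np.asarray(d_L, dtype=float) + np.zeros(state.n_alleles)
        d_H = p.gamma0 * g2_H * q * (1.0 - g1_H)
        d_H = np.asarray(d_H, dtype=float) + np.zeros(state.n_alleles)
        r = self.switching.r_of_dox(C) * state.r_mult
        f = np.full(state.n_alleles, self.switching.f)
        return b_L, d_L, b_H, d_H, r, f

    def _build_cache(self, state: PopulationState, dt: float) -> dict:
        """Rates plus the dt-step transition matrix and event probabilities.

        Valid until the allele set or the internal drug levels change.
        """
        b_L, d_L, b_H, d_H, r, f = self._rates(state)
        m11, m12, m21, m22 = _expm2_entries(b_L - d_L, b_H - d_H, r, f, dt)
        pev = lambda rate: -np.expm1(-rate * dt)
        # division probability e^{b dt} - 1 makes the survivors-then-divide
        # scheme's mean growth exactly e^{(b-d) dt} (no O(dt^2) bias)
        cache = {
            "C": state.C_int, "Z": state.Z_int, "dt": dt,
            "b_L": b_L, "d_L": d_L, "b_H": b_H, "d_H": d_H, "r": r, "f": f,
            "m11": m11, "m12": m12, "m21": m21, "m22": m22,
            "p_die_L": pev(d_L), "p_die_H": pev(d_H),
            "p_div_L": np.minimum(np.expm1(b_L * dt), 1.0),
            "p_div_H": np.minimum(np.expm1(b_H * dt), 1.0),
            "p_up": pev(r), "p_dn": pev(f),
        }
        state._cache = cache
        return cache

    def step_growth(self, state: PopulationState, env: Environment,
                    dt: float, rng: np.random.Generator) -> tuple[float, float]:
        """Advance all lineages by dt; returns ancestral (Off, On) births."""
        if dt > max(self.config.dt_h, self.config.resuspension_interval_h):
            raise ValueError("dt exceeds the configured maximum step")
        cache = state._cache
        if cache is None or cache["dt"] != dt:
            cache = self._build_cache(state, dt)
        thr = self.config.stochastic_size_threshold
        # promote lineages that outgrew the stochastic regime
        np.logical_and(state.stoch, state.totals < thr, out=state.stoch)
        sto = state.stoch
        det = ~sto

        births_anc_L = births_anc_H = 0.0
        if det.any():
            nL, nH = state.n_L[det], state.n_H[det]
            bL = cache["b_L"][det] * nL * dt
            bH = cache["b_H"][det] * nH * dt
            state.divisions += float(bL.sum() + bH.sum())
            state.n_L[det] = cache["m11"][det] * nL + cache["m12"][det] * nH
            state.n_H[det] = cache["m21"][det] * nL + cache["m22"][det] * nH
            if det[0]:
                births_anc_L = float(bL[0])
                births_anc_H = float(bH[0])
        if sto.any():
            nL = state.n_L[sto].astype(np.int64)
            nH = state.n_H[sto].astype(np.int64)
            die_L = rng.binomial(nL, cache["p_die_L"][sto])
            die_H = rng.binomial(nH, cache["p_die_H"][sto])
            sur_L = nL - die_L
            sur_H = nH - die_H
            div_L = rng.binomial(sur_L, cache["p_div_L"][sto])
            div_H = rng.binomial(sur_H, cache["p_div_H"][sto])
            n_L2 = sur_L + div_L
            n_H2 = sur_H + div_H
            sw_up = rng.binomial(n_L2, cache["p_up"][sto])
            sw_dn = rng.binomial(n_H2, cache["p_dn"][sto])
            state.n_L[sto] = n_L2 - sw_up + sw_dn
            state.n_H[sto] = n_H2 + sw_up - sw_dn
            divs = div_L + div_H
            state.divisions += float(divs.sum())
            if sto[0]:
                # realized ancestral divisions, split by state occupancy
                d0 = float(divs[0])
                wL = cache["b_L"][0] * nL[0]
                wH = cache["b_H"][0] * nH[0]
                tot = wL + wH
                births_anc_L = d0 * (wL / tot) if tot > 0 else 0.0
                births_anc_H = d0 - births_anc_L
        if state.total <= 0:
            state.extinct = True
        return births_anc_L, births_anc_H

    def _draw_resistance_mult(self, u: np.ndarray, env: Environment,
                              state_is_on: np.ndarray,
                              log10_f_on: np.ndarray) -> np.ndarray:
        """Kill-constant multiplier, uniform between 1 and the cap at
        which the cell's fitness reaches the zeocin-free value.

        The cap solves gamma1(multiplier) = 1 - epsilon at the
        lineage's current expression state (the Hill kill term only
        reaches 1 asymptotically, so the cap is taken at
        ``resistance_cap_epsilon`` below it).
        """
        p = self.params
        if env.zeo <= 0:
            return np.ones_like(u)
        eps = self.config.resistance_cap_epsilon
        f_ref = np.where(state_is_on, 10.0 ** log10_f_on, self.modes.f_off)
        zi = steady_state_internal_zeocin(f_ref, env.zeo, p)
        m_cap = (zi / p.K_z) / (eps / (1.0 - eps)) ** (1.0 / p.h_z)
        m_cap = np.maximum(m_cap, 1.0)
        return 1.0 + u * (m_cap - 1.0)

    def inject_mutations(self, state: PopulationState, env: Environment,
                         births: tuple[float, float],
                         rng: np.random.Generator,
                         preexisting: bool = False) -> int:
        """Poisson mutation entry from the realized ancestral divisions."""
        cfg = self.config
        mu = cfg.mu(env)
        births_L, births_H = births
        lam = mu * (births_L + births_H)
        if lam <= 0:
            return 0
        n_new = int(rng.poisson(lam))
        if n_new == 0:
            return 0
        types = rng.choice([MUT_K, MUT_T, MUT_G], size=n_new,
                           p=[cfg.p_K, cfg.p_T, cfg.p_G]).astype(np.int8)
        p_on = births_H / (births_L + births_H)
        on = rng.random(n_new) < p_on
        on &= types != MUT_K   # knockouts collapse to basal expression
        theta = rng.random(n_new)
        r_mult = np.where(types == MUT_T, theta,
                          np.where(types == MUT_K, 0.0, 1.0))
        off, span = self.modes.off_log10, self.modes.on_log10 - self.modes.off_log10
        log10_f_on = np.where(types == MUT_T, off + theta * span,
                              np.where(types == MUT_K, off, self.modes.on_log10))
        res_u = np.where(types == MUT_G, rng.random(n_new), 0.0)
        res_mult = np.ones(n_new)
        g_mask = types == MUT_G
        if g_mask.any():
            res_mult[g_mask] = self._draw_resistance_mult(
                res_u[g_mask], env, on[g_mask], log10_f_on[g_mask])
        ids = np.arange(state.next_id, state.next_id + n_new, dtype=np.int64)
        state.next_id += n_new
        state.append(ids=ids, mut_type=types, r_mult=r_mult, res_u=res_u,
                     res_mult=res_mult, log10_f_on=log10_f_on,
                     preexisting=np.full(n_new, preexisting),
                     n_L=(~on).astype(float), n_H=on.astype(float))
        return n_new

    def assign_resistance(self, state: PopulationState, env: Environment) -> None:
        """(Re)compute G-allele kill multipliers for a new environment.

        Used when preexisting mutations drawn in a zeocin-free pre-phase
        meet zeocin after the condition switch.
        """
        g = (state.mut_type == MUT_G) & (state.res_mult == 1.0)
        if g.any() and env.zeo > 0:
            on = state.n_H[g] > state.n_L[g]
            state.res_mult[g] = self._draw_resistance_mult(
                state.res_u[g], env, on, state.log10_f_on[g])

    def resuspend(self, state: PopulationState, env: Environment,
                  rng: np.random.Generator) -> None:
        """Multinomial dilution to the bottleneck size into fresh medium.

        External drug returns to the fresh-medium concentration (it is
        held constant here); internalized drug persists in the cells.
        """
        cfg = self.config
        total = state.total
        if total > cfg.bottleneck:
            if cfg.deterministic_resuspension:
                scale = cfg.bottleneck / total
                state.n_L = state.n_L * scale
                state.n_H = state.n_H * scale
            else:
                counts = np.concatenate([state.n_L, state.n_H])
                probs = counts / counts.sum()
                sampled = rng.multinomial(int(cfg.bottleneck), probs)
                k = state.n_alleles
                state.n_L = sampled[:k].astype(float)
                state.n_H = sampled[k:].astype(float)
            state.stoch = state.totals < cfg.stochastic_size_threshold
        state.prune()

    # -- full runs ---------------------------------------------------------

    def run_replicate(self, env: Environment, seed,
                      duration_days: float | None = None,
                      record_trajectory: bool = True,
                      preexisting_hours: float = 0.0,
                      pre_env: Environment | None = None):
        """One replicate: uptake -> growth -> mutation loop with
        periodic resuspensions; returns (trajectory, SummaryStats).

        With ``preexisting_hours`` > 0 the run starts with that much
        neutral growth in ``pre_env`` (default D0Z0) at the zeocin-free
        mutation rate; mutations arising there are flagged preexisting
        and the clock restarts at the condition switch.
        """
        cfg = self.config
        duration = cfg.duration_days if duration_days is None else duration_days
        rng = np.random.default_rng(seed)
        state = self.new_population()

        records: list[tuple] = []
        anc_series: list[tuple[float, float]] = []

        def run_phase(phase_env: Environment, hours: float,
                      preexisting: bool, t_offset: float) -> None:
            dt = cfg.dt_h
            n_steps = int(round(hours / dt))
            resus_every = max(1, int(round(cfg.resuspension_interval_h / dt)))
            record_every = max(1, int(round(1.0 / dt)))
            day_every = max(1, int(round(24.0 / dt)))
            for i in range(1, n_steps + 1):
                self.update_drug_uptake(state, phase_env, dt)
                births = self.step_growth(state, phase_env, dt, rng)
                self.inject_mutations(state, phase_env, births, rng,
                                      preexisting=preexisting)
                state.t_h += dt
                if state.extinct:
                    break
                if i % resus_every == 0:
                    self.resuspend(state, phase_env, rng)
                t_run = t_offset + i * dt
                if not preexisting and i % record_every == 0:
                    anc_series.append((t_run / 24.0, state.ancestral_fraction()))
                if record_trajectory and not preexisting and i % day_every == 0:
                    freqs = state.frequencies()
                    day = round(t_run / 24.0)
                    for j in range(state.n_alleles):
                        if freqs[j] > 0:
                            records.append((day, int(state.ids[j]),
                                            TYPE_NAMES[int(state.mut_type[j])],
                                            bool(state.preexisting[j]),
                                            float(freqs[j])))

        if preexisting_hours > 0:
            run_phase(pre_env or Environment(0.0, 0.0), preexisting_hours,
                      preexisting=True, t_offset=-preexisting_hours)
            # condition switch: zeocin-free resistance draws become real
            self.assign_resistance(state, env)
        run_phase(env, duration * 24.0, preexisting=False, t_offset=0.0)

        stats = self._summarize_state(state, anc_series,
                                      has_pre_phase=preexisting_hours > 0)
        traj = pd.DataFrame(records, columns=["day", "allele_id", "mut_type",
                                              "preexisting", "frequency"])
        return traj, stats

    def _summarize_state(self, state: PopulationState,
                         anc_series: list[tuple[float, float]],
                         has_pre_phase: bool) -> SummaryStats:
        if anc_series:
            anc = pd.DataFrame(anc_series, columns=["time_day", "x_anc"])
            half_life = ancestral_half_life(anc)
        else:
            half_life = HALF_LIFE_NOT_REACHED
        freqs = state.frequencies()
        mut = state.mut_type != MUT_ANC
        established = mut & (freqs > self.config.established_threshold)
        type_fr = {name: float(freqs[state.mut_type == code].sum())
                   for code, name in TYPE_NAMES.items() if code != MUT_ANC}
        mut_mass = float(freqs[mut].sum())
        pre_mass = float(freqs[mut & state.preexisting].sum())
        pre_frac = pre_mass / mut_mass if (has_pre_phase and mut_mass > 0) else (
            0.0 if has_pre_phase else float("nan"))
        n_mut_alleles = int(mut.sum())
        pre_alleles = int((mut & state.preexisting).sum())
        pre_allele_frac = pre_alleles / n_mut_alleles if (
            has_pre_phase and n_mut_alleles > 0) else (
            0.0 if has_pre_phase else float("nan"))
        return SummaryStats(
            half_life_days=half_life,
            n_established=int(established.sum()),
            type_fractions=type_fr,
            mutant_fraction=mut_mass,
            preexisting_fraction=pre_frac,
            preexisting_allele_fraction=pre_allele_frac,
            extinct=state.extinct,
        )

    def run_preexisting_variant(self, env: Environment, seed,
                                pre_hours: float = 24.0):
        """Replicate with 24 h of neutral pre-growth before the switch."""
        return self.run_replicate(env, seed, preexisting_hours=pre_hours)

    def run_ensemble(self, env: Environment, n_replicates: int | None = None,
                     master_seed: int | None = None,
                     preexisting_hours: float = 0.0,
                     record_trajectory: bool = False):
        """N independent replicates; returns (summaries, trajectories)."""
        cfg = self.config
        n = cfg.n_replicates if n_replicates is None else n_replicates
        master = cfg.seed if master_seed is None else master_seed
        seeds = np.random.SeedSequence(master).spawn(n)
        summaries, trajs = [], []
        for rep, ss in enumerate(seeds):
            traj, stats = self.run_replicate(
                env, ss, record_trajectory=record_trajectory,
                preexisting_hours=preexisting_hours)
            summaries.append(stats)
            if record_trajectory:
                traj.insert(0, "replicate", rep)
                trajs.append(traj)
        traj_df = pd.concat(trajs, ignore_index=True) if trajs else None
        return summaries, traj_df


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan"), float("nan")
    if values.size == 1:
        return float(values[0]), float("nan")
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))


def summarize_ensemble(summaries: list[SummaryStats]) -> EnsembleSummary:
    """Mean +/- SEM of the replicate summaries.

    Half-lives never reached (inf sentinel) are excluded from the
    half-life mean; their prevalence is reported as
    ``fraction_half_life_reached``.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 replicates to summarize")
    hl = np.array([s.half_life_days for s in summaries])
    reached = np.isfinite(hl)
    hl_mean, hl_sem = _mean_sem(hl[reached])
    ne_mean, ne_sem = _mean_sem(np.array([s.n_established for s in summaries]))
    type_mean, type_sem = {}, {}
    for t in ("K", "T", "G"):
        m, s = _mean_sem(np.array([x.type_fractions[t] for x in summaries]))
        type_mean[t], type_sem[t] = m, s
    pre = np.array([s.preexisting_fraction for s in summaries])
    pre = pre[np.isfinite(pre)]
    pre_mean, pre_sem = _mean_sem(pre) if pre.size else (float("nan"),) * 2
    return EnsembleSummary(
        n_replicates=len(summaries),
        half_life_mean=hl_mean, half_life_sem=hl_sem,
        fraction_half_life_reached=float(reached.mean()),
        n_established_mean=ne_mean, n_established_sem=ne_sem,
        type_fraction_mean=type_mean, type_fraction_sem=type_sem,
        preexisting_mean=pre_mean, preexisting_sem=pre_sem,
    )
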