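"""Synthetic measurement layers for every pipeline input.

Generates the four data families the analysis consumes, with the
statistical structure the downstream methods assume:

* growth curves -- exponential density trajectories at the population
  fitness of each (doxycycline, zeocin) condition, with multiplicative
  log-normal noise, on the 13-condition design of the landscape
  mapping experiment (zeocin 0.5/1/1.5/2 mg/ml; dox 0.2/0.5/1/2 ug/ml;
  the dox grid crossed with 2 mg/ml zeocin; plus the untreated control);
* flow-cytometry samples -- bimodal log10-fluorescence mixtures whose
  On weight follows the two-state switching model;
* sequencing observations -- binomial whole-genome calls at a given
  coverage plus clonal-isolate genotypes (multinomial over haplotypes)
  that preserve linkage;
* dose-response On-fraction tables for switching-rate inference.

Every generator is a pure function of its inputs and seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .environment import Environment
from .fitness import FitnessParams, ExpressionModes, population_fitness
from .switching import SwitchingParams, TwoStateCounts, two_state_step, predict_on_fraction

__all__ = [
    "SynthConfig", "default_condition_grid", "gen_growth_curves",
    "gen_flow_sample", "gen_sequencing_observations", "gen_dose_response",
    "classify_on_fraction",
]


@dataclass(frozen=True)
class SynthConfig:
    """Settings of the synthetic measurement layers."""

    seed: int = 0
    cells_per_sample: int = 10_000
    growth_noise_sd: float = 0.02       # multiplicative log-normal
    od0: float = 0.01
    timepoints_h: tuple = tuple(range(0, 72, 6))   # every 6 h, 12 points
    n_replicates: int = 3
    wgs_coverage: int = 100
    clones_per_timepoint: int = 20
    sampled_days: tuple = (5, 9, 13, 17, 20)

    def __post_init__(self) -> None:
        for name in ("cells_per_sample", "wgs_coverage", "clones_per_timepoint"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.growth_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_condition_grid() -> list[Environment]:
    """The 13 landscape-mapping conditions."""
    envs = [Environment(0.0, 0.0)]
    envs += [Environment(0.0, z) for z in (0.5, 1.0, 1.5, 2.0)]
    envs += [Environment(d, 0.0) for d in (0.2, 0.5, 1.0, 2.0)]
    envs += [Environment(d, 2.0) for d in (0.2, 0.5, 1.0, 2.0)]
    return envs


def _on_fraction(switching: SwitchingParams, env: Environment,
                 t_h: float) -> float:
    """On fraction of an initially Off culture after t_h in env."""
    g = predict_on_fraction(switching.at_dox(env.dox), np.array([t_h]),
                            np.array([env.dox]))
    return float(g[0])


def gen_flow_sample(switching: SwitchingParams, env: Environment, t_h: float,
                    modes: ExpressionModes, config: SynthConfig,
                    rng: np.random.Generator,
                    on_fraction: float | None = None) -> np.ndarray:
    """A log10-fluorescence sample: two-mode log-normal mixture.

    The On weight comes from the two-state model at time ``t_h`` unless
    given explicitly.
    """
    w = _on_fraction(switching, env, t_h) if on_fraction is None else on_fraction
    n = config.cells_per_sample
    n_on = int(rng.binomial(n, min(max(w, 0.0), 1.0)))
    off = rng.normal(modes.off_log10, modes.sd_log10, size=n - n_on)
    on = rng.normal(modes.on_log10, modes.sd_log10, size=n_on)
    sample = np.concatenate([off, on])
    rng.shuffle(sample)
    return sample


def classify_on_fraction(sample: np.ndarray, modes: ExpressionModes,
                         threshold: float | None = None) -> float:
    """Fraction of cells above the Off/On midpoint threshold."""
    thr = 0.5 * (modes.off_log10 + modes.on_log10) if threshold is None else threshold
    sample = np.asarray(sample, dtype=float)
    return float(np.mean(sample > thr))


def gen_growth_curves(params: FitnessParams, switching: SwitchingParams,
                      modes: ExpressionModes, config: SynthConfig,
                      rng: np.random.Generator,
                      envs: list[Environment] | None = None,
                      expression_age_h: float = 24.0):
    """Growth-curve and expression-sample tables for the drug grid.

    Returns (curves, expression) DataFrames in the dialects the fitting
    stage consumes.  Expression samples are drawn at ``expression_age_h``
    of induction; the growth rate of each condition is the population
    fitness over its sample.
    """
    envs = envs or default_condition_grid()
    curve_rows, expr_rows = [], []
    for env in envs:
        sample = gen_flow_sample(switching, env, expression_age_h, modes,
                                 config, rng)
        rate = population_fitness(sample, env, params)
        for i, x in enumerate(sample):
            expr_rows.append((env.label, expression_age_h / 24.0, float(x)))
        for rep in range(config.n_replicates):
            noise = rng.normal(0.0, config.growth_noise_sd,
                               size=len(config.timepoints_h))
            for t, eps in zip(config.timepoints_h, noise):
                od = config.od0 * np.exp(rate * t) * np.exp(eps)
                curve_rows.append((float(t), float(od), env.dox, env.zeo, rep))
    curves = pd.DataFrame(curve_rows, columns=["time_h", "od", "dox_ug_ml",
                                               "zeo_mg_ml", "replicate"])
    expr = pd.DataFrame(expr_rows, columns=["condition_label", "timepoint_day",
                                            "log10_fluorescence"])
    return curves, expr


@dataclass(frozen=True)
class HaplotypeSpec:
    """Ancestral background plus single-mutation lineages.

    ``linkage`` lists groups of allele ids that ride on one haplotype
    (arose in the same lineage); all other alleles are independent.
    """

    allele_ids: tuple
    linkage: tuple = ()

    def haplotypes(self) -> list[tuple]:
        linked = {a for grp in self.linkage for a in grp}
        haps = [tuple(sorted(grp)) for grp in self.linkage]
        haps += [(a,) for a in self.allele_ids if a not in linked]
        return haps


def gen_sequencing_observations(
    true_traj: pd.DataFrame,
    spec: HaplotypeSpec,
    config: SynthConfig,
    rng: np.random.Generator,
):
    """Noisy sequencing calls from true haplotype trajectories.

    ``true_traj`` has columns day, haplotype (tuple or '+'-joined str)
    and frequency; haplotype frequencies at a day must sum to <= 1
    (remainder ancestral).  Returns (observations, clonal genotypes):
    whole-genome calls are Binomial(coverage, locus frequency)/coverage
    per allele; Sanger calls and clone genotypes come from multinomial
    draws of whole clones over haplotypes, so linkage is preserved.
    """
    if (true_traj["frequency"] < 0).any() or (true_traj["frequency"] > 1).any():
        raise ValueError("true frequencies must lie in [0, 1]")
    haps = spec.haplotypes()
    obs_rows, clone_rows = [], []
    for day in config.sampled_days:
        sub = true_traj[true_traj["day"] == day]
        if not len(sub):
            continue
        hap_freq = {}
        for _, row in sub.iterrows():
            key = tuple(sorted(row["haplotype"].split("+"))) \
                if isinstance(row["haplotype"], str) else tuple(sorted(row["haplotype"]))
            hap_freq[key] = float(row["frequency"])
        freqs = np.array([hap_freq.get(h, 0.0) for h in haps])
        if freqs.sum() > 1 + 1e-9:
            raise ValueError(f"haplotype frequencies exceed 1 at day {day}")
        # whole-genome: per-locus binomial read support
        for allele in spec.allele_ids:
            locus_f = sum(f for h, f in zip(haps, freqs) if allele in h)
            reads = rng.binomial(config.wgs_coverage, min(locus_f, 1.0))
            obs_rows.append((allele, day, "wgs", reads / config.wgs_coverage))
        # clonal isolates: whole genomes drawn over haplotypes + ancestor
        p = np.concatenate([freqs, [max(0.0, 1.0 - freqs.sum())]])
        p = p / p.sum()
        counts = rng.multinomial(config.clones_per_timepoint, p)
        clone_no = 0
        for h, c in zip(list(haps) + [()], counts):
            for _ in range(c):
                cid = f"d{day}_c{clone_no}"
                clone_no += 1
                for allele in spec.allele_ids:
                    clone_rows.append((cid, day, allele, int(allele in h)))
        # Sanger: clone proportion per allele
        clones_day = pd.DataFrame(
            [r for r in clone_rows if r[1] == day],
            columns=["clone_id", "day", "allele_id", "present"])
        for allele in spec.allele_ids:
            carried = clones_day[clones_day["allele_id"] == allele]["present"]
            obs_rows.append((allele, day, "sanger", float(carried.mean())))
    obs = pd.DataFrame(obs_rows, columns=["allele_id", "day", "method",
                                          "frequency"])
    clones = pd.DataFrame(clone_rows, columns=["clone_id", "day", "allele_id",
                                               "present"])
    return obs, clones


def gen_dose_response(switching: SwitchingParams, dox_grid,
                      timepoints_h, config: SynthConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """On-fraction table over a dox grid with binomial counting noise."""
    rows = []
    n = config.cells_per_sample
    for t in timepoints_h:
        for c in dox_grid:
            true = predict_on_fraction(switching, np.array([float(t)]),
                                       np.array([float(c)]))[0]
            observed = rng.binomial(n, min(max(true, 0.0), 1.0)) / n
            rows.append((float(t), float(c), 0.0, observed, n))
    return pd.DataFrame(rows, columns=["time_h", "dox_ug_ml", "zeo_mg_ml",
                                       "on_fraction", "n_cells"])


def write_manifest(path, config: SynthConfig, extra: dict | None = None) -> None:
    payload = {"synth_config": asdict(config)} | (extra or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
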