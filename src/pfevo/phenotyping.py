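"""Growth-rate estimation and clone phenotyping statistics.

Fitness of a clone is the exponential growth rate of its density time
series, estimated as the log-linear regression slope over the sliding
window (>= 4 points) that maximizes R^2.  Clone phenotypes are
summarized by log10 fitness/fluorescence ratios between conditions, and
groups are compared with Student's t-tests (independent samples across
conditions, paired within a condition) with Bonferroni correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "growth_rate_from_curve", "cycle_growth_rate",
    "dox_fitness_effect", "zeocin_fitness_effect", "expression_effect",
    "compare_groups", "TestResult", "PhenotypeRecord",
]


@dataclass(frozen=True)
class PhenotypeRecord:
    """Fitness and expression summary of one clonal isolate."""

    clone_id: str
    condition: str
    fitness_per_h: float
    fitness_sd: float
    mean_log10_fluorescence: float
    fluorescence_sd: float
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.fitness_per_h):
            raise ValueError("fitness must be finite")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")


def growth_rate_from_curve(series: pd.DataFrame, min_window: int = 4):
    """Exponential growth rate from a (time_h, density) table.

    Scans every contiguous window of >= ``min_window`` points, fits
    log(density) ~ time by least squares, and returns the slope of the
    window with the highest R^2 (ties: the longest, then the earliest).

    Returns (rate_per_h, (t_start, t_end), r_squared).
    """
    t = series["time_h"].to_numpy(dtype=float)
    dens = series[series.columns[1]].to_numpy(dtype=float)
    if len(t) < min_window:
        raise ValueError(f"need >= {min_window} points, got {len(t)}")
    if np.any(dens <= 0):
        raise ValueError("densities must be positive for log-linear fitting")
    order = np.argsort(t)
    t, y = t[order], np.log(dens[order])

    best = None  # (r2, length, -start, slope, window)
    n = len(t)
    for w in range(min_window, n + 1):
        for i in range(0, n - w + 1):
            tt, yy = t[i:i + w], y[i:i + w]
            slope, intercept = np.polyfit(tt, yy, 1)
            resid = yy - (slope * tt + intercept)
            ss_tot = np.sum((yy - yy.mean()) ** 2)
            # a flat window carries no growth signal; score it 0
            flat = ss_tot <= w * (1e-10 * max(1.0, np.abs(yy).max())) ** 2
            r2 = 0.0 if flat else 1.0 - np.sum(resid ** 2) / ss_tot
            key = (round(r2, 12), w, -i)
            if best is None or key > best[0]:
                best = (key, slope, (tt[0], tt[-1]), r2)
    _, slope, window, r2 = best
    return float(slope), window, float(r2)


def cycle_growth_rate(n_start: float, n_end: float, interval_h: float) -> float:
    """Per-cycle fitness of resuspension regimes: ln(N_end/N_start)/dt."""
    if n_start <= 0 or n_end <= 0:
        raise ValueError("cell counts must be positive")
    return math.log(n_end / n_start) / interval_h


def _log10_ratio(a: float, b: float, what: str) -> float:
    if a <= 0 or b <= 0:
        raise ValueError(f"{what} must be positive for a log ratio")
    return math.log10(a / b)


def dox_fitness_effect(fit_with_dox: float, fit_no_dox: float) -> float:
    """log10[(fitness with doxycycline)/(fitness without)].

    0 means no effect; negative values are an inducer (squelching) cost.
    """
    return _log10_ratio(fit_with_dox, fit_no_dox, "fitness")


def zeocin_fitness_effect(fit_with_zeo: float, fit_no_zeo: float) -> float:
    """log10[(fitness with zeocin)/(fitness without)]."""
    return _log10_ratio(fit_with_zeo, fit_no_zeo, "fitness")


def expression_effect(mean_fluo_a: float, mean_fluo_b: float) -> float:
    """log10 ratio of mean fluorescences (e.g. evolved clone vs ancestor)."""
    return _log10_ratio(mean_fluo_a, mean_fluo_b, "fluorescence")


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    p_value: float
    alpha: float
    n_comparisons: int
    significant: bool

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.n_comparisons


def compare_groups(sample_a, sample_b, paired: bool = False,
                   n_comparisons: int = 1, alpha: float = 0.05,
                   equal_var: bool = True) -> TestResult:
    """Two-sided t-test with Bonferroni-adjusted significance.

    Independent-samples by default (different conditions); ``paired``
    for within-condition timepoint comparisons.  ``equal_var`` selects
    the classical Student's test (default) vs Welch's.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        if len(a) < 2:
            raise ValueError("need >= 2 pairs")
        res = sps.ttest_rel(a, b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per group")
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):   # identical paired samples: zero difference
        t, p = 0.0, 1.0
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return TestResult(t_statistic=t, p_value=p, alpha=alpha,
                      n_comparisons=n_comparisons,
                      significant=bool(p < alpha / n_comparisons))
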