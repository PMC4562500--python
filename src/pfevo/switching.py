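"""Two-state (Off/On) growth-and-switching dynamics of the bistable circuit.

The population composition follows the linear ODE system

    dn_L/dt = (g_L - r) n_L + f n_H
    dn_H/dt = r n_L + (g_H - f) n_H

with Off/On division rates ``g_L``/``g_H`` and switching rates ``r``
(Off->On, inducer-driven) and ``f`` (On->Off, memory loss).  The system
is solved exactly with the 2x2 matrix exponential.  The Off->On rate can
carry a Hill-type dose dependence on doxycycline,
``r(C) = r_max C^n / (C^n + K^n)``, with ``f`` constant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy.linalg import expm as _scipy_expm
from scipy.optimize import least_squares

__all__ = [
    "SwitchingParams",
    "TwoStateCounts",
    "propagate_two_state",
    "equilibrium_on_fraction",
    "dominant_growth_rate",
    "fit_switching_rates",
    "two_state_step",
    "expm2_entries",
]

_EIG_GAP_TOL = 1e-12


@dataclass(frozen=True)
class SwitchingParams:
    """Growth and switching rates of the two-state model (per hour)."""

    g_L: float = 0.25     # Off-state division rate
    g_H: float = 0.074    # On-state division rate (condition-specific)
    r: float = 0.0        # Off->On rate; overridden by dose model when set
    f: float = 0.01       # On->Off rate (cellular memory loss)
    # optional dose dependence of r on doxycycline
    r_max: float | None = 0.4
    K_r: float | None = 1.0    # ug/ml
    n_r: float | None = 2.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g_L) and math.isfinite(self.g_H)):
            raise ValueError("growth rates must be finite")
        if self.r < 0 or self.f < 0:
            raise ValueError("switching rates must be >= 0")

    @property
    def dose_dependent(self) -> bool:
        return self.r_max is not None

    def r_of_dox(self, C: float) -> float:
        """Off->On switching rate at doxycycline concentration C (ug/ml)."""
        if not self.dose_dependent:
            return self.r
        C = float(C)
        if C <= 0:
            return 0.0
        cn = C ** self.n_r
        return self.r_max * cn / (cn + self.K_r ** self.n_r)

    def at_dox(self, C: float) -> "SwitchingParams":
        return replace(self, r=self.r_of_dox(C))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchingParams":
        return cls(**d)


@dataclass(frozen=True)
class TwoStateCounts:
    """Off/On cell counts of a lineage."""

    n_L: float
    n_H: float

    def __post_init__(self) -> None:
        if self.n_L < 0 or self.n_H < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def total(self) -> float:
        return self.n_L + self.n_H

    @property
    def on_fraction(self) -> float:
        tot = self.total
        return self.n_H / tot if tot > 0 else float("nan")


def expm2_entries(g_L, g_H, r, f, dt):
    """Entries of expm(A*dt) for the two-state rate matrix, vectorized.

    A = [[g_L - r, f], [r, g_H - f]].  Uses the eigendecomposition,
    with a scaling-and-squaring fallback when the eigenvalue gap is
    below 1e-12 (near-defective matrix).  Returns (m11, m12, m21, m22)
    such that (n_L', n_H') = (m11 n_L + m12 n_H, m21 n_L + m22 n_H).
    """
    g_L, g_H, r, f = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (g_L, g_H, r, f)))
    a = g_L - r
    d = g_H - f
    disc = (a - d) ** 2 + 4.0 * f * r   # >= 0 for non-negative f, r
    s = np.sqrt(np.maximum(disc, 0.0))
    lam1 = 0.5 * (a + d + s)
    lam2 = 0.5 * (a + d - s)
    gap = lam1 - lam2

    shape = a.shape
    m11 = np.empty(shape)
    m12 = np.empty(shape)
    m21 = np.empty(shape)
    m22 = np.empty(shape)
    ok = gap > _EIG_GAP_TOL
    if np.any(ok):
        # expm(A dt) = e1*(A - lam2 I)/gap - e2*(A - lam1 I)/gap
        e1 = np.exp(lam1[ok] * dt)
        e2 = np.exp(lam2[ok] * dt)
        c1 = (e1 - e2) / gap[ok]
        m11[ok] = e2 + c1 * (a[ok] - lam2[ok])
        m12[ok] = c1 * f[ok]
        m21[ok] = c1 * r[ok]
        m22[ok] = e2 + c1 * (d[ok] - lam2[ok])
    if np.any(~ok):
        for idx in np.argwhere(~ok):
            i = tuple(idx)
            A = np.array([[a[i], f[i]], [r[i], d[i]]])
            M = _scipy_expm(A * dt)
            m11[i], m12[i], m21[i], m22[i] = M[0, 0], M[0, 1], M[1, 0], M[1, 1]
    return m11, m12, m21, m22


def two_state_step(g_L, g_H, r, f, dt, n_L, n_H):
    """Exact propagation of the two-state linear system, vectorized."""
    n_L = np.asarray(n_L, dtype=float)
    n_H = np.asarray(n_H, dtype=float)
    m11, m12, m21, m22 = expm2_entries(g_L, g_H, r, f, dt)
    out_L = m11 * n_L + m12 * n_H
    out_H = m21 * n_L + m22 * n_H
    # exact solution preserves non-negativity; clip rounding error only
    return np.maximum(out_L, 0.0), np.maximum(out_H, 0.0)


def propagate_two_state(state: TwoStateCounts, params: SwitchingParams,
                        dt: float) -> TwoStateCounts:
    """Advance a lineage by ``dt`` hours (exact matrix exponential)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    nL, nH = two_state_step(params.g_L, params.g_H, params.r, params.f,
                            dt, state.n_L, state.n_H)
    return TwoStateCounts(float(nL), float(nH))


def dominant_growth_rate(params: SwitchingParams) -> float:
    """Long-time exponential growth rate (dominant eigenvalue)."""
    a = params.g_L - params.r
    d = params.g_H - params.f
    disc = (a - d) ** 2 + 4.0 * params.f * params.r
    return 0.5 * (a + d + math.sqrt(max(disc, 0.0)))


def equilibrium_on_fraction(params: SwitchingParams) -> float:
    """Long-time On fraction: the dominant eigenvector, normalized.

    For a degenerate (tied-eigenvalue) system the limit of the
    propagated state from (1, 1) is returned instead.
    """
    a = params.g_L - params.r
    d = params.g_H - params.f
    disc = (a - d) ** 2 + 4.0 * params.f * params.r
    s = math.sqrt(max(disc, 0.0))
    if s <= _EIG_GAP_TOL:
        state = TwoStateCounts(1.0, 1.0)
        state = propagate_two_state(state, params, 5000.0)
        return state.on_fraction
    lam1 = 0.5 * (a + d + s)
    # dominant eigenvector of [[a, f], [r, d]]: v_H / v_L = r / (lam1 - d)
    if params.r > 0:
        if lam1 - d <= 0:   # lam1 == d only when r*f == 0; guarded above
            return 1.0
        ratio = params.r / (lam1 - d)
        return ratio / (1.0 + ratio)
    # r == 0: On feeds Off via f but receives nothing; if On outgrows Off
    # the limit keeps the mixture (d - a)/((d - a) + f), otherwise all Off
    if d > a:
        return (d - a) / ((d - a) + params.f)
    return 0.0


# ---------------------------------------------------------------------------
# switching-rate inference from dose-response On-fraction data
# ---------------------------------------------------------------------------

@dataclass
class SwitchFitDiagnostics:
    cost: float
    n_points: int
    success: bool
    message: str
    ratio_only: bool = False


_SW_START_SCALES = [
    (1.0, 1.0, 1.0, 1.0),
    (0.3, 0.5, 1.0, 3.0),
    (3.0, 2.0, 1.0, 0.3),
    (1.0, 0.2, 1.5, 1.0),
    (0.5, 5.0, 0.75, 1.0),
    (2.0, 1.0, 1.25, 0.5),
    (1.0, 3.0, 0.6, 2.0),
    (0.7, 0.7, 1.4, 0.7),
]


def predict_on_fraction(params: SwitchingParams, time_h, dox,
                        initial: TwoStateCounts | None = None) -> np.ndarray:
    """On fraction of an initially Off population after ``time_h`` at dose."""
    initial = initial or TwoStateCounts(1.0, 0.0)
    tb, db = np.broadcast_arrays(np.asarray(time_h, dtype=float),
                                 np.asarray(dox, dtype=float))
    rb = np.array([params.r_of_dox(c) for c in db.ravel()]).reshape(db.shape)
    out = np.empty(tb.shape, dtype=float)
    for t in np.unique(tb):   # propagation is per-duration; group equal dt
        m = tb == t
        L, H = two_state_step(params.g_L, params.g_H, rb[m], params.f, t,
                              np.full(m.sum(), initial.n_L),
                              np.full(m.sum(), initial.n_H))
        tot = L + H
        out[m] = np.divide(H, tot, out=np.full_like(H, np.nan), where=tot > 0)
    return out


def fit_switching_rates(
    series: pd.DataFrame,
    growth_rates: tuple[float, float],
    fit_f: bool = True,
) -> tuple[SwitchingParams, SwitchFitDiagnostics]:
    """Least-squares switching rates from an On-fraction table.

    ``series`` has columns time_h, dox_ug_ml, on_fraction (and optional
    n_cells used as weights).  ``growth_rates`` supplies the
    independently measured (g_L, g_H).  Fits (r_max, K_r, n_r, f) of the
    Hill dose model with 8 fixed multi-starts; deterministic.
    """
    required = {"time_h", "dox_ug_ml", "on_fraction"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"on-fraction table missing columns: {sorted(missing)}")
    frac = series["on_fraction"].to_numpy(dtype=float)
    if np.all(frac <= 0) or np.all(frac >= 1):
        raise ValueError("all-zero or all-one On fractions: rates unidentifiable")
    n_t = series["time_h"].nunique()
    n_d = series["dox_ug_ml"].nunique()
    if n_t < 3 and n_d < 3:
        raise ValueError("need >= 3 timepoints or >= 3 dose levels")
    ratio_only = n_t == 1

    g_L, g_H = growth_rates
    t = series["time_h"].to_numpy(dtype=float)
    dox = series["dox_ug_ml"].to_numpy(dtype=float)
    w = np.sqrt(series["n_cells"].to_numpy(dtype=float)) if "n_cells" in series \
        else np.ones_like(frac)
    w = w / w.max()

    def residuals(logvec: np.ndarray) -> np.ndarray:
        r_max, K_r, n_r, f = np.exp(logvec)
        p = SwitchingParams(g_L=g_L, g_H=g_H, f=f if fit_f else 0.01,
                            r_max=r_max, K_r=K_r, n_r=max(n_r, 0.5))
        pred = predict_on_fraction(p, t, dox)
        return w * (pred - frac)

    nominal = np.log(np.array([0.4, 1.0, 2.0, 0.01]))
    lo = np.log(np.array([1e-4, 1e-3, 0.5, 1e-5]))
    hi = np.log(np.array([10.0, 50.0, 6.0, 5.0]))
    best = None
    for scales in _SW_START_SCALES:
        start = np.clip(nominal + np.log(np.asarray(scales)), lo, hi)
        try:
            sol = least_squares(residuals, start, bounds=(lo, hi),
                                xtol=1e-13, ftol=1e-13, gtol=1e-13)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ArithmeticError("switching fit failed from every start")
    r_max, K_r, n_r, f = np.exp(best.x)
    fitted = SwitchingParams(g_L=g_L, g_H=g_H, f=float(f), r_max=float(r_max),
                             K_r=float(K_r), n_r=float(n_r))
    diag = SwitchFitDiagnostics(cost=float(best.cost), n_points=len(series),
                                success=bool(best.success),
                                message=str(best.message), ratio_only=ratio_only)
    return fitted, diag
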