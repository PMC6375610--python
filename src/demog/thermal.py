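"""Asymmetric thermal-performance curve for the intrinsic rate of increase.

Model: ``r(T) = a·T·(T − T0)·sqrt(TL − T)`` on the thermal window
``[T0, TL]`` and 0 outside it (clamped convention — no growth beyond the
thermal limits).  ``TL`` is constrained to at least the largest observed
temperature, since the square root is undefined above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BrierePoint",
    "BriereFit",
    "briere_r",
    "fit_briere",
    "optimum_temperature",
]


@dataclass(frozen=True)
class BrierePoint:
    """One (temperature, rate) observation; anchors are assumed-zero points."""

    temperature_C: float
    r_value: float
    is_anchor: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature_C):
            raise ValueError("temperature must be finite")
        if self.is_anchor and self.r_value != 0.0:
            raise ValueError("anchor points must have r_value = 0")


@dataclass(frozen=True)
class BriereFit:
    a: float
    T0: float
    TL: float
    r_squared: float
    residuals: np.ndarray
    points: tuple[BrierePoint, ...] = field(default_factory=tuple)

    def predict(self, T):
        return briere_r(T, self.a, self.T0, self.TL)

    @property
    def T_opt(self) -> float:
        return optimum_temperature(self.T0, self.TL)


def briere_r(T, a: float, T0: float, TL: float):
    """Evaluate the curve; 0 outside ``[T0, TL]``.  Vectorized over ``T``."""
    if not T0 < TL:
        raise ValueError("T0 must be < TL")
    T = np.asarray(T, dtype=float)
    inside = (T >= T0) & (T <= TL)
    out = np.zeros_like(T)
    Ti = T[inside]
    out[inside] = a * Ti * (Ti - T0) * np.sqrt(TL - Ti)
    return float(out) if out.ndim == 0 else out


def _design(T: np.ndarray, T0: float, TL: float) -> np.ndarray:
    """Basis x(T) with r_pred = a·x(T), clamped to 0 outside [T0, TL]."""
    inside = (T >= T0) & (T <= TL)
    x = np.zeros_like(T)
    x[inside] = T[inside] * (T[inside] - T0) * np.sqrt(TL - T[inside])
    return x


def _profile_a(T: np.ndarray, r: np.ndarray, T0: float, TL: float) -> float:
    x = _design(T, T0, TL)
    denom = float(np.dot(x, x))
    return float(np.dot(x, r) / denom) if denom > 0 else 0.0


def fit_briere(
    points: Sequence[BrierePoint],
    TL_upper_bound: float | None = None,
) -> BriereFit:
    """Least-squares fit of ``(a, T0, TL)`` to (temperature, rate) points.

    The scale ``a`` is profiled out analytically (the model is linear in it);
    ``(T0, TL)`` are found by a deterministic multi-start grid search refined
    with bounded trust-region least squares.  ``TL`` is bounded below by the
    maximum observed temperature and above by ``TL_upper_bound`` (default:
    max temperature + 20 °C).

    ``r_squared = 1 − SS_res/SS_tot`` with SS_tot about the mean observed
    rate; for flat data (SS_tot = 0) it is 1 when SS_res = 0, else 0.
    """
    points = tuple(
        p if isinstance(p, BrierePoint) else BrierePoint(*p) for p in points
    )
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    T = np.array([p.temperature_C for p in points], dtype=float)
    r = np.array([p.r_value for p in points], dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("need at least 3 distinct temperatures")

    T_min, T_max = float(T.min()), float(T.max())
    TL_ub = float(TL_upper_bound) if TL_upper_bound is not None else T_max + 20.0
    if TL_ub < T_max:
        raise ValueError("TL_upper_bound below the maximum observed temperature")
    T0_lo, T0_hi = min(0.0, T_min), T_min

    def sse(T0: float, TL: float) -> float:
        a = _profile_a(T, r, T0, TL)
        resid = r - a * _design(T, T0, TL)
        return float(np.dot(resid, resid))

    # deterministic coarse grid, then local refinement
    best = (math.inf, T0_lo, T_max)
    grid_T0 = np.linspace(T0_lo, T0_hi, 41)
    grid_TL = np.linspace(T_max, TL_ub, 41)
    for t0 in grid_T0:
        for tl in grid_TL:
            if t0 >= tl:
                continue
            s = sse(t0, tl)
            if s < best[0]:
                best = (s, float(t0), float(tl))

    def residual_vec(theta):
        t0, tl = theta
        a = _profile_a(T, r, t0, tl)
        return r - a * _design(T, t0, tl)

    sol = least_squares(
        residual_vec,
        x0=[best[1], min(max(best[2], T_max + 1e-9), TL_ub)],
        bounds=([T0_lo, T_max], [T0_hi, TL_ub + 1e-9]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    cand = [(float(np.dot(sol.fun, sol.fun)), float(sol.x[0]), float(sol.x[1])), best]
    ss_res, T0_hat, TL_hat = min(cand)
    TL_hat = min(max(TL_hat, T_max), TL_ub)
    a_hat = _profile_a(T, r, T0_hat, TL_hat)
    resid = r - a_hat * _design(T, T0_hat, TL_hat)
    ss_res = float(np.dot(resid, resid))

    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-24 else 0.0

    if not np.isfinite([a_hat, T0_hat, TL_hat]).all():
        raise RuntimeError(f"fit did not converge: status={sol.status} {sol.message}")
    return BriereFit(
        a=a_hat,
        T0=T0_hat,
        TL=TL_hat,
        r_squared=float(r2),
        residuals=resid,
        points=points,
    )


def optimum_temperature(T0: float, TL: float) -> float:
    """Temperature maximizing the curve on ``(T0, TL)``.

    Stationarity of ``T·(T − T0)·sqrt(TL − T)`` gives
    ``5T² − (3·T0 + 4·TL)·T + 2·T0·TL = 0``; the relevant optimum is the
    larger root, which lies in ``(T0, TL)`` for ``0 <= T0 < TL``.
    """
    if not 0.0 <= T0 < TL:
        raise ValueError("require 0 <= T0 < TL")
    b = 3.0 * T0 + 4.0 * TL
    disc = b * b - 40.0 * T0 * TL
    assert disc > 0, "stationarity discriminant must be positive for T0 < TL"
    Topt = (b + math.sqrt(disc)) / 10.0
    assert T0 < Topt < TL
    return float(Topt)
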