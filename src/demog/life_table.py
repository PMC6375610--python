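"""Cohort life tables and the classical deterministic demographic parameters.

Ages are integer days with age 0 at oviposition.  The table carries the
survivorship schedule ``lx`` (proportion of the cohort alive at exact age x),
age-specific mortality ``qx`` and the age-specific female-offspring fecundity
``mx`` (mean eggs per female alive at age x, scaled by the female ratio).

From a table the module derives the net reproductive rate ``R0 = Σ lx·mx``,
the intrinsic rate of increase ``r`` solving ``Σ exp(-r·x)·lx·mx = 1``, the
finite rate ``λ = exp(r)``, the mean generation time ``ln(R0)/r``, the
doubling time ``ln(2)/r``, age-specific reproductive values and remaining
life expectancies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .synthetic import IndividualRecord

__all__ = [
    "LifeTable",
    "DemographicParams",
    "AgeSchedules",
    "NoReproductionError",
    "DegenerateRateError",
    "build_life_table",
    "net_reproductive_rate",
    "intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "doubling_time",
    "reproductive_value",
    "expected_remaining_life",
    "demographic_params",
    "age_schedules",
]


class NoReproductionError(ValueError):
    """Raised when a rate is requested for a schedule with no reproduction."""


class DegenerateRateError(ValueError):
    """Raised for quantities undefined at r = 0 (or R0 <= 0)."""


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed ``lx``/``qx``/``mx`` schedules for one cohort.

    ``qx`` and derived per-age quantities are NaN at ages with ``lx = 0``.
    """

    ages: np.ndarray
    lx: np.ndarray
    qx: np.ndarray
    mx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        lx = np.asarray(self.lx, dtype=float)
        mx = np.asarray(self.mx, dtype=float)
        if not (ages.size == lx.size == mx.size == np.asarray(self.qx).size):
            raise ValueError("ages, lx, qx, mx must have equal length")
        if ages.size == 0:
            raise ValueError("empty life table")
        if abs(lx[0] - 1.0) > 1e-12:
            raise ValueError("l0 must equal 1")
        if np.any(np.diff(lx) > 1e-12):
            raise ValueError("lx must be non-increasing")
        if np.any((lx < -1e-12) | (lx > 1 + 1e-12)):
            raise ValueError("lx must lie in [0, 1]")
        if np.any(mx < 0):
            raise ValueError("mx must be non-negative")

    def __len__(self) -> int:
        return int(self.ages.size)


@dataclass(frozen=True)
class DemographicParams:
    """Scalar summary parameters of one cohort schedule."""

    R0: float
    r: float
    lambda_finite: float
    T_gen: float
    DT: float


@dataclass(frozen=True)
class AgeSchedules:
    """Per-age reproductive value ``Vx`` and remaining life expectancy ``Ex``."""

    ages: np.ndarray
    Vx: np.ndarray
    Ex: np.ndarray


def build_life_table(
    cohort: Sequence[IndividualRecord],
    female_ratio: float,
    fecundity_denominator: str = "alive",
) -> LifeTable:
    """Tabulate ``lx``, ``qx`` and ``mx`` from individual event histories.

    Parameters
    ----------
    cohort
        Non-empty collection of individual records.
    female_ratio
        Proportion of offspring assumed female; scales raw egg counts into
        female-offspring fecundity.
    fecundity_denominator
        ``"alive"`` (default) divides the eggs laid at age x by the number of
        females still alive at x; ``"initial"`` divides by the number of
        females that entered the cohort.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if not 0.0 <= female_ratio <= 1.0:
        raise ValueError("female_ratio must be in [0, 1]")
    if fecundity_denominator not in ("alive", "initial"):
        raise ValueError("fecundity_denominator must be 'alive' or 'initial'")

    death_ages = np.array([rec.death_age_d for rec in cohort], dtype=int)
    if np.any(death_ages < 0):
        raise ValueError("negative death ages in cohort")
    max_age = int(death_ages.max())
    ages = np.arange(max_age + 1)
    n = len(cohort)

    deaths_sorted = np.sort(death_ages)
    lx = (n - np.searchsorted(deaths_sorted, ages, side="right")) / n
    lx[0] = 1.0  # exact age 0: everyone enters alive

    lx_next = np.append(lx[1:], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = np.where(lx > 0, 1.0 - lx_next / np.where(lx > 0, lx, 1.0), np.nan)

    female_deaths = np.sort(
        [rec.death_age_d for rec in cohort if rec.sex == "female"]
    ).astype(int)
    eggs = np.zeros(max_age + 1)
    for rec in cohort:
        if rec.sex != "female":
            continue
        for age, count in rec.daily_eggs:
            eggs[age] += count

    n_females0 = female_deaths.size
    if fecundity_denominator == "alive":
        denom = (n_females0 - np.searchsorted(female_deaths, ages, side="right")).astype(float)
    else:
        denom = np.full(ages.size, float(n_females0))
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(denom > 0, eggs / np.where(denom > 0, denom, 1.0) * female_ratio, 0.0)

    return LifeTable(ages=ages, lx=lx, qx=qx, mx=mx)


def net_reproductive_rate(lt: LifeTable) -> float:
    """Net reproductive rate ``R0 = Σ lx·mx`` (female offspring per female)."""
    return float(np.dot(lt.lx, lt.mx))


def _log_lotka(lt: LifeTable):
    """Return (ages, log(lx*mx)) over ages carrying reproductive mass."""
    mass = lt.lx * lt.mx
    keep = mass > 0
    return lt.ages[keep].astype(float), np.log(mass[keep])


def intrinsic_rate(lt: LifeTable, bracket: tuple[float, float] = (-10.0, 10.0)) -> float:
    """Intrinsic rate of increase: the root of ``Σ exp(-r·x)·lx·mx = 1``.

    The left-hand side is strictly decreasing in r (for mass at positive
    ages), so the root is unique.  Solved on a log scale for numerical range.
    """
    x, logmass = _log_lotka(lt)
    if x.size == 0:
        raise NoReproductionError("R0 = 0: no age with lx*mx > 0")
    if np.all(x == 0):
        raise DegenerateRateError("all reproductive mass at age 0; r undefined")

    def g(r: float) -> float:
        return logsumexp(-r * x + logmass)

    lo, hi = bracket
    if g(lo) < 0 or g(hi) > 0:
        raise ValueError(f"no root in bracket [{lo}, {hi}]")
    r = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    return float(r)


def euler_lotka_residual(lt: LifeTable, r: float) -> float:
    """``Σ exp(-r·x)·lx·mx − 1`` at the supplied rate."""
    x, logmass = _log_lotka(lt)
    if x.size == 0:
        return -1.0
    return float(math.expm1(logsumexp(-r * x + logmass)))


def finite_rate(r: float) -> float:
    """Finite rate of increase ``λ = exp(r)``."""
    return float(math.exp(r))


def mean_generation_time(R0: float, r: float) -> float:
    """Mean generation time ``ln(R0)/r``."""
    if R0 <= 0:
        raise NoReproductionError("mean generation time requires R0 > 0")
    if r == 0:
        raise DegenerateRateError("mean generation time undefined at r = 0")
    return float(math.log(R0) / r)


def doubling_time(r: float) -> float:
    """Doubling time ``ln(2)/r`` (negative when the population declines)."""
    if r == 0:
        raise DegenerateRateError("doubling time undefined at r = 0")
    return float(math.log(2.0) / r)


def reproductive_value(lt: LifeTable, r: float) -> np.ndarray:
    """Reproductive value schedule ``Vx``.

    ``Vx = Σ_{t>=x} exp(-r·t)·lt·mt / (lx·exp(-r·x))``, evaluated with the
    exponent shifted by x for numerical stability.  NaN where ``lx = 0``.
    When ``r`` is the Euler–Lotka root, ``V0 = 1`` by construction.
    """
    n = len(lt)
    Vx = np.full(n, np.nan)
    mass = lt.lx * lt.mx
    for i in range(n):
        if lt.lx[i] <= 0:
            continue
        t = lt.ages[i:].astype(float)
        tail = np.sum(np.exp(-r * (t - lt.ages[i])) * mass[i:])
        Vx[i] = tail / lt.lx[i]
    return Vx


def expected_remaining_life(lt: LifeTable) -> np.ndarray:
    """Remaining life expectancy ``Ex = Σ_{t>=x} (lt + l(t+1))/2 / lx`` in days.

    Survivorship beyond the table is treated as zero; NaN where ``lx = 0``.
    """
    lx_next = np.append(lt.lx[1:], 0.0)
    trapezoids = (lt.lx + lx_next) / 2.0
    tail = np.cumsum(trapezoids[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        Ex = np.where(lt.lx > 0, tail / np.where(lt.lx > 0, lt.lx, 1.0), np.nan)
    return Ex


def demographic_params(lt: LifeTable) -> DemographicParams:
    """All scalar parameters for one table (raises if reproduction is absent)."""
    R0 = net_reproductive_rate(lt)
    r = intrinsic_rate(lt)
    lam = finite_rate(r)
    if r == 0:
        T_gen, DT = math.nan, math.nan
    else:
        T_gen = mean_generation_time(R0, r)
        DT = doubling_time(r)
    return DemographicParams(R0=R0, r=r, lambda_finite=lam, T_gen=T_gen, DT=DT)


def age_schedules(lt: LifeTable, r: float | None = None) -> AgeSchedules:
    """Bundle ``Vx`` (at the solved or supplied rate) and ``Ex``."""
    if r is None:
        r = intrinsic_rate(lt)
    return AgeSchedules(
        ages=lt.ages.copy(),
        Vx=reproductive_value(lt, r),
        Ex=expected_remaining_life(lt),
    )
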