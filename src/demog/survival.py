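"""Nonparametric and parametric survival analysis for right-censored times.

Implements the Kaplan–Meier product-limit estimator with Greenwood variance
and log-transformed 95% bands, and accelerated-failure-time (AFT) regression
on log time for four families (exponential, Weibull, lognormal, loglogistic)
with a single continuous covariate, ranked by AIC.

The AFT likelihood is maximized directly:  ``log T = β0 + β1·x + σ·ε`` with
ε standard extreme-value (Weibull; σ fixed at 1 for the exponential),
standard normal (lognormal) or standard logistic (loglogistic).  An observed
event contributes ``log f(t)``, a right-censored one ``log S(t)``.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "SurvivalSample",
    "KMEstimate",
    "AFTFit",
    "SelectionResult",
    "FAMILIES",
    "km_fit",
    "km_median",
    "aft_fit",
    "aic",
    "select_model",
    "death_sample",
    "first_egg_sample",
]

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censorable times with optional per-subject covariate."""

    times: np.ndarray
    events: np.ndarray
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if times.size == 0:
            raise ValueError("empty sample")
        if times.size != events.size:
            raise ValueError("times and events must have equal length")
        if np.any(times <= 0):
            raise ValueError("times must be strictly positive")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (observed)")
        if self.covariate is not None:
            cov = np.asarray(self.covariate, dtype=float)
            object.__setattr__(self, "covariate", cov)
            if cov.size != times.size:
                raise ValueError("covariate length mismatch")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.times.tobytes())
        h.update(self.events.tobytes())
        if self.covariate is not None:
            h.update(self.covariate.tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class KMEstimate:
    event_times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    mean: float
    mean_is_restricted: bool
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(sample: SurvivalSample) -> KMEstimate:
    """Kaplan–Meier product-limit estimate with Greenwood variance.

    The reported mean is the restricted mean: the area under the step
    function up to the largest observed (event or censoring) time.  With an
    all-censored sample the curve stays flat at 1 and a warning is emitted.
    """
    times, events = sample.times, sample.events
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    n = t_sorted.size

    if events.sum() == 0:
        warnings.warn("all observations censored: survival curve is flat at 1")
        t_max = float(t_sorted[-1])
        return KMEstimate(
            event_times=np.array([]),
            survival=np.array([]),
            variance=np.array([]),
            ci_low=np.array([]),
            ci_high=np.array([]),
            median=None,
            median_ci=(None, None),
            mean=t_max,
            mean_is_restricted=True,
            n=n,
        )

    event_times = []
    surv, var, lo, hi = [], [], [], []
    S = 1.0
    greenwood_sum = 0.0
    at_risk = n
    i = 0
    while i < n:
        t = t_sorted[i]
        d = 0
        c = 0
        while i < n and t_sorted[i] == t:
            if e_sorted[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            S *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood_sum += d / (at_risk * (at_risk - d))
            event_times.append(t)
            if S <= 0.0:
                surv.append(0.0)
                var.append(0.0)
                lo.append(0.0)
                hi.append(0.0)
            else:
                surv.append(S)
                var.append(S * S * greenwood_sum)
                half = _Z95 * math.sqrt(greenwood_sum)
                lo.append(max(0.0, S * math.exp(-half)))
                hi.append(min(1.0, S * math.exp(half)))
        at_risk -= d + c

    event_times = np.asarray(event_times)
    surv = np.asarray(surv)
    lo_a, hi_a = np.asarray(lo), np.asarray(hi)

    # restricted mean: area under the step function up to the largest time
    t_max = float(t_sorted[-1])
    knots = np.concatenate([[0.0], event_times, [t_max]])
    steps = np.concatenate([[1.0], surv])
    widths = np.diff(knots)
    mean = float(np.sum(steps * np.clip(widths, 0.0, None)))
    restricted = bool(e_sorted[np.argmax(t_sorted)] == 0 or surv[-1] > 0)

    def first_crossing(values: np.ndarray) -> float | None:
        idx = np.nonzero(values <= 0.5)[0]
        return float(event_times[idx[0]]) if idx.size else None

    median = first_crossing(surv)
    median_ci = (first_crossing(lo_a), first_crossing(hi_a))

    return KMEstimate(
        event_times=event_times,
        survival=surv,
        variance=np.asarray(var),
        ci_low=lo_a,
        ci_high=hi_a,
        median=median,
        median_ci=median_ci,
        mean=mean,
        mean_is_restricted=restricted,
        n=n,
    )


def km_median(
    est: KMEstimate,
) -> tuple[float | None, tuple[float | None, float | None]]:
    """Median survival time (smallest t with S(t) <= 0.5) and its 95% CI.

    ``None`` entries mark quantities undefined because the curve (or a band)
    never reaches 0.5.
    """
    return est.median, est.median_ci


# --- AFT families ----------------------------------------------------------


def _ev_logpdf(z):
    return z - np.exp(z)


def _ev_logsf(z):
    return -np.exp(z)


def _logistic_logpdf(z):
    return z - 2.0 * np.logaddexp(0.0, z)


def _logistic_logsf(z):
    return -np.logaddexp(0.0, z)


_ERROR_DISTS = {
    "exponential": (_ev_logpdf, _ev_logsf),
    "weibull": (_ev_logpdf, _ev_logsf),
    "lognormal": (norm.logpdf, norm.logsf),
    "loglogistic": (_logistic_logpdf, _logistic_logsf),
}
# standard deviation of each standardized error distribution, for inits
_ERROR_SD = {
    "weibull": math.pi / math.sqrt(6.0),
    "lognormal": 1.0,
    "loglogistic": math.pi / math.sqrt(3.0),
}


@dataclass(frozen=True)
class AFTFit:
    family: str
    coefficients: np.ndarray  # intercept [+ covariate slope], log-time scale
    shape: float | None  # scale σ of the log-time error; None for exponential
    loglik: float
    k: int
    aic: float
    sample_fingerprint: str


def _aft_negloglik(params, family, logt, events, X):
    logpdf, logsf = _ERROR_DISTS[family]
    if family == "exponential":
        beta, sigma = params, 1.0
    else:
        beta, sigma = params[:-1], math.exp(params[-1])
    z = (logt - X @ beta) / sigma
    ll = np.where(events == 1, logpdf(z) - math.log(sigma) - logt, logsf(z))
    return -float(np.sum(ll))


def aft_fit(sample: SurvivalSample, family: str) -> AFTFit:
    """Maximum-likelihood AFT fit for one family.

    With a covariate present the parameter count is 2 for the exponential
    (intercept + slope) and 3 otherwise (+ scale), and ``aic = −2ℓ + 2k``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if sample.events.sum() < 1:
        raise ValueError("need at least one observed event")
    logt = np.log(sample.times)
    if sample.covariate is not None:
        X = np.column_stack([np.ones(sample.n), sample.covariate])
    else:
        X = np.ones((sample.n, 1))

    # method-of-moments start from an OLS fit of log time
    beta0, *_ = np.linalg.lstsq(X, logt, rcond=None)
    resid_sd = float(np.std(logt - X @ beta0)) or 0.5
    starts = []
    if family == "exponential":
        starts.append(beta0)
    else:
        sigma0 = max(resid_sd / _ERROR_SD[family], 1e-3)
        starts.append(np.append(beta0, math.log(sigma0)))
        starts.append(np.append(beta0, 0.0))  # exponential-like start (σ = 1)
        exp_fit = aft_fit(sample, "exponential")
        starts.append(np.append(exp_fit.coefficients, 0.0))

    best = None
    for x0 in starts:
        res = minimize(
            _aft_negloglik,
            x0,
            args=(family, logt, sample.events, X),
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 1000},
        )
        for cand_x, cand_f in ((res.x, res.fun), (x0, _aft_negloglik(x0, family, logt, sample.events, X))):
            if np.isfinite(cand_f) and (best is None or cand_f < best[1]):
                best = (np.asarray(cand_x, dtype=float), float(cand_f))
    if best is None:
        raise RuntimeError(f"{family} AFT fit failed to converge")
    # Nelder-Mead polish: gradient-free, tightens flat directions
    res = minimize(
        _aft_negloglik,
        best[0],
        args=(family, logt, sample.events, X),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    if np.isfinite(res.fun) and res.fun < best[1]:
        best = (np.asarray(res.x, dtype=float), float(res.fun))

    x_hat, nll = best
    if not np.isfinite(nll):
        raise RuntimeError(f"{family} AFT fit diverged (non-finite log-likelihood)")
    if family == "exponential":
        coef, shape = x_hat, None
    else:
        coef, shape = x_hat[:-1], float(math.exp(x_hat[-1]))
    k = coef.size + (0 if shape is None else 1)
    ll = -nll
    return AFTFit(
        family=family,
        coefficients=coef,
        shape=shape,
        loglik=ll,
        k=int(k),
        aic=aic(ll, int(k)),
        sample_fingerprint=sample.fingerprint(),
    )


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion ``−2·loglik + 2·k``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if not math.isfinite(loglik):
        raise ValueError("loglik must be finite")
    return -2.0 * loglik + 2.0 * k


@dataclass(frozen=True)
class SelectionResult:
    best: AFTFit
    ranking: tuple[AFTFit, ...]


def select_model(fits: Sequence[AFTFit]) -> SelectionResult:
    """Rank fits by AIC (lowest wins; ties broken by lower k, then input order)."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    fingerprints = {f.sample_fingerprint for f in fits}
    if len(fingerprints) > 1:
        raise ValueError("fits were computed on differing samples")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].k, i))
    ranking = tuple(fits[i] for i in order)
    return SelectionResult(best=ranking[0], ranking=ranking)


# --- endpoint extraction from event histories ------------------------------


def death_sample(cohort, use_covariate: bool = True) -> SurvivalSample:
    """Time-to-death sample: every individual, no censoring by design."""
    times = [max(rec.death_age_d, 1) for rec in cohort]
    cov = [rec.temperature_C for rec in cohort] if use_covariate else None
    return SurvivalSample(
        times=np.asarray(times, dtype=float),
        events=np.ones(len(times), dtype=int),
        covariate=None if cov is None else np.asarray(cov, dtype=float),
    )


def first_egg_sample(cohort, use_covariate: bool = True) -> SurvivalSample:
    """Time to first egg for adult females; death before any egg right-censors.

    Time is the age (days from oviposition) at the first nonzero daily count;
    females that die without laying contribute their death age as a censored
    observation.  Males and individuals dying as immatures are excluded.
    """
    times, events, cov = [], [], []
    for rec in cohort:
        if rec.sex != "female" or not rec.reached_adulthood:
            continue
        first = next((age for age, c in rec.daily_eggs if c > 0), None)
        if first is not None:
            times.append(first)
            events.append(1)
        else:
            times.append(max(rec.death_age_d, 1))
            events.append(0)
        cov.append(rec.temperature_C)
    if not times:
        raise ValueError("no adult females in cohort")
    return SurvivalSample(
        times=np.asarray(times, dtype=float),
        events=np.asarray(events, dtype=int),
        covariate=np.asarray(cov, dtype=float) if use_covariate else None,
    )
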