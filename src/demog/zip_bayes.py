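"""Bayesian zero-inflated Poisson (ZIP) model for daily egg counts.

A count is zero with probability ``p`` (a structural zero) and otherwise
Poisson(λ).  Priors: Uniform(0, 1) on ``p`` and Normal(0, prior_sd²) on
``log λ``.  Inference is by a data-augmentation Gibbs sampler: each observed
zero carries a latent indicator (structural vs. Poisson zero), ``p`` has a
conjugate Beta update, and ``log λ`` is updated with a Gaussian random-walk
Metropolis step whose scale adapts during burn-in and is frozen afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .bootstrap import WaldResult, wald_compare

__all__ = [
    "ZipPosterior",
    "GroupComparison",
    "zip_loglik",
    "zip_mcmc",
    "zero_probability",
    "pearson_residuals",
    "compare_groups",
]


def _validate_counts(counts, allow_empty: bool = False) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size == 0:
        if allow_empty:
            return counts.astype(int)
        raise ValueError("need at least one count")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        if np.any(counts != np.floor(counts)) or np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(int)
    return counts.astype(int)


def zip_loglik(counts, p: float, lam: float) -> float:
    """ZIP log-likelihood.

    Zeros contribute ``log(p + (1−p)·e^(−λ))``; a nonzero count k contributes
    ``log(1−p) + k·log λ − λ − log k!``.  Returns −inf when the data are
    impossible under the parameters (e.g. p = 1 with a nonzero count).
    """
    counts = _validate_counts(counts)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    zeros = counts == 0
    n0 = int(zeros.sum())
    k = counts[~zeros]
    ll = n0 * math.log(p + (1.0 - p) * math.exp(-lam)) if n0 else 0.0
    if k.size:
        if p >= 1.0:
            return -math.inf
        ll += float(
            k.size * (math.log1p(-p) - lam)
            + np.sum(k * math.log(lam) - gammaln(k + 1.0))
        )
    return float(ll)


@dataclass(frozen=True)
class ZipPosterior:
    """Kept MCMC draws and posterior summaries for one group."""

    p_draws: np.ndarray
    lambda_draws: np.ndarray
    n_kept: int
    summaries: Mapping[str, tuple[float, float, float]]  # mean, 2.5%, 97.5%
    zero_prob_summary: tuple[float, float, float]
    group: str | None = None

    @property
    def p_mean(self) -> float:
        return self.summaries["p"][0]

    @property
    def lambda_mean(self) -> float:
        return self.summaries["lambda"][0]


def _summary(draws: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi)


def zip_mcmc(
    counts,
    n_iter: int = 7000,
    burn_in: int = 4000,
    seed: int | None = None,
    prior_sd_loglambda: float = 10.0,
    group: str | None = None,
) -> ZipPosterior:
    """Posterior draws of (p, λ) by data-augmentation Gibbs sampling.

    Defaults: 7000 iterations with the first 4000 discarded as burn-in.
    Fully reproducible for a fixed ``seed``.  With an all-zero sample the λ
    posterior is driven by its prior; a warning is emitted but the run
    proceeds.
    """
    counts = _validate_counts(counts, allow_empty=True)
    if not n_iter > burn_in >= 0:
        raise ValueError("require n_iter > burn_in >= 0")
    if prior_sd_loglambda <= 0:
        raise ValueError("prior_sd_loglambda must be > 0")
    if np.all(counts == 0):
        warnings.warn("no nonzero counts: lambda posterior follows its prior")

    rng = np.random.default_rng(seed)
    n = counts.size
    zeros = counts == 0
    n0 = int(zeros.sum())
    nonzero = counts[~zeros]
    m1 = int(nonzero.size)
    S1 = int(nonzero.sum())
    prior_var = prior_sd_loglambda**2

    # initial state
    p = min(max(n0 / n, 0.05), 0.95) if n else 0.5
    lam = float(nonzero.mean()) if m1 else 1.0
    theta = math.log(lam)
    step = 0.5
    accepted = 0
    window = 0

    p_draws = np.empty(n_iter)
    l_draws = np.empty(n_iter)
    for it in range(n_iter):
        # latent split of the zeros into structural vs Poisson zeros
        if n0:
            prob_struct = p / (p + (1.0 - p) * math.exp(-lam))
            k_struct = int(rng.binomial(n0, prob_struct))
        else:
            k_struct = 0
        # conjugate Beta update for p under the Uniform(0,1) = Beta(1,1) prior
        p = float(rng.beta(1 + k_struct, 1 + n - k_struct))
        # Metropolis update for log λ
        m_active = n0 - k_struct + m1

        def log_target(th: float) -> float:
            lam_ = math.exp(th)
            return S1 * th - m_active * lam_ - th * th / (2.0 * prior_var)

        prop = theta + step * rng.normal()
        if math.log(rng.random()) < log_target(prop) - log_target(theta):
            theta = prop
            accepted += 1
        window += 1
        if it < burn_in and window == 50:  # adapt toward ~44% acceptance
            rate = accepted / window
            step *= math.exp(0.5 * (rate - 0.44))
            accepted = 0
            window = 0
        lam = math.exp(theta)
        p_draws[it] = p
        l_draws[it] = lam

    kept_p = p_draws[burn_in:]
    kept_l = l_draws[burn_in:]
    zero_probs = zero_probability(kept_p, kept_l)
    return ZipPosterior(
        p_draws=kept_p,
        lambda_draws=kept_l,
        n_kept=n_iter - burn_in,
        summaries={"p": _summary(kept_p), "lambda": _summary(kept_l)},
        zero_prob_summary=_summary(np.asarray(zero_probs)),
        group=group,
    )


def zero_probability(p, lam):
    """Marginal probability of a zero count: ``p + (1−p)·e^(−λ)``."""
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must be in [0, 1]")
    if np.any(lam <= 0):
        raise ValueError("lambda must be > 0")
    out = p + (1.0 - p) * np.exp(-lam)
    return float(out) if out.ndim == 0 else out


def pearson_residuals(counts, p: float, lam: float) -> np.ndarray:
    """Standardized residuals ``(k − μ)/σ`` under the ZIP mean/variance.

    ``μ = (1−p)·λ`` and ``σ² = (1−p)·λ·(1 + p·λ)``.
    """
    counts = _validate_counts(counts)
    mu = (1.0 - p) * lam
    var = (1.0 - p) * lam * (1.0 + p * lam)
    if var <= 0:
        raise ValueError("ZIP variance is zero; residuals undefined")
    return (counts - mu) / math.sqrt(var)


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    wald: WaldResult
    prob_a_greater: float


def compare_groups(
    posteriors: Mapping[str, ZipPosterior] | Sequence[ZipPosterior],
) -> list[GroupComparison]:
    """Pairwise comparison of the Poisson rates λ across groups.

    For each pair: a Wald z-test on the posterior means using the posterior
    standard deviations as standard errors (a "Bayesian p-value"), plus the
    direct posterior probability ``Pr(λ_a > λ_b)`` from paired draws.
    """
    if isinstance(posteriors, Mapping):
        items = list(posteriors.items())
    else:
        items = [(post.group or str(i), post) for i, post in enumerate(posteriors)]
    if len(items) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (name_a, post_a), (name_b, post_b) = items[i], items[j]
            sd_a = float(np.std(post_a.lambda_draws, ddof=1))
            sd_b = float(np.std(post_b.lambda_draws, ddof=1))
            if sd_a == 0 or sd_b == 0:
                raise ValueError(
                    f"degenerate posterior (zero sd) in group {name_a if sd_a == 0 else name_b}"
                )
            wald = wald_compare(post_a.lambda_mean, sd_a, post_b.lambda_mean, sd_b)
            m = min(post_a.lambda_draws.size, post_b.lambda_draws.size)
            prob = float(
                np.mean(post_a.lambda_draws[:m] > post_b.lambda_draws[:m])
            )
            out.append(
                GroupComparison(
                    group_a=name_a, group_b=name_b, wald=wald, prob_a_greater=prob
                )
            )
    return out
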