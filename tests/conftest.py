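import numpy as np
import pytest

from demog.life_table import LifeTable
from demog.synthetic import default_scenario, generate_cohort


@pytest.fixture(scope="session")
def cohort30():
    return generate_cohort(default_scenario(30.0, n_individuals=2000, seed=101))


@pytest.fixture(scope="session")
def cohort35():
    return generate_cohort(default_scenario(35.0, n_individuals=2000, seed=102))


@pytest.fixture(scope="session")
def cohort40():
    return generate_cohort(default_scenario(40.0, n_individuals=2000, seed=103))


@pytest.fixture(scope="session")
def small_cohorts():
    """One modest cohort per temperature, for pipeline/CLI smoke tests."""
    return {
        temp: generate_cohort(default_scenario(temp, n_individuals=150, seed=200 + i))
        for i, temp in enumerate((30.0, 35.0, 40.0))
    }


def make_table(lx, mx):
    """LifeTable from raw schedules, with qx derived the standard way."""
    lx = np.asarray(lx, dtype=float)
    mx = np.asarray(mx, dtype=float)
    lx_next = np.append(lx[1:], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = np.where(lx > 0, 1.0 - lx_next / np.where(lx > 0, lx, 1.0), np.nan)
    return LifeTable(ages=np.arange(lx.size), lx=lx, qx=qx, mx=mx)


@pytest.fixture
def table_factory():
    return make_table


def expected_R0(cfg):
    """Generating expectation of R0 under sex-independent survival.

    R0 -> female_ratio * P(reach adulthood) * E[# ZIP-active days] * (1-p)*lam,
    with the active-day count E[max(0, L - G)] computed by enumerating the
    adult-lifespan (shifted Poisson) and pre-oviposition (geometric) laws.
    """
    import math

    from scipy.stats import geom, poisson

    p_adult = 1.0
    for s in ("egg", "larva", "pupa"):
        p_adult *= cfg.stage_survival_probs[s]
    mean_L = float(cfg.adult_death_dist["mean"])
    q = 1.0 / (1.0 + cfg.preoviposition_mean)
    expected_days = 0.0
    for L in range(1, int(mean_L + 12 * math.sqrt(mean_L)) + 2):
        pL = poisson.pmf(L - 1, mean_L - 1.0)
        for G in range(0, L):
            expected_days += pL * geom.pmf(G + 1, q) * (L - G)
    return (
        cfg.female_ratio * p_adult * expected_days * (1.0 - cfg.zip_p) * cfg.zip_lambda
    )


def random_schedule(rng, max_age=60):
    """Random decreasing lx with reproductive mass at adult ages."""
    n = int(rng.integers(6, max_age))
    drops = rng.random(n) * 0.1
    lx = np.clip(1.0 - np.cumsum(drops), 0.0, 1.0)
    lx = np.concatenate([[1.0], lx])
    mx = np.zeros(n + 1)
    start = int(rng.integers(1, max(2, n // 2)))
    mx[start:] = rng.random(n + 1 - start) * rng.uniform(0.2, 4.0)
    mx[lx == 0] = 0.0
    if not np.any(lx * mx > 0):
        mx[1] = 1.0  # guarantee reproduction somewhere lx > 0
    return make_table(lx, mx)
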