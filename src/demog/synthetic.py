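"""Seeded synthetic insect cohorts with stage-structured mortality and
zero-inflated daily fecundity.

The generator produces individual-level event histories on a whole-day grid
(age 0 = oviposition day): three immature stages (egg, larva, pupa) with
per-stage survival, an adult lifespan drawn from a configurable discrete
distribution, a geometric pre-oviposition delay for females, and daily egg
counts drawn from a zero-inflated Poisson (ZIP) process — a structural zero
with probability ``zip_p``, otherwise ``Poisson(zip_lambda)``.

Per-female daily egg series cover every adult day (zeros included), so the
observed zero fraction combines pre-oviposition zeros with ZIP zeros; the
ZIP draw itself starts only after the pre-oviposition delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "STAGES",
    "ScenarioConfig",
    "IndividualRecord",
    "generate_cohort",
    "default_scenario",
    "zip_counts",
]

STAGES = ("egg", "larva", "pupa")

_ADULT_DEATH_DISTS = ("shifted_poisson", "geometric", "fixed")


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid ScenarioConfig.{fieldname}: {msg}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulated temperature treatment."""

    temperature_C: float
    n_individuals: int
    stage_duration_means: Mapping[str, float]
    stage_survival_probs: Mapping[str, float]
    adult_death_dist: Mapping[str, float | str]
    female_ratio: float = 0.5
    zip_p: float = 0.9
    zip_lambda: float = 1.0
    preoviposition_mean: float = 3.0
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        _check(self.temperature_C > 0, "temperature_C", "must be positive")
        _check(
            isinstance(self.n_individuals, (int, np.integer)) and self.n_individuals >= 1,
            "n_individuals",
            "must be an integer >= 1",
        )
        for stage in STAGES:
            _check(
                stage in self.stage_duration_means,
                "stage_duration_means",
                f"missing stage {stage!r}",
            )
            _check(
                stage in self.stage_survival_probs,
                "stage_survival_probs",
                f"missing stage {stage!r}",
            )
            _check(
                self.stage_duration_means[stage] > 0,
                "stage_duration_means",
                f"{stage} mean must be > 0",
            )
            _check(
                0.0 <= self.stage_survival_probs[stage] <= 1.0,
                "stage_survival_probs",
                f"{stage} probability must be in [0, 1]",
            )
        name = self.adult_death_dist.get("name")
        _check(
            name in _ADULT_DEATH_DISTS,
            "adult_death_dist",
            f"name must be one of {_ADULT_DEATH_DISTS}",
        )
        _check(
            float(self.adult_death_dist.get("mean", 0.0)) > 0,
            "adult_death_dist",
            "mean must be > 0",
        )
        _check(0.0 <= self.female_ratio <= 1.0, "female_ratio", "must be in [0, 1]")
        _check(0.0 <= self.zip_p <= 1.0, "zip_p", "must be in [0, 1]")
        _check(self.zip_lambda > 0, "zip_lambda", "must be > 0")
        _check(self.preoviposition_mean > 0, "preoviposition_mean", "must be > 0")
        _check(isinstance(self.seed, (int, np.integer)), "seed", "must be an integer")
        return self


@dataclass(frozen=True)
class IndividualRecord:
    """One individual's event history, all ages in integer days from oviposition.

    ``egg_days``/``larval_days``/``pupal_days`` are completed stage durations
    (0 when death occurred before the stage was completed).  ``daily_eggs``
    holds ``(age_d, count)`` pairs for every adult day of a female that
    reached adulthood, and is empty for males and individuals dying as
    immatures.  ``oviposition_start_d`` is the first age at which the ZIP
    laying process is active (``None`` for males / immature deaths); it may
    exceed ``death_age_d`` when the female died before laying was possible.
    """

    id: int
    temperature_C: float
    sex: str
    egg_days: int
    larval_days: int
    pupal_days: int
    death_age_d: int
    oviposition_start_d: int | None = None
    daily_eggs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        dev = self.egg_days + self.larval_days + self.pupal_days
        if min(self.egg_days, self.larval_days, self.pupal_days, self.death_age_d) < 0:
            raise ValueError("stage durations and death age must be non-negative")
        if self.death_age_d < dev:
            raise ValueError("death_age_d below the sum of completed stage durations")
        for age, count in self.daily_eggs:
            if not dev <= age < self.death_age_d:
                raise ValueError(
                    f"daily_eggs age {age} outside adult lifespan [{dev}, {self.death_age_d})"
                )
            if count < 0 or int(count) != count:
                raise ValueError("daily_eggs counts must be non-negative integers")

    @property
    def development_days(self) -> int:
        return self.egg_days + self.larval_days + self.pupal_days

    @property
    def reached_adulthood(self) -> bool:
        return (
            self.egg_days > 0
            and self.larval_days > 0
            and self.pupal_days > 0
            and self.death_age_d >= self.development_days
        )

    def eggs_at(self, age: int) -> int:
        for a, c in self.daily_eggs:
            if a == age:
                return c
        return 0


def _shifted_poisson(rng: np.random.Generator, mean: float) -> int:
    # integer duration >= 1 with the requested mean (for mean >= 1)
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _draw_adult_lifespan(rng: np.random.Generator, dist: Mapping) -> int:
    name = dist["name"]
    mean = float(dist["mean"])
    if name == "shifted_poisson":
        return _shifted_poisson(rng, mean)
    if name == "geometric":
        return int(rng.geometric(min(1.0, 1.0 / mean)))
    if name == "fixed":
        return max(1, int(round(mean)))
    raise ValueError(f"unknown adult death distribution {name!r}")


def zip_counts(
    rng: np.random.Generator, n: int, p: float, lam: float
) -> np.ndarray:
    """Draw ``n`` zero-inflated Poisson counts: 0 w.p. ``p``, else Poisson(lam)."""
    structural = rng.random(n) < p
    counts = rng.poisson(lam, size=n)
    counts[structural] = 0
    return counts


def generate_cohort(config: ScenarioConfig) -> list[IndividualRecord]:
    """Simulate one cohort of ``config.n_individuals`` event histories.

    Deterministic for a fixed ``config.seed``: one RNG sub-stream per
    individual, spawned from a single seed sequence.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_individuals)
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sex = "female" if rng.random() < config.female_ratio else "male"

        completed = {stage: 0 for stage in STAGES}
        age = 0
        died_immature = False
        for stage in STAGES:
            duration = _shifted_poisson(rng, config.stage_duration_means[stage])
            if rng.random() < config.stage_survival_probs[stage]:
                completed[stage] = duration
                age += duration
            else:
                # death on a uniformly chosen day within the stage
                age += int(rng.integers(1, duration + 1))
                died_immature = True
                break

        if died_immature:
            records.append(
                IndividualRecord(
                    id=i,
                    temperature_C=config.temperature_C,
                    sex=sex,
                    egg_days=completed["egg"],
                    larval_days=completed["larva"],
                    pupal_days=completed["pupa"],
                    death_age_d=age,
                )
            )
            continue

        development = age
        death_age = development + _draw_adult_lifespan(rng, config.adult_death_dist)

        oviposition_start = None
        daily: tuple[tuple[int, int], ...] = ()
        if sex == "female":
            # geometric pre-oviposition delay on {0, 1, 2, ...}
            delay = int(rng.geometric(1.0 / (1.0 + config.preoviposition_mean))) - 1
            oviposition_start = development + delay
            adult_ages = np.arange(development, death_age)
            counts = np.zeros(adult_ages.size, dtype=int)
            active = adult_ages >= oviposition_start
            n_active = int(active.sum())
            if n_active:
                counts[active] = zip_counts(
                    rng, n_active, config.zip_p, config.zip_lambda
                )
            daily = tuple(
                (int(a), int(c)) for a, c in zip(adult_ages, counts)
            )

        records.append(
            IndividualRecord(
                id=i,
                temperature_C=config.temperature_C,
                sex=sex,
                egg_days=completed["egg"],
                larval_days=completed["larva"],
                pupal_days=completed["pupa"],
                death_age_d=death_age,
                oviposition_start_d=oviposition_start,
                daily_eggs=daily,
            )
        )
    return records


# Presets chosen to preserve the qualitative pattern of interest: growing
# populations at 30 and 35 °C, a collapsing one at 40 °C, a zero fraction of
# daily egg counts above 0.90 everywhere, and heavy right-censoring of
# time-to-first-egg at 40 °C.  No attempt is made to match any particular
# empirical cohort.
_PRESETS: dict[float, dict] = {
    30.0: dict(
        stage_duration_means={"egg": 5.0, "larva": 25.0, "pupa": 5.0},
        stage_survival_probs={"egg": 0.95, "larva": 0.90, "pupa": 0.95},
        adult_death_dist={"name": "shifted_poisson", "mean": 28.0},
        zip_p=0.93,
        zip_lambda=5.0,
        preoviposition_mean=4.0,
    ),
    35.0: dict(
        stage_duration_means={"egg": 4.0, "larva": 16.0, "pupa": 4.0},
        stage_survival_probs={"egg": 0.92, "larva": 0.85, "pupa": 0.92},
        adult_death_dist={"name": "shifted_poisson", "mean": 14.0},
        zip_p=0.92,
        zip_lambda=6.0,
        preoviposition_mean=3.0,
    ),
    40.0: dict(
        stage_duration_means={"egg": 3.0, "larva": 10.0, "pupa": 3.0},
        stage_survival_probs={"egg": 0.70, "larva": 0.50, "pupa": 0.70},
        adult_death_dist={"name": "shifted_poisson", "mean": 6.0},
        zip_p=0.85,
        zip_lambda=1.2,
        preoviposition_mean=4.0,
    ),
}


def _interpolate_presets(temperature_C: float) -> dict:
    temps = sorted(_PRESETS)
    if temperature_C <= temps[0]:
        return dict(_PRESETS[temps[0]])
    if temperature_C >= temps[-1]:
        return dict(_PRESETS[temps[-1]])
    hi = next(t for t in temps if t >= temperature_C)
    lo = max(t for t in temps if t <= temperature_C)
    if hi == lo:
        return dict(_PRESETS[lo])
    w = (temperature_C - lo) / (hi - lo)

    def lerp(a, b):
        if isinstance(a, dict):
            if "name" in a:  # distribution spec: interpolate the mean only
                return {"name": a["name"], "mean": lerp(float(a["mean"]), float(b["mean"]))}
            return {k: lerp(a[k], b[k]) for k in a}
        return (1.0 - w) * a + w * b

    return {k: lerp(_PRESETS[lo][k], _PRESETS[hi][k]) for k in _PRESETS[lo]}


def default_scenario(
    temperature_C: float, n_individuals: int = 400, seed: int = 0
) -> ScenarioConfig:
    """Preset scenario for a temperature treatment.

    The 30/35/40 °C presets are tabulated; any other positive temperature
    gets linearly interpolated (clamped outside the preset range).
    """
    if not np.isfinite(temperature_C) or temperature_C <= 0:
        raise ValueError("invalid ScenarioConfig.temperature_C: must be positive")
    params = _interpolate_presets(float(temperature_C))
    return ScenarioConfig(
        temperature_C=float(temperature_C),
        n_individuals=n_individuals,
        female_ratio=0.5,
        seed=seed,
        **params,
    ).validate()


def with_overrides(config: ScenarioConfig, **kwargs) -> ScenarioConfig:
    """Return a copy of ``config`` with the given fields replaced and re-validated."""
    return replace(config, **kwargs).validate()
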