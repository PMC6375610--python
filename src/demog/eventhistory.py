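"""Two-file CSV event-history schema and its validated reader/writer.

``individuals.csv``: id, temperature_C, sex, egg_days, larval_days,
pupal_days, oviposition_start_d, death_age_d — one row per individual.
``fecundity.csv``: id, age_d, eggs — one row per recorded female-day.

Comma-separated, UTF-8, header row required, "." decimal; missing values are
empty fields.  Schema violations fail hard with row-level messages.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .synthetic import IndividualRecord, ScenarioConfig

__all__ = [
    "EventHistoryError",
    "write_event_history",
    "read_event_history",
    "write_scenario_sidecar",
]

INDIVIDUAL_COLUMNS = [
    "id",
    "temperature_C",
    "sex",
    "egg_days",
    "larval_days",
    "pupal_days",
    "oviposition_start_d",
    "death_age_d",
]
FECUNDITY_COLUMNS = ["id", "age_d", "eggs"]


class EventHistoryError(ValueError):
    """Schema or consistency violation in event-history CSVs."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid event history:\n" + "\n".join(self.problems))


def write_event_history(
    cohort: Sequence[IndividualRecord],
    individuals_path: str | Path,
    fecundity_path: str | Path,
) -> None:
    """Serialize a cohort to the two-file CSV schema (rows sorted by id/age)."""
    cohort = sorted(cohort, key=lambda rec: rec.id)
    ind_rows = []
    fec_rows = []
    for rec in cohort:
        ind_rows.append(
            {
                "id": rec.id,
                "temperature_C": rec.temperature_C,
                "sex": rec.sex,
                "egg_days": rec.egg_days,
                "larval_days": rec.larval_days,
                "pupal_days": rec.pupal_days,
                "oviposition_start_d": "" if rec.oviposition_start_d is None else rec.oviposition_start_d,
                "death_age_d": rec.death_age_d,
            }
        )
        for age, count in sorted(rec.daily_eggs):
            fec_rows.append({"id": rec.id, "age_d": age, "eggs": count})
    pd.DataFrame(ind_rows, columns=INDIVIDUAL_COLUMNS).to_csv(
        individuals_path, index=False
    )
    pd.DataFrame(fec_rows, columns=FECUNDITY_COLUMNS).to_csv(
        fecundity_path, index=False
    )


def write_scenario_sidecar(config: ScenarioConfig, path: str | Path) -> None:
    """Write the generating scenario next to its CSVs as JSON."""
    payload = asdict(config)
    payload["stage_duration_means"] = dict(payload["stage_duration_means"])
    payload["stage_survival_probs"] = dict(payload["stage_survival_probs"])
    payload["adult_death_dist"] = dict(payload["adult_death_dist"])
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_event_history(
    individuals_path: str | Path, fecundity_path: str | Path
) -> dict[float, list[IndividualRecord]]:
    """Load and validate the two CSVs; returns cohorts keyed by temperature."""
    for path in (individuals_path, fecundity_path):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    ind = pd.read_csv(individuals_path)
    fec = pd.read_csv(fecundity_path)

    problems: list[str] = []
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in ind.columns and c != "oviposition_start_d"]
    missing += [c for c in FECUNDITY_COLUMNS if c not in fec.columns]
    if missing:
        raise EventHistoryError([f"missing column(s): {', '.join(missing)}"])
    if "oviposition_start_d" not in ind.columns:
        ind["oviposition_start_d"] = pd.NA

    dup_ids = ind["id"][ind["id"].duplicated()].unique()
    for i in dup_ids:
        problems.append(f"duplicate individual id {i}")
    known_ids = set(ind["id"])
    for row in fec.itertuples(index=True):
        if row.id not in known_ids:
            problems.append(f"fecundity row {row.Index}: unknown id {row.id}")
    dup_pairs = fec[fec.duplicated(subset=["id", "age_d"], keep=False)]
    for (i, age), _ in dup_pairs.groupby(["id", "age_d"]):
        problems.append(f"duplicate fecundity pair (id={i}, age_d={age})")
    for col in ("egg_days", "larval_days", "pupal_days", "death_age_d"):
        bad = ind.index[ind[col] < 0]
        for idx in bad:
            problems.append(f"individuals row {idx}: negative {col}")
    bad = fec.index[fec["eggs"] < 0]
    for idx in bad:
        problems.append(f"fecundity row {idx}: negative eggs")
    if problems:
        raise EventHistoryError(problems)

    eggs_by_id: dict = {i: [] for i in known_ids}
    for row in fec.itertuples():
        eggs_by_id[row.id].append((int(row.age_d), int(row.eggs)))

    cohorts: dict[float, list[IndividualRecord]] = {}
    for row in ind.itertuples(index=True):
        start = row.oviposition_start_d
        start = None if pd.isna(start) else int(start)
        try:
            rec = IndividualRecord(
                id=int(row.id),
                temperature_C=float(row.temperature_C),
                sex=str(row.sex),
                egg_days=int(row.egg_days),
                larval_days=int(row.larval_days),
                pupal_days=int(row.pupal_days),
                death_age_d=int(row.death_age_d),
                oviposition_start_d=start,
                daily_eggs=tuple(sorted(eggs_by_id[row.id])),
            )
        except ValueError as exc:
            problems.append(f"individuals row {row.Index} (id={row.id}): {exc}")
            continue
        cohorts.setdefault(rec.temperature_C, []).append(rec)
    if problems:
        raise EventHistoryError(problems)
    return cohorts
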