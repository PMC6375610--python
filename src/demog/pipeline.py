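"""End-to-end orchestration: simulate/read cohorts, then run every analysis
stage (life table → bootstrap → thermal fit → survival → ZIP) and write the
report bundle.

Each stage logs to stderr, records the seeds it used in the report, and
leaves its partial outputs behind if a later stage fails.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bootstrap as bootmod
from . import life_table as ltmod
from . import survival as survmod
from . import thermal as thermod
from . import zip_bayes as zipmod
from .eventhistory import read_event_history, write_event_history, write_scenario_sidecar
from .synthetic import IndividualRecord, default_scenario, with_overrides

log = logging.getLogger("demog")

__all__ = ["PipelineError", "run_pipeline", "simulate_cohorts", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "simulate": {"temperatures": [30.0, 35.0, 40.0], "n_individuals": 400, "seed": 1},
    "lifetable": {"female_ratio": 0.5, "fecundity_denominator": "alive"},
    "bootstrap": {"B": 1000, "seed": 2},
    "thermal": {"anchor_temperature": 17.2, "TL_upper_bound": None},
    "zip": {"n_iter": 7000, "burn_in": 4000, "seed": 3, "prior_sd_loglambda": 10.0},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for user-facing reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def merge_config(config: Mapping | None) -> dict:
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (config or {}).items():
        merged.setdefault(section, {}).update(values)
    return merged


def simulate_cohorts(config: Mapping) -> dict[float, list[IndividualRecord]]:
    """Generate one cohort per configured temperature from the presets."""
    sim = config["simulate"]
    cohorts = {}
    for i, temp in enumerate(sim["temperatures"]):
        scenario = default_scenario(
            float(temp), n_individuals=int(sim["n_individuals"]), seed=int(sim["seed"]) + i
        )
        overrides = {k: v for k, v in sim.items() if k in ("female_ratio", "zip_p", "zip_lambda")}
        if overrides:
            scenario = with_overrides(scenario, **overrides)
        from .synthetic import generate_cohort

        cohorts[float(temp)] = generate_cohort(scenario)
        log.info("simulated %d individuals at %g degC (seed %d)", len(cohorts[float(temp)]), temp, scenario.seed)
    return cohorts


def _load_or_simulate(config: Mapping, out: Path) -> dict[float, list[IndividualRecord]]:
    inputs = config.get("inputs", {})
    if inputs.get("individuals"):
        log.info("reading event history from %s", inputs["individuals"])
        return read_event_history(inputs["individuals"], inputs["fecundity"])
    cohorts = _write_simulated(config, out)
    return cohorts


def _write_simulated(config: Mapping, out: Path) -> dict[float, list[IndividualRecord]]:
    cohorts = simulate_cohorts(config)
    sim = config["simulate"]
    for i, (temp, cohort) in enumerate(sorted(cohorts.items())):
        stem = out / f"cohort_{temp:g}C"
        write_event_history(cohort, f"{stem}_individuals.csv", f"{stem}_fecundity.csv")
        scenario = default_scenario(
            temp, n_individuals=int(sim["n_individuals"]), seed=int(sim["seed"]) + i
        )
        write_scenario_sidecar(scenario, f"{stem}_scenario.json")
    return cohorts


def _lifetable_stage(cohorts, cfg, out: Path) -> dict:
    block = {}
    for temp, cohort in sorted(cohorts.items()):
        lt = ltmod.build_life_table(
            cohort, cfg["female_ratio"], cfg["fecundity_denominator"]
        )
        try:
            r = ltmod.intrinsic_rate(lt)
        except ltmod.NoReproductionError:
            r = None
        schedules = ltmod.age_schedules(lt, r) if r is not None else None
        frame = pd.DataFrame(
            {
                "age": lt.ages,
                "lx": lt.lx,
                "qx": lt.qx,
                "mx": lt.mx,
                "Vx": schedules.Vx if schedules else np.nan,
                "Ex": ltmod.expected_remaining_life(lt),
            }
        )
        frame.to_csv(out / f"lifetable_{temp:g}C.csv", index=False)
        params = ltmod.demographic_params(lt) if r is not None else None
        block[f"{temp:g}"] = {
            "n": len(cohort),
            "R0": ltmod.net_reproductive_rate(lt),
            "r": None if params is None else params.r,
            "lambda_finite": None if params is None else params.lambda_finite,
            "T_gen": None if params is None else params.T_gen,
            "DT": None if params is None else params.DT,
        }
        log.info("life table at %g degC: R0=%.3f r=%s", temp, block[f"{temp:g}"]["R0"],
                 "n/a" if r is None else f"{r:.4f}")
    return block


def _bootstrap_stage(cohorts, lt_cfg, cfg, out: Path) -> dict:
    block = {}
    for i, (temp, cohort) in enumerate(sorted(cohorts.items())):
        seed = int(cfg["seed"]) + i
        results = bootmod.bootstrap_params(
            cohort,
            lt_cfg["female_ratio"],
            B=int(cfg["B"]),
            seed=seed,
            fecundity_denominator=lt_cfg["fecundity_denominator"],
        )
        block[f"{temp:g}"] = {
            "seed": seed,
            "B": int(cfg["B"]),
            "parameters": {
                name: {
                    "point_estimate": res.point_estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_failed": res.n_failed,
                }
                for name, res in results.items()
            },
        }
        log.info("bootstrap at %g degC done (B=%d, seed=%d)", temp, int(cfg["B"]), seed)
    return block


def _thermal_stage(lifetable_block, cfg, out: Path) -> dict:
    points = [thermod.BrierePoint(float(cfg["anchor_temperature"]), 0.0, is_anchor=True)]
    for temp, vals in lifetable_block.items():
        if vals["r"] is not None:
            points.append(thermod.BrierePoint(float(temp), vals["r"]))
    fit = thermod.fit_briere(points, TL_upper_bound=cfg.get("TL_upper_bound"))
    block = {
        "a": fit.a,
        "T0": fit.T0,
        "TL": fit.TL,
        "T_opt": fit.T_opt,
        "r_squared": fit.r_squared,
        "points": [
            {"temperature_C": p.temperature_C, "r": p.r_value, "is_anchor": p.is_anchor}
            for p in fit.points
        ],
    }
    (out / "briere_fit.json").write_text(json.dumps(block, indent=2) + "\n")
    grid = np.linspace(fit.T0, fit.TL, 200)
    pd.DataFrame({"temperature_C": grid, "r": fit.predict(grid)}).to_csv(
        out / "briere_curve.csv", index=False
    )
    log.info("thermal fit: T0=%.2f TL=%.2f Topt=%.2f R2=%.3f", fit.T0, fit.TL, fit.T_opt, fit.r_squared)
    return block


def _km_to_csv(est: survmod.KMEstimate, path: Path) -> None:
    pd.DataFrame(
        {
            "time": est.event_times,
            "survival": est.survival,
            "variance": est.variance,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
        }
    ).to_csv(path, index=False)


def _survival_stage(cohorts, out: Path) -> dict:
    pooled = [rec for cohort in cohorts.values() for rec in cohort]
    block: dict = {"km": {}, "aft": {}}
    for endpoint, extractor in (
        ("death", survmod.death_sample),
        ("first_egg", survmod.first_egg_sample),
    ):
        km_block = {}
        for temp, cohort in sorted(cohorts.items()):
            try:
                sample = extractor(cohort, use_covariate=False)
            except ValueError:
                continue
            est = survmod.km_fit(sample)
            _km_to_csv(est, out / f"km_{endpoint}_{temp:g}C.csv")
            km_block[f"{temp:g}"] = {
                "n": est.n,
                "median": est.median,
                "median_ci": list(est.median_ci),
                "mean": est.mean,
                "mean_is_restricted": est.mean_is_restricted,
            }
        block["km"][endpoint] = km_block

        sample = extractor(pooled, use_covariate=True)
        fits = [survmod.aft_fit(sample, fam) for fam in survmod.FAMILIES]
        selection = survmod.select_model(fits)
        pd.DataFrame(
            [
                {"family": f.family, "loglik": f.loglik, "aic": f.aic, "k": f.k}
                for f in fits
            ]
        ).to_csv(out / f"aft_{endpoint}.csv", index=False)
        block["aft"][endpoint] = {
            "best_family": selection.best.family,
            "table": [
                {"family": f.family, "loglik": f.loglik, "aic": f.aic, "k": f.k}
                for f in selection.ranking
            ],
        }
        log.info("AFT (%s): best family %s", endpoint, selection.best.family)
    return block


def _egg_counts(cohort: Sequence[IndividualRecord]) -> np.ndarray:
    counts = [c for rec in cohort if rec.sex == "female" for _, c in rec.daily_eggs]
    return np.asarray(counts, dtype=int)


def _zip_stage(cohorts, cfg, out: Path) -> dict:
    posteriors = {}
    block: dict = {"groups": {}, "comparisons": []}
    for i, (temp, cohort) in enumerate(sorted(cohorts.items())):
        counts = _egg_counts(cohort)
        if counts.size == 0:
            log.warning("no female-day counts at %g degC; skipping ZIP", temp)
            continue
        seed = int(cfg["seed"]) + i
        post = zipmod.zip_mcmc(
            counts,
            n_iter=int(cfg["n_iter"]),
            burn_in=int(cfg["burn_in"]),
            seed=seed,
            prior_sd_loglambda=float(cfg["prior_sd_loglambda"]),
            group=f"{temp:g}",
        )
        posteriors[f"{temp:g}"] = post
        resid = zipmod.pearson_residuals(counts, post.p_mean, post.lambda_mean)
        pd.DataFrame({"count": counts, "residual": resid}).to_csv(
            out / f"zip_residuals_{temp:g}C.csv", index=False
        )
        pd.DataFrame(
            {"p": post.p_draws, "lambda": post.lambda_draws}
        ).to_csv(out / f"zip_draws_{temp:g}C.csv", index=False)
        block["groups"][f"{temp:g}"] = {
            "seed": seed,
            "n_days": int(counts.size),
            "observed_zero_fraction": float((counts == 0).mean()),
            "p": list(post.summaries["p"]),
            "lambda": list(post.summaries["lambda"]),
            "zero_probability": list(post.zero_prob_summary),
        }
        log.info("ZIP at %g degC: p=%.3f lambda=%.3f", temp, post.p_mean, post.lambda_mean)
    if len(posteriors) >= 2:
        for comp in zipmod.compare_groups(posteriors):
            block["comparisons"].append(
                {
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "z": comp.wald.z,
                    "p_value": comp.wald.p_value,
                    "prob_a_greater": comp.prob_a_greater,
                }
            )
    (out / "zip_posterior.json").write_text(json.dumps(block, indent=2) + "\n")
    return block


def run_pipeline(config: Mapping | None, out_dir: str | Path) -> dict:
    """Run every stage in order and write the merged ``report.json``.

    Returns the report dict.  On a stage failure a :class:`PipelineError`
    naming the stage is raised; outputs of completed stages remain on disk.
    """
    config = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config}

    stages = [
        ("simulate", lambda: _load_or_simulate(config, out)),
    ]
    cohorts = None
    for stage_name, fn in stages:
        try:
            cohorts = fn()
        except Exception as exc:  # noqa: BLE001 — rewrap with stage name
            raise PipelineError(stage_name, exc) from exc

    def run(stage_name, fn):
        try:
            report[stage_name] = fn()
        except Exception as exc:  # noqa: BLE001
            _dump_report(report, out)
            raise PipelineError(stage_name, exc) from exc

    run("lifetable", lambda: _lifetable_stage(cohorts, config["lifetable"], out))
    run("bootstrap", lambda: _bootstrap_stage(cohorts, config["lifetable"], config["bootstrap"], out))
    run("thermal", lambda: _thermal_stage(report["lifetable"], config["thermal"], out))
    run("survival", lambda: _survival_stage(cohorts, out))
    run("zip", lambda: _zip_stage(cohorts, config["zip"], out))
    _dump_report(report, out)
    log.info("pipeline complete; report at %s", out / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_report(report: dict, out: Path) -> None:
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, float) and math.isnan(x):
            return None
        return x

    (out / "report.json").write_text(
        json.dumps(clean(report), indent=2, default=_json_default) + "\n"
    )
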