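# demog

Deterministic and stochastic cohort demography for stage-structured insect
populations reared at multiple constant temperatures, driven by a seeded
synthetic cohort generator.

The pipeline covers:

- **`demog.synthetic`** — seeded event-history simulation: egg/larva/pupa
  stage durations with per-stage survival, adult lifespan, geometric
  pre-oviposition delay, and zero-inflated Poisson (ZIP) daily egg counts.
  Presets for 30/35/40 °C preserve the qualitative pattern of a growing
  population at 30/35 °C and a collapsing one at 40 °C.
- **`demog.life_table`** — cohort schedules `lx`, `qx`, `mx`; net
  reproductive rate `R0 = Σ lx·mx`; intrinsic rate of increase `r` solving
  `Σ exp(−r·x)·lx·mx = 1`; finite rate `exp(r)`; mean generation time
  `ln(R0)/r`; doubling time `ln(2)/r`; reproductive value `Vx` and remaining
  life expectancy `Ex`.
- **`demog.bootstrap`** — percentile bootstrap (resampling whole
  individuals) for all scalar parameters, plus a Wald z-comparison helper.
- **`demog.thermal`** — the asymmetric thermal-performance curve
  `r(T) = a·T·(T−T0)·√(TL−T)` with profiled least squares, clamped
  predictions outside `[T0, TL]`, and the closed-form optimum temperature.
- **`demog.survival`** — Kaplan–Meier product-limit estimation (Greenwood
  variance, log-transformed bands, restricted mean) and maximum-likelihood
  AFT regression for exponential/Weibull/lognormal/loglogistic families with
  AIC ranking. Time-to-death is uncensored by design; time-to-first-egg is
  right-censored at death for females that never lay.
- **`demog.zip_bayes`** — Bayesian ZIP model of daily egg counts via a
  data-augmentation Gibbs sampler (conjugate Beta step for the
  structural-zero probability, adaptive Metropolis step for `log λ`),
  marginal zero probability `p + (1−p)e^(−λ)`, standardized residuals, and
  pairwise group comparisons.
- **`demog.eventhistory` / `demog.pipeline` / `demog.cli`** — the two-file
  CSV schema, TOML configuration, and the `demog` command.

## Command line

```sh
demog simulate --out out/                  # write synthetic event-history CSVs
demog all --config config.toml --out out/  # full pipeline + report.json
demog lifetable  --individuals out/cohort_30C_individuals.csv \
                 --fecundity   out/cohort_30C_fecundity.csv --out out/
demog bootstrap ... -B 1000
demog thermal ... / demog survfit ... / demog zipfit ...
```

Configuration is TOML with one section per stage (`[simulate]`,
`[lifetable]`, `[bootstrap]`, `[thermal]`, `[zip]`, `[inputs]`); flags
override config values. Logs go to stderr (`--quiet` to silence); results
are written as CSV/JSON files under `--out`, including a merged
`report.json` that records every seed used.

### Event-history schema

`individuals.csv`: `id, temperature_C, sex, egg_days, larval_days,
pupal_days, oviposition_start_d, death_age_d` (stage columns are completed
durations, 0 if death occurred earlier; ages are integer days from
oviposition).  `fecundity.csv`: `id, age_d, eggs`, one row per recorded
female-day, zeros included.

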