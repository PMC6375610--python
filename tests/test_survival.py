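import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demog.survival import (
    FAMILIES,
    AFTFit,
    SurvivalSample,
    aft_fit,
    aic,
    death_sample,
    first_egg_sample,
    km_fit,
    km_median,
    select_model,
)


def sample(times, events=None, cov=None):
    times = np.asarray(times, dtype=float)
    events = np.ones(times.size, dtype=int) if events is None else np.asarray(events)
    return SurvivalSample(times=times, events=events, covariate=cov)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        est = km_fit(sample([1, 2, 3]))
        assert np.allclose(est.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit(self):
        est = km_fit(sample([1, 2, 3], events=[1, 0, 1]))
        assert est.survival_at(1) == pytest.approx(2 / 3)
        assert est.survival_at(3) == pytest.approx(0.0)

    def test_heavy_censoring_median_undefined(self):
        # one early event among many later-censored subjects: S stays > 0.5
        est = km_fit(sample([1] + [10] * 9, events=[1] + [0] * 9))
        assert est.median is None

    def test_all_censored_warns_flat(self):
        with pytest.warns(UserWarning, match="censored"):
            est = km_fit(sample([2, 4, 6], events=[0, 0, 0]))
        assert est.median is None
        assert est.mean_is_restricted
        assert est.mean == pytest.approx(6.0)  # area under S == 1 up to t_max

    def test_empirical_survivor_property(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(3.0, 200) + 0.01
        est = km_fit(sample(times))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert est.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)
        assert est.mean == pytest.approx(times.mean())

    def test_greenwood_zero_at_boundaries(self):
        est = km_fit(sample([1, 2, 3, 4]))
        assert est.variance[-1] == 0.0  # S = 0
        assert np.all(est.variance >= 0)

    def test_bands_contain_estimate(self):
        rng = np.random.default_rng(1)
        times = rng.weibull(1.5, 100) * 10 + 0.01
        events = rng.integers(0, 2, 100) | (times > np.median(times)).astype(int)
        est = km_fit(sample(times, events))
        assert np.all(est.ci_low <= est.survival + 1e-12)
        assert np.all(est.ci_high >= est.survival - 1e-12)

    def test_median_first_crossing(self):
        est = km_fit(sample([7, 7, 7, 7, 7], events=[1, 1, 1, 0, 0]))
        # S drops 1 -> 0.4 at t=7
        assert est.survival_at(7) == pytest.approx(0.4)
        assert km_median(est)[0] == 7

    def test_median_tie_rule(self):
        # S hits exactly 0.5 at t=5, drops lower at t=8: median 5 by <= rule
        est = km_fit(sample([5, 5, 8, 8]))
        assert est.survival_at(5) == pytest.approx(0.5)
        assert km_median(est)[0] == 5

    def test_rejects_bad_samples(self):
        with pytest.raises(ValueError, match="positive"):
            sample([0.0, 1.0])
        with pytest.raises(ValueError, match="events"):
            SurvivalSample(times=np.array([1.0]), events=np.array([2]))


class TestAFT:
    def test_exponential_closed_form(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5.0, 400)
        fit = aft_fit(sample(t), "exponential")
        rate = 1.0 / t.mean()
        assert fit.coefficients[0] == pytest.approx(-math.log(rate), abs=1e-5)
        assert fit.loglik == pytest.approx(t.size * math.log(rate) - rate * t.sum(), abs=1e-6)
        assert fit.k == 1 and fit.shape is None

    def test_weibull_nests_exponential(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(2.0, 2000)
        fit = aft_fit(sample(t), "weibull")
        assert fit.shape == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(4))
    def test_weibull_loglik_dominates_exponential(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.weibull(rng.uniform(0.5, 3.0), 150) * 5 + 0.01
        events = (rng.random(150) < 0.8).astype(int)
        if events.sum() == 0:
            events[0] = 1
        s = sample(t, events)
        assert aft_fit(s, "weibull").loglik >= aft_fit(s, "exponential").loglik - 1e-6

    @pytest.mark.parametrize(
        "family, gen",
        [
            ("lognormal", lambda rng, mu, sig, n: rng.lognormal(mu, sig, n)),
            (
                "weibull",
                lambda rng, mu, sig, n: math.exp(mu)
                * rng.weibull(1.0 / sig, n) ** 1.0,
            ),
        ],
    )
    def test_parameter_recovery(self, family, gen):
        rng = np.random.default_rng(11)
        mu, sig = 2.0, 0.5
        t = gen(rng, mu, sig, 2000)
        fit = aft_fit(sample(t), family)
        assert fit.coefficients[0] == pytest.approx(mu, rel=0.05)
        assert fit.shape == pytest.approx(sig, rel=0.05)

    def test_covariate_slope_recovery(self):
        rng = np.random.default_rng(12)
        temp = rng.choice([30.0, 35.0, 40.0], 3000)
        t = np.exp(5.0 - 0.1 * temp + 0.4 * rng.normal(size=3000))
        fit = aft_fit(sample(t, cov=temp), "lognormal")
        assert fit.coefficients[1] == pytest.approx(-0.1, rel=0.05)
        assert fit.k == 3

    def test_parameter_counts_with_covariate(self, small_cohorts):
        pooled = [rec for c in small_cohorts.values() for rec in c]
        s = death_sample(pooled)
        ks = {fam: aft_fit(s, fam).k for fam in FAMILIES}
        assert ks == {"exponential": 2, "weibull": 3, "lognormal": 3, "loglogistic": 3}

    def test_aic_identity(self, small_cohorts):
        pooled = [rec for c in small_cohorts.values() for rec in c]
        s = death_sample(pooled)
        for fam in FAMILIES:
            fit = aft_fit(s, fam)
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, rel=1e-14)

    def test_matches_lifelines_oracle(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(21)
        n = 500
        temp = rng.choice([30.0, 35.0, 40.0], n)
        t = np.exp(4.0 - 0.08 * temp + 0.5 * rng.normal(size=n))
        events = (rng.random(n) < 0.85).astype(int)
        s = sample(t, events, cov=temp)
        df = pd.DataFrame({"T": t, "E": events, "temp": temp})
        oracles = {
            "weibull": lifelines.WeibullAFTFitter(),
            "lognormal": lifelines.LogNormalAFTFitter(),
            "loglogistic": lifelines.LogLogisticAFTFitter(),
        }
        for family, fitter in oracles.items():
            fitter.fit(df, duration_col="T", event_col="E")
            ours = aft_fit(s, family)
            assert ours.loglik == pytest.approx(fitter.log_likelihood_, abs=0.05)

    def test_scaling_preserves_family_ordering(self):
        rng = np.random.default_rng(31)
        t = rng.lognormal(2.0, 0.8, 300)
        events = (rng.random(300) < 0.9).astype(int)
        order_at = []
        for c in (1.0, 3.7):
            s = sample(t * c, events)
            fits = [aft_fit(s, fam) for fam in FAMILIES]
            order_at.append([f.family for f in select_model(fits).ranking])
        assert order_at[0] == order_at[1]

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            aft_fit(sample([1.0, 2.0]), "gamma")

    def test_requires_event(self):
        with pytest.raises(ValueError, match="event"):
            aft_fit(sample([1.0, 2.0], events=[0, 0]), "weibull")


class TestAIC:
    def test_printed_row(self):
        assert aic(-2046.2, 2) == pytest.approx(4096.4, abs=1e-9)

    def test_zero(self):
        assert aic(0.0, 0) == 0.0

    def test_simple(self):
        assert aic(-10.0, 3) == 26.0

    def test_nonfinite(self):
        with pytest.raises(ValueError):
            aic(math.inf, 2)


def _fit_stub(family, loglikv, k, fingerprint="x"):
    return AFTFit(
        family=family,
        coefficients=np.zeros(2),
        shape=None if family == "exponential" else 1.0,
        loglik=loglikv,
        k=k,
        aic=aic(loglikv, k),
        sample_fingerprint=fingerprint,
    )


class TestSelectModel:
    def test_printed_death_ranking(self):
        fits = [
            _fit_stub("exponential", -2046.2, 2),
            _fit_stub("weibull", -2017.35, 3),
            _fit_stub("lognormal", -1883.05, 3),
            _fit_stub("loglogistic", -1842.75, 3),
        ]
        assert select_model(fits).best.family == "loglogistic"

    def test_printed_first_egg_ranking(self):
        fits = [
            _fit_stub("exponential", -352.45, 2),
            _fit_stub("lognormal", -282.05, 3),
            _fit_stub("loglogistic", -284.2, 3),
        ]
        assert select_model(fits).best.family == "lognormal"

    def test_tie_breaks_on_k_then_order(self):
        a = _fit_stub("exponential", -10.0, 2)  # aic 24
        b = _fit_stub("weibull", -9.0, 3)  # aic 24
        assert select_model([b, a]).best.family == "exponential"
        c = _fit_stub("lognormal", -9.0, 3)
        assert select_model([c, b]).best.family == "lognormal"

    def test_differing_samples_rejected(self):
        with pytest.raises(ValueError, match="differing"):
            select_model([_fit_stub("exponential", -1, 2, "a"), _fit_stub("weibull", -1, 3, "b")])

    def test_needs_two(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_model([_fit_stub("exponential", -1, 2)])


class TestEndpointExtraction:
    def test_death_sample_uncensored(self, small_cohorts):
        cohort = small_cohorts[30.0]
        s = death_sample(cohort)
        assert s.n == len(cohort)
        assert s.events.sum() == s.n  # no censoring by design

    def test_first_egg_censoring(self, cohort40):
        s = first_egg_sample(cohort40)
        assert 0 < s.events.sum() < s.n  # some lay, some die first
        # censored times are death ages of egg-less adult females
        assert s.times[s.events == 0].min() > 0

    def test_first_egg_event_time_matches_record(self, cohort30):
        s = first_egg_sample(cohort30, use_covariate=False)
        females = [
            rec
            for rec in cohort30
            if rec.sex == "female" and rec.reached_adulthood
        ]
        assert s.n == len(females)
        first = next(
            next(a for a, c in rec.daily_eggs if c > 0)
            for rec in females
            if any(c > 0 for _, c in rec.daily_eggs)
        )
        assert first in s.times[s.events == 1]


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(3, 60),
)
def test_km_monotone_property(seed, n):
    rng = np.random.default_rng(seed)
    times = rng.exponential(5.0, n) + 0.01
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[0] = 1
    est = km_fit(SurvivalSample(times=times, events=events))
    assert np.all(np.diff(est.survival) <= 1e-12)
    assert est.survival[0] <= 1.0
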