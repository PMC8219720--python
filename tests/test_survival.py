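"""Current-status Weibull PH: interval construction, likelihood oracles,
MCMC behaviour and posterior summaries."""
import math

import numpy as np
import pytest
from scipy import integrate, optimize

from crcpathways.cohort import PriorBloodCount
from crcpathways.survival import (
    CurrentStatusRecord,
    PosteriorDraws,
    Priors,
    SurvivalDataError,
    WeibullPHParams,
    build_intervals,
    convergence_diagnostics,
    loglik,
    posterior_summaries,
    sample_posterior,
    survival_curves,
)
from conftest import make_record


def cs(c, late, x, horizon=10.0):
    return CurrentStatusRecord.from_observation(c, late, x, horizon)


class TestBuildIntervals:
    def test_late_stage_interval(self):
        rec = make_record(0, pathway="IDA", tnm_stage="IV", age=80.0)
        out = build_intervals([rec])
        assert (out[0].interval_lower, out[0].interval_upper) == (0.0, 80.0)

    def test_early_stage_interval_uses_horizon(self):
        rec = make_record(0, pathway="IDA", tnm_stage="I", age=80.0)
        out = build_intervals([rec], horizon_years=10)
        assert (out[0].interval_lower, out[0].interval_upper) == (80.0, 90.0)

    def test_zero_horizon_rejected(self):
        rec = make_record(0, pathway="IDA", tnm_stage="I", age=80.0)
        with pytest.raises(SurvivalDataError):
            build_intervals([rec], horizon_years=0)

    def test_tested_indicator_ignores_hb_result(self):
        low = make_record(0, pathway="IDA", prior=PriorBloodCount(5.0, 90.0))
        normal = make_record(1, pathway="IDA", prior=PriorBloodCount(5.0, 130.0))
        none = make_record(2, pathway="IDA")
        out = build_intervals([low, normal, none])
        assert [r.tested for r in out] == [1, 1, 0]


class TestLoglik:
    def test_exponential_closed_form(self):
        # k=1, C=sigma: late contribution log(1 - e^-1)
        params = WeibullPHParams(shape=1.0, scale=70.0, beta=0.0)
        val = loglik(params, [cs(70.0, True, 0)])
        assert val == pytest.approx(math.log(1 - math.exp(-1)), rel=1e-12)

    def test_beta_zero_ignores_covariate(self):
        params = WeibullPHParams(shape=3.0, scale=80.0, beta=0.0)
        data0 = [cs(70.0, True, 0), cs(60.0, False, 0)]
        data1 = [cs(70.0, True, 1), cs(60.0, False, 1)]
        assert loglik(params, data0) == pytest.approx(loglik(params, data1), rel=1e-14)

    def test_quadrature_oracle_on_random_instances(self):
        """Interval log-probability agrees with numeric integration of the
        Weibull-PH density to 1e-8 on 100 random parameter/data draws."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            k = rng.uniform(1.1, 8.0)
            s = rng.uniform(50.0, 100.0)
            b = rng.normal(scale=0.7)
            x = int(rng.integers(0, 2))
            c = rng.uniform(45.0, 95.0)
            late = bool(rng.integers(0, 2))
            rec = cs(c, late, x)
            params = WeibullPHParams(k, s, b)

            def density(t):
                h = (k / s) * (t / s) ** (k - 1) * math.exp(b * x)
                return h * math.exp(-((t / s) ** k) * math.exp(b * x))

            prob, _ = integrate.quad(density, rec.interval_lower, rec.interval_upper,
                                     limit=400)
            assert loglik(params, [rec]) == pytest.approx(math.log(prob), abs=1e-8)

    def test_monte_carlo_oracle(self):
        """Interval probability matches the fraction of simulated onsets in
        the interval within 3 standard errors."""
        rng = np.random.default_rng(11)
        k, s, b, x = 4.0, 75.0, -0.4, 1
        rec = cs(72.0, False, x)
        n = 10**6
        t = s * (rng.exponential(size=n) * math.exp(-b * x)) ** (1 / k)
        hits = ((t >= rec.interval_lower) & (t <= rec.interval_upper)).mean()
        se = math.sqrt(hits * (1 - hits) / n)
        assert abs(math.exp(loglik(WeibullPHParams(k, s, b), [rec])) - hits) < 3 * se

    def test_empty_interval_probability_is_minus_inf(self):
        params = WeibullPHParams(shape=8.0, scale=10.0, beta=0.0)
        # interval far in the upper tail: S(L) - S(U) underflows
        val = loglik(params, [cs(200.0, False, 0)])
        assert val == -math.inf


@pytest.fixture(scope="module")
def recovery_fit(generator_truth):
    from crcpathways.synthetic import generate_current_status_dataset

    data = generate_current_status_dataset(generator_truth, 171, seed=314)
    return sample_posterior(data, seed=2718)


class TestSampler:
    def test_determinism(self, generator_truth):
        from crcpathways.synthetic import generate_current_status_dataset

        data = generate_current_status_dataset(generator_truth, 60, seed=5)
        d1 = sample_posterior(data, n_chains=2, n_kept=200, n_burn=200, seed=9)
        d2 = sample_posterior(data, n_chains=2, n_kept=200, n_burn=200, seed=9)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_kept_draws_respect_prior_constraint(self, recovery_fit):
        assert (recovery_fit.draws[:, :, 0] > 1.0).all()
        assert (recovery_fit.draws[:, :, 1] > 0.0).all()

    def test_hazard_increasing_for_every_kept_draw(self, recovery_fit):
        # k > 1 makes the Weibull hazard k/s (t/s)^(k-1) strictly increasing;
        # spot-check numerically on a grid for a thinned subset
        flat = recovery_fit.flat()[::97]
        t = np.linspace(40, 95, 12)
        for k, s, b in flat:
            h = (k / s) * (t / s) ** (k - 1)
            assert (np.diff(h) > 0).all()

    def test_acceptance_rate_in_tuned_band(self, recovery_fit):
        assert ((recovery_fit.acceptance_rates > 0.1)
                & (recovery_fit.acceptance_rates < 0.6)).all()

    def test_uninformative_data_returns_prior_for_beta(self):
        # intervals covering essentially the whole support carry no
        # information, so the beta posterior reproduces its prior
        data = [cs(1e8, True, i % 2, horizon=10.0) for i in range(20)]
        priors = Priors()
        d = sample_posterior(data, priors=priors, n_chains=4, n_kept=2000,
                             n_burn=1000, seed=42)
        beta = d.flat()[:, 2]
        assert abs(beta.mean() - priors.mu_beta) < 0.5
        assert abs(beta.std() - priors.sd_beta) < 0.8

    def test_single_covariate_level_rejected(self):
        data = [cs(70.0, True, 0), cs(60.0, False, 0)]
        with pytest.raises(SurvivalDataError):
            sample_posterior(data, n_chains=2, n_kept=50, n_burn=50, seed=0)

    def test_empty_data_rejected(self):
        with pytest.raises(SurvivalDataError):
            sample_posterior([], seed=0)

    def test_posterior_contraction_with_sample_size(self, generator_truth):
        from crcpathways.synthetic import generate_current_status_dataset

        widths = {}
        for n in (171, 342):
            w = []
            for s in range(3):
                data = generate_current_status_dataset(generator_truth, n, seed=60 + s)
                d = sample_posterior(data, n_chains=2, n_kept=600, n_burn=600,
                                     seed=80 + s)
                beta = d.flat()[:, 2]
                w.append(np.percentile(beta, 97.5) - np.percentile(beta, 2.5))
            widths[n] = np.mean(w)
        assert widths[342] < widths[171]


class TestSummaries:
    def test_null_beta_draws_give_unit_hazard_ratios(self):
        draws = PosteriorDraws(draws=np.tile([2.0, 80.0, 0.0], (2, 100, 1)))
        summ = posterior_summaries(draws)
        assert summ["effect_tested"]["mean"] == 1.0
        assert summ["hr_untested_vs_tested"]["mean"] == 1.0

    def test_median_onset_matches_root_finder(self):
        k, s, b = 4.5, 78.0, -0.5
        draws = PosteriorDraws(draws=np.tile([k, s, b], (2, 10, 1)))
        summ = posterior_summaries(draws)
        root = optimize.brentq(
            lambda t: math.exp(-((t / s) ** k) * math.exp(b)) - 0.5, 1.0, 300.0
        )
        assert summ["median_onset_age"]["tested"]["median"] == pytest.approx(root, rel=1e-10)

    def test_empty_draws_rejected(self):
        with pytest.raises(SurvivalDataError):
            posterior_summaries(PosteriorDraws(draws=np.empty((2, 0, 3))))


class TestCurves:
    def test_survival_starts_at_one_and_decreases(self, recovery_fit):
        grid = np.r_[0.0, np.linspace(40, 100, 31)]
        for x in (0, 1):
            cur = survival_curves(recovery_fit, x, grid)
            assert cur.median[0] == 1.0
            assert cur.lower[0] == 1.0 and cur.upper[0] == 1.0
            assert (np.diff(cur.median) <= 1e-12).all()

    def test_baseline_curve_falls_between_60_and_80(self, recovery_fit):
        cur = survival_curves(recovery_fit, 0, np.array([60.0, 80.0]))
        assert cur.median[0] > cur.median[1]

    def test_negative_ages_rejected(self, recovery_fit):
        with pytest.raises(SurvivalDataError):
            survival_curves(recovery_fit, 0, np.array([-1.0, 10.0]))


class TestDiagnostics:
    def test_iid_chains_have_unit_rhat(self):
        rng = np.random.default_rng(1)
        draws = PosteriorDraws(draws=rng.normal(size=(4, 800, 3)) + [2.0, 80.0, 0.0])
        diag = convergence_diagnostics(draws)
        for p in ("shape", "scale", "beta"):
            assert diag[p]["rhat"] == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.01, size=(1, 500, 3))
        b = rng.normal(5.0, 0.01, size=(1, 500, 3))
        draws = PosteriorDraws(draws=np.concatenate([a, b]) + [2.0, 80.0, 0.0])
        diag = convergence_diagnostics(draws)
        assert diag["beta"]["rhat"] > 1.1

    def test_single_chain_rejected(self):
        draws = PosteriorDraws(draws=np.zeros((1, 100, 3)) + [2.0, 80.0, 0.0])
        with pytest.raises(SurvivalDataError):
            convergence_diagnostics(draws)

    def test_ar1_effective_sample_size(self):
        """ESS of an AR(1) chain with rho=0.5 is ~ n(1-rho)/(1+rho)."""
        rng = np.random.default_rng(3)
        rho, n, n_chains = 0.5, 20_000, 2
        chains = np.empty((n_chains, n, 3))
        for c in range(n_chains):
            z = rng.normal(size=n)
            x = np.empty(n)
            x[0] = z[0]
            for i in range(1, n):
                x[i] = rho * x[i - 1] + math.sqrt(1 - rho**2) * z[i]
            chains[c] = x[:, None] + [2.0, 80.0, 0.0]
        diag = convergence_diagnostics(PosteriorDraws(draws=chains))
        expected = n_chains * n * (1 - rho) / (1 + rho)
        assert diag["beta"]["ess"] == pytest.approx(expected, rel=0.2)
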