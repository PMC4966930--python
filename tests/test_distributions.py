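"""MLE fitting of the candidate ICS distribution families, AIC, z test."""
import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

import icskin as ik
from icskin.distributions import (
    FittedDistribution,
    FitError,
    ZTestResult,
    aic,
    fit_mle,
    select_model,
    z_test,
)


class TestFitMle:
    def test_normal_mean_is_sample_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 5, 200)
        fit = fit_mle(x, "normal")
        assert fit.mu == pytest.approx(x.mean(), abs=1e-12)
        assert fit.sigma == pytest.approx(x.std(ddof=0), abs=1e-12)

    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(7.0, 0.1, 10_000))
        fit = fit_mle(x, "lognormal")
        assert fit.mu == pytest.approx(7.0, abs=0.01)
        assert fit.sigma == pytest.approx(0.1, rel=0.05)

    def test_truncnorm_with_huge_bounds_matches_normal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(50, 3, 500)
        fn = fit_mle(x, "normal")
        ft = fit_mle(x, "truncnorm", bounds=(-1e12, 1e12))
        assert ft.mu == pytest.approx(fn.mu, abs=1e-6)
        assert ft.sigma == pytest.approx(fn.sigma, abs=1e-6)

    def test_truncnorm_recovery_with_active_bound(self):
        # generating truncnorm with the lower bound biting
        rng = np.random.default_rng(3)
        tn = stats.truncnorm(a=(0 - 2.0) / 2.0, b=np.inf, loc=2.0, scale=2.0)
        x = tn.rvs(size=10_000, random_state=rng)
        fit = fit_mle(x, "truncnorm", bounds=(0.0, 1e9))
        assert fit.mu == pytest.approx(2.0, abs=0.15)
        assert fit.sigma == pytest.approx(2.0, abs=0.1)

    def test_closed_form_matches_numeric_optimum(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(3.0, 0.4, 400))
        fit = fit_mle(x, "lognormal")

        def nll(theta):
            mu, log_s = theta
            return -stats.lognorm(s=math.exp(log_s), scale=math.exp(mu)).logpdf(x).sum()

        res = optimize.minimize(nll, [2.5, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.mu == pytest.approx(res.x[0], abs=1e-5)
        assert fit.sigma == pytest.approx(math.exp(res.x[1]), abs=1e-5)

    @pytest.mark.parametrize("family", ["normal", "truncnorm", "lognormal"])
    def test_parameter_recovery_bias_below_one_percent(self, family):
        rng = np.random.default_rng(5)
        mu, sigma = 8.0, 0.5
        if family == "lognormal":
            x = np.exp(rng.normal(mu, sigma, 10_000))
            fit = fit_mle(x, family)
        else:
            x = rng.normal(mu, sigma, 10_000)
            fit = fit_mle(x, family, bounds=(0.0, 100.0))
        assert abs(fit.mu - mu) / mu < 0.01
        assert abs(fit.sigma - sigma) / sigma < 0.05

    def test_lognormal_rejects_negatives_and_counts_zeros(self):
        with pytest.raises(FitError, match="negative"):
            fit_mle([-1.0] + [1.0] * 20, "lognormal")
        x = [0.0] * 5 + list(np.exp(np.random.default_rng(6).normal(2, 0.3, 20)))
        with pytest.raises(FitError, match="zero ICS"):
            fit_mle(x, "lognormal")  # 5/25 = 20% zeros
        few = [0.0] + list(np.exp(np.random.default_rng(7).normal(2, 0.3, 40)))
        fit = fit_mle(few, "lognormal")  # 1/41 tolerated, dropped
        assert fit.n_fit == 40

    def test_too_few_values(self):
        with pytest.raises(FitError, match="at least 10"):
            fit_mle([1.0] * 5, "normal")


class TestPdf:
    def test_lognormal_closed_form_at_median(self):
        fit = FittedDistribution("X", "lognormal", mu=7.0, sigma=0.25,
                                 n_fit=10, log_likelihood=0.0)
        x = math.exp(7.0)
        expected = 1.0 / (x * 0.25 * math.sqrt(2 * math.pi))
        assert fit.pdf(x) == pytest.approx(expected, rel=1e-12)

    def test_truncnorm_normalizes_over_bounds(self):
        fit = FittedDistribution("X", "truncnorm", mu=10.0, sigma=40.0,
                                 n_fit=10, log_likelihood=0.0,
                                 lower=0.0, upper=100.0)
        total, err = integrate.quad(fit.pdf, 0.0, 100.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_lognormal_density_zero_at_origin(self):
        fit = FittedDistribution("X", "lognormal", mu=1.0, sigma=1.0,
                                 n_fit=10, log_likelihood=0.0)
        assert fit.pdf(0.0) == 0.0

    def test_pdf_matches_histogram_of_draws(self):
        fit = FittedDistribution("X", "lognormal", mu=6.0, sigma=0.3,
                                 n_fit=10, log_likelihood=0.0)
        rng = np.random.default_rng(8)
        draws = fit.rvs(1_000_000, rng)
        lo, hi = np.quantile(draws, [0.1, 0.9])
        edges = np.linspace(lo, hi, 21)
        counts, _ = np.histogram(draws, bins=edges)
        hist = counts / (draws.size * np.diff(edges))
        centers = 0.5 * (edges[:-1] + edges[1:])
        np.testing.assert_allclose(hist, fit.pdf(centers), rtol=0.02)


class TestAic:
    def test_definition(self):
        fit = FittedDistribution("X", "normal", 0.0, 1.0, 10, log_likelihood=0.0)
        assert aic(fit) == 4.0

    def test_delta_aic_is_twice_loglik_difference(self):
        f1 = FittedDistribution("X", "normal", 0.0, 1.0, 10, log_likelihood=-12.5)
        f2 = FittedDistribution("X", "normal", 0.0, 1.0, 10, log_likelihood=-10.0)
        assert aic(f1) - aic(f2) == pytest.approx(-2 * (-12.5 - -10.0))

    def test_aic_matches_density_sum_oracle(self):
        rng = np.random.default_rng(9)
        x = np.exp(rng.normal(4.0, 0.2, 500))
        fit = fit_mle(x, "lognormal")
        ll = np.log(stats.lognorm(s=fit.sigma, scale=math.exp(fit.mu)).pdf(x)).sum()
        assert aic(fit) == pytest.approx(4 - 2 * ll, rel=1e-10)


class TestSelectModel:
    @staticmethod
    def _values(family, rng, rels=("C-1", "C-2", "UN"), n=300):
        out = {}
        for i, rel in enumerate(rels):
            mu, sigma = 6.0 - i, 0.4
            if family == "lognormal":
                out[rel] = np.exp(rng.normal(mu, sigma, n))
            else:
                out[rel] = rng.normal(200 * (i + 1), 20, n)
        return out

    def test_lognormal_data_selects_lognormal(self):
        rng = np.random.default_rng(10)
        sel = select_model(self._values("lognormal", rng), "C", bounds=(0, 4000))
        assert sel.chosen_family == "lognormal"

    def test_normal_data_far_from_bounds_ties_resolve_deterministically(self):
        rng = np.random.default_rng(11)
        sel = select_model(self._values("normal", rng), "C", bounds=(0, 4000))
        assert sel.chosen_family in ("normal", "truncnorm")
        a_n = sel.aic_by_family["normal"]
        a_t = sel.aic_by_family["truncnorm"]
        if abs(a_n - a_t) < 1e-6:
            assert sel.chosen_family == "truncnorm"  # tie preference

    def test_single_relationship_group(self):
        rng = np.random.default_rng(12)
        vals = {"UN": np.exp(rng.normal(3.0, 0.5, 200))}
        sel = select_model(vals, "C", bounds=(0, 1000))
        assert sel.chosen_family == "lognormal"
        assert set(sel.fits) == {"UN"}

    def test_group_aic_is_sum_of_relationship_aics(self):
        rng = np.random.default_rng(13)
        vals = self._values("lognormal", rng)
        sel = select_model(vals, "C", bounds=(0, 4000))
        for family, fits in sel.fits_by_family.items():
            assert sel.aic_by_family[family] == pytest.approx(
                sum(aic(f) for f in fits.values())
            )


class TestZTest:
    def test_observation_at_lognormal_median(self):
        fit = FittedDistribution("X", "lognormal", mu=5.0, sigma=0.2,
                                 n_fit=10, log_likelihood=0.0)
        res = z_test([math.exp(5.0)], fit)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_gross_violation(self):
        fit = FittedDistribution("X", "normal", mu=0.0, sigma=1.0,
                                 n_fit=10, log_likelihood=0.0)
        res = z_test([10.0, 10.0, 10.0], fit)
        assert res.p_value < 1e-6

    def test_empty_rejected(self):
        fit = FittedDistribution("X", "normal", mu=0.0, sigma=1.0,
                                 n_fit=10, log_likelihood=0.0)
        with pytest.raises(ValueError):
            z_test([], fit)

    def test_null_p_values_roughly_uniform(self):
        fit = FittedDistribution("X", "lognormal", mu=6.0, sigma=0.3,
                                 n_fit=10, log_likelihood=0.0)
        rng = np.random.default_rng(14)
        ps = [z_test(fit.rvs(25, rng), fit).p_value for _ in range(300)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
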