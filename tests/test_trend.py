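"""Local-level trend model: transforms, smoother, Gibbs sampler, reports."""

import numpy as np
import pandas as pd
import pytest

from dogait.synth import TruePanelParams, generate_panel
from dogait.trend import (
    MCMCSettings,
    Panel,
    PriorSpec,
    beta_report_from_draws,
    coefficient_report,
    compare_trends,
    fit_local_level,
    forward_transform,
    inverse_transform,
    kalman_smoother,
    transform_values,
)
from oracles import dense_smoother_oracle


class TestTransforms:
    @pytest.mark.parametrize(
        "transform, value, expected",
        [
            ("log", 1.0, 0.0),
            ("logit100", 50.0, 0.0),
            ("logit100", 90.0, np.log(9.0)),
        ],
    )
    def test_point_values(self, transform, value, expected):
        z = forward_transform(np.array([value]), transform)
        assert z[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("transform", ["log", "logit100"])
    def test_inverse_restores_inputs(self, transform):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.5, 99.5 if transform == "logit100" else 50.0, 100)
        back = inverse_transform(forward_transform(v, transform), transform)
        assert np.allclose(back, v, atol=1e-10)

    def test_domain_errors_identify_row(self):
        with pytest.raises(ValueError, match="row 1"):
            forward_transform(np.array([1.0, -2.0]), "log")
        with pytest.raises(ValueError, match="row 0"):
            forward_transform(np.array([100.0, 50.0]), "logit100")

    def test_transform_values_appends_z(self):
        df = pd.DataFrame(
            {"dog_id": ["a", "a"], "month": [2, 3], "value": [1.0, np.e]}
        )
        panel = Panel(data=df, transform="log", months=[2, 3])
        out = transform_values(panel)
        assert np.allclose(out["z"], [0.0, 1.0])

    def test_logit_equals_log_of_odds(self):
        r = np.array([5.0, 50.0, 95.0])
        assert np.allclose(
            forward_transform(r, "logit100"),
            forward_transform(r / (100.0 - r), "log"),
            atol=1e-12,
        )


class TestPanelValidation:
    def test_log_requires_positive_values(self):
        df = pd.DataFrame({"dog_id": ["a"], "month": [2], "value": [-1.0]})
        with pytest.raises(ValueError):
            Panel(data=df, transform="log", months=[2])

    def test_months_must_be_contiguous(self):
        df = pd.DataFrame({"dog_id": ["a"], "month": [2], "value": [1.0]})
        with pytest.raises(ValueError, match="contiguous"):
            Panel(data=df, transform="log", months=[2, 4])

    def test_empty_panel_rejected(self):
        df = pd.DataFrame({"dog_id": [], "month": [], "value": []})
        with pytest.raises(ValueError, match="no observations"):
            Panel(data=df, transform="log", months=[2, 3])


class TestKalmanSmoother:
    def test_static_limit_equals_grand_mean(self):
        # sigma1 -> 0 with a diffuse prior: the level is constant, so every
        # smoothed mean is the precision-weighted (here plain) mean of z - bx
        rng = np.random.default_rng(1)
        months = np.arange(2, 8)
        obs_month = np.repeat(months, 3)
        x = rng.normal(0, 1, obs_month.size)
        beta = -0.4
        z = rng.normal(1.0, 0.3, obs_month.size) + beta * x
        mean, var = kalman_smoother(
            months, obs_month, z, sigma0_sq=0.09, sigma1_sq=1e-14,
            beta=beta, x=x, m1_prior=(0.0, 1e8),
        )
        grand = np.mean(z - beta * x)
        assert np.allclose(mean, grand, atol=1e-5)
        assert np.allclose(var, var[0], atol=1e-6)

    def test_single_observation_diffuse_prior(self):
        z, x, beta, s0 = 2.3, 1.5, -0.5, 0.04
        mean, var = kalman_smoother(
            [3], [3], [z], sigma0_sq=s0, sigma1_sq=0.01,
            beta=beta, x=[x], m1_prior=(0.0, 1e10),
        )
        assert mean[0] == pytest.approx(z - beta * x, abs=1e-6)
        assert var[0] == pytest.approx(s0, rel=1e-6)

    def test_matches_dense_gaussian_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            T = int(rng.integers(1, 6))
            N = int(rng.integers(1, 11))
            months = np.arange(2, 2 + T)
            obs_month = rng.choice(months, size=N)
            z = rng.normal(0, 1, N)
            x = rng.normal(0, 1, N)
            s0 = float(rng.uniform(0.01, 1.0))
            s1 = float(rng.uniform(0.001, 0.5))
            beta = float(rng.normal(0, 0.5))
            m1, v1 = kalman_smoother(months, obs_month, z, s0, s1, beta, x)
            m2, v2 = dense_smoother_oracle(months, obs_month, z, s0, s1, beta, x)
            assert np.allclose(m1, m2, atol=1e-8)
            assert np.allclose(v1, v2, atol=1e-8)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            kalman_smoother([2], [2], [1.0], sigma0_sq=0.0, sigma1_sq=0.01)

    def test_deleting_interior_month_widens_its_band(self):
        months = np.arange(2, 9)
        obs_month = np.repeat(months, 2)
        rng = np.random.default_rng(3)
        z = rng.normal(0.5, 0.2, obs_month.size)
        _, var_full = kalman_smoother(months, obs_month, z, 0.04, 0.01)
        keep = obs_month != 5
        _, var_gap = kalman_smoother(months, obs_month[keep], z[keep], 0.04, 0.01)
        gap_idx = 3  # month 5
        assert var_gap[gap_idx] > var_full[gap_idx]
        # other months change but stay finite and ordered
        assert np.all(var_gap >= var_full - 1e-12)


class TestFitLocalLevel:
    def test_reproducible_with_same_seed(self, small_panel, fast_mcmc):
        a = fit_local_level(small_panel, mcmc=fast_mcmc, compute_diagnostics=False)
        b = fit_local_level(small_panel, mcmc=fast_mcmc, compute_diagnostics=False)
        assert np.array_equal(a.draws["m"], b.draws["m"])
        assert np.array_equal(a.draws["sigma0_sq"], b.draws["sigma0_sq"])

    def test_fixed_variances_match_smoother(self, small_panel):
        df = small_panel.transformed()
        sm_mean, sm_var = kalman_smoother(
            small_panel.months, df["month"], df["z"], 0.04, 0.01
        )
        fit = fit_local_level(
            small_panel,
            mcmc=MCMCSettings(chains=2, iterations=3000, burn_in=500, seed=4),
            priors=PriorSpec(fix_sigma0_sq=0.04, fix_sigma1_sq=0.01),
            compute_diagnostics=False,
        )
        flat = fit.draws["m"].reshape(-1, len(small_panel.months))
        mcse = flat.std(axis=0) / np.sqrt(flat.shape[0])
        assert np.all(np.abs(fit.trend_mean - sm_mean) < 3 * mcse)
        assert np.allclose(flat.var(axis=0), sm_var, rtol=0.10)

    def test_constant_panel_recovers_flat_trend(self):
        df = pd.DataFrame({
            "dog_id": [f"d{i}" for i in range(4)] * 5,
            "month": np.repeat(np.arange(2, 7), 4),
            "value": 5.0,
        })
        panel = Panel(data=df, transform="log", months=np.arange(2, 7))
        fit = fit_local_level(
            panel,
            mcmc=MCMCSettings(chains=2, iterations=3000, burn_in=1000, seed=5),
            compute_diagnostics=False,
        )
        z = np.log(5.0)
        assert np.allclose(fit.trend_mean, z, atol=0.05)
        # no observation noise in the data: sigma0 posterior concentrates low
        assert fit.sigma0_sq["mean"] < 0.01

    def test_beta_interval_covers_planted_effect(self):
        months = range(2, 13)
        rng = np.random.default_rng(6)
        x = {(f"d{i}", m): float(rng.normal()) for i in range(6) for m in months}
        params = TruePanelParams(
            m=tuple(np.linspace(0.2, 0.8, 11)), sigma0_sq=0.04,
            sigma1_sq=0.01, beta=-0.5, transform="log",
        )
        panel = generate_panel(params, [f"d{i}" for i in range(6)], months,
                               covariate_table=x, seed=7)
        fit = fit_local_level(
            panel,
            mcmc=MCMCSettings(chains=2, iterations=3000, burn_in=1000, seed=8),
        )
        assert fit.beta is not None
        assert fit.beta["lower"] < -0.5 < fit.beta["upper"]
        assert fit.beta["excludes_zero"]
        assert fit.diagnostics["converged"]

    def test_no_covariate_column_means_no_beta(self, small_panel, fast_mcmc):
        fit = fit_local_level(small_panel, mcmc=fast_mcmc,
                              compute_diagnostics=False)
        assert fit.beta is None
        assert "beta" not in fit.draws

    def test_quantile_ordering_and_positive_variances(self, small_panel, fast_mcmc):
        fit = fit_local_level(small_panel, mcmc=fast_mcmc,
                              compute_diagnostics=False)
        assert np.all(fit.trend_lower <= fit.trend_mean)
        assert np.all(fit.trend_mean <= fit.trend_upper)
        assert fit.sigma0_sq["lower"] > 0
        assert fit.sigma1_sq["lower"] > 0

    def test_identical_z_gives_identical_fit_across_transforms(self):
        # a log panel on y = exp(z) and a logit100 panel on r = 100u/(1+u),
        # u = exp(z), present the sampler with the same transformed data
        rng = np.random.default_rng(9)
        z = rng.normal(0.0, 0.5, 12)
        months = np.repeat(np.arange(2, 6), 3)
        dogs = [f"d{i}" for i in range(3)] * 4
        u = np.exp(z)
        log_df = pd.DataFrame({"dog_id": dogs, "month": months, "value": u})
        r = 100 * u / (1 + u)
        logit_df = pd.DataFrame({"dog_id": dogs, "month": months, "value": r})
        mcmc = MCMCSettings(chains=2, iterations=1500, burn_in=500, seed=10)
        fit_log = fit_local_level(
            Panel(data=log_df, transform="log", months=np.arange(2, 6)),
            mcmc=mcmc, compute_diagnostics=False,
        )
        fit_logit = fit_local_level(
            Panel(data=logit_df, transform="logit100", months=np.arange(2, 6)),
            mcmc=mcmc, compute_diagnostics=False,
        )
        assert np.allclose(fit_log.trend_mean, fit_logit.trend_mean, atol=1e-10)

    def test_prior_sensitivity_keeps_strong_effect_decision(self):
        months = range(2, 13)
        rng = np.random.default_rng(11)
        x = {(f"d{i}", m): float(rng.normal()) for i in range(5) for m in months}
        params = TruePanelParams(
            m=tuple(np.linspace(0.5, -0.5, 11)), sigma0_sq=0.04,
            sigma1_sq=0.01, beta=-0.8, transform="log",
        )
        panel = generate_panel(params, [f"d{i}" for i in range(5)], months,
                               covariate_table=x, seed=12)
        mcmc = MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=13)
        loose = fit_local_level(panel, mcmc=mcmc, compute_diagnostics=False)
        tight = fit_local_level(
            panel, mcmc=mcmc, compute_diagnostics=False,
            priors=PriorSpec(beta_var=1.0, sigma0_a=0.01, sigma0_b=0.01,
                             sigma1_a=0.01, sigma1_b=0.01),
        )
        assert loose.beta["excludes_zero"] and tight.beta["excludes_zero"]


class TestCoefficientReport:
    def test_constant_draws(self):
        rep = beta_report_from_draws(np.full((2, 100), 1.3))
        assert rep["mean"] == pytest.approx(1.3)
        assert (rep["lower"], rep["upper"]) == (1.3, 1.3)
        assert rep["excludes_zero"]

    def test_symmetric_draws_include_zero(self):
        rng = np.random.default_rng(14)
        draws = rng.normal(0, 1, 10_000)
        rep = beta_report_from_draws(draws)
        assert not rep["excludes_zero"]

    def test_shifted_normal_quantiles(self):
        rng = np.random.default_rng(15)
        draws = rng.normal(0, 1, 10_000) + 3.0
        rep = beta_report_from_draws(draws)
        assert rep["lower"] == pytest.approx(3 - 1.96, abs=0.08)
        assert rep["upper"] == pytest.approx(3 + 1.96, abs=0.08)
        assert rep["excludes_zero"]

    def test_fit_without_covariate_rejected(self, small_panel, fast_mcmc):
        fit = fit_local_level(small_panel, mcmc=fast_mcmc,
                              compute_diagnostics=False)
        with pytest.raises(ValueError, match="no covariate"):
            coefficient_report(fit)

    def test_report_matches_fit_summary(self):
        months = range(2, 7)
        x = {(f"d{i}", m): float((i - 1) / 2) for i in range(4) for m in months}
        params = TruePanelParams(
            m=(0.0,) * 5, sigma0_sq=0.04, sigma1_sq=0.01, beta=1.0,
            transform="log",
        )
        panel = generate_panel(params, [f"d{i}" for i in range(4)], months,
                               covariate_table=x, seed=16)
        fit = fit_local_level(
            panel, mcmc=MCMCSettings(chains=2, iterations=1500, burn_in=500,
                                     seed=17),
            compute_diagnostics=False,
        )
        point, (lo, hi), flag = coefficient_report(fit)
        assert point == fit.beta["mean"]
        assert (lo, hi) == (fit.beta["lower"], fit.beta["upper"])
        assert flag == fit.beta["excludes_zero"]


class TestCompareTrends:
    def test_self_comparison_has_no_separation(self, small_panel, fast_mcmc):
        fit = fit_local_level(small_panel, mcmc=fast_mcmc,
                              compute_diagnostics=False)
        comp = compare_trends(fit, fit)
        assert not comp["disjoint"].any()
        assert np.allclose(comp["mean_a"], comp["mean_b"])

    def test_separated_trends_have_disjoint_bands(self, fast_mcmc):
        months = range(2, 13)
        dogs = [f"d{i}" for i in range(6)]
        hi = generate_panel(
            TruePanelParams(m=(np.log(2.0),) * 11, sigma0_sq=0.01,
                            sigma1_sq=0.001, beta=0.0, transform="log"),
            dogs, months, seed=18,
        )
        lo = generate_panel(
            TruePanelParams(m=(np.log(0.3),) * 11, sigma0_sq=0.01,
                            sigma1_sq=0.001, beta=0.0, transform="log"),
            dogs, months, seed=19,
        )
        fit_hi = fit_local_level(hi, mcmc=fast_mcmc, compute_diagnostics=False)
        fit_lo = fit_local_level(lo, mcmc=fast_mcmc, compute_diagnostics=False)
        comp = compare_trends(fit_hi, fit_lo)
        assert comp["disjoint"].all()
        assert np.all(comp["mean_a"] > comp["mean_b"])

    def test_mismatched_months_rejected(self, fast_mcmc):
        df = pd.DataFrame({
            "dog_id": ["a"] * 4, "month": [2, 3, 4, 5], "value": [1.0] * 4,
        })
        p1 = Panel(data=df, transform="log", months=[2, 3, 4, 5])
        p2 = Panel(data=df[df["month"] < 5], transform="log", months=[2, 3, 4])
        f1 = fit_local_level(p1, mcmc=fast_mcmc, compute_diagnostics=False)
        f2 = fit_local_level(p2, mcmc=fast_mcmc, compute_diagnostics=False)
        with pytest.raises(ValueError, match="month ranges"):
            compare_trends(f1, f2)
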