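import numpy as np
import pytest
from scipy import stats

from lhfi.data import build_centered_design
from lhfi.model import (
    ModelSpec,
    ParamState,
    PriorSpec,
    assemble_sigma,
    collapse_two_level,
    group_probabilities,
    latent_health_loglik,
    linear_predictor,
    log_posterior,
    log_prior,
    metric_effect_logprior,
    model_preset,
    observation_loglik,
    salinity_loglik,
    variance_ratio,
)

SPEC1 = model_preset("model1")
SPEC3 = model_preset("model3")


class TestLinearPredictor:
    @pytest.mark.parametrize(
        "H, delta, gamma, sign, expected",
        [(0.0, 0.0, 0.0, +1, 0.0), (1.5, 0.2, -0.1, -1, -1.4), (2.0, 0.5, 0.25, +1, 2.75)],
    )
    def test_arithmetic(self, H, delta, gamma, sign, expected):
        assert linear_predictor(H, delta, gamma, sign) == pytest.approx(expected)

    def test_monotone_in_health(self):
        h = np.linspace(-2, 2, 9)
        up = [linear_predictor(x, 0.3, -0.2, +1) for x in h]
        down = [linear_predictor(x, 0.3, -0.2, -1) for x in h]
        assert np.all(np.diff(up) > 0) and np.all(np.diff(down) < 0)


class TestGroupProbabilities:
    def test_symmetric_zero_etas(self):
        np.testing.assert_allclose(group_probabilities([0.0, 0.0]), [1 / 3] * 3, rtol=1e-14)

    def test_single_eta_closed_form(self):
        np.testing.assert_allclose(
            group_probabilities([np.log(2.0)]), [2 / 3, 1 / 3], rtol=1e-14
        )

    def test_matches_direct_formula(self):
        etas = np.array([1.0, 2.0, 3.0])
        denom = 1.0 + np.exp(etas).sum()
        expected = np.append(np.exp(etas) / denom, 1.0 / denom)
        np.testing.assert_allclose(group_probabilities(etas), expected, atol=1e-12, rtol=0)

    def test_valid_simplex_under_extremes(self):
        p = group_probabilities([700.0, -700.0])
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)

    def test_shifting_etas_scales_odds_against_remainder(self):
        etas = np.array([0.4, -1.2, 0.7])
        c = 0.9
        p0 = group_probabilities(etas)
        p1 = group_probabilities(etas + c)
        np.testing.assert_allclose(p1[:-1] / p1[-1], np.exp(c) * p0[:-1] / p0[-1], rtol=1e-10)

    def test_health_moves_groups_oppositely(self, make_state, scheme):
        """Raising H raises every plus-group probability and lowers every
        minus-group probability (remainder moves opposite within group)."""
        gamma = np.array([0.2, -0.1, 0.3, 0.0, -0.2])
        delta = 0.4
        for h0, h1 in [(-1.0, -0.5), (0.0, 0.3), (1.0, 1.8)]:
            pp0 = group_probabilities(gamma[:2] + h0)
            pp1 = group_probabilities(gamma[:2] + h1)
            pm0 = group_probabilities(delta + gamma[2:] - h0)
            pm1 = group_probabilities(delta + gamma[2:] - h1)
            assert np.all(pp1[:-1] > pp0[:-1]) and pp1[-1] < pp0[-1]
            assert np.all(pm1[:-1] < pm0[:-1]) and pm1[-1] > pm0[-1]


def _oracle_observation_loglik(data, scheme, state):
    """Independent multinomial-pmf oracle via scipy.stats.multinomial."""
    total = 0.0
    counts = data.counts()
    totals = data.totals()
    sites = list(data.sites)
    site_idx = data.site_index()
    plus = [m - 1 for m in scheme.metrics_in("plus")]
    minus = [m - 1 for m in scheme.metrics_in("minus")]
    for r in range(data.n_records):
        H = state.H[site_idx[r]]
        p_plus = group_probabilities(state.gamma[plus] + H)
        p_minus = group_probabilities(state.delta_minus + state.gamma[minus] - H)
        y_plus = np.append(counts[r, plus], totals[r] - counts[r, plus].sum())
        y_minus = np.append(counts[r, minus], totals[r] - counts[r, minus].sum())
        total += stats.multinomial.logpmf(y_plus, totals[r], p_plus)
        total += stats.multinomial.logpmf(y_minus, totals[r], p_minus)
    return float(total)


class TestObservationLoglik:
    def test_single_trial_closed_form(self, scheme):
        import pandas as pd

        from lhfi.data import BenthicDataset

        data = BenthicDataset(
            pd.DataFrame(
                [{"site": 1, "month": "Sep", "replicate": 1,
                  "m1": 1, "m2": 0, "m3": 0, "m4": 0, "m5": 0, "total": 1}]
            )
        )
        state = ParamState(H=np.zeros(1), delta_minus=0.0, gamma=np.zeros(5),
                           beta0=0.0, beta=np.zeros(1), sigma_eps=1.0, sigma_gamma=1.0)
        # plus group: 3 equiprobable categories, count on metric 1 -> log(1/3)
        # minus group: 4 equiprobable categories, the single organism falls in
        # the remainder -> log(1/4)
        assert observation_loglik(data, scheme, state) == pytest.approx(
            np.log(1 / 3) + np.log(1 / 4), abs=1e-12
        )

    def test_all_remainder_closed_form(self, scheme):
        import pandas as pd

        from lhfi.data import BenthicDataset

        n = 17
        data = BenthicDataset(
            pd.DataFrame(
                [{"site": 1, "month": "Sep", "replicate": 1,
                  "m1": 0, "m2": 0, "m3": 0, "m4": 0, "m5": 0, "total": n}]
            )
        )
        state = ParamState(H=np.zeros(1), delta_minus=0.0, gamma=np.zeros(5),
                           beta0=0.0, beta=np.zeros(1), sigma_eps=1.0, sigma_gamma=1.0)
        assert observation_loglik(data, scheme, state) == pytest.approx(
            n * np.log(1 / 3) + n * np.log(1 / 4), abs=1e-10
        )

    def test_matches_multinomial_oracle(self, scheme, tiny_counts, make_state):
        rng = np.random.default_rng(3)
        state = make_state(SPEC1, tiny_counts.n_sites, rng)
        ours = observation_loglik(tiny_counts, scheme, state)
        oracle = _oracle_observation_loglik(tiny_counts, scheme, state)
        assert ours == pytest.approx(oracle, abs=1e-10)


class TestLatentHealthLoglik:
    def test_at_mode(self, tiny_covariates):
        design = build_centered_design(tiny_covariates, ("dd",))
        state = ParamState(H=design.matrix[:, 0] * 0.5, delta_minus=0.0,
                           gamma=np.zeros(5), beta0=0.0, beta=np.array([0.5]),
                           sigma_eps=1.0, sigma_gamma=1.0)
        assert latent_health_loglik(state, design, SPEC1) == pytest.approx(
            -1.5 * np.log(2 * np.pi)
        )

    def test_doubling_sigma_at_mode_costs_log2_per_site(self, tiny_covariates):
        design = build_centered_design(tiny_covariates, ("dd",))
        args = dict(delta_minus=0.0, gamma=np.zeros(5), beta0=0.0,
                    beta=np.array([0.5]), sigma_gamma=1.0)
        at_mode = design.matrix[:, 0] * 0.5
        l1 = latent_health_loglik(ParamState(H=at_mode, sigma_eps=1.0, **args), design, SPEC1)
        l2 = latent_health_loglik(ParamState(H=at_mode, sigma_eps=2.0, **args), design, SPEC1)
        assert l1 - l2 == pytest.approx(3 * np.log(2.0))

    def test_matches_normal_oracle(self, tiny_covariates, make_state):
        rng = np.random.default_rng(11)
        design = build_centered_design(tiny_covariates, ("dd",))
        state = make_state(SPEC1, 3, rng)
        mu = state.beta0 + design.matrix @ state.beta
        oracle = stats.norm.logpdf(state.H, mu, state.sigma_eps).sum()
        assert latent_health_loglik(state, design, SPEC1) == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch_rejected(self, tiny_covariates, make_state):
        design = build_centered_design(tiny_covariates, ("dd", "salinity"))
        state = make_state(SPEC1, 3, np.random.default_rng(0))
        with pytest.raises(ValueError, match="columns"):
            latent_health_loglik(state, design, SPEC1)


class TestSalinityLoglik:
    def test_exact_fit(self, tiny_covariates, make_state):
        """When centered salinity lies exactly on the regression line with
        unit noise s.d., each site contributes -log(2 pi)/2."""
        cov_frame = tiny_covariates.frame.copy()
        cov_frame["salinity_ppt"] = 18.0 + 1.2 * cov_frame["dd_km"]
        from lhfi.data import CovariateTable

        cov = CovariateTable(cov_frame)
        design = build_centered_design(cov, ("salinity",))
        state = make_state(SPEC3, 3, np.random.default_rng(2))
        state.b0, state.b1, state.sigma_s = 0.0, 1.2, 1.0
        assert salinity_loglik(cov, design, state) == pytest.approx(
            -1.5 * np.log(2 * np.pi), abs=1e-10
        )

    def test_zero_coefficients_reduce_to_residual_density(self, richibucto_like, make_state):
        _, cov, _ = richibucto_like
        design = build_centered_design(cov, ("salinity",))
        state = make_state(SPEC3, 18, np.random.default_rng(5))
        state.b0, state.b1 = 0.0, 0.0
        oracle = stats.norm.logpdf(design.centered_salinity, 0.0, state.sigma_s).sum()
        assert salinity_loglik(cov, design, state) == pytest.approx(oracle, abs=1e-12)

    def test_random_matches_oracle(self, richibucto_like, make_state):
        _, cov, _ = richibucto_like
        design = build_centered_design(cov, ("salinity",))
        state = make_state(SPEC3, 18, np.random.default_rng(9))
        mu = state.b0 + state.b1 * design.centered_dd
        oracle = stats.norm.logpdf(design.centered_salinity, mu, state.sigma_s).sum()
        assert salinity_loglik(cov, design, state) == pytest.approx(oracle, abs=1e-12)

    def test_requires_two_level_parameters(self, richibucto_like, make_state):
        _, cov, _ = richibucto_like
        design = build_centered_design(cov, ("dd",))
        state = make_state(SPEC1, 18, np.random.default_rng(1))
        with pytest.raises(ValueError, match="two-level"):
            salinity_loglik(cov, design, state)


class TestMetricEffectPrior:
    def test_iid_zero_gamma(self, make_state):
        state = make_state(SPEC1, 3, np.random.default_rng(0))
        state.sigma_gamma = 1.0
        lp = metric_effect_logprior(np.zeros(5), state, SPEC1)
        assert lp == pytest.approx(-2.5 * np.log(2 * np.pi))

    def test_block_identity_equals_iid_unit(self, make_state):
        rng = np.random.default_rng(4)
        gamma = rng.normal(size=5)
        iid_state = make_state(SPEC1, 3, np.random.default_rng(0))
        iid_state.sigma_gamma = 1.0
        block_spec = ModelSpec(("dd",), metric_cov_structure="block_diagonal")
        block_state = make_state(block_spec, 3, np.random.default_rng(0))
        block_state.Sigma_pp = np.eye(2)
        block_state.Sigma_mm = np.eye(3)
        assert metric_effect_logprior(gamma, block_state, block_spec) == pytest.approx(
            metric_effect_logprior(gamma, iid_state, SPEC1), abs=1e-12
        )

    def test_unstructured_matches_quadratic_form_oracle(self, make_state):
        rng = np.random.default_rng(8)
        spec = ModelSpec(("dd",), metric_cov_structure="unstructured")
        state = make_state(spec, 3, rng)
        gamma = rng.normal(size=5)
        S = assemble_sigma(state)
        oracle = stats.multivariate_normal.logpdf(gamma, mean=np.zeros(5), cov=S)
        assert metric_effect_logprior(gamma, state, spec) == pytest.approx(oracle, abs=1e-10)

    def test_non_positive_definite_rejected(self, make_state):
        spec = ModelSpec(("dd",), metric_cov_structure="block_diagonal")
        state = make_state(spec, 3, np.random.default_rng(0))
        state.Sigma_pp = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PD
        with pytest.raises(ValueError, match="positive definite"):
            metric_effect_logprior(np.zeros(5), state, spec)


class TestLogPrior:
    def test_componentwise_oracle(self, make_state):
        state = ParamState(H=np.zeros(3), delta_minus=0.0, gamma=np.zeros(5),
                           beta0=0.0, beta=np.zeros(1), sigma_eps=1.0, sigma_gamma=1.0)
        lp = log_prior(state, SPEC1)
        expected = (
            stats.norm.logpdf([0.0, 0.0, 0.0], 0.0, 10.0).sum()  # delta, beta0, beta
            + 2 * stats.invgamma.logpdf(1.0, 1.0, scale=1.0)  # sigma_eps^2, sigma_gamma^2
            + stats.norm.logpdf(np.zeros(5), 0.0, 1.0).sum()  # gamma | sigma_gamma
        )
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_out_of_support_is_minus_inf(self, make_state):
        state = make_state(SPEC1, 3, np.random.default_rng(0))
        state.sigma_eps = -1.0
        assert log_prior(state, SPEC1) == -np.inf

    def test_bivariate_rho_zero_factorizes(self, make_state):
        spec4 = model_preset("model4")
        state = make_state(spec4, 3, np.random.default_rng(6))
        state.rho = 0.0
        spec3 = model_preset("model3")
        assert log_prior(state, spec4) == pytest.approx(log_prior(state, spec3), abs=1e-10)

    def test_rho_outside_support(self, make_state):
        spec4 = model_preset("model4")
        state = make_state(spec4, 3, np.random.default_rng(6))
        state.rho = 1.0
        assert log_prior(state, spec4) == -np.inf


class TestLogPosterior:
    def test_additivity(self, richibucto_like, make_state, scheme):
        data, cov, _ = richibucto_like
        spec = SPEC3
        design = build_centered_design(cov, spec.health_covariates)
        state = make_state(spec, 18, np.random.default_rng(10))
        total = log_posterior(state, data, design, cov, spec)
        parts = (
            log_prior(state, spec)
            + latent_health_loglik(state, design, spec)
            + observation_loglik(data, scheme, state)
            + salinity_loglik(cov, design, state)
        )
        assert total == pytest.approx(parts, abs=1e-10)

    def test_single_level_ignores_salinity_block(self, richibucto_like, make_state):
        data, cov, _ = richibucto_like
        design = build_centered_design(cov, SPEC1.health_covariates)
        state = make_state(SPEC1, 18, np.random.default_rng(12))
        base = log_posterior(state, data, design, cov, SPEC1)
        state.b0, state.b1, state.sigma_s = 3.0, -2.0, 0.5
        assert log_posterior(state, data, design, cov, SPEC1) == base

    def test_subset_of_sites_changes_contribution(self, richibucto_like, make_state, scheme):
        import pandas as pd

        from lhfi.data import BenthicDataset

        data, cov, _ = richibucto_like
        state = make_state(SPEC1, 18, np.random.default_rng(13))
        full = observation_loglik(data, scheme, state)
        drop_site = data.sites[0]
        sub = BenthicDataset(data.frame[data.frame["site"] != drop_site].copy())
        sub_state = state.copy()
        sub_state.H = state.H[1:]
        partial = observation_loglik(sub, scheme, sub_state)
        ws_site0 = full - partial
        # recompute site 0's contribution directly
        only = BenthicDataset(data.frame[data.frame["site"] == drop_site].copy())
        only_state = state.copy()
        only_state.H = state.H[:1]
        assert ws_site0 == pytest.approx(observation_loglik(only, scheme, only_state), abs=1e-9)

    def test_structure_change_shifts_posterior_by_constant(self, richibucto_like, make_state):
        """iid vs block-diagonal with identity blocks differ only through the
        variance hyperpriors, i.e. by a state-independent constant."""
        data, cov, _ = richibucto_like
        design = build_centered_design(cov, ("dd",))
        spec_iid = SPEC1
        spec_blk = ModelSpec(("dd",), metric_cov_structure="block_diagonal")
        diffs = []
        for seed in (21, 22):
            st_i = make_state(spec_iid, 18, np.random.default_rng(seed))
            st_i.sigma_gamma = 1.0
            st_b = st_i.copy()
            st_b.sigma_gamma = None
            st_b.Sigma_pp = np.eye(2)
            st_b.Sigma_mm = np.eye(3)
            diffs.append(
                log_posterior(st_i, data, design, cov, spec_iid)
                - log_posterior(st_b, data, design, cov, spec_blk)
            )
        assert diffs[0] == pytest.approx(diffs[1], abs=1e-9)


class TestCollapsedModel:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1.2, 0.0, 0.4, 0.9, 0.8, 0.5), (1.2, 0.0, 0.64)),
            ((0.0, 1.0, 0.0, 0.77, 1.0, 1.0), (0.0, 0.77, 2.0)),
        ],
    )
    def test_arithmetic(self, args, expected):
        out = collapse_two_level(*args)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_monte_carlo_moments(self):
        """H simulated through the two-level generator has the collapsed
        mean and total variance, within 3 standard errors at 1e5 draws."""
        rng = np.random.default_rng(123)
        beta0, beta_sal, b0, b1, sig_e, sig_s = 0.3, 0.8, 0.1, 0.77, 0.6, 0.7
        d = 1.9  # a fixed centered distance value
        n = 100_000
        s = b0 + b1 * d + sig_s * rng.standard_normal(n)
        H = beta0 + beta_sal * s + sig_e * rng.standard_normal(n)
        intercept, slope, total_var = collapse_two_level(beta0, beta_sal, b0, b1, sig_e, sig_s)
        mean_se = np.sqrt(total_var / n)
        assert H.mean() == pytest.approx(intercept + slope * d, abs=3 * mean_se)
        var_se = total_var * np.sqrt(2.0 / (n - 1))
        assert H.var(ddof=1) == pytest.approx(total_var, abs=3 * var_se)


class TestVarianceRatio:
    def test_no_implicit_contribution(self):
        assert variance_ratio(1.3, 0.0, 5.0) == 1.0

    def test_equal_split(self):
        assert variance_ratio(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_monotone_decreasing_in_implicit_strength(self):
        bs = np.linspace(0.0, 3.0, 13)
        r = [variance_ratio(1.0, b, 0.8) for b in bs]
        assert np.all(np.diff(r) < 0)
        ss = np.linspace(0.1, 3.0, 13)
        r2 = [variance_ratio(1.0, 0.8, s) for s in ss]
        assert np.all(np.diff(r2) < 0)
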