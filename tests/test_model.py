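"""Unit tests for the BWS likelihood, priors and joint log-posterior."""

import math

import numpy as np
import pytest
from scipy import stats

from bwsum import (
    BWSModelSpec,
    ExposureGroup,
    MixtureDataset,
    ParameterState,
    ResidualSDPrior,
    log_likelihood,
    log_posterior,
    log_prior,
    weighted_sum,
)


class TestWeightedSum:
    def test_single_member_identity(self):
        X = np.array([[1.0], [2.0], [5.0]])
        g = ExposureGroup("solo", (0,))
        np.testing.assert_array_equal(weighted_sum(X, g, [1.0]), X[:, 0])

    def test_equal_weights_on_identical_columns(self):
        X = np.full((4, 3), 7.0)
        g = ExposureGroup("same", (0, 1, 2))
        np.testing.assert_allclose(weighted_sum(X, g, np.full(3, 1 / 3)), 7.0)

    def test_hand_arithmetic(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        g = ExposureGroup("pair", (0, 1))
        np.testing.assert_allclose(
            weighted_sum(X, g, [0.25, 0.75]), [1.75, 3.75]
        )

    def test_dimension_mismatch_names_group(self):
        g = ExposureGroup("pbde", (0, 1))
        with pytest.raises(ValueError, match="pbde"):
            weighted_sum(np.ones((3, 2)), g, [1.0])

    def test_off_simplex_rejected(self):
        g = ExposureGroup("pair", (0, 1))
        with pytest.raises(ValueError, match="simplex"):
            weighted_sum(np.ones((3, 2)), g, [0.7, 0.7])


def _single_group_model(n=1, y=None, X=None, link="gaussian"):
    X = np.ones((n, 1)) if X is None else X
    y = np.zeros(n) if y is None else y
    data = MixtureDataset(outcome=y, exposures=X)
    spec = BWSModelSpec(
        link=link,
        groups=(ExposureGroup("g", (0,)),),
        residual_sd_prior=ResidualSDPrior() if link == "gaussian" else None,
    )
    return data, spec


class TestLogLikelihood:
    def test_gaussian_zero_residual(self):
        # y equals the linear predictor, sigma = 1: density is N(0|0,1)
        data, spec = _single_group_model(n=4, y=np.full(4, 2.5), X=np.full((4, 1), 2.5))
        state = ParameterState(0.0, [1.0], [np.array([1.0])], residual_sd=1.0)
        assert log_likelihood(state, data, spec) == pytest.approx(
            -4 * 0.5 * math.log(2 * math.pi), abs=1e-12
        )

    def test_logit_symmetric(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        data, spec = _single_group_model(n=4, y=y, X=np.zeros((4, 1)), link="logit")
        state = ParameterState(0.0, [0.5], [np.array([1.0])])
        assert log_likelihood(state, data, spec) == pytest.approx(
            4 * math.log(0.5), abs=1e-12
        )

    @pytest.mark.parametrize("link", ["gaussian", "logit"])
    def test_matches_per_observation_density_sum(self, link):
        rng = np.random.default_rng(5)
        n, K, P = 25, 3, 2
        X = rng.normal(size=(n, K))
        Z = rng.normal(size=(n, P))
        w = np.array([0.5, 0.3, 0.2])
        eta = 0.3 + 0.9 * (X @ w) + Z @ [0.2, -0.4]
        y = (
            eta + 0.4 * rng.normal(size=n)
            if link == "gaussian"
            else rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        )
        data = MixtureDataset(outcome=y, exposures=X, covariates=Z)
        spec = BWSModelSpec(link=link, groups=(ExposureGroup("g", (0, 1, 2)),))
        state = ParameterState(
            0.3, [0.9], [w], covariate_coefs=[0.2, -0.4],
            residual_sd=0.4 if link == "gaussian" else None,
        )
        if link == "gaussian":
            oracle = stats.norm.logpdf(y, loc=eta, scale=0.4).sum()
        else:
            p = 1 / (1 + np.exp(-eta))
            oracle = stats.bernoulli.logpmf(y.astype(int), p).sum()
        assert log_likelihood(state, data, spec) == pytest.approx(oracle, abs=1e-10)


class TestLogPrior:
    def test_matches_scipy_assembled_oracle(self):
        spec = BWSModelSpec(
            link="gaussian",
            groups=(ExposureGroup("g", (0, 1, 2), dirichlet_alpha=(2.0, 2.0, 2.0)),),
        )
        w = np.array([0.2, 0.3, 0.5])
        state = ParameterState(
            0.7, [1.3], [w], covariate_coefs=[], residual_sd=0.8
        )
        oracle = (
            stats.norm.logpdf(0.7, 0, 10.0)
            + stats.norm.logpdf(1.3, 0, 10.0)
            + stats.dirichlet.logpdf(w, [2.0, 2.0, 2.0])
            + stats.halfcauchy.logpdf(0.8, scale=2.5)
        )
        assert log_prior(state, spec) == pytest.approx(oracle, abs=1e-10)

    def test_flat_dirichlet_is_constant_log_gamma_k(self):
        # Dirichlet(1,1,1) has constant density Gamma(3) = 2 on the simplex
        spec = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0, 1, 2)),))
        base = dict(intercept=0.0, theta=[0.0], residual_sd=1.0)
        lp1 = log_prior(ParameterState(weights=[np.array([0.2, 0.3, 0.5])], **base), spec)
        lp2 = log_prior(ParameterState(weights=[np.array([0.6, 0.3, 0.1])], **base), spec)
        assert lp1 == pytest.approx(lp2, abs=1e-12)
        # the constant the flat Dirichlet contributes is log Gamma(3)
        assert stats.dirichlet.logpdf([0.2, 0.3, 0.5], [1, 1, 1]) == pytest.approx(
            math.log(math.gamma(3)), abs=1e-12
        )

    def test_theta_prior_mode_value(self):
        spec = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0,)),))
        s0 = ParameterState(0.0, [0.0], [np.array([1.0])], residual_sd=1.0)
        s1 = ParameterState(0.0, [10.0], [np.array([1.0])], residual_sd=1.0)
        # N(0, 100): density drop from 0 to 10 is exactly half a unit of z^2
        assert log_prior(s0, spec) - log_prior(s1, spec) == pytest.approx(0.5, abs=1e-12)

    def test_off_simplex_weights_error(self):
        spec = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0, 1)),))
        state = ParameterState(0.0, [1.0], [np.array([0.6, 0.6])], residual_sd=1.0)
        with pytest.raises(ValueError, match="sum"):
            log_prior(state, spec)


class TestLogPosterior:
    def test_additivity(self, tiny_dataset, tiny_spec, tiny_state):
        lp = log_posterior(tiny_state, tiny_dataset, tiny_spec)
        assert lp == pytest.approx(
            log_likelihood(tiny_state, tiny_dataset, tiny_spec)
            + log_prior(tiny_state, tiny_spec),
            abs=1e-12,
        )

    def test_invariant_under_member_permutation(self, tiny_dataset):
        w = np.array([0.5, 0.3, 0.2])
        spec_a = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0, 1, 2)),))
        spec_b = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (2, 0, 1)),))
        sa = ParameterState(0.4, [1.1], [w], [0.3, -0.1], residual_sd=0.35)
        sb = ParameterState(0.4, [1.1], [w[[2, 0, 1]]], [0.3, -0.1], residual_sd=0.35)
        assert log_posterior(sa, tiny_dataset, spec_a) == pytest.approx(
            log_posterior(sb, tiny_dataset, spec_b), abs=1e-10
        )

    def test_single_exposure_reduction_to_plain_regression(self):
        # K_g = 1 forces w = 1, so the model is ordinary Bayesian regression
        rng = np.random.default_rng(11)
        n = 30
        x = rng.normal(size=n)
        y = 0.2 + 0.8 * x + 0.5 * rng.normal(size=n)
        data = MixtureDataset(outcome=y, exposures=x[:, None])
        spec = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0,)),))
        state = ParameterState(0.2, [0.8], [np.array([1.0])], residual_sd=0.5)
        oracle = (
            stats.norm.logpdf(y, 0.2 + 0.8 * x, 0.5).sum()
            + stats.norm.logpdf(0.2, 0, 10.0)
            + stats.norm.logpdf(0.8, 0, 10.0)
            + stats.halfcauchy.logpdf(0.5, scale=2.5)
        )
        assert log_posterior(state, data, spec) == pytest.approx(oracle, abs=1e-10)


class TestValidation:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BWSModelSpec(
                link="gaussian",
                groups=(ExposureGroup("a", (0, 1)), ExposureGroup("b", (1, 2))),
            )

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ExposureGroup("a", (0, 1), dirichlet_alpha=(1.0, 0.0))

    def test_logit_requires_both_classes(self):
        from bwsum.model import BayesianWeightedSums

        data = MixtureDataset(outcome=np.zeros(20), exposures=np.ones((20, 1)))
        spec = BWSModelSpec(link="logit", groups=(ExposureGroup("g", (0,)),))
        with pytest.raises(ValueError, match="both classes"):
            BayesianWeightedSums(data, spec)

    def test_residual_prior_forbidden_for_logit(self):
        with pytest.raises(ValueError, match="gaussian"):
            BWSModelSpec(
                link="logit",
                groups=(ExposureGroup("g", (0,)),),
                residual_sd_prior=ResidualSDPrior(),
            )

    def test_missing_values_rejected(self):
        y = np.array([1.0, np.nan, 0.5])
        with pytest.raises(ValueError, match="non-finite"):
            MixtureDataset(outcome=y, exposures=np.ones((3, 1)))
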