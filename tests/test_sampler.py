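"""Sampler correctness: determinism, bookkeeping, and moment agreement
with closed-form and independent-sampler oracles."""

import numpy as np
import pytest

from bwsum import (
    BayesianWeightedSums,
    BWSModelSpec,
    ExposureGroup,
    MixtureDataset,
    ResidualSDPrior,
    SamplerConfig,
    run_mcmc,
)


def _ess(chains: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(az.convert_to_dataset(chains[..., None]))["x"].values.item())


class TestContracts:
    def test_identical_seeds_bit_identical(self, tiny_dataset, tiny_spec):
        cfg = SamplerConfig(n_iterations=600, burn_in=100, thin=2, n_chains=2, seed=3)
        a = run_mcmc(tiny_dataset, tiny_spec, cfg)
        b = run_mcmc(tiny_dataset, tiny_spec, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_different_seeds_differ(self, tiny_dataset, tiny_spec):
        cfg1 = SamplerConfig(n_iterations=600, burn_in=100, thin=2, n_chains=1, seed=3)
        cfg2 = SamplerConfig(n_iterations=600, burn_in=100, thin=2, n_chains=1, seed=4)
        a = run_mcmc(tiny_dataset, tiny_spec, cfg1)
        b = run_mcmc(tiny_dataset, tiny_spec, cfg2)
        assert not np.array_equal(a.draws, b.draws)

    @pytest.mark.parametrize("n_iter,burn,thin", [(1000, 100, 2), (901, 100, 3), (500, 460, 7)])
    def test_draw_count_bookkeeping(self, tiny_dataset, tiny_spec, n_iter, burn, thin):
        cfg = SamplerConfig(n_iterations=n_iter, burn_in=burn, thin=thin, n_chains=1, seed=0)
        s = run_mcmc(tiny_dataset, tiny_spec, cfg)
        assert s.n_draws == (n_iter - burn) // thin

    def test_simplex_conservation_every_draw(self, quick_fit):
        s = quick_fit.samples
        w = np.stack([s.get(f"w_x{k}") for k in (1, 2, 3)], axis=-1)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all((w > 0.0) & (w < 1.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)


class TestMomentAgreement:
    def test_conjugate_limit_matches_closed_form(self):
        """With weights fixed at truth (single-member group on the realised
        weighted sum) and sigma fixed, the Gaussian posterior for
        (intercept, theta) is exactly normal; sampled moments must agree."""
        rng = np.random.default_rng(21)
        n, sigma = 120, 0.5
        X = rng.normal(size=(n, 5))
        w = np.array([0.1, 0.3, 0.2, 0.1, 0.3])
        s = X @ w
        y = 0.3 + 1.0 * s + sigma * rng.normal(size=n)
        data = MixtureDataset(outcome=y, exposures=s[:, None])
        spec = BWSModelSpec(
            link="gaussian",
            groups=(ExposureGroup("mix", (0,)),),
            residual_sd_prior=ResidualSDPrior.fixed(sigma),
        )
        fit = BayesianWeightedSums(data, spec).fit(
            n_iterations=20_000, burn_in=2000, thin=1, n_chains=3, seed=5
        )
        A = np.column_stack([np.ones(n), s])
        V0inv = np.diag([1 / 100.0, 1 / 100.0])
        prec = A.T @ A / sigma**2 + V0inv
        cov = np.linalg.inv(prec)
        mean = cov @ (A.T @ y / sigma**2)
        for i, name in enumerate(["intercept", "theta_mix"]):
            chains = fit.samples.get(name)
            ess = _ess(chains)
            sd_true = np.sqrt(cov[i, i])
            mcse_mean = sd_true / np.sqrt(ess)
            assert fit.posterior_mean(name) == pytest.approx(mean[i], abs=3 * mcse_mean)
            mcse_sd = sd_true / np.sqrt(2 * ess)
            assert fit.posterior_sd(name) == pytest.approx(sd_true, abs=3 * mcse_sd)

    def test_single_exposure_reduction_matches_emcee(self):
        """One group of one exposure is plain Bayesian regression; an
        independently-written log-posterior sampled with emcee must give
        the same theta posterior within Monte-Carlo error."""
        import emcee
        from scipy import stats

        rng = np.random.default_rng(8)
        n = 80
        x = rng.normal(size=n)
        y = 0.4 + 0.9 * x + 0.6 * rng.normal(size=n)
        data = MixtureDataset(outcome=y, exposures=x[:, None])
        spec = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0,)),))
        fit = BayesianWeightedSums(data, spec).fit(
            n_iterations=20_000, burn_in=2000, thin=1, n_chains=3, seed=9
        )

        def logpost(params):
            b0, b1, logsig = params
            sig = np.exp(logsig)
            return (
                stats.norm.logpdf(y, b0 + b1 * x, sig).sum()
                + stats.norm.logpdf(b0, 0, 10).sum()
                + stats.norm.logpdf(b1, 0, 10).sum()
                + stats.halfcauchy.logpdf(sig, scale=2.5)
                + logsig  # Jacobian of sigma -> log sigma
            )

        nw = 24
        p0 = np.column_stack(
            [
                0.4 + 0.1 * rng.normal(size=nw),
                0.9 + 0.1 * rng.normal(size=nw),
                np.log(0.6) + 0.1 * rng.normal(size=nw),
            ]
        )
        sampler = emcee.EnsembleSampler(nw, 3, logpost)
        sampler.run_mcmc(p0, 3000, progress=False)
        ref = sampler.get_chain(discard=1000, flat=True)

        for i, name in enumerate(["intercept", "theta_g"]):
            ours = fit.samples.pooled(name)
            sd = ref[:, i].std()
            tol = 3 * sd * (1 / np.sqrt(_ess(fit.samples.get(name))) + 1 / np.sqrt(1000))
            assert ours.mean() == pytest.approx(ref[:, i].mean(), abs=tol)
            assert ours.std() == pytest.approx(sd, rel=0.12)

    def test_scale_equivariance_of_theta(self):
        """Scaling all exposure columns in a group by c rescales theta by
        1/c and leaves the weight posterior essentially unchanged."""
        rng = np.random.default_rng(13)
        n, c = 300, 4.0
        X = rng.normal(size=(n, 3))
        w = np.array([0.5, 0.3, 0.2])
        y = 1.0 * (X @ w) + 0.4 * rng.normal(size=n)
        spec = BWSModelSpec(link="gaussian", groups=(ExposureGroup("g", (0, 1, 2)),))
        fit1 = BayesianWeightedSums(MixtureDataset(outcome=y, exposures=X), spec).fit(
            n_iterations=8000, burn_in=1500, thin=2, n_chains=3, seed=2
        )
        fit2 = BayesianWeightedSums(MixtureDataset(outcome=y, exposures=c * X), spec).fit(
            n_iterations=8000, burn_in=1500, thin=2, n_chains=3, seed=2
        )
        assert fit2.posterior_median("theta_g") * c == pytest.approx(
            fit1.posterior_median("theta_g"), abs=0.03
        )
        for k in (1, 2, 3):
            assert fit2.posterior_median(f"w_x{k}") == pytest.approx(
                fit1.posterior_median(f"w_x{k}"), abs=0.03
            )


class TestMultipleGroups:
    def test_two_groups_recover_distinct_summed_effects(self):
        """Two exposure groups in one regression, each with its own summed
        effect and Dirichlet-weighted composition."""
        rng = np.random.default_rng(19)
        n = 600
        X = rng.normal(size=(n, 5))
        w_a, w_b = np.array([0.7, 0.3]), np.array([0.5, 0.3, 0.2])
        y = 1.0 * (X[:, :2] @ w_a) - 0.5 * (X[:, 2:] @ w_b) + 0.4 * rng.normal(size=n)
        data = MixtureDataset(outcome=y, exposures=X)
        spec = BWSModelSpec(
            link="gaussian",
            groups=(ExposureGroup("a", (0, 1)), ExposureGroup("b", (2, 3, 4))),
        )
        fit = BayesianWeightedSums(data, spec).fit(
            n_iterations=8000, burn_in=1500, thin=2, n_chains=2, seed=12
        )
        assert fit.posterior_median("theta_a") == pytest.approx(1.0, abs=0.1)
        assert fit.posterior_median("theta_b") == pytest.approx(-0.5, abs=0.1)
        assert fit.posterior_median("w_x1") == pytest.approx(0.7, abs=0.1)
        assert fit.posterior_median("w_x3") == pytest.approx(0.5, abs=0.12)
        # each group's mean weights form their own simplex
        wa = fit.weight_means("a")
        wb = fit.weight_means("b")
        assert sum(wa.values()) == pytest.approx(1.0, abs=1e-6)
        assert sum(wb.values()) == pytest.approx(1.0, abs=1e-6)


class TestErrorsAndWarnings:
    def test_separable_logit_warns_not_fails(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = (x > 0).astype(float)  # perfectly separable
        data = MixtureDataset(outcome=y, exposures=x[:, None])
        spec = BWSModelSpec(link="logit", groups=(ExposureGroup("g", (0,)),))
        cfg = SamplerConfig(n_iterations=500, burn_in=100, thin=1, n_chains=1, seed=1)
        with pytest.warns(UserWarning, match="separable"):
            samples = run_mcmc(data, spec, cfg)
        assert samples.n_draws == 400
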