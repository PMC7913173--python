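import numpy as np
import pytest

from bwsum import (
    BayesianWeightedSums,
    BWSModelSpec,
    ExposureGroup,
    MixtureDataset,
    ParameterState,
    SamplerConfig,
)


@pytest.fixture(scope="session")
def tiny_dataset() -> MixtureDataset:
    """Small fixed Gaussian dataset with 3 exposures and 2 covariates."""
    rng = np.random.default_rng(42)
    n = 40
    X = rng.normal(size=(n, 3))
    Z = rng.normal(size=(n, 2))
    y = 0.5 + 1.2 * (0.5 * X[:, 0] + 0.3 * X[:, 1] + 0.2 * X[:, 2]) + Z @ [0.4, -0.2]
    y = y + 0.3 * rng.normal(size=n)
    return MixtureDataset(outcome=y, exposures=X, covariates=Z)


@pytest.fixture(scope="session")
def tiny_spec() -> BWSModelSpec:
    return BWSModelSpec(link="gaussian", groups=(ExposureGroup("mix", (0, 1, 2)),))


@pytest.fixture(scope="session")
def tiny_state() -> ParameterState:
    return ParameterState(
        intercept=0.4,
        theta=[1.1],
        weights=[np.array([0.5, 0.3, 0.2])],
        covariate_coefs=[0.3, -0.1],
        residual_sd=0.35,
    )


@pytest.fixture(scope="session")
def quick_fit(tiny_dataset, tiny_spec):
    """A short but converged fit used by structural checks."""
    model = BayesianWeightedSums(tiny_dataset, tiny_spec)
    return model.fit(n_iterations=4000, burn_in=1000, thin=2, n_chains=3, seed=7)


@pytest.fixture(scope="session")
def desk_config() -> SamplerConfig:
    return SamplerConfig(n_iterations=6000, burn_in=1000, thin=2, n_chains=3)
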