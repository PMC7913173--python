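"""Probability model for Bayesian weighted-sum (BWS) mixture regression.

BWS couples an ordinary generalised linear regression with one or more
*weighted sums* of exposures:

    g(E[y_i]) = theta_0 + sum_g theta_g * (sum_k w_gk x_i,gk) + z_i' gamma

Each weight vector ``w_g`` lives on the probability simplex (``w_gk > 0``,
``sum_k w_gk = 1``) under a Dirichlet prior, so ``theta_g`` is the effect of
a one-unit increase in the weighted sum of group ``g`` and ``w_gk`` is the
fraction of that summed effect attributed to exposure ``k``.  Exposures that
belong to no group, and any other adjustment variables, enter as ordinary
covariates with independent normal priors.

Supported links: identity with Gaussian errors (continuous outcomes) and
logit with Bernoulli errors (binary outcomes).  The residual standard
deviation of the Gaussian model carries a half-Cauchy prior by default, with
an inverse-gamma-on-variance alternative and a point-mass option used by
conjugate checks.

This module evaluates the model (likelihood, priors, joint log-posterior)
and holds the data containers; sampling lives in :mod:`bwsum.sampler` and
posterior reporting in :mod:`bwsum.summaries`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ExposureGroup",
    "ResidualSDPrior",
    "BWSModelSpec",
    "MixtureDataset",
    "ParameterState",
    "BayesianWeightedSums",
    "weighted_sum",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

SIMPLEX_TOL = 1e-8
LINKS = ("gaussian", "logit")

_LOG_2PI = math.log(2.0 * math.pi)


def _normal_logpdf(x: float, mean: float, var: float) -> float:
    d = x - mean
    return -0.5 * (_LOG_2PI + math.log(var)) - 0.5 * d * d / var


@dataclass(frozen=True)
class ExposureGroup:
    """One mixture group: which exposure columns share a summed effect.

    Parameters
    ----------
    name
        Label for the group (used in parameter names, e.g. ``theta_<name>``).
    member_indices
        Column indices into the exposure matrix; order defines weight order.
    dirichlet_alpha
        Concentration vector of the Dirichlet prior on the weights.  The
        default ``alpha_k = 1`` is the flat prior on the simplex: before
        seeing data, all weights are most likely equal.
    """

    name: str
    member_indices: tuple[int, ...]
    dirichlet_alpha: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.member_indices)
        if len(idx) == 0:
            raise ValueError(f"group {self.name!r} has no members")
        if len(set(idx)) != len(idx):
            raise ValueError(f"group {self.name!r} has duplicate member indices {idx}")
        object.__setattr__(self, "member_indices", idx)
        alpha = tuple(float(a) for a in (self.dirichlet_alpha or (1.0,) * len(idx)))
        if len(alpha) != len(idx):
            raise ValueError(
                f"group {self.name!r}: dirichlet_alpha has length {len(alpha)}, "
                f"expected {len(idx)}"
            )
        if any(a <= 0 for a in alpha):
            raise ValueError(f"group {self.name!r}: Dirichlet alpha must be positive")
        object.__setattr__(self, "dirichlet_alpha", alpha)

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class ResidualSDPrior:
    """Prior on the Gaussian residual standard deviation sigma.

    ``half_cauchy`` (default, scale 2.5) is weakly informative and proper;
    ``inverse_gamma`` places InvGamma(shape, rate) on sigma^2 for
    comparability with precision-parameterised Gibbs samplers; ``fixed``
    pins sigma at a known value (used by conjugate closed-form checks).
    """

    kind: str = "half_cauchy"
    scale: float = 2.5
    shape: float = 0.001
    rate: float = 0.001
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("half_cauchy", "inverse_gamma", "fixed"):
            raise ValueError(f"unknown residual SD prior kind {self.kind!r}")
        if self.kind == "half_cauchy" and self.scale <= 0:
            raise ValueError("half-Cauchy scale must be positive")
        if self.kind == "inverse_gamma" and (self.shape <= 0 or self.rate <= 0):
            raise ValueError("inverse-gamma shape and rate must be positive")
        if self.kind == "fixed" and self.value <= 0:
            raise ValueError("fixed residual SD must be positive")

    @classmethod
    def half_cauchy(cls, scale: float = 2.5) -> "ResidualSDPrior":
        return cls(kind="half_cauchy", scale=scale)

    @classmethod
    def inverse_gamma(cls, shape: float = 0.001, rate: float = 0.001) -> "ResidualSDPrior":
        return cls(kind="inverse_gamma", shape=shape, rate=rate)

    @classmethod
    def fixed(cls, value: float) -> "ResidualSDPrior":
        return cls(kind="fixed", value=value)

    def logpdf(self, sigma: float) -> float:
        if sigma <= 0:
            return -math.inf
        if self.kind == "half_cauchy":
            s = self.scale
            return math.log(2.0) - math.log(math.pi * s * (1.0 + (sigma / s) ** 2))
        if self.kind == "inverse_gamma":
            v = sigma * sigma
            # density of sigma induced by InvGamma(shape, rate) on sigma^2
            lp_v = (
                self.shape * math.log(self.rate)
                - gammaln(self.shape)
                - (self.shape + 1.0) * math.log(v)
                - self.rate / v
            )
            return lp_v + math.log(2.0 * sigma)
        return 0.0  # fixed: point mass, constant contribution


@dataclass(frozen=True)
class BWSModelSpec:
    """Link, group structure and prior hyperparameters of a BWS model."""

    link: str = "gaussian"
    groups: tuple[ExposureGroup, ...] = ()
    theta_prior_mean: float = 0.0
    theta_prior_var: float = 100.0
    intercept_prior_mean: float = 0.0
    intercept_prior_var: float = 100.0
    covariate_prior_mean: float = 0.0
    covariate_prior_var: float = 100.0
    residual_sd_prior: ResidualSDPrior | None = None

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}, got {self.link!r}")
        groups = tuple(self.groups)
        if not groups:
            raise ValueError("at least one exposure group is required")
        seen: set[int] = set()
        for g in groups:
            overlap = seen.intersection(g.member_indices)
            if overlap:
                raise ValueError(f"exposure groups overlap on indices {sorted(overlap)}")
            seen.update(g.member_indices)
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        object.__setattr__(self, "groups", groups)
        for v in (
            self.theta_prior_var,
            self.intercept_prior_var,
            self.covariate_prior_var,
        ):
            if v <= 0:
                raise ValueError("prior variances must be positive")
        if self.link == "gaussian":
            if self.residual_sd_prior is None:
                object.__setattr__(self, "residual_sd_prior", ResidualSDPrior())
        elif self.residual_sd_prior is not None:
            raise ValueError("residual_sd_prior only applies to the gaussian link")

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class MixtureDataset:
    """Outcome, exposure matrix and covariate matrix for one analysis."""

    outcome: np.ndarray
    exposures: np.ndarray
    covariates: np.ndarray | None = None
    outcome_name: str = "y"
    exposure_names: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(self.exposures, dtype=float))
        if X.shape[0] != y.size and X.shape[1] == y.size:
            X = X.T
        Z = self.covariates
        Z = np.zeros((y.size, 0)) if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError(f"exposures have {X.shape[0]} rows but outcome has {y.size}")
        if Z.shape[0] != y.size:
            raise ValueError(f"covariates have {Z.shape[0]} rows but outcome has {y.size}")
        for label, arr in (("outcome", y), ("exposures", X), ("covariates", Z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{label} contains missing or non-finite values")
        xnames = tuple(self.exposure_names) or tuple(f"x{i+1}" for i in range(X.shape[1]))
        znames = tuple(self.covariate_names) or tuple(f"z{i+1}" for i in range(Z.shape[1]))
        if len(xnames) != X.shape[1]:
            raise ValueError("exposure_names length mismatch")
        if len(znames) != Z.shape[1]:
            raise ValueError("covariate_names length mismatch")
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "exposures", X)
        object.__setattr__(self, "covariates", Z)
        object.__setattr__(self, "exposure_names", xnames)
        object.__setattr__(self, "covariate_names", znames)

    @property
    def n_obs(self) -> int:
        return self.outcome.size

    @property
    def n_exposures(self) -> int:
        return self.exposures.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class ParameterState:
    """One point in parameter space (weights already on the simplex)."""

    intercept: float
    theta: np.ndarray
    weights: list[np.ndarray]
    covariate_coefs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.weights = [np.atleast_1d(np.asarray(w, dtype=float)) for w in self.weights]
        self.covariate_coefs = np.atleast_1d(np.asarray(self.covariate_coefs, dtype=float))

    def validate(self, spec: BWSModelSpec) -> None:
        if self.theta.size != spec.n_groups:
            raise ValueError(
                f"state has {self.theta.size} theta values for {spec.n_groups} groups"
            )
        if len(self.weights) != spec.n_groups:
            raise ValueError("state has wrong number of weight vectors")
        for g, w in zip(spec.groups, self.weights):
            if w.size != g.size:
                raise ValueError(
                    f"group {g.name!r} expects {g.size} weights, got {w.size}"
                )
            if abs(float(w.sum()) - 1.0) > SIMPLEX_TOL:
                raise ValueError(
                    f"group {g.name!r}: weights sum to {w.sum():.12f}, not 1"
                )
            if np.any(w <= 0.0) or np.any(w >= 1.0):
                if not (w.size == 1 and np.isclose(w[0], 1.0)):
                    raise ValueError(f"group {g.name!r}: weights must lie in (0, 1)")
        if spec.link == "gaussian":
            if self.residual_sd is None or self.residual_sd <= 0:
                raise ValueError("gaussian link requires residual_sd > 0")


def weighted_sum(
    exposures: np.ndarray, group: ExposureGroup, weights: np.ndarray
) -> np.ndarray:
    """Weighted sum ``sum_k w_k X[:, member_k]`` for one mixture group."""
    X = np.atleast_2d(np.asarray(exposures, dtype=float))
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if w.size != group.size:
        raise ValueError(
            f"group {group.name!r} expects {group.size} weights, got {w.size}"
        )
    if abs(float(w.sum()) - 1.0) > SIMPLEX_TOL or np.any(w < 0):
        raise ValueError(f"group {group.name!r}: weights are not on the simplex")
    return X[:, list(group.member_indices)] @ w


def linear_predictor(
    state: ParameterState, data: MixtureDataset, spec: BWSModelSpec
) -> np.ndarray:
    state.validate(spec)
    eta = np.full(data.n_obs, state.intercept, dtype=float)
    for g, th, w in zip(spec.groups, state.theta, state.weights):
        eta += th * weighted_sum(data.exposures, g, w)
    if data.n_covariates:
        if state.covariate_coefs.size != data.n_covariates:
            raise ValueError("covariate coefficient length mismatch")
        eta += data.covariates @ state.covariate_coefs
    return eta


def log_likelihood(
    state: ParameterState, data: MixtureDataset, spec: BWSModelSpec
) -> float:
    """Joint log-likelihood under the Gaussian or Bernoulli-logit link."""
    eta = linear_predictor(state, data, spec)
    bad = ~np.isfinite(eta)
    if bad.any():
        raise ValueError(f"non-finite linear predictor at row {int(np.argmax(bad))}")
    y = data.outcome
    if spec.link == "gaussian":
        sd = float(state.residual_sd)
        resid = y - eta
        n = data.n_obs
        return float(
            -0.5 * n * (_LOG_2PI + 2.0 * math.log(sd))
            - 0.5 * float(resid @ resid) / (sd * sd)
        )
    # Bernoulli-logit: y*eta - log(1 + exp(eta)), guarded via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _dirichlet_logpdf(w: np.ndarray, alpha: np.ndarray) -> float:
    if abs(float(w.sum()) - 1.0) > SIMPLEX_TOL:
        raise ValueError("weights are off the simplex beyond tolerance")
    if w.size == 1:
        return 0.0  # degenerate one-component simplex
    const = gammaln(alpha.sum()) - gammaln(alpha).sum()
    return float(const + ((alpha - 1.0) * np.log(w)).sum())


def log_prior(state: ParameterState, spec: BWSModelSpec) -> float:
    """Log prior density at ``state``: normals, Dirichlets and the sigma prior."""
    state.validate(spec)
    lp = _normal_logpdf(state.intercept, spec.intercept_prior_mean, spec.intercept_prior_var)
    for th in state.theta:
        lp += _normal_logpdf(float(th), spec.theta_prior_mean, spec.theta_prior_var)
    for b in state.covariate_coefs:
        lp += _normal_logpdf(float(b), spec.covariate_prior_mean, spec.covariate_prior_var)
    for g, w in zip(spec.groups, state.weights):
        lp += _dirichlet_logpdf(w, np.asarray(g.dirichlet_alpha))
    if spec.link == "gaussian":
        lp += spec.residual_sd_prior.logpdf(float(state.residual_sd))
    return float(lp)


def log_posterior(
    state: ParameterState, data: MixtureDataset, spec: BWSModelSpec
) -> float:
    """Unnormalised joint log-posterior: the single target of the sampler."""
    return log_likelihood(state, data, spec) + log_prior(state, spec)


def _validate_model(data: MixtureDataset, spec: BWSModelSpec) -> None:
    K = data.n_exposures
    for g in spec.groups:
        if max(g.member_indices) >= K:
            raise ValueError(
                f"group {g.name!r} references exposure index {max(g.member_indices)} "
                f"but the dataset has only {K} exposure columns"
            )
    n_min = K + data.n_covariates + 2
    if data.n_obs < n_min:
        raise ValueError(f"need at least {n_min} observations, got {data.n_obs}")
    if spec.link == "logit":
        vals = np.unique(data.outcome)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("logit link requires a 0/1 outcome")
        if vals.size < 2:
            raise ValueError("binary outcome must contain both classes")


class BayesianWeightedSums:
    """Bayesian weighted-sum mixture regression model.

    Parameters
    ----------
    data
        A :class:`MixtureDataset`.
    spec
        A :class:`BWSModelSpec` describing link, groups and priors.

    Examples
    --------
    >>> model = BayesianWeightedSums.from_dataframe(
    ...     df, outcome="srs_z",
    ...     groups={"pbde": ["pbde28", "pbde47", "pbde99", "pbde100", "pbde153"]},
    ...     covariates=["maternal_age", "male"])
    >>> results = model.fit(n_iterations=30_000, burn_in=3000, thin=2, seed=7)
    >>> print(results.summary())
    """

    def __init__(self, data: MixtureDataset, spec: BWSModelSpec) -> None:
        _validate_model(data, spec)
        self.data = data
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        groups: dict[str, Sequence[str]],
        covariates: Sequence[str] = (),
        link: str = "gaussian",
        **spec_kwargs,
    ) -> "BayesianWeightedSums":
        """Build a model from a DataFrame and named exposure groups.

        ``groups`` maps a group label to the exposure column names whose
        summed effect it carries; ``covariates`` are adjustment columns.
        """
        exposure_cols: list[str] = []
        group_objs: list[ExposureGroup] = []
        alphas = spec_kwargs.pop("dirichlet_alpha", {})
        for name, cols in groups.items():
            idx = tuple(range(len(exposure_cols), len(exposure_cols) + len(cols)))
            exposure_cols.extend(cols)
            group_objs.append(
                ExposureGroup(name, idx, tuple(alphas.get(name, ())))
            )
        missing = [c for c in [outcome, *exposure_cols, *covariates] if c not in frame]
        if missing:
            raise KeyError(f"columns not found in data: {missing}")
        sub = frame[[outcome, *exposure_cols, *covariates]].apply(
            pd.to_numeric, errors="coerce"
        )
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"non-numeric or missing values in columns: {bad}")
        data = MixtureDataset(
            outcome=sub[outcome].to_numpy(),
            exposures=sub[exposure_cols].to_numpy(),
            covariates=sub[list(covariates)].to_numpy() if covariates else None,
            outcome_name=outcome,
            exposure_names=tuple(exposure_cols),
            covariate_names=tuple(covariates),
        )
        spec = BWSModelSpec(link=link, groups=tuple(group_objs), **spec_kwargs)
        return cls(data, spec)

    # -- model evaluation ------------------------------------------------
    def loglike(self, state: ParameterState) -> float:
        return log_likelihood(state, self.data, self.spec)

    def logprior(self, state: ParameterState) -> float:
        return log_prior(state, self.spec)

    def logposterior(self, state: ParameterState) -> float:
        return log_posterior(state, self.data, self.spec)

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        n_iterations: int = 30_000,
        burn_in: int = 3000,
        thin: int = 2,
        n_chains: int = 3,
        seed: int | None = None,
        config=None,
    ):
        """Run the adaptive Metropolis-within-Gibbs sampler.

        Returns a :class:`bwsum.results.BWSResults` with posterior draws,
        summaries and convergence diagnostics.  Defaults mirror the
        simulation-study settings (30 000 iterations, burn-in 3000,
        thinning 2, three chains).
        """
        from .results import BWSResults
        from .sampler import SamplerConfig, run_mcmc

        if config is None:
            config = SamplerConfig(
                n_iterations=n_iterations,
                burn_in=burn_in,
                thin=thin,
                n_chains=n_chains,
                seed=seed,
            )
        samples = run_mcmc(self.data, self.spec, config)
        return BWSResults(self, samples)
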