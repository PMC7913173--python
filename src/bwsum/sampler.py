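"""Adaptive Metropolis-within-Gibbs sampler for the BWS posterior.

The sampler updates three blocks per sweep: (1) the location block
(intercept, the summed effects theta_g, covariate coefficients) with a
joint random-walk proposal, (2) each group's weight vector in unconstrained
additive-log-ratio (ALR) coordinates, and (3) log sigma for the Gaussian
link.  Proposal step sizes follow Robbins-Monro adaptation toward standard
optimal acceptance rates (0.44 scalar / 0.234 multivariate) during burn-in
only, so the post-burn-in kernel is a fixed Metropolis kernel with the
correct stationary distribution.

Working in ALR coordinates removes the simplex boundary: for a group of
size K the coordinates are v_k = log(w_k / w_K), k < K, and the exact
Jacobian of the transform (sum_k log w_k) is added to the log-posterior, so
the Dirichlet prior on the simplex is preserved.  Reported draws are mapped
back to the simplex and sum to one by construction.

The per-chain loop is compiled with numba; the Gaussian-link likelihood is
evaluated through precomputed Gram matrices (X'X, X'y, y'y), which is
algebraically identical to the per-observation density sum but independent
of the sample size per evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .model import BWSModelSpec, MixtureDataset

__all__ = ["SamplerConfig", "PosteriorSamples", "run_mcmc"]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings (iterations, burn-in, thinning, chains, seed)."""

    n_iterations: int = 30_000
    burn_in: int = 3000
    thin: int = 2
    n_chains: int = 3
    seed: int | None = None
    target_accept_scalar: float = 0.44
    target_accept_vector: float = 0.234
    initial_step: float = 0.1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.burn_in < 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("invalid sampler configuration")
        if (self.n_iterations - self.burn_in) // self.thin < 1:
            raise ValueError("no draws would be kept; increase n_iterations")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _weights_from_alr(v, group_sizes, w_out):
    vi = 0
    wi = 0
    for g in range(group_sizes.shape[0]):
        K = group_sizes[g]
        m = 0.0
        for k in range(K - 1):
            if v[vi + k] > m:
                m = v[vi + k]
        s = math.exp(-m)
        for k in range(K - 1):
            s += math.exp(v[vi + k] - m)
        for k in range(K - 1):
            w_out[wi + k] = math.exp(v[vi + k] - m) / s
        w_out[wi + K - 1] = math.exp(-m) / s
        vi += K - 1
        wi += K
    return w_out


@njit(cache=True)
def _log_target(
    x_loc,
    v,
    logsig,
    link,
    Gm,
    bvec,
    yty,
    A,
    y,
    n_obs,
    col_means,
    group_sizes,
    alpha,
    dir_const,
    loc_mean,
    loc_var,
    sig_kind,
    sig_p1,
    sig_p2,
    w_buf,
    c_buf,
):
    """Log-posterior in unconstrained coordinates (Jacobian terms included).

    The design columns are mean-centered and ``x_loc[0]`` is the centered
    intercept; the prior is evaluated on the raw intercept (an exact
    unit-Jacobian reparameterization), so the posterior is unchanged while
    the intercept decorrelates from the slopes.
    """
    _weights_from_alr(v, group_sizes, w_buf)
    G = group_sizes.shape[0]
    d_loc = x_loc.shape[0]
    P = d_loc - 1 - G
    # coefficient vector on the centered design [1, exposures..., covariates]
    c_buf[0] = x_loc[0]
    wi = 0
    for g in range(G):
        th = x_loc[1 + g]
        for _k in range(group_sizes[g]):
            c_buf[1 + wi] = th * w_buf[wi]
            wi += 1
    for p in range(P):
        c_buf[1 + wi + p] = x_loc[1 + G + p]
    raw_intercept = c_buf[0]
    for j in range(1, c_buf.shape[0]):
        raw_intercept -= c_buf[j] * col_means[j]

    lp = dir_const
    d = raw_intercept - loc_mean[0]
    lp += -0.5 * d * d / loc_var[0] - 0.5 * math.log(2.0 * math.pi * loc_var[0])
    for j in range(1, d_loc):
        d = x_loc[j] - loc_mean[j]
        lp += -0.5 * d * d / loc_var[j] - 0.5 * math.log(2.0 * math.pi * loc_var[j])
    # Dirichlet density + ALR Jacobian collapses to sum_k alpha_k * log w_k
    wi = 0
    for g in range(G):
        for _k in range(group_sizes[g]):
            lp += alpha[wi] * math.log(w_buf[wi])
            wi += 1

    ncol = c_buf.shape[0]
    if link == 0:
        sig = math.exp(logsig)
        if sig_kind == 0:  # half-Cauchy(scale) on sigma, + Jacobian sigma
            lp += (
                math.log(2.0 / (math.pi * sig_p1 * (1.0 + (sig / sig_p1) ** 2)))
                + logsig
            )
        elif sig_kind == 1:  # InvGamma(shape, rate) on sigma^2, + Jacobian 2 sigma^2
            vv = sig * sig
            lp += (
                sig_p1 * math.log(sig_p2)
                - sig_p2 / vv
                - (sig_p1 + 1.0) * math.log(vv)
                + math.log(2.0 * vv)
            )
        # residual sum of squares via Gram identities
        cb = 0.0
        q = 0.0
        for i in range(ncol):
            ci = c_buf[i]
            cb += ci * bvec[i]
            s = 0.0
            for j in range(ncol):
                s += Gm[i, j] * c_buf[j]
            q += ci * s
        ssr = yty - 2.0 * cb + q
        lp += -0.5 * n_obs * math.log(2.0 * math.pi * sig * sig) - ssr / (2.0 * sig * sig)
    else:
        for i in range(n_obs):
            eta = 0.0
            for j in range(ncol):
                eta += A[i, j] * c_buf[j]
            if eta > 0.0:
                lp += y[i] * eta - eta - math.log1p(math.exp(-eta))
            else:
                lp += y[i] * eta - math.log1p(math.exp(eta))
    return lp


@njit(cache=True)
def _run_chain(
    seed,
    n_iter,
    burn_in,
    thin,
    link,
    Gm,
    bvec,
    yty,
    A,
    y,
    n_obs,
    col_means,
    group_sizes,
    alpha,
    dir_const,
    loc_mean,
    loc_var,
    sig_kind,
    sig_p1,
    sig_p2,
    x_loc0,
    v0,
    logsig0,
    step0,
    target_scalar,
    target_vector,
):
    np.random.seed(seed)
    d_loc = x_loc0.shape[0]
    G = group_sizes.shape[0]
    nv = v0.shape[0]
    Kw = 0
    for g in range(G):
        Kw += group_sizes[g]
    sample_sigma = (link == 0) and (sig_kind != 2)
    has_sigma_col = link == 0

    n_keep = (n_iter - burn_in) // thin
    D = d_loc + Kw + (1 if has_sigma_col else 0)
    draws = np.empty((n_keep, D))
    n_blocks = 1 + G + (1 if sample_sigma else 0)
    accept = np.zeros(n_blocks)
    steps = np.empty(n_blocks)

    x_loc = x_loc0.copy()
    v = v0.copy()
    logsig = logsig0
    w_buf = np.empty(Kw)
    c_buf = np.empty(1 + Kw + (d_loc - 1 - G))
    prop_loc = np.empty(d_loc)
    prop_v = np.empty(nv)

    ls_loc = math.log(step0)
    ls_w = np.full(G, math.log(step0))
    ls_s = math.log(step0)
    t_loc = target_scalar if d_loc == 1 else target_vector

    # Haario-style covariance adaptation for the location block: learn the
    # empirical covariance during burn-in (Welford) and propose along its
    # Cholesky factor, so collinear designs (e.g. intercept vs. an
    # uncentered covariate) still mix.  Frozen after burn-in.
    mu = x_loc.copy()
    M2 = np.zeros((d_loc, d_loc))
    cnt = 0
    Lc = np.eye(d_loc)
    use_cov = False
    cov_start = 300 if burn_in >= 600 else burn_in + 1
    zbuf = np.empty(d_loc)

    lp = _log_target(
        x_loc, v, logsig, link, Gm, bvec, yty, A, y, n_obs, col_means,
        group_sizes, alpha, dir_const, loc_mean, loc_var, sig_kind, sig_p1,
        sig_p2, w_buf, c_buf,
    )

    ki = 0
    for t in range(1, n_iter + 1):
        gamma = 1.0 / (1.0 * t) ** 0.6
        post = t > burn_in

        # block 1: intercept + thetas + covariate coefficients
        s = math.exp(ls_loc)
        if use_cov:
            for j in range(d_loc):
                zbuf[j] = np.random.normal()
            for j in range(d_loc):
                step = 0.0
                for k in range(j + 1):
                    step += Lc[j, k] * zbuf[k]
                prop_loc[j] = x_loc[j] + s * step
        else:
            for j in range(d_loc):
                prop_loc[j] = x_loc[j] + s * np.random.normal()
        lp_new = _log_target(
            prop_loc, v, logsig, link, Gm, bvec, yty, A, y, n_obs, col_means,
            group_sizes, alpha, dir_const, loc_mean, loc_var, sig_kind,
            sig_p1, sig_p2, w_buf, c_buf,
        )
        dl = lp_new - lp
        a = 1.0 if dl >= 0.0 else math.exp(dl)
        if np.random.random() < a:
            for j in range(d_loc):
                x_loc[j] = prop_loc[j]
            lp = lp_new
            if post:
                accept[0] += 1.0
        if not post:
            ls_loc += gamma * (a - t_loc)
            cnt += 1
            for j in range(d_loc):
                dj = x_loc[j] - mu[j]
                mu[j] += dj / cnt
                zbuf[j] = dj  # delta against the pre-update mean
            for j in range(d_loc):
                dj2 = x_loc[j] - mu[j]
                for k in range(d_loc):
                    M2[j, k] += zbuf[k] * dj2 if j >= k else 0.0
            if t >= cov_start and cnt > 2 * d_loc + 4 and t % 50 == 0:
                cov = np.empty((d_loc, d_loc))
                tr = 0.0
                for j in range(d_loc):
                    tr += M2[j, j] / (cnt - 1)
                ridge = 1e-6 * tr / d_loc + 1e-12
                for j in range(d_loc):
                    for k in range(d_loc):
                        m2jk = M2[j, k] if j >= k else M2[k, j]
                        cov[j, k] = m2jk / (cnt - 1)
                    cov[j, j] += ridge
                Lc = np.linalg.cholesky(cov)
                if not use_cov:
                    use_cov = True
                    ls_loc = math.log(2.38 / math.sqrt(1.0 * d_loc))

        # block 2: ALR weight coordinates, one block per group
        vi = 0
        for g in range(G):
            Kg1 = group_sizes[g] - 1
            if Kg1 > 0:
                s = math.exp(ls_w[g])
                for j in range(nv):
                    prop_v[j] = v[j]
                for k in range(Kg1):
                    prop_v[vi + k] = v[vi + k] + s * np.random.normal()
                lp_new = _log_target(
                    x_loc, prop_v, logsig, link, Gm, bvec, yty, A, y, n_obs,
                    col_means, group_sizes, alpha, dir_const, loc_mean,
                    loc_var, sig_kind, sig_p1, sig_p2, w_buf, c_buf,
                )
                dl = lp_new - lp
                a = 1.0 if dl >= 0.0 else math.exp(dl)
                if np.random.random() < a:
                    for k in range(Kg1):
                        v[vi + k] = prop_v[vi + k]
                    lp = lp_new
                    if post:
                        accept[1 + g] += 1.0
                if not post:
                    tgt = target_scalar if Kg1 == 1 else target_vector
                    ls_w[g] += gamma * (a - tgt)
            vi += Kg1

        # block 3: log sigma
        if sample_sigma:
            s = math.exp(ls_s)
            prop_ls = logsig + s * np.random.normal()
            lp_new = _log_target(
                x_loc, v, prop_ls, link, Gm, bvec, yty, A, y, n_obs, col_means,
                group_sizes, alpha, dir_const, loc_mean, loc_var, sig_kind,
                sig_p1, sig_p2, w_buf, c_buf,
            )
            dl = lp_new - lp
            a = 1.0 if dl >= 0.0 else math.exp(dl)
            if np.random.random() < a:
                logsig = prop_ls
                lp = lp_new
                if post:
                    accept[n_blocks - 1] += 1.0
            if not post:
                ls_s += gamma * (a - target_scalar)

        if post and (t - burn_in) % thin == 0 and ki < n_keep:
            for j in range(d_loc):
                draws[ki, j] = x_loc[j]
            _weights_from_alr(v, group_sizes, w_buf)
            for j in range(Kw):
                draws[ki, d_loc + j] = w_buf[j]
            # report the raw-scale intercept
            raw0 = x_loc[0]
            wi2 = 0
            for g in range(G):
                for _k in range(group_sizes[g]):
                    raw0 -= x_loc[1 + g] * w_buf[wi2] * col_means[1 + wi2]
                    wi2 += 1
            for p in range(d_loc - 1 - G):
                raw0 -= x_loc[1 + G + p] * col_means[1 + Kw + p]
            draws[ki, 0] = raw0
            if has_sigma_col:
                draws[ki, d_loc + Kw] = math.exp(logsig)
            ki += 1

    n_post = float(n_iter - burn_in)
    for b in range(n_blocks):
        accept[b] /= n_post
    steps[0] = math.exp(ls_loc)
    for g in range(G):
        steps[1 + g] = math.exp(ls_w[g])
    if sample_sigma:
        steps[n_blocks - 1] = math.exp(ls_s)
    return draws, accept, steps


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorSamples:
    """Post-burn-in, thinned draws for every parameter, per chain.

    ``draws`` has shape ``(n_chains, n_draws, n_params)``; ``names`` gives
    the parameter order: intercept, one ``theta_<group>`` per group,
    ``beta_<covariate>`` terms, ``w_<exposure>`` weights (simplex scale) and
    ``sigma`` for the Gaussian link.
    """

    names: tuple[str, ...]
    draws: np.ndarray
    config: SamplerConfig
    chain_seeds: tuple[int, ...]
    acceptance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chains, draws, params)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def _index(self, name: str) -> int:
        if name in self.names:
            return self.names.index(name)
        # convenience aliases: 'theta' / unprefixed weight names when unique
        matches = [
            i
            for i, n in enumerate(self.names)
            if n == name or n.split("_", 1)[0] == name or n.split("_", 1)[-1] == name
        ]
        if len(matches) == 1:
            return matches[0]
        raise KeyError(f"unknown or ambiguous parameter {name!r}; have {self.names}")

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_draws)."""
        return self.draws[:, :, self._index(name)]

    def pooled(self, name: str) -> np.ndarray:
        """Draws for one parameter pooled across chains."""
        return self.get(name).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=list(self.names))
            df.insert(0, "draw", np.arange(self.n_draws))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={n: self.draws[:, :, i] for i, n in enumerate(self.names)}
        )


def _initial_state(rng: np.random.Generator, spec: BWSModelSpec, n_cov: int):
    d_loc = 1 + spec.n_groups + n_cov
    x_loc = rng.normal(0.0, 1.0, size=d_loc)
    v_parts = []
    for g in spec.groups:
        w = rng.dirichlet(np.asarray(g.dirichlet_alpha))
        w = np.clip(w, 1e-6, None)
        w /= w.sum()
        if g.size > 1:
            v_parts.append(np.log(w[:-1] / w[-1]))
    v = np.concatenate(v_parts) if v_parts else np.zeros(0)
    sigma = abs(rng.normal()) + 0.1
    return x_loc, v, math.log(sigma)


def _check_separation(data: MixtureDataset) -> None:
    """Heuristic (quasi-)separation check: a diverging ML logit fit."""
    import statsmodels.api as sm

    Xfull = np.column_stack(
        [np.ones(data.n_obs), data.exposures, data.covariates]
    )
    separable = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(data.outcome, Xfull).fit(disp=0, maxiter=100)
        separable = bool(np.max(np.abs(fit.params)) > 15.0)
    except Exception:
        separable = True
    if separable:
        warnings.warn(
            "binary outcome appears (quasi-)separable given the predictors; "
            "posterior summaries for theta may be prior-driven",
            UserWarning,
            stacklevel=3,
        )


def run_mcmc(
    data: MixtureDataset, spec: BWSModelSpec, config: SamplerConfig
) -> PosteriorSamples:
    """Draw from the BWS posterior; deterministic given (data, spec, config)."""
    from .model import _validate_model

    _validate_model(data, spec)
    if spec.link == "logit":
        _check_separation(data)

    member_order = [i for g in spec.groups for i in g.member_indices]
    A = np.column_stack(
        [np.ones(data.n_obs), data.exposures[:, member_order], data.covariates]
    ).astype(float)
    # sample against mean-centered design columns (exact reparameterization;
    # the kernel maps the intercept back to the raw scale)
    col_means = A.mean(axis=0)
    col_means[0] = 0.0
    A = A - col_means
    y = data.outcome.astype(float)
    Gm = A.T @ A
    bvec = A.T @ y
    yty = float(y @ y)

    group_sizes = np.array([g.size for g in spec.groups], dtype=np.int64)
    alpha = np.concatenate([np.asarray(g.dirichlet_alpha) for g in spec.groups])
    dir_const = float(
        sum(
            gammaln(np.sum(g.dirichlet_alpha)) - np.sum(gammaln(np.asarray(g.dirichlet_alpha)))
            for g in spec.groups
            if g.size > 1
        )
    )
    P = data.n_covariates
    loc_mean = np.concatenate(
        [
            [spec.intercept_prior_mean],
            np.full(spec.n_groups, spec.theta_prior_mean),
            np.full(P, spec.covariate_prior_mean),
        ]
    )
    loc_var = np.concatenate(
        [
            [spec.intercept_prior_var],
            np.full(spec.n_groups, spec.theta_prior_var),
            np.full(P, spec.covariate_prior_var),
        ]
    )

    link_flag = 0 if spec.link == "gaussian" else 1
    if spec.link == "gaussian":
        prior = spec.residual_sd_prior
        sig_kind = {"half_cauchy": 0, "inverse_gamma": 1, "fixed": 2}[prior.kind]
        sig_p1 = prior.scale if prior.kind == "half_cauchy" else prior.shape
        sig_p2 = prior.rate
        fixed_sigma = prior.value if prior.kind == "fixed" else None
    else:
        sig_kind, sig_p1, sig_p2, fixed_sigma = 2, 0.0, 0.0, None

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = tuple(
        int(s) % (2**32) for s in ss.generate_state(config.n_chains, dtype=np.uint64)
    )
    init_rngs = [np.random.default_rng(c) for c in ss.spawn(config.n_chains)]

    names = (
        ["intercept"]
        + [f"theta_{g.name}" for g in spec.groups]
        + [f"beta_{c}" for c in data.covariate_names]
        + [f"w_{data.exposure_names[i]}" for i in member_order]
        + (["sigma"] if spec.link == "gaussian" else [])
    )

    all_draws = []
    acceptance = {}
    for c in range(config.n_chains):
        x_loc0, v0, logsig0 = _initial_state(init_rngs[c], spec, P)
        if fixed_sigma is not None:
            logsig0 = math.log(fixed_sigma)
        # guard against a degenerate start before entering the kernel
        w_buf = np.empty(int(group_sizes.sum()))
        c_buf = np.empty(A.shape[1])
        lp0 = _log_target(
            x_loc0, v0, logsig0, link_flag, Gm, bvec, yty, A, y, data.n_obs,
            col_means, group_sizes, alpha, dir_const, loc_mean, loc_var,
            sig_kind, sig_p1, sig_p2, w_buf, c_buf,
        )
        if not np.isfinite(lp0):
            raise RuntimeError(
                f"non-finite log-posterior at initialization of chain {c}: "
                f"loc={x_loc0}, alr={v0}, log_sigma={logsig0}"
            )
        draws, accept, steps = _run_chain(
            chain_seeds[c],
            config.n_iterations,
            config.burn_in,
            config.thin,
            link_flag,
            Gm,
            bvec,
            yty,
            A,
            y,
            data.n_obs,
            col_means,
            group_sizes,
            alpha,
            dir_const,
            loc_mean,
            loc_var,
            sig_kind,
            sig_p1,
            sig_p2,
            x_loc0,
            v0,
            logsig0,
            config.initial_step,
            config.target_accept_scalar,
            config.target_accept_vector,
        )
        all_draws.append(draws)
        acceptance[c] = {"rates": accept.copy(), "steps": steps.copy()}

    return PosteriorSamples(
        names=tuple(names),
        draws=np.stack(all_draws),
        config=config,
        chain_seeds=chain_seeds,
        acceptance=acceptance,
    )
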