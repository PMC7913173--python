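"""Synthetic data generation and the Monte-Carlo recovery/coverage study.

Two roles live here.  First, the scenario harness: generate replicate
datasets with five correlated standard-normal exposures and a Gaussian (or
Bernoulli) outcome driven by a weighted sum, fit the BWS model to each
replicate, and aggregate recovery metrics (median point estimate, average
posterior SD, average bias, MSE, 95% interval coverage) per parameter.
Default truth follows the study design: weights (0.1, 0.3, 0.2, 0.1, 0.3),
summed effects 1.0 or 0.2, residual SDs 0.5 or 0.1, sample sizes
250/500/1000, 500 replicates, exposures either low-to-moderately correlated
(pairwise 0.1-0.5) or highly correlated (exchangeable 0.9).

Second, a synthetic stand-in for a restricted autism-risk pregnancy cohort:
~166 mother-child pairs, five log-normal serum biomarker exposures of which
four are strongly intercorrelated and one only weakly, a continuous
z-scored behavioural score, a binary diagnosis (~25% prevalence, strongly
male-skewed), and the usual adjustment covariates.  It exists so the full
pipeline (preprocessing, fitting, reporting) can run end to end without the
restricted data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import BWSModelSpec, ExposureGroup, MixtureDataset
from .sampler import SamplerConfig, run_mcmc
from .summaries import hpd_interval

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "DESK_SAMPLER",
    "low_moderate_correlation",
    "high_correlation",
    "simulate_dataset",
    "fit_replicate",
    "run_scenario",
    "aggregate_replicates",
    "null_effect_probe",
    "Cohort",
    "make_earli_like_cohort",
]

log = logging.getLogger("bwsum")

DEFAULT_WEIGHTS = (0.1, 0.3, 0.2, 0.1, 0.3)

#: Desk-scale sampler settings for Monte-Carlo scenario runs (the full-study
#: settings, 30 000 iterations / burn-in 3000, remain available by config).
DESK_SAMPLER = SamplerConfig(n_iterations=6000, burn_in=1000, thin=2, n_chains=3)


def _nearest_positive_definite(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() > 1e-8:
        return C
    vals = np.clip(vals, 1e-6, None)
    C2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def low_moderate_correlation(k: int = 5) -> np.ndarray:
    """Deterministic pairwise correlations cycling through 0.1..0.5.

    Off-diagonal entries are assigned by lexicographic pair index so the
    matrix is fixed and runs are bit-reproducible; it is projected to the
    nearest positive-definite correlation matrix if required.
    """
    vals = (0.1, 0.2, 0.3, 0.4, 0.5)
    C = np.eye(k)
    p = 0
    for i in range(k):
        for j in range(i + 1, k):
            C[i, j] = C[j, i] = vals[p % len(vals)]
            p += 1
    return _nearest_positive_definite(C)


def high_correlation(k: int = 5, rho: float = 0.9) -> np.ndarray:
    """Exchangeable correlation matrix with off-diagonal ``rho``."""
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the recovery study: truth, design, and replicate count."""

    n: int = 250
    true_theta: float = 1.0
    true_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    correlation: str | np.ndarray = "low-moderate"
    residual_sd: float = 0.5
    link: str = "gaussian"
    n_replicates: int = 500
    base_seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-8 or np.any(w <= 0):
            raise ValueError("true_weights must be a positive simplex vector")
        object.__setattr__(self, "true_weights", tuple(w))
        C = self.correlation_matrix()
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("correlation matrix is not positive definite")

    @property
    def n_exposures(self) -> int:
        return len(self.true_weights)

    def correlation_matrix(self) -> np.ndarray:
        if isinstance(self.correlation, str):
            if self.correlation in ("low-moderate", "low_moderate"):
                return low_moderate_correlation(self.n_exposures)
            if self.correlation == "high":
                return high_correlation(self.n_exposures)
            raise ValueError(f"unknown correlation regime {self.correlation!r}")
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (self.n_exposures, self.n_exposures):
            raise ValueError("explicit correlation matrix has wrong shape")
        return C

    def truth(self) -> dict[str, float]:
        t = {"theta": self.true_theta}
        for k, w in enumerate(self.true_weights, start=1):
            t[f"w{k}"] = w
        if self.link == "gaussian":
            t["sigma"] = self.residual_sd
        return t


def _replicate_rng(scenario: ScenarioSpec, replicate_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(scenario.base_seed), spawn_key=(int(replicate_index),)
    )
    return np.random.default_rng(ss)


def _replicate_sampler_seed(scenario: ScenarioSpec, replicate_index: int) -> int:
    ss = np.random.SeedSequence(
        entropy=int(scenario.base_seed), spawn_key=(int(replicate_index), 65537)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_dataset(scenario: ScenarioSpec, replicate_index: int = 0) -> MixtureDataset:
    """Generate one replicate dataset; deterministic in (base_seed, index).

    Exposures are multivariate normal with zero mean, unit variances and the
    scenario correlation; the Gaussian outcome is
    ``y = theta * sum_k w_k x_k + eps`` with ``eps ~ N(0, residual_sd^2)``
    and intercept 0; the logit option draws Bernoulli outcomes from the same
    linear predictor.
    """
    rng = _replicate_rng(scenario, replicate_index)
    K = scenario.n_exposures
    L = np.linalg.cholesky(scenario.correlation_matrix())
    X = rng.standard_normal((scenario.n, K)) @ L.T
    w = np.asarray(scenario.true_weights)
    eta = scenario.true_theta * (X @ w)
    if scenario.link == "gaussian":
        y = eta + scenario.residual_sd * rng.standard_normal(scenario.n)
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
        y = rng.binomial(1, p).astype(float)
    return MixtureDataset(
        outcome=y,
        exposures=X,
        outcome_name="y",
        exposure_names=tuple(f"x{i+1}" for i in range(K)),
    )


def _scenario_spec_model(scenario: ScenarioSpec) -> BWSModelSpec:
    group = ExposureGroup("mixture", tuple(range(scenario.n_exposures)))
    return BWSModelSpec(link=scenario.link, groups=(group,))


def fit_replicate(
    scenario: ScenarioSpec,
    replicate_index: int,
    sampler_config: SamplerConfig | None = None,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Simulate one replicate, fit BWS, return per-parameter records."""
    config = sampler_config or DESK_SAMPLER
    config = replace(config, seed=_replicate_sampler_seed(scenario, replicate_index))
    data = simulate_dataset(scenario, replicate_index)
    spec = _scenario_spec_model(scenario)
    samples = run_mcmc(data, spec, config)

    names = {"theta": "theta_mixture"}
    for k in range(scenario.n_exposures):
        names[f"w{k+1}"] = f"w_x{k+1}"
    if scenario.link == "gaussian":
        names["sigma"] = "sigma"
    truth = scenario.truth()

    from .diagnostics import gelman_rubin

    rows = []
    for label, pname in names.items():
        pooled = samples.pooled(pname)
        hpd = hpd_interval(pooled, mass)
        rows.append(
            {
                "replicate": replicate_index,
                "parameter": label,
                "truth": truth[label],
                "median": float(np.median(pooled)),
                "mean": float(np.mean(pooled)),
                "sd": float(np.std(pooled, ddof=1)),
                "hpd_lower": hpd.lower,
                "hpd_upper": hpd.upper,
                "gelman_rubin": (
                    gelman_rubin(samples, pname) if config.n_chains > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScenarioResult:
    """Aggregated recovery metrics plus the replicate-level records."""

    scenario: ScenarioSpec
    table: pd.DataFrame
    replicates: pd.DataFrame
    n_failed: int = 0
    failed_indices: tuple[int, ...] = ()

    def metric(self, parameter: str, column: str) -> float:
        row = self.table.loc[self.table["parameter"] == parameter]
        if row.empty:
            raise KeyError(f"no parameter {parameter!r} in scenario table")
        return float(row[column].iloc[0])

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, index=False)


def aggregate_replicates(
    scenario: ScenarioSpec, replicates: pd.DataFrame
) -> pd.DataFrame:
    """Collapse replicate records into the study's summary metrics.

    The point estimate per replicate is the posterior median; the reported
    estimate is the median of those medians; average bias and MSE are the
    mean error and mean squared error about the truth; average SD is the
    mean posterior standard deviation; coverage is the fraction of
    replicates whose 95% HPD interval contains the truth.
    """
    rows = []
    for label, grp in replicates.groupby("parameter", sort=False):
        truth = float(grp["truth"].iloc[0])
        est = grp["median"].to_numpy()
        rows.append(
            {
                "parameter": label,
                "truth": truth,
                "estimate": float(np.median(est)),
                "average_sd": float(grp["sd"].mean()),
                "average_bias": float(np.mean(est - truth)),
                "mse": float(np.mean((est - truth) ** 2)),
                "coverage": float(
                    np.mean((grp["hpd_lower"] <= truth) & (truth <= grp["hpd_upper"]))
                ),
                "mean_gelman_rubin": float(grp["gelman_rubin"].mean()),
                "n_replicates": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def run_scenario(
    scenario: ScenarioSpec,
    sampler_config: SamplerConfig | None = None,
    progress: bool = False,
    skip_replicates: Sequence[int] = (),
    on_replicate=None,
) -> ScenarioResult:
    """Run the full Monte-Carlo cell: simulate, fit and aggregate.

    A replicate whose fit raises is recorded and excluded with a logged
    count, never silently.  ``on_replicate(index, frame)`` can be used for
    incremental persistence (e.g. resumable runs).
    """
    frames = []
    failed = []
    skip = set(int(i) for i in skip_replicates)
    for r in range(scenario.n_replicates):
        if r in skip:
            continue
        try:
            frame = fit_replicate(scenario, r, sampler_config)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            failed.append(r)
            log.warning("replicate %d failed: %s", r, exc)
            continue
        frames.append(frame)
        if on_replicate is not None:
            on_replicate(r, frame)
        if progress and (r + 1) % 10 == 0:
            log.info("scenario replicate %d/%d done", r + 1, scenario.n_replicates)
    if failed:
        log.warning("%d/%d replicates failed and were excluded",
                    len(failed), scenario.n_replicates)
    if not frames:
        raise RuntimeError("every replicate failed; nothing to aggregate")
    replicates = pd.concat(frames, ignore_index=True)
    return ScenarioResult(
        scenario=scenario,
        table=aggregate_replicates(scenario, replicates),
        replicates=replicates,
        n_failed=len(failed),
        failed_indices=tuple(failed),
    )


def null_effect_probe(
    scenario: ScenarioSpec | None = None,
    sampler_config: SamplerConfig | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Posterior-mean weights under a null summed effect (theta = 0).

    With nothing for the weights to explain, their posterior stays at the
    Dirichlet prior, so the posterior-mean weights sit near 1/K regardless
    of the weights used to generate the data.  Returns one row per exposure
    with the across-replicate average posterior-mean weight.
    """
    scenario = scenario or ScenarioSpec(true_theta=0.0, n_replicates=n_replicates)
    if scenario.true_theta != 0.0:
        raise ValueError("null_effect_probe requires true_theta = 0")
    scenario = replace(scenario, n_replicates=min(scenario.n_replicates, n_replicates))
    result = run_scenario(scenario, sampler_config)
    wsub = result.replicates[result.replicates["parameter"].str.startswith("w")]
    grouped = wsub.groupby("parameter", sort=False)["mean"]
    out = grouped.mean().rename("posterior_mean_weight").reset_index()
    # chance correlation between noise and exposures tilts single
    # replicates; the median across replicates is the robust typical value
    out["replicate_median_weight"] = grouped.median().to_numpy()
    out["prior_mean"] = 1.0 / scenario.n_exposures
    return out


# ---------------------------------------------------------------------------
# synthetic cohort fixture
# ---------------------------------------------------------------------------

PBDE_NAMES = ("pbde28", "pbde47", "pbde99", "pbde100", "pbde153")


@dataclass(frozen=True)
class Cohort:
    """Synthetic cohort table plus its limit-of-detection table."""

    frame: pd.DataFrame
    lod: dict[str, float]

    def dataset(
        self,
        outcome: str = "srs_z",
        exposures: Sequence[str] = PBDE_NAMES,
        covariates: Sequence[str] = (),
    ) -> MixtureDataset:
        df = self.frame
        return MixtureDataset(
            outcome=df[outcome].to_numpy(),
            exposures=df[list(exposures)].to_numpy(),
            covariates=df[list(covariates)].to_numpy() if covariates else None,
            outcome_name=outcome,
            exposure_names=tuple(exposures),
            covariate_names=tuple(covariates),
        )


def make_earli_like_cohort(
    seed: int = 0,
    n: int = 166,
    below_lod_fraction: float = 0.15,
) -> Cohort:
    """Synthetic stand-in for the restricted autism-risk pregnancy cohort.

    Emulates the published structure only: five log-normal serum PBDE
    exposures with four strongly intercorrelated congeners and one (153)
    only weakly correlated; a continuous z-scored social-responsiveness
    outcome; a binary diagnosis with ~25% prevalence and strong male excess;
    covariates shaped like the cohort's adjustment set (maternal age,
    ordinal income, 5-level race/ethnicity, 4-level site, child sex,
    gestational age).  It reproduces no individual-level feature of the real
    data.
    """
    rng = np.random.default_rng(seed)
    K = 5
    C = np.full((K, K), 0.88)
    C[4, :] = C[:, 4] = 0.25
    np.fill_diagonal(C, 1.0)
    C = _nearest_positive_definite(C)
    L = np.linalg.cholesky(C)
    log_mean = np.log(np.array([1.0, 20.0, 5.0, 4.0, 6.0]))
    log_sd = np.array([0.9, 1.0, 1.0, 0.95, 0.8])
    latent = rng.standard_normal((n, K)) @ L.T
    logx = log_mean + latent * log_sd
    x = np.exp(logx)
    lod = {
        name: float(np.quantile(x[:, k], below_lod_fraction))
        for k, name in enumerate(PBDE_NAMES)
    }

    age = np.clip(rng.normal(33.7, 5.0, n), 18.0, 45.0)
    gest = np.clip(rng.normal(38.7, 2.2, n), 30.0, 42.0)
    income = rng.choice(
        np.arange(1, 9),
        size=n,
        p=np.array([0.05, 0.02, 0.04, 0.14, 0.15, 0.16, 0.31, 0.13]),
    ).astype(float)
    race = rng.choice(5, size=n, p=np.array([0.55, 0.08, 0.11, 0.13, 0.13]))
    site = rng.choice(4, size=n, p=np.array([0.24, 0.25, 0.30, 0.21]))
    male = rng.binomial(1, 0.56, n).astype(float)

    # outcomes respond to the standardized log-scale exposures
    wmix = np.array([0.22, 0.24, 0.18, 0.18, 0.18])
    ws = latent @ wmix

    srs_raw = 0.25 * ws + 0.8 * male - 0.03 * (income - income.mean()) + rng.standard_normal(n)
    srs_z = (srs_raw - srs_raw.mean()) / srs_raw.std(ddof=1)

    eta = np.log(1.41) * ws + 1.6 * male - 0.05 * (income - income.mean())
    intercept = np.log(42 / 124) - eta.mean() - 0.45  # calibrated for ~25% prevalence
    p = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    asd = rng.binomial(1, p).astype(float)

    frame = pd.DataFrame(x, columns=list(PBDE_NAMES))
    frame["srs_z"] = srs_z
    frame["asd"] = asd
    frame["maternal_age"] = age
    frame["gestational_age"] = gest
    frame["income"] = income
    frame["male"] = male
    for r, label in enumerate(("hisp_white", "black", "asian", "other"), start=1):
        frame[f"race_{label}"] = (race == r).astype(float)
    for s, label in enumerate(("jh", "kp", "ucd"), start=1):
        frame[f"site_{label}"] = (site == s).astype(float)
    return Cohort(frame=frame, lod=lod)
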