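"""Convergence diagnostics: Gelman-Rubin, autocorrelation, trace plots."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sampler import PosteriorSamples

__all__ = [
    "gelman_rubin",
    "autocorrelation",
    "DiagnosticsReport",
    "compute_diagnostics",
    "plot_trace",
    "plot_autocorrelation",
]


def _chain_matrix(samples: PosteriorSamples | np.ndarray, parameter: str | None):
    if isinstance(samples, PosteriorSamples):
        return samples.get(parameter)
    return np.atleast_2d(np.asarray(samples, dtype=float))


def gelman_rubin(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Each chain is split in half, so m = 2 * n_chains sequences enter the
    classic between/within variance ratio.  Values near 1 indicate that all
    chains explore the same posterior distribution.
    """
    chains = _chain_matrix(samples, parameter)
    if chains.shape[0] < 2:
        raise ValueError(
            "Gelman-Rubin requires at least two chains; rerun with n_chains >= 2"
        )
    if chains.shape[1] < 10:
        raise ValueError("chains are too short for a meaningful diagnostic")
    L = chains.shape[1] // 2
    halves = np.vstack([chains[:, :L], chains[:, L : 2 * L]])
    means = halves.mean(axis=1)
    W = float(halves.var(axis=1, ddof=1).mean())
    B_over_L = float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_L == 0.0 else float("inf")
    var_plus = (L - 1) / L * W + B_over_L
    return float(np.sqrt(var_plus / W))


def autocorrelation(
    samples: PosteriorSamples | np.ndarray,
    parameter: str | None = None,
    max_lag: int = 50,
) -> np.ndarray:
    """Normalized autocorrelation function, averaged over chains (lag 0 = 1)."""
    from statsmodels.tsa.stattools import acf

    chains = _chain_matrix(samples, parameter)
    if max_lag >= chains.shape[1]:
        raise ValueError("max_lag must be smaller than the chain length")
    if np.any(chains.var(axis=1) == 0.0):
        raise ValueError("constant chain: autocorrelation is undefined")
    acfs = [acf(chain, nlags=max_lag, fft=True) for chain in chains]
    return np.mean(acfs, axis=0)


@dataclass
class DiagnosticsReport:
    """Per-parameter R-hat and autocorrelation, plus any exported plot paths."""

    gelman_rubin: dict[str, float]
    autocorrelation: dict[str, np.ndarray]
    trace_paths: dict[str, str] = field(default_factory=dict)

    @property
    def max_gelman_rubin(self) -> float:
        return max(self.gelman_rubin.values())

    def flagged(self, threshold: float = 1.1) -> list[str]:
        return [p for p, r in self.gelman_rubin.items() if r > threshold]


def compute_diagnostics(samples: PosteriorSamples, max_lag: int = 50) -> DiagnosticsReport:
    rhat = {}
    ac = {}
    for name in samples.names:
        chains = samples.get(name)
        if np.allclose(chains, chains[0, 0]):
            rhat[name] = 1.0
            continue
        rhat[name] = gelman_rubin(samples, name)
        ac[name] = autocorrelation(samples, name, min(max_lag, samples.n_draws - 1))
    return DiagnosticsReport(gelman_rubin=rhat, autocorrelation=ac)


def _require_pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_trace(
    samples: PosteriorSamples, out_dir: str | Path, parameters=None
) -> dict[str, str]:
    """Write one trace-plot PNG per parameter; returns name -> path."""
    plt = _require_pyplot()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in parameters or samples.names:
        fig, ax = plt.subplots(figsize=(7, 2.4))
        for c in range(samples.n_chains):
            ax.plot(samples.get(name)[c], lw=0.4, label=f"chain {c}")
        ax.set_xlabel("draw")
        ax.set_ylabel(name)
        ax.legend(fontsize=6, loc="upper right")
        fig.tight_layout()
        path = out / f"trace_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths[name] = str(path)
    return paths


def plot_autocorrelation(
    samples: PosteriorSamples, out_dir: str | Path, parameters=None, max_lag: int = 50
) -> dict[str, str]:
    """Write one autocorrelation PNG per parameter; returns name -> path."""
    plt = _require_pyplot()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in parameters or samples.names:
        chains = samples.get(name)
        if np.any(chains.var(axis=1) == 0.0):
            continue
        rho = autocorrelation(samples, name, min(max_lag, samples.n_draws - 1))
        fig, ax = plt.subplots(figsize=(4, 2.4))
        ax.bar(np.arange(rho.size), rho, width=0.8)
        ax.set_xlabel("lag")
        ax.set_ylabel(f"acf {name}")
        fig.tight_layout()
        path = out / f"acf_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths[name] = str(path)
    return paths
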