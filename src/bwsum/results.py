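"""Results object returned by :meth:`BayesianWeightedSums.fit`."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import (
    DiagnosticsReport,
    autocorrelation,
    compute_diagnostics,
    gelman_rubin,
    plot_autocorrelation,
    plot_trace,
)
from .summaries import (
    HPDInterval,
    format_summary_table,
    hpd_interval,
    summarize_fit,
    summary_frame,
)

__all__ = ["BWSResults", "BWSSummary"]


class BWSSummary:
    """Summary table wrapper with a DataFrame view and aligned text rendering."""

    def __init__(self, summaries, title: str):
        self.summaries = summaries
        self.title = title
        self.frame = summary_frame(summaries)

    def as_text(self) -> str:
        return f"{self.title}\n{format_summary_table(self.summaries)}"

    def __str__(self) -> str:  # pragma: no cover - formatting convenience
        return self.as_text()

    def __repr__(self) -> str:  # pragma: no cover
        return self.as_text()


class BWSResults:
    """Posterior draws plus summaries and diagnostics for a fitted BWS model."""

    def __init__(self, model, samples):
        self.model = model
        self.samples = samples

    # -- point and interval estimates ------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        return self.samples.names

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.samples.pooled(name)))

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.samples.pooled(name)))

    def posterior_sd(self, name: str) -> float:
        return float(np.std(self.samples.pooled(name), ddof=1))

    def hpd(self, name: str, mass: float = 0.95) -> HPDInterval:
        return hpd_interval(self.samples.pooled(name), mass)

    def summary(self, mass: float = 0.95) -> BWSSummary:
        spec = self.model.spec
        title = (
            f"Bayesian weighted sums ({spec.link} link, "
            f"{self.samples.n_chains} chains x {self.samples.n_draws} draws)"
        )
        return BWSSummary(summarize_fit(self.samples, spec, mass), title)

    def weight_means(self, group: str | None = None) -> dict[str, float]:
        """Posterior-mean weights; means sum to one within each group."""
        spec = self.model.spec
        names = self.model.data.exposure_names
        groups = [g for g in spec.groups if group is None or g.name == group]
        out = {}
        for g in groups:
            for i in g.member_indices:
                out[f"w_{names[i]}"] = self.posterior_mean(f"w_{names[i]}")
        return out

    # -- diagnostics ------------------------------------------------------
    def gelman_rubin(self, name: str | None = None):
        if name is not None:
            return gelman_rubin(self.samples, name)
        return compute_diagnostics(self.samples).gelman_rubin

    def autocorrelation(self, name: str, max_lag: int = 50) -> np.ndarray:
        return autocorrelation(self.samples, name, max_lag)

    def diagnostics(self, max_lag: int = 50) -> DiagnosticsReport:
        return compute_diagnostics(self.samples, max_lag)

    def plot_trace(self, out_dir, parameters=None) -> dict[str, str]:
        return plot_trace(self.samples, out_dir, parameters)

    def plot_autocorrelation(self, out_dir, parameters=None, max_lag: int = 50):
        return plot_autocorrelation(self.samples, out_dir, parameters, max_lag)

    # -- export -----------------------------------------------------------
    def save_draws(self, path, header_lines=()) -> None:
        """Write all draws as CSV (chain, draw, one column per parameter)."""
        df = self.samples.to_dataframe()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)

    def to_inference_data(self):
        return self.samples.to_inference_data()
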