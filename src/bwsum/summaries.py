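"""Posterior summaries: medians, means, highest-posterior-density intervals.

Reporting follows the conventions of mixture-effect analyses: the median
draw is the effect estimate of interest, means are shown alongside to make
visible that exposure weights average to one, and interval estimates are
95% highest-posterior-density (HPD) intervals — the shortest contiguous
interval containing the requested posterior mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HPDInterval", "ParameterSummary", "hpd_interval", "summarize_fit", "summary_frame"]

MIN_DRAWS = 100


@dataclass(frozen=True)
class HPDInterval:
    """Highest-posterior-density credible interval of a given mass."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("HPD lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> HPDInterval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties between equally short windows are broken toward the lower window
    start.  Assumes a unimodal posterior; split regions are not produced.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws for an HPD interval, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(math.ceil(mass * n))
    if m >= n:
        return HPDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) minimiser
    return HPDInterval(float(x[i]), float(x[i + m - 1]), mass)


@dataclass(frozen=True)
class ParameterSummary:
    """Median / mean / SD / HPD for one parameter (posterior scale)."""

    name: str
    median: float
    mean: float
    sd: float
    hpd: HPDInterval

    def as_row(self) -> dict:
        return {
            "parameter": self.name,
            "median": self.median,
            "mean": self.mean,
            "sd": self.sd,
            "hpd_lower": self.hpd.lower,
            "hpd_upper": self.hpd.upper,
            "hpd_mass": self.hpd.mass,
        }


def _summarize_draws(name: str, pooled: np.ndarray, mass: float) -> ParameterSummary:
    return ParameterSummary(
        name=name,
        median=float(np.median(pooled)),
        mean=float(np.mean(pooled)),
        sd=float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
        hpd=hpd_interval(pooled, mass),
    )


def summarize_fit(samples, spec=None, mass: float = 0.95) -> list[ParameterSummary]:
    """Pooled-across-chains summaries for every sampled parameter.

    For the logit link, each summed effect ``theta_g`` is additionally
    reported on the odds-ratio scale as ``exp(theta_g)``: median and mean of
    the exponentiated draws, with HPD endpoints exponentiated (the
    exponential is monotone, so the theta-scale HPD maps onto the OR scale).
    """
    out = []
    logit = spec is not None and getattr(spec, "link", None) == "logit"
    for name in samples.names:
        pooled = samples.pooled(name)
        out.append(_summarize_draws(name, pooled, mass))
        if logit and name.startswith("theta"):
            base = out[-1]
            out.append(
                ParameterSummary(
                    name=f"exp({name})",
                    median=math.exp(base.median),
                    mean=float(np.mean(np.exp(pooled))),
                    sd=float(np.std(np.exp(pooled), ddof=1)),
                    hpd=HPDInterval(
                        math.exp(base.hpd.lower), math.exp(base.hpd.upper), mass
                    ),
                )
            )
    return out


def summary_frame(summaries: list[ParameterSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def format_summary_table(summaries: list[ParameterSummary]) -> str:
    """Aligned plain-text table: parameter | Median | Mean | 95% HPD."""
    mass = summaries[0].hpd.mass if summaries else 0.95
    header = f"{'parameter':<20}{'Median':>10}{'Mean':>10}  {int(round(mass * 100))}% HPD"
    lines = [header, "-" * len(header)]
    for s in summaries:
        lines.append(
            f"{s.name:<20}{s.median:>10.3f}{s.mean:>10.3f}  "
            f"({s.hpd.lower:.3f}, {s.hpd.upper:.3f})"
        )
    return "\n".join(lines)
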