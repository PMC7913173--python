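"""Data ingestion and biomarker preprocessing.

The preprocessing order is fixed and logged — limit-of-detection
imputation, then natural-log transform, then (optional) z-score
standardization — because changing the order changes the result; the
applied order is written into every output's provenance header.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessSpec",
    "impute_below_lod",
    "zscore",
    "log_transform",
    "read_table",
    "apply_preprocessing",
]

log = logging.getLogger("bwsum")


def impute_below_lod(
    values: np.ndarray,
    lod: float,
    below_lod: np.ndarray | None = None,
) -> np.ndarray:
    """Replace below-detection-limit entries with ``lod / sqrt(2)``.

    Entries are flagged either explicitly (``below_lod`` boolean mask, which
    wins on conflict) or implicitly as measured values strictly below the
    LOD.  Other entries are untouched; the replacement count is logged.
    """
    x = np.asarray(values, dtype=float).copy()
    if lod <= 0:
        raise ValueError("LOD must be positive")
    if np.any(x < 0):
        raise ValueError("negative measured values are not valid biomarker readings")
    mask = np.asarray(below_lod, dtype=bool) if below_lod is not None else x < lod
    x[mask] = lod / math.sqrt(2.0)
    log.info("imputed %d of %d values at LOD/sqrt(2) = %.6g", mask.sum(), x.size, lod / math.sqrt(2))
    return x


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant (zero-variance) vector")
    return (x - x.mean()) / sd


def log_transform(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("natural-log transform requires strictly positive values")
    return np.log(x)


@dataclass(frozen=True)
class PreprocessSpec:
    """Per-run preprocessing switches and LOD table.

    ``lod`` maps exposure column -> detection limit; ``flag_columns`` maps
    exposure column -> name of a 0/1 below-LOD indicator column (explicit
    flags win over value-below-LOD detection).
    """

    lod: dict[str, float] = field(default_factory=dict)
    flag_columns: dict[str, str] = field(default_factory=dict)
    impute_lod: bool = True
    log_transform_exposures: bool = False
    zscore_exposures: bool = False
    zscore_outcome: bool = False

    def __post_init__(self) -> None:
        bad = {c: v for c, v in self.lod.items() if v <= 0}
        if bad:
            raise ValueError(f"LOD values must be positive: {bad}")

    def order(self) -> list[str]:
        steps = []
        if self.impute_lod and self.lod:
            steps.append("lod_imputation")
        if self.log_transform_exposures:
            steps.append("log_transform")
        if self.zscore_exposures:
            steps.append("zscore_exposures")
        if self.zscore_outcome:
            steps.append("zscore_outcome")
        return steps


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table with a header (comma/tab/semicolon)."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def apply_preprocessing(
    frame: pd.DataFrame,
    spec: PreprocessSpec,
    outcome: str,
    exposure_cols: list[str],
    covariate_cols: list[str] = (),
) -> pd.DataFrame:
    """Apply the fixed preprocessing order; complete-case on used columns."""
    df = frame.copy()
    used = [outcome, *exposure_cols, *covariate_cols]
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise KeyError(f"columns not found in data: {missing_cols}")
    n0 = len(df)
    df = df.dropna(subset=used)
    if len(df) < n0:
        log.info("dropped %d incomplete rows (complete-case analysis)", n0 - len(df))
    if df[exposure_cols].isna().all().any():
        raise ValueError("an exposure column is entirely missing")

    if spec.impute_lod:
        for col, lod in spec.lod.items():
            if col not in exposure_cols:
                continue
            flag_col = spec.flag_columns.get(col)
            mask = df[flag_col].to_numpy().astype(bool) if flag_col in df.columns else None
            df[col] = impute_below_lod(df[col].to_numpy(), lod, mask)
    if spec.log_transform_exposures:
        for col in exposure_cols:
            df[col] = log_transform(df[col].to_numpy())
    if spec.zscore_exposures:
        for col in exposure_cols:
            df[col] = zscore(df[col].to_numpy())
    if spec.zscore_outcome:
        df[outcome] = zscore(df[outcome].to_numpy())
    log.info("preprocessing order: %s", " -> ".join(spec.order()) or "none")
    return df
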