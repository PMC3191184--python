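"""Statistical reporting: bootstrap CIs, per-culture SEs, densitometry.

Colocalization coefficients are summarized across cells with a percentile
bootstrap of the mean (cells are the resampling unit; dendrites are first
averaged within a cell). Percent-colocalization statistics are summarized
with the standard error of per-culture means, which is undefined (reported
as NaN) when only one independent culture contributed. Western-blot
densitometry is normalized to a loading control and expressed relative to
the earliest timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapCI",
    "DensitometryProfile",
    "bootstrap_ci",
    "per_culture_se",
    "densitometry_normalize",
    "coefficient_report",
    "percent_colocalization_report",
]


@dataclass(frozen=True)
class BootstrapCI:
    """A bootstrap confidence interval for a sample mean."""

    estimate: float
    lower: float
    upper: float
    level: float
    n_reps: int
    seed: int | None
    method: str = "percentile"

    def __str__(self) -> str:  # Table-style "0.63 (0.59-0.67)"
        return f"{self.estimate:.2f} ({self.lower:.2f}-{self.upper:.2f})"


def bootstrap_ci(
    values,
    level: float = 0.95,
    n_reps: int = 10_000,
    seed: int | None = None,
    method: str = "percentile",
) -> BootstrapCI:
    """Bootstrap CI of the mean over individual observations (cells).

    ``method="percentile"`` (default) takes the empirical quantiles of the
    resampled means; ``method="basic"`` reflects them about the observed
    mean. Deterministic for a fixed ``seed``. Requires at least 2 values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least 2 observations")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_reps, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    # percentile bounds are means of observations, hence inside the sample
    # range up to float summation noise; pin them there
    lo, hi = np.clip([lo, hi], vals.min(), vals.max())
    estimate = float(vals.mean())
    if method == "basic":
        lo, hi = 2 * estimate - hi, 2 * estimate - lo
    elif method != "percentile":
        raise ValueError(f"unknown bootstrap method {method!r}")
    return BootstrapCI(estimate, float(lo), float(hi), level, n_reps, seed, method)


def per_culture_se(values, group_labels) -> tuple[float, float]:
    """Mean and standard error of per-culture means.

    Each culture's observations are first averaged; the returned mean is
    the mean of those culture means and the SE is their (n−1) SD divided
    by √(number of cultures). With a single culture the SE is undefined
    and returned as NaN (reported as "N/A" in tables).
    """
    vals = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if vals.size == 0 or vals.shape != labels.shape:
        raise ValueError("values and group_labels must be equal-length and non-empty")
    culture_means = pd.Series(vals).groupby(labels).mean().to_numpy()
    mean = float(culture_means.mean())
    if culture_means.size < 2:
        return mean, float("nan")
    se = float(culture_means.std(ddof=1) / np.sqrt(culture_means.size))
    return mean, se


@dataclass(frozen=True)
class DensitometryProfile:
    """Band and loading-control intensities across developmental timepoints."""

    timepoints: list[str]
    band_intensity: np.ndarray
    control_intensity: np.ndarray
    reference_index: int = 0

    def __post_init__(self) -> None:
        band = np.asarray(self.band_intensity, dtype=float)
        ctrl = np.asarray(self.control_intensity, dtype=float)
        if not (len(self.timepoints) == band.size == ctrl.size):
            raise ValueError("timepoints, band and control must be equal length")
        if (band <= 0).any() or (ctrl <= 0).any():
            raise ValueError("all intensities must be positive")
        if not 0 <= self.reference_index < band.size:
            raise ValueError("reference_index out of range")
        object.__setattr__(self, "band_intensity", band)
        object.__setattr__(self, "control_intensity", ctrl)


def densitometry_normalize(profile: DensitometryProfile) -> np.ndarray:
    """Control-normalized band intensity as % of the reference timepoint.

    ``ratio_t = band_t / control_t``; output is ``100 · ratio_t /
    ratio_ref``, so the reference timepoint is exactly 100.
    """
    ratios = profile.band_intensity / profile.control_intensity
    out = 100.0 * ratios / ratios[profile.reference_index]
    out[profile.reference_index] = 100.0  # exact by definition
    return out


def coefficient_report(
    per_cell: pd.DataFrame,
    coefficient_cols: list[str],
    pair_col: str = "pair",
    level: float = 0.95,
    n_reps: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Coefficient means with bootstrap CIs, one row per channel pair.

    ``per_cell`` holds one row per cell (dendrites already averaged within
    the cell). Output cells are formatted ``mean (lower-upper)`` with the
    number of cells in an ``n_cells`` column — the layout used for summary
    tables of Rr / M1 / M2 / ICQ.
    """
    rows = {}
    for pair, grp in per_cell.groupby(pair_col):
        row = {}
        for col in coefficient_cols:
            row[col] = str(bootstrap_ci(grp[col].to_numpy(), level, n_reps, seed))
        row["n_cells"] = len(grp)
        rows[pair] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def percent_colocalization_report(
    per_cell: pd.DataFrame,
    value_col: str = "percent_colocalized",
    culture_col: str = "culture",
    pair_col: str = "pair",
) -> pd.DataFrame:
    """Percent colocalization as ``mean (SE)`` over independent cultures.

    Single-culture rows print ``mean (N/A)`` since a between-culture SE
    needs at least two cultures.
    """
    rows = {}
    for pair, grp in per_cell.groupby(pair_col):
        mean, se = per_culture_se(grp[value_col].to_numpy(), grp[culture_col].to_numpy())
        rows[pair] = {
            "percent_colocalization": f"{mean:.1f} ({'N/A' if np.isnan(se) else format(se, '.1f')})",
            "n_cultures": grp[culture_col].nunique(),
            "n_cells": len(grp),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
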