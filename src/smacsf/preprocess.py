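"""Leakage-aware preprocessing of raw LFQ intensity tables.

Fixed pipeline order: log2 -> per-sample median-centering -> completeness
filter -> min-imputation -> (per-analysis) train-only z-scaling.  Zeros in
the raw table are treated as missing (standard LFQ semantics).  The scaler
is fitted on a training subset only and applied unchanged to held-out
samples, so no statistic of the test partition leaks into model fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix

__all__ = [
    "log2_median_center",
    "filter_by_completeness",
    "impute_min",
    "ScalerState",
    "fit_scaler",
    "apply_scaler",
]

logger = logging.getLogger(__name__)


def log2_median_center(raw: pd.DataFrame, already_log2: bool = False) -> IntensityMatrix:
    """Log2-transform and median-center each sample (column).

    Parameters
    ----------
    raw
        Proteins x samples table.  On the raw scale values must be >= 0 and
        zeros mean "not quantified"; with ``already_log2=True`` the values
        are taken as log2 abundances (NaN = missing) and only centering is
        applied, which makes the operation idempotent.
    """
    if already_log2:
        log2 = raw.astype(float)
    else:
        arr = raw.to_numpy(float)
        if np.nanmin(arr) < 0:
            raise ValueError("raw intensities must be non-negative")
        with np.errstate(divide="ignore"):
            log2 = pd.DataFrame(
                np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan),
                index=raw.index,
                columns=raw.columns,
            )
    n_obs = log2.notna().sum(axis=0)
    thin = n_obs[n_obs < 2]
    if len(thin):
        raise ValueError(f"samples with fewer than 2 quantified proteins: {list(thin.index)}")
    centered = log2.sub(log2.median(axis=0, skipna=True), axis=1)
    return IntensityMatrix(centered)


def filter_by_completeness(
    matrix: IntensityMatrix,
    min_fraction_per_group: float = 0.7,
    groups: pd.Series | None = None,
) -> IntensityMatrix:
    """Keep proteins observed in >= ``min_fraction_per_group`` of the samples
    of at least one group (all samples form one group when none are given).
    Protein order is preserved."""
    if not 0 < min_fraction_per_group <= 1:
        raise ValueError("min_fraction_per_group must lie in (0, 1]")
    mask = matrix.mask
    if groups is None:
        groups = pd.Series("all", index=matrix.sample_ids)
    groups = groups.reindex(matrix.sample_ids)
    keep = pd.Series(False, index=matrix.protein_ids)
    for _, cols in groups.groupby(groups).groups.items():
        frac = mask.loc[:, cols].mean(axis=1)
        keep |= frac >= min_fraction_per_group
    if not keep.any():
        logger.warning("completeness filter removed every protein")
    return IntensityMatrix(matrix.values.loc[keep])


def impute_min(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace missing cells by the protein's minimum observed value.

    A deliberately conservative stand-in for left-censored LFQ dropout;
    proteins with no observation at all are dropped with a warning.
    """
    vals = matrix.values
    n_obs = vals.notna().sum(axis=1)
    if (n_obs == 0).any():
        dropped = list(vals.index[n_obs == 0])
        warnings.warn(f"dropping {len(dropped)} proteins with no observations")
        vals = vals.loc[n_obs > 0]
    row_min = vals.min(axis=1)
    return IntensityMatrix(vals.T.fillna(row_min).T)


@dataclass
class ScalerState:
    """Per-protein location/scale estimated on a training subset only."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            raise ValueError("scaler sd must be positive for retained proteins")


def fit_scaler(train: IntensityMatrix, ddof: int = 1) -> ScalerState:
    """Fit per-protein mean/sd on a complete training matrix.

    Zero-variance proteins are dropped from the state with a warning; the
    state is a pure function of the training subset.
    """
    vals = train.values
    if vals.isna().any().any():
        raise ValueError("fit_scaler expects a complete (imputed) matrix")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    flat = sd <= 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance proteins from scaler")
        mean, sd = mean[~flat], sd[~flat]
    return ScalerState(mean=mean, sd=sd)


def apply_scaler(state: ScalerState, matrix: IntensityMatrix) -> IntensityMatrix:
    """Apply a fitted scaler: (x - train mean) / train sd, restricted to the
    proteins retained by the state."""
    vals = matrix.values.loc[state.mean.index]
    return IntensityMatrix(vals.sub(state.mean, axis=0).div(state.sd, axis=0))
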