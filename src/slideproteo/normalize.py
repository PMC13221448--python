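"""Sample-median normalization, log2 transform and per-protein scaling.

Every quantitative stage downstream (signature scoring, differential
abundance) consumes these transforms: each sample's quantifications are
divided by that sample's median (so the per-sample median of the
back-transformed matrix is exactly 1), then log2-transformed; signature
heat-map style views additionally z-score each protein across samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import NormalizationError

logger = logging.getLogger(__name__)


def median_normalize_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell by its sample's median, then log2.

    Missing cells are preserved; every sample must contribute at least
    one positive value. Idempotent on already-normalized data.
    """
    values = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(values, initial=np.inf) <= 0:
            raise NormalizationError("matrix contains non-positive abundances")
    medians = np.nanmedian(values, axis=0)
    empty = ~np.isfinite(medians)
    if empty.any():
        bad = matrix.columns[empty][0]
        raise NormalizationError(f"sample {bad!r} has no quantified values")
    return pd.DataFrame(
        np.log2(values / medians[None, :]), index=matrix.index, columns=matrix.columns
    )


def back_transform(norm: pd.DataFrame) -> pd.DataFrame:
    """Linear-scale view of a median-normalized log2 matrix (2**values)."""
    return np.power(2.0, norm)


def scale_per_protein(norm: pd.DataFrame) -> pd.DataFrame:
    """Z-score each protein across samples (sample-SD, ddof=1, convention).

    Proteins quantified in fewer than two samples, or with zero
    variance, are set to all zeros with a warning rather than dropped.
    """
    values = norm.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    n_obs = np.sum(np.isfinite(values), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
        scaled = (values - mean) / sd
    degenerate = (n_obs < 2) | ~np.isfinite(sd[:, 0]) | (sd[:, 0] == 0)
    if degenerate.any():
        logger.warning(
            "scale_per_protein: %d protein(s) constant or underobserved; set to 0",
            int(degenerate.sum()),
        )
        scaled[degenerate, :] = np.where(
            np.isfinite(values[degenerate, :]), 0.0, np.nan
        )
    return pd.DataFrame(scaled, index=norm.index, columns=norm.columns)
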