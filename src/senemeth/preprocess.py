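"""Beta computation, detection-p filtering and quantile normalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from senemeth.io_formats import BetaMatrix
from senemeth.synthetic_data import IntensityPair

__all__ = [
    "DetectionMatrix",
    "compute_beta",
    "filter_by_detection",
    "filter_missing",
    "quantile_normalize",
]

#: platform-convention channel offset in fluorescence units
DEFAULT_OFFSET = 100.0


@dataclass
class DetectionMatrix:
    """Per CpG/sample detection p-values in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("detection p-values must lie in [0, 1]")


def compute_beta(intensities: IntensityPair,
                 offset: float = DEFAULT_OFFSET) -> BetaMatrix:
    """beta = M / (M + U + offset), elementwise.

    Cells with ``M + U + offset == 0`` become missing with a warning.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    m = intensities.methylated.to_numpy(dtype=float)
    u = intensities.unmethylated.to_numpy(dtype=float)
    denom = m + u + offset
    zero = denom == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} cells with zero total intensity "
                      "set to missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zero, np.nan, m / np.where(zero, 1.0, denom))
    return BetaMatrix(pd.DataFrame(beta,
                                   index=intensities.methylated.index,
                                   columns=intensities.methylated.columns))


def filter_by_detection(
    beta: BetaMatrix,
    detection: DetectionMatrix,
    alpha_det: float = 0.01,
    max_fail_fraction: float = 0.0,
) -> tuple[BetaMatrix, list[str]]:
    """Drop CpGs whose fraction of samples failing detection
    (p > alpha_det) exceeds ``max_fail_fraction``.

    Defaults are strict: any failing sample removes the CpG.  Returns the
    filtered matrix and the removed CpG ids.
    """
    if beta.shape != detection.values.shape:
        raise ValueError(
            f"beta {beta.shape} and detection {detection.values.shape} "
            "matrices differ in shape"
        )
    fail_frac = (detection.values.to_numpy() > alpha_det).mean(axis=1)
    removed_mask = fail_frac > max_fail_fraction
    removed = list(beta.cpg_ids[removed_mask])
    return BetaMatrix(beta.values.loc[~removed_mask]), removed


def filter_missing(beta: BetaMatrix) -> tuple[BetaMatrix, list[str]]:
    """Drop CpGs with any missing value (they are excluded from
    normalization and all downstream statistics)."""
    has_na = beta.values.isna().any(axis=1).to_numpy()
    removed = list(beta.cpg_ids[has_na])
    return BetaMatrix(beta.values.loc[~has_na]), removed


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Force every column onto the common distribution of mean order
    statistics while preserving within-column ranks.

    Ties within a column receive the mean of the order-statistic means
    across their tied ranks.  Requires a complete matrix (see
    :func:`filter_missing`).
    """
    values = beta.values
    if values.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix; "
                         "apply filter_missing first")
    arr = values.to_numpy(dtype=float)
    n, k = arr.shape
    if n == 1:
        mean = float(arr.mean())
        return BetaMatrix(pd.DataFrame(np.full_like(arr, mean),
                                       index=values.index,
                                       columns=values.columns))
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        mapped = reference[ranks]
        # average the reference over tied ranks
        uniq, inverse = np.unique(col, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inverse, weights=mapped)
            counts = np.bincount(inverse)
            mapped = (sums / counts)[inverse]
        out[:, j] = mapped
    return BetaMatrix(pd.DataFrame(out, index=values.index,
                                   columns=values.columns))
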