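"""Lowess normalization of two-channel intensities and missing-value imputation.

Each array is hybridized against a common reference pool, so normalization is
per-array: intensity-dependent dye bias is removed by subtracting a locally
weighted regression of M = log2(sample/reference) on
A = 0.5 * log2(sample * reference) from M.  The corrected log-ratios are the
substrate of all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ValidationError
from .io_formats import ExpressionMatrix

__all__ = ["TwoChannelArray", "lowess_normalize", "impute_missing"]

DEFAULT_SPAN = 0.3
DEFAULT_ITERATIONS = 3
MIN_GENES_FOR_FIT = 50


@dataclass
class TwoChannelArray:
    """Raw intensities of one hybridization: sample channel vs reference channel."""

    gene_ids: list
    sample_channel: np.ndarray
    reference_channel: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_channel = np.asarray(self.sample_channel, dtype=float)
        self.reference_channel = np.asarray(self.reference_channel, dtype=float)
        n = len(self.gene_ids)
        if self.sample_channel.shape != (n,) or self.reference_channel.shape != (n,):
            raise ValidationError("channel lengths must match the gene list")
        if (self.sample_channel <= 0).any() or (self.reference_channel <= 0).any():
            raise ValidationError("channel intensities must be strictly positive")


def lowess_normalize(
    array: TwoChannelArray,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
) -> np.ndarray:
    """Return Lowess-corrected log2 ratios for one array.

    Parameters
    ----------
    array
        The two-channel intensities.
    span
        Lowess smoothing fraction in (0, 1].
    iterations
        Robustness (residual re-weighting) iterations.

    Returns
    -------
    ndarray
        Corrected M values, one per gene, in the array's gene order.
    """
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    if len(array.gene_ids) < MIN_GENES_FOR_FIT:
        raise ValidationError(
            f"need >= {MIN_GENES_FOR_FIT} genes for a stable lowess fit, got {len(array.gene_ids)}"
        )
    m = np.log2(array.sample_channel / array.reference_channel)
    a = 0.5 * np.log2(array.sample_channel * array.reference_channel)
    fit = _sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - fit


def impute_missing(
    matrix: ExpressionMatrix,
    method: str = "gene_mean",
    max_missing_fraction: float = 0.2,
) -> ExpressionMatrix:
    """Replace missing log-ratios by the per-gene mean of observed values.

    Genes missing in more than ``max_missing_fraction`` of samples carry too
    little information to impute and are reported as an error.  Imputed cells
    are recorded in the result's metadata.
    """
    if method != "gene_mean":
        raise ValidationError(f"unknown imputation method {method!r}")
    values = matrix.values
    missing = np.isnan(values)
    if not missing.any():
        return matrix
    frac = missing.mean(axis=0)
    over_cap = [g for g, f in zip(matrix.gene_ids, frac) if f > max_missing_fraction]
    if over_cap:
        raise ValidationError(
            f"genes exceed missingness cap of {max_missing_fraction:.0%}: {over_cap}"
        )
    out = values.copy()
    gene_means = np.nanmean(values, axis=0)
    rows, cols = np.nonzero(missing)
    out[rows, cols] = gene_means[cols]
    meta = dict(matrix.metadata)
    meta["imputed_cells"] = [
        (matrix.sample_ids[i], matrix.gene_ids[j]) for i, j in zip(rows.tolist(), cols.tolist())
    ]
    meta["has_missing"] = False
    return ExpressionMatrix(matrix.sample_ids, matrix.gene_ids, out, meta)
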