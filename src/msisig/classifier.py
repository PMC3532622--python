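"""Nearest-centroid MSI classification with a cosine-correlation index.

A sample's signature index is the difference between its cosine similarity to
the MSI centroid and to the MSS centroid, computed on the signature genes
only.  Two thresholds split the index range into three calls: below the
primary threshold the sample is MSS; at or above the secondary threshold it
is MSI; in between it is MSI-like (signature-positive but typically assessed
MSS by hospital methods).  The boundary convention is "at or above" at both
thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import MSI, MSI_LIKE, MSS, ExpressionMatrix, SignatureModel

__all__ = [
    "build_centroids",
    "msi_index",
    "msi_index_matrix",
    "classify",
    "classify_matrix",
    "reduce_to_platform",
]

RESULT_COLUMNS = ["sample_id", "corr_msi", "corr_mss", "index", "call"]


def build_centroids(matrix: ExpressionMatrix, labels, gene_list) -> SignatureModel:
    """Per-class mean profiles over the signature genes; thresholds left unset.

    ``labels`` is binary per sample (1 = MSI).  Genes absent from the matrix
    raise with the full list of missing ids.
    """
    labels = np.asarray(labels)
    if labels.shape != (matrix.n_samples,):
        raise ValidationError("labels must align with matrix samples")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValidationError("both classes must be present to build centroids")
    sub = matrix.subset_genes(gene_list)
    centroid_msi = sub.values[labels == 1].mean(axis=0)
    centroid_mss = sub.values[labels == 0].mean(axis=0)
    return SignatureModel(
        list(gene_list),
        centroid_msi,
        centroid_mss,
        provenance={"n_msi": int((labels == 1).sum()), "n_mss": int((labels == 0).sum())},
    )


def _cosine(x: np.ndarray, c: np.ndarray, centered: bool) -> np.ndarray:
    """Cosine similarity of each row of x against centroid c."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    c = np.asarray(c, dtype=float)
    if centered:
        x = x - x.mean(axis=1, keepdims=True)
        c = c - c.mean()
    xn = np.linalg.norm(x, axis=1)
    cn = np.linalg.norm(c)
    if cn == 0 or (xn == 0).any():
        raise ValidationError("cosine undefined for zero-norm vector")
    return x @ c / (xn * cn)


def msi_index(profile, model: SignatureModel, centered: bool = False):
    """Index of a single profile aligned to ``model.gene_ids``.

    Returns ``(corr_msi, corr_mss, index)`` with
    ``index = corr_msi - corr_mss`` in [-2, 2].  ``centered=True`` replaces
    cosine similarity with Pearson correlation.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (model.n_genes,):
        raise ValidationError(
            f"profile length {profile.shape} does not match {model.n_genes} signature genes"
        )
    corr_msi = float(_cosine(profile, model.centroid_msi, centered)[0])
    corr_mss = float(_cosine(profile, model.centroid_mss, centered)[0])
    return corr_msi, corr_mss, corr_msi - corr_mss


def msi_index_matrix(matrix: ExpressionMatrix, model: SignatureModel, centered: bool = False) -> pd.DataFrame:
    """Vectorized index for every sample; genes are aligned by id."""
    sub = matrix.subset_genes(model.gene_ids)
    corr_msi = _cosine(sub.values, model.centroid_msi, centered)
    corr_mss = _cosine(sub.values, model.centroid_mss, centered)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "corr_msi": corr_msi,
            "corr_mss": corr_mss,
            "index": corr_msi - corr_mss,
        }
    )


def classify(index: float, model: SignatureModel) -> str:
    """Three-way call for one index value.

    MSS below the primary threshold, MSI at or above the secondary, MSI-like
    in between.  Binary signature-positive is any non-MSS call.
    """
    if not model.has_thresholds():
        raise ValidationError("model thresholds are unset; optimize thresholds first")
    if model.thresholds_stale:
        raise ValidationError(
            "model thresholds are stale (gene set changed); re-optimize on a calibration set"
        )
    if index >= model.threshold_secondary:
        return MSI
    if index >= model.threshold_primary:
        return MSI_LIKE
    return MSS


def classify_matrix(matrix: ExpressionMatrix, model: SignatureModel, centered: bool = False) -> pd.DataFrame:
    """Per-sample classification table: sample_id, corr_msi, corr_mss, index, call."""
    result = msi_index_matrix(matrix, model, centered)
    result["call"] = [classify(v, model) for v in result["index"]]
    return result[RESULT_COLUMNS]


def reduce_to_platform(model: SignatureModel, available_genes, floor: int = 50) -> SignatureModel:
    """Restrict a signature to the genes measurable on another platform.

    Centroid order is preserved; dropped genes are recorded in provenance.
    The returned model keeps its numeric thresholds but is flagged stale:
    index distributions shift with signature dimension, so thresholds must be
    re-optimized on a calibration set before classification.
    """
    available = set(available_genes)
    keep = [g for g in model.gene_ids if g in available]
    if len(keep) < floor:
        raise ValidationError(
            f"only {len(keep)} signature genes available; floor is {floor}"
        )
    idx = [model.gene_ids.index(g) for g in keep]
    dropped = [g for g in model.gene_ids if g not in available]
    provenance = dict(model.provenance)
    provenance["dropped_genes"] = dropped
    return SignatureModel(
        keep,
        model.centroid_msi[idx],
        model.centroid_mss[idx],
        model.threshold_primary,
        model.threshold_secondary,
        thresholds_stale=model.thresholds_stale or bool(dropped),
        provenance=provenance,
    )
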