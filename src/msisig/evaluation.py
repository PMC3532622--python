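"""Threshold optimization and classifier performance metrics.

Thresholds are chosen by exhaustive evaluation of every decision boundary the
data can distinguish: midpoints between adjacent sorted unique index values,
plus one candidate below the minimum (everything positive) and one above the
maximum (nothing positive).  The optimization criterion is the Youden-style
sum of sensitivity and specificity, optionally subject to a sensitivity
floor; plain accuracy is reported separately.  A sample is positive when its
index is at or above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ValidationError

__all__ = [
    "PerformanceReport",
    "optimize_primary_threshold",
    "optimize_secondary_threshold",
    "roc_auc",
    "performance_report",
]


@dataclass
class PerformanceReport:
    """Confusion counts and derived rates at one threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    overall_accuracy: float
    threshold_used: float
    auc: float | None = None
    auc_ci_low: float | None = None
    auc_ci_high: float | None = None

    @classmethod
    def from_confusion(cls, tp: int, fp: int, tn: int, fn: int, threshold: float) -> "PerformanceReport":
        total = tp + fp + tn + fn
        if total == 0:
            raise ValidationError("empty confusion table")
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            overall_accuracy=(tp + tn) / total,
            threshold_used=threshold,
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _check_binary(indices, labels):
    indices = np.asarray(indices, dtype=float)
    labels = np.asarray(labels)
    if indices.shape != labels.shape or indices.ndim != 1:
        raise ValidationError("indices and labels must be equal-length 1-D arrays")
    if len(indices) == 0:
        raise ValidationError("empty input")
    if not np.isfinite(indices).all():
        raise ValidationError("indices must be finite")
    if not np.isin(labels, [0, 1]).all():
        raise ValidationError("labels must be binary 0/1")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValidationError("both classes must be present")
    return indices, labels.astype(int)


def _candidate_thresholds(indices: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique values, bracketed by one
    candidate below the minimum and one above the maximum."""
    u = np.unique(indices)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def _sens_spec_at(indices, labels, threshold):
    pos = indices >= threshold
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec


def optimize_primary_threshold(
    indices,
    labels,
    rule: str = "max_sens_plus_spec",
    sens_floor: float = 0.90,
) -> float:
    """Threshold maximizing sensitivity + specificity over all candidates.

    ``rule='max_sens_plus_spec_with_floor'`` restricts the search to
    candidates achieving sensitivity >= ``sens_floor`` (the validation-cohort
    read-out rule); an unattainable floor raises with the best achievable
    sensitivity.  Ties are resolved toward the lowest threshold, favoring
    sensitivity.
    """
    if rule not in ("max_sens_plus_spec", "max_sens_plus_spec_with_floor"):
        raise ValidationError(f"unknown rule {rule!r}")
    indices, labels = _check_binary(indices, labels)
    candidates = _candidate_thresholds(indices)
    best_thr = None
    best_score = -np.inf
    max_sens = 0.0
    for thr in candidates:  # ascending, so strict '>' keeps the lowest tie
        sens, spec = _sens_spec_at(indices, labels, thr)
        max_sens = max(max_sens, sens)
        if rule == "max_sens_plus_spec_with_floor" and sens < sens_floor:
            continue
        if sens + spec > best_score:
            best_score = sens + spec
            best_thr = thr
    if best_thr is None:
        raise ValidationError(
            f"sensitivity floor {sens_floor} unattainable; maximum achievable is {max_sens:.3f}"
        )
    return float(best_thr)


def optimize_secondary_threshold(indices, hospital_labels) -> float:
    """Split signature-positive samples into MSI-like vs MSI.

    ``indices`` are the index values of signature-positive samples only and
    ``hospital_labels`` their hospital assessment (1 = MSI).  The threshold
    maximizes sensitivity + specificity for hospital-MSI vs hospital-MSS
    among the positives; samples below it are called MSI-like, at or above
    it MSI.
    """
    indices = np.asarray(indices, dtype=float)
    labels = np.asarray(hospital_labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValidationError(
            "secondary threshold undefined: signature-positive samples are a single hospital class"
        )
    return optimize_primary_threshold(indices, labels, rule="max_sens_plus_spec")


def _auc(indices, labels) -> float:
    return float(roc_auc_score(labels, indices))


def _delong_variance(indices, labels):
    """DeLong placement-value variance of the empirical AUC."""
    x = indices[labels == 1]
    y = indices[labels == 0]
    m, n = len(x), len(y)
    # placement of each positive among negatives and vice versa, ties at 1/2
    v10 = np.array([(np.sum(xi > y) + 0.5 * np.sum(xi == y)) / n for xi in x])
    v01 = np.array([(np.sum(x > yj) + 0.5 * np.sum(x == yj)) / m for yj in y])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    indices,
    labels,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Empirical AUC (Mann-Whitney, ties counted 1/2) with a 95% CI.

    Returns ``(auc, (ci_low, ci_high))``.  The CI is a class-stratified
    bootstrap percentile interval by default, or an asymptotic DeLong
    interval.
    """
    indices, labels = _check_binary(indices, labels)
    auc = _auc(indices, labels)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                (rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True))
            )
            aucs[b] = _auc(indices[take], labels[take])
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    elif ci_method == "delong":
        se = np.sqrt(_delong_variance(indices, labels))
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return auc, (float(lo), float(hi))


def performance_report(indices, labels, threshold: float) -> PerformanceReport:
    """Confusion counts and rates with positive = (index >= threshold)."""
    indices, labels = _check_binary(indices, labels)
    pos = indices >= threshold
    return PerformanceReport.from_confusion(
        tp=int(np.sum(pos & (labels == 1))),
        fp=int(np.sum(pos & (labels == 0))),
        tn=int(np.sum(~pos & (labels == 0))),
        fn=int(np.sum(~pos & (labels == 1))),
        threshold=float(threshold),
    )
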