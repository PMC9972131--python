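"""Specificity-calibrated comparison classifiers.

Two baselines from the nonresponsivity literature, both calibrated on
the human rows of the stratified calibration sample, ignoring
prevalence:

* the *univariate union rule*: one threshold per suspicion-increasing
  index at a nominal quantile of the calibration humans; flag anyone
  exceeding any threshold (multiple testing attenuates realized
  specificity below nominal);
* the *feature-space Mahalanobis cutoff*: squared Mahalanobis distance
  to the human feature centroid, thresholded at a nominal human
  quantile — a multivariate cutoff with no psychometric model.

Empirical quantiles use the ceiling rule: the smallest order statistic
whose cumulative proportion reaches the nominal level, which guarantees
at-least-nominal coverage on the calibration sample itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics_theory import ClassificationReport, confusion_metrics
from .nri import (
    ORIENT_INCREASING,
    FeatureMatrix,
    ReferenceStats,
    mahalanobis_many,
    to_suspicion_increasing,
)


def ceiling_quantile(values, level: float) -> float:
    """Smallest order statistic with cumulative proportion >= level."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not 0.0 < level <= 1.0:
        raise ValueError("quantile level must be in (0, 1]")
    k = math.ceil(level * n)
    return float(values[k - 1])


@dataclass(frozen=True)
class UnivariateCutoffs:
    """Per-index thresholds in suspicion-increasing form."""

    thresholds: np.ndarray
    index_names: tuple[str, ...]
    nominal_specificity: float

    def __post_init__(self) -> None:
        thresholds = np.asarray(self.thresholds, dtype=float)
        if thresholds.shape != (len(self.index_names),):
            raise ValueError("need exactly one threshold per index")
        object.__setattr__(self, "thresholds", thresholds)
        object.__setattr__(self, "index_names", tuple(self.index_names))


@dataclass(frozen=True)
class MahalanobisCutoff:
    """Human feature centroid/covariance and a distance threshold."""

    reference: ReferenceStats
    threshold: float
    nominal_specificity: float

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("squared-distance threshold must be non-negative")


def _require_increasing(fm: FeatureMatrix) -> FeatureMatrix:
    if all(o == ORIENT_INCREASING for o in fm.orientations):
        return fm
    return to_suspicion_increasing(fm)


def fit_univariate_union(cal_features_increasing: FeatureMatrix, labels,
                         nominal_specificity: float = 0.99) -> UnivariateCutoffs:
    """Threshold each index at the nominal quantile of the calibration
    *humans* only."""
    fm = _require_increasing(cal_features_increasing)
    labels = np.asarray(labels).astype(np.int64)
    human = fm.values[labels == 0]
    if human.shape[0] == 0:
        raise ValueError("no human rows in the calibration sample")
    thresholds = np.array([ceiling_quantile(human[:, j], nominal_specificity)
                           for j in range(fm.n_features)])
    return UnivariateCutoffs(thresholds=thresholds, index_names=fm.index_names,
                             nominal_specificity=nominal_specificity)


def predict_univariate_union(fm: FeatureMatrix, cuts: UnivariateCutoffs, *,
                             truth=None) -> ClassificationReport:
    """Flag a row iff any index strictly exceeds its threshold."""
    fm = _require_increasing(fm)
    if fm.index_names != cuts.index_names:
        raise ValueError(
            f"feature columns {fm.index_names} do not match fitted cutoffs "
            f"{cuts.index_names}")
    exceed = fm.values > cuts.thresholds
    predicted = (exceed.sum(axis=1) > 0).astype(np.int64)
    # suspicion-increasing composite: largest margin over any threshold
    scores = (fm.values - cuts.thresholds).max(axis=1)
    if truth is not None:
        return confusion_metrics(truth, predicted, scores=scores, threshold=0.0)
    return ClassificationReport(predicted=predicted, scores=scores, threshold=0.0)


def fit_mahalanobis_cutoff(cal_features: FeatureMatrix, labels,
                           nominal_specificity: float = 0.99, *,
                           ridge: float | None = None) -> MahalanobisCutoff:
    """Human feature centroid, MLE covariance, and the nominal human
    quantile of the squared distances as threshold."""
    labels = np.asarray(labels).astype(np.int64)
    human = cal_features.values[labels == 0]
    n0 = human.shape[0]
    if n0 < cal_features.n_features + 1:
        raise ValueError(
            f"need at least J+1 = {cal_features.n_features + 1} calibration "
            f"humans, got {n0}")
    mean = human.mean(axis=0)
    dev = human - mean
    cov = dev.T @ dev / n0
    reference = ReferenceStats(mean=mean, covariance=cov, source_n=n0)
    dists = mahalanobis_many(human, reference, ridge=ridge)
    threshold = ceiling_quantile(dists, nominal_specificity)
    return MahalanobisCutoff(reference=reference, threshold=threshold,
                             nominal_specificity=nominal_specificity)


def predict_mahalanobis_cutoff(fm: FeatureMatrix, cutoff: MahalanobisCutoff, *,
                               ridge: float | None = None,
                               truth=None) -> ClassificationReport:
    """Flag a row iff its feature-space squared distance strictly exceeds
    the fitted threshold."""
    dists = mahalanobis_many(fm.values, cutoff.reference, ridge=ridge)
    predicted = (dists > cutoff.threshold).astype(np.int64)
    if truth is not None:
        return confusion_metrics(truth, predicted, scores=dists,
                                 threshold=cutoff.threshold)
    return ClassificationReport(predicted=predicted, scores=dists,
                                threshold=cutoff.threshold)


def fit_predict_mahalanobis_cutoff(cal_features: FeatureMatrix, labels,
                                   target_features: FeatureMatrix,
                                   nominal_specificity: float = 0.99, *,
                                   ridge: float | None = None,
                                   truth=None) -> ClassificationReport:
    """Convenience composition of fit + predict for the distance cutoff."""
    cutoff = fit_mahalanobis_cutoff(cal_features, labels, nominal_specificity,
                                    ridge=ridge)
    return predict_mahalanobis_cutoff(target_features, cutoff, ridge=ridge,
                                      truth=truth)
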