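"""Nonresponsivity indices (NRIs).

Each index maps a respondent's raw response vector to a real number
measuring deviation from the response structure of a human reference
sample, and carries a *suspicion orientation*: ``"increasing"`` if
larger values are more suspicious, ``"decreasing"`` otherwise.

The built-in battery:

``mahalanobis``
    Squared Mahalanobis distance ``(z - m)^T S^{-1} (z - m)`` to the
    reference mean; suspicion-increasing.  The squared form (no root) is
    used throughout; it is monotone-equivalent for thresholding.
``person_total``
    Pearson correlation between the response vector and the reference
    item-mean vector; suspicion-decreasing.
``fmt_coherence`` / ``fmt_reliability``
    Optional factor-model coherence/reliability indices in ``[0, 1]``
    and ``[-1, 1]`` respectively, both suspicion-decreasing.  These are
    plugins; the core pipeline runs with the first two indices alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import linalg

from .response_data import LabeledSample, ResponseMatrix

logger = logging.getLogger(__name__)

ORIENT_INCREASING = "increasing"
ORIENT_DECREASING = "decreasing"


class SingularCovarianceError(np.linalg.LinAlgError):
    """Reference covariance is singular and no ridge was requested."""


@dataclass(frozen=True)
class ReferenceStats:
    """Item mean vector and covariance of the human reference sample.

    The covariance uses divisor ``n`` (the maximum-likelihood
    convention), matching the class-density estimates used downstream.
    """

    mean: np.ndarray
    covariance: np.ndarray
    source_n: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.ndim != 1:
            raise ValueError("reference mean must be a vector")
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance dimensions must match the mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def n_items(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class FeatureMatrix:
    """``(n, J)`` matrix of NRI values with per-column orientation.

    ``degenerate_mask`` marks rows where a degeneracy policy fired
    (e.g. a constant response vector in the person-total index); it is
    preserved through recoding for auditability.
    """

    values: np.ndarray
    index_names: tuple[str, ...]
    orientations: tuple[str, ...]
    degenerate_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] < 1:
            raise ValueError("feature values must be an (n, J) array with J >= 1")
        if not np.isfinite(values).all():
            raise ValueError("feature matrix contains non-finite values")
        names = tuple(self.index_names)
        orients = tuple(self.orientations)
        if len(names) != values.shape[1] or len(orients) != values.shape[1]:
            raise ValueError("need one name and one orientation per column")
        for o in orients:
            if o not in (ORIENT_INCREASING, ORIENT_DECREASING):
                raise ValueError(f"unknown orientation {o!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "index_names", names)
        object.__setattr__(self, "orientations", orients)
        if self.degenerate_mask is not None:
            mask = np.asarray(self.degenerate_mask, dtype=bool)
            if mask.shape != (values.shape[0],):
                raise ValueError("degenerate_mask must have one entry per row")
            object.__setattr__(self, "degenerate_mask", mask)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def reference_from_humans(cal: LabeledSample) -> ReferenceStats:
    """Mean and MLE covariance of the calibration *human* rows only."""
    humans = cal.humans()
    if humans.has_missing:
        raise ValueError("impute missing responses before computing reference stats")
    X = humans.values.astype(float)
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / X.shape[0]
    return ReferenceStats(mean=mean, covariance=cov, source_n=X.shape[0])


def _solve_covariance(cov: np.ndarray, ridge: float | None):
    """Cholesky factor of the (optionally ridged) covariance.

    Raises :class:`SingularCovarianceError` naming the near-null
    directions when the matrix is not positive definite and no ridge
    was requested.
    """
    if ridge is not None:
        cov = cov + ridge * np.eye(cov.shape[0])
    try:
        return linalg.cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        pass
    except linalg.LinAlgError:
        pass
    eigvals, eigvecs = np.linalg.eigh(cov)
    bad = np.flatnonzero(eigvals <= 1e-12 * max(eigvals.max(), 1.0))
    directions = [np.round(eigvecs[:, j], 3).tolist() for j in bad[:3]]
    raise SingularCovarianceError(
        f"covariance is singular along {bad.size} direction(s), e.g. "
        f"{directions}; rerun with a ridge (e.g. ridge=1e-8) or drop "
        f"zero-variance items"
    )


def mahalanobis(z, ref: ReferenceStats, *, ridge: float | None = None) -> float:
    """Squared Mahalanobis distance of ``z`` to the reference."""
    return float(mahalanobis_many(np.atleast_2d(z), ref, ridge=ridge)[0])


def mahalanobis_many(Z, ref: ReferenceStats, *, ridge: float | None = None) -> np.ndarray:
    """Row-wise squared Mahalanobis distances for an ``(n, d)`` array."""
    Z = np.asarray(Z, dtype=float)
    factor = _solve_covariance(ref.covariance, ridge)
    dev = Z - ref.mean
    sol = linalg.cho_solve(factor, dev.T)
    return np.einsum("ij,ji->i", dev, sol)


def person_total_correlation(z, ref: ReferenceStats) -> float:
    """Pearson correlation between ``z`` and the reference mean vector.

    Degenerate rows (zero variance in ``z`` or in the reference mean)
    return 0.0 — the no-information midpoint of ``[-1, 1]``.
    """
    value, _ = _person_total_many(np.atleast_2d(z), ref)
    return float(value[0])


def _person_total_many(Z, ref: ReferenceStats):
    Z = np.asarray(Z, dtype=float)
    m = ref.mean
    mc = m - m.mean()
    m_ss = float(mc @ mc)
    zc = Z - Z.mean(axis=1, keepdims=True)
    z_ss = np.einsum("ij,ij->i", zc, zc)
    degenerate = (z_ss <= 0) | (m_ss <= 0)
    if degenerate.any():
        logger.warning(
            "%d degenerate (constant) row(s) in person-total correlation; "
            "returning 0", int(degenerate.sum()),
        )
    denom = np.sqrt(np.where(degenerate, 1.0, z_ss * m_ss))
    r = np.where(degenerate, 0.0, zc @ mc / denom)
    return np.clip(r, -1.0, 1.0), degenerate


# ---------------------------------------------------------------------------
# Factor-model (FMT-style) indices.
#
# These follow the published contract — coherence in [0, 1], reliability
# in [-1, 1], both suspicion-decreasing, requiring an assumed number of
# dimensions and an iteration count — but the exact recurrences of the
# reference implementation are not reproduced here; this is a
# deterministic principal-axis stand-in and is NOT part of the default
# battery.

def _principal_axis_loadings(reference: ResponseMatrix, n_dimensions: int,
                             n_iterations: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = reference.values.astype(float)
    d = X.shape[1]
    if not (1 <= n_dimensions <= d):
        raise ValueError(f"n_dimensions must be in [1, {d}], got {n_dimensions}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be positive")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("reference sample has zero-variance items; cannot standardize")
    R = np.corrcoef(X, rowvar=False)
    comm = np.ones(d)
    loadings = None
    for _ in range(n_iterations):  # communality iteration
        Rh = R.copy()
        np.fill_diagonal(Rh, comm)
        eigvals, eigvecs = np.linalg.eigh(Rh)
        order = np.argsort(eigvals)[::-1][:n_dimensions]
        vals = np.clip(eigvals[order], 0.0, None)
        loadings = eigvecs[:, order] * np.sqrt(vals)
        comm = np.clip(np.sum(loadings**2, axis=1), 0.0, 1.0)
    return loadings, mean, sd


def _fmt_projections(Z, reference: ResponseMatrix, n_dimensions: int,
                     n_iterations: int):
    L, mean, sd = _principal_axis_loadings(reference, n_dimensions, n_iterations)
    U = (np.asarray(Z, dtype=float) - mean) / sd
    # regression factor scores, then model-implied responses
    gram = L.T @ L
    scores = np.linalg.solve(gram, L.T @ U.T).T
    fitted = scores @ L.T
    return U, fitted


def fmt_coherence(z, reference: ResponseMatrix, n_dimensions: int = 4,
                  n_iterations: int = 30) -> float:
    """Share of a respondent's standardized response variance captured by
    an ``n_dimensions``-factor model of the reference sample; in [0, 1],
    suspicion-decreasing."""
    U, fitted = _fmt_projections(np.atleast_2d(z), reference, n_dimensions, n_iterations)
    return float(_coherence_from_projections(U, fitted)[0])


def _coherence_from_projections(U, fitted):
    total = np.einsum("ij,ij->i", U, U)
    explained = np.einsum("ij,ij->i", fitted, fitted)
    out = np.where(total <= 0, 0.0, explained / np.where(total <= 0, 1.0, total))
    return np.clip(out, 0.0, 1.0)


def fmt_reliability(z, reference: ResponseMatrix, n_dimensions: int = 4,
                    n_iterations: int = 30) -> float:
    """Correlation between observed and model-implied standardized
    responses; in [-1, 1], suspicion-decreasing."""
    U, fitted = _fmt_projections(np.atleast_2d(z), reference, n_dimensions, n_iterations)
    return float(_reliability_from_projections(U, fitted)[0])


def _reliability_from_projections(U, fitted):
    uc = U - U.mean(axis=1, keepdims=True)
    fc = fitted - fitted.mean(axis=1, keepdims=True)
    u_ss = np.einsum("ij,ij->i", uc, uc)
    f_ss = np.einsum("ij,ij->i", fc, fc)
    degenerate = (u_ss <= 0) | (f_ss <= 0)
    denom = np.sqrt(np.where(degenerate, 1.0, u_ss * f_ss))
    r = np.where(degenerate, 0.0, np.einsum("ij,ij->i", uc, fc) / denom)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Index registry and featurization.

@dataclass(frozen=True)
class IndexSpec:
    name: str
    orientation: str
    compute: Callable  # (Z, ref, reference_rm, settings) -> (values, degenerate)


def _compute_mahalanobis(Z, ref, reference_rm, settings):
    vals = mahalanobis_many(Z, ref, ridge=settings.get("ridge"))
    return vals, np.zeros(Z.shape[0], dtype=bool)


def _compute_person_total(Z, ref, reference_rm, settings):
    return _person_total_many(Z, ref)


def _compute_fmt_coherence(Z, ref, reference_rm, settings):
    if reference_rm is None:
        raise ValueError("fmt indices need the raw reference response matrix")
    U, fitted = _fmt_projections(Z, reference_rm,
                                 settings.get("n_dimensions", 4),
                                 settings.get("n_iterations", 30))
    return _coherence_from_projections(U, fitted), np.zeros(Z.shape[0], dtype=bool)


def _compute_fmt_reliability(Z, ref, reference_rm, settings):
    if reference_rm is None:
        raise ValueError("fmt indices need the raw reference response matrix")
    U, fitted = _fmt_projections(Z, reference_rm,
                                 settings.get("n_dimensions", 4),
                                 settings.get("n_iterations", 30))
    return _reliability_from_projections(U, fitted), np.zeros(Z.shape[0], dtype=bool)


INDEX_REGISTRY: dict[str, IndexSpec] = {}


def register_index(name: str, orientation: str, compute: Callable) -> None:
    """Register a custom NRI; ``compute(Z, ref, reference_rm, settings)``
    must return ``(values, degenerate_mask)`` for an ``(n, d)`` input."""
    if orientation not in (ORIENT_INCREASING, ORIENT_DECREASING):
        raise ValueError(f"unknown orientation {orientation!r}")
    INDEX_REGISTRY[name] = IndexSpec(name, orientation, compute)


register_index("mahalanobis", ORIENT_INCREASING, _compute_mahalanobis)
register_index("person_total", ORIENT_DECREASING, _compute_person_total)
register_index("fmt_coherence", ORIENT_DECREASING, _compute_fmt_coherence)
register_index("fmt_reliability", ORIENT_DECREASING, _compute_fmt_reliability)

#: Indices used when no battery is configured.  The factor-model indices
#: are opt-in plugins; the pipeline is fully functional with these two.
DEFAULT_INDICES = ("mahalanobis", "person_total")


def featurize(rm: ResponseMatrix, ref: ReferenceStats,
              reference_rm: ResponseMatrix | None = None,
              indices=DEFAULT_INDICES,
              settings: dict | None = None) -> FeatureMatrix:
    """Apply each requested index to every row of ``rm``.

    Column order matches the requested index order; orientations are
    taken from the registry.
    """
    if rm.has_missing:
        raise ValueError("impute missing responses before featurizing")
    settings = dict(settings or {})
    names = tuple(indices)
    if not names:
        raise ValueError("at least one index is required")
    unknown = [n for n in names if n not in INDEX_REGISTRY]
    if unknown:
        raise KeyError(f"unknown index name(s): {unknown}; "
                       f"registered: {sorted(INDEX_REGISTRY)}")
    Z = rm.values.astype(float)
    cols, orients = [], []
    degenerate = np.zeros(Z.shape[0], dtype=bool)
    for name in names:
        spec = INDEX_REGISTRY[name]
        vals, degen = spec.compute(Z, ref, reference_rm, settings)
        cols.append(np.asarray(vals, dtype=float))
        orients.append(spec.orientation)
        degenerate |= np.asarray(degen, dtype=bool)
    return FeatureMatrix(values=np.column_stack(cols), index_names=names,
                         orientations=tuple(orients), degenerate_mask=degenerate)


def to_suspicion_increasing(fm: FeatureMatrix) -> FeatureMatrix:
    """Negate suspicion-decreasing columns so every column is increasing."""
    values = fm.values.copy()
    for j, orient in enumerate(fm.orientations):
        if orient == ORIENT_DECREASING:
            values[:, j] = -values[:, j]
    return replace(fm, values=values,
                   orientations=(ORIENT_INCREASING,) * fm.n_features)
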