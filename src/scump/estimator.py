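"""The SCUMP estimator: supervised class densities, unsupervised mixing
proportion, Bayes prediction.

Stage 1 fits per-class Gaussian feature distributions on the labeled,
stratified calibration sample (means and MLE covariances, divisor
``n_class``).  Stage 2 treats those densities as known and estimates the
target sample's contamination rate ``lambda`` by maximizing the mixture
log-likelihood

    l(lambda) = sum_i log(lambda * phi1_i + (1 - lambda) * phi0_i)

over [0, 1].  The score (first derivative) is monotone decreasing
because the second derivative is a sum of non-positive terms, so the
maximizer is either a root of the score found by bisection or the
endpoint whose score sign points at it.  All densities are evaluated in
log space and the score from per-row density ratios; raw densities
underflow for realistic feature dimensions and far outliers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .metrics_theory import ClassificationReport, confusion_metrics
from .nri import (
    DEFAULT_INDICES,
    FeatureMatrix,
    SingularCovarianceError,
    _solve_covariance,
    featurize,
    reference_from_humans,
)
from .response_data import LabeledSample, ResponseMatrix, impute_middle

_RATIO_FLOOR = 1e-300
_RATIO_CEIL = 1e300


class ImpossibleObservationError(ValueError):
    """A target row has (numerically) zero density under both classes.

    This indicates density underflow not handled upstream or a feature
    point wildly outside both fitted classes; inspect the row rather
    than silently clipping it.
    """


@dataclass(frozen=True)
class GaussianClassParams:
    """Per-class Gaussian feature parameters (MLE, divisor n_class)."""

    mean0: np.ndarray
    cov0: np.ndarray
    mean1: np.ndarray
    cov1: np.ndarray
    n0: int
    n1: int

    def __post_init__(self) -> None:
        for name in ("mean0", "mean1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("cov0", "cov1"):
            cov = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be symmetric")
            object.__setattr__(self, name, cov)
        if self.mean0.shape != self.mean1.shape:
            raise ValueError("class means must have equal dimension")

    @property
    def n_features(self) -> int:
        return self.mean0.size

    def swapped(self) -> "GaussianClassParams":
        """Exchange the roles of the two classes."""
        return GaussianClassParams(mean0=self.mean1, cov0=self.cov1,
                                   mean1=self.mean0, cov1=self.cov0,
                                   n0=self.n1, n1=self.n0)


@dataclass(frozen=True)
class GaussianMixtureFit:
    """Fitted mixture: class parameters plus the estimated mixing
    proportion and convergence bookkeeping."""

    params: GaussianClassParams
    lambda_hat: float
    loglik_at_max: float
    iterations: int = 0
    bracket: tuple[float, float] = (0.0, 1.0)
    tol: float = 1e-8
    at_endpoint: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_hat <= 1.0:
            raise ValueError("lambda_hat must lie in [0, 1]")


def _feature_values(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.atleast_2d(np.asarray(features, dtype=float))


def estimate_class_params(cal_features, labels, *,
                          ridge: float | None = None) -> GaussianClassParams:
    """Per-class mean and MLE covariance (divisor ``n_class``) of the
    calibration features."""
    X = _feature_values(cal_features)
    labels = np.asarray(labels).astype(np.int64)
    if labels.shape != (X.shape[0],):
        raise ValueError("labels must have one entry per feature row")
    J = X.shape[1]
    out = {}
    for k in (0, 1):
        Xk = X[labels == k]
        nk = Xk.shape[0]
        if nk == 0:
            raise ValueError(f"class {k} is absent from the calibration sample")
        if nk < J + 1 and ridge is None:
            raise ValueError(
                f"class {k} has {nk} rows for {J} features; covariance is "
                f"singular — supply more rows or a ridge"
            )
        mean = Xk.mean(axis=0)
        dev = Xk - mean
        cov = dev.T @ dev / nk
        if ridge is not None:
            # an explicit ridge (even 0.0) waives the definiteness check;
            # the printed MLE is returned as-is and any singularity
            # surfaces at density evaluation
            cov = cov + ridge * np.eye(J)
        else:
            _solve_covariance(cov, None)  # raises SingularCovarianceError
        out[k] = (mean, cov, nk)
    return GaussianClassParams(mean0=out[0][0], cov0=out[0][1],
                               mean1=out[1][0], cov1=out[1][1],
                               n0=out[0][2], n1=out[1][2])


def _log_mvn_density(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise multivariate normal log-density via Cholesky."""
    factor = _solve_covariance(cov, None)
    L = factor[0]
    dev = X - mean
    sol = linalg.solve_triangular(L, dev.T, lower=True)
    quad = np.einsum("ji,ji->i", sol, sol)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = mean.size
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + quad)


def class_log_densities(features, params: GaussianClassParams):
    """``(logphi1, logphi0)`` for every feature row."""
    X = _feature_values(features)
    if X.shape[1] != params.n_features:
        raise ValueError("feature dimension does not match fitted parameters")
    logphi1 = _log_mvn_density(X, params.mean1, params.cov1)
    logphi0 = _log_mvn_density(X, params.mean0, params.cov0)
    return logphi1, logphi0


def _density_ratios(logphi1: np.ndarray, logphi0: np.ndarray) -> np.ndarray:
    """Per-row ratios phi1/phi0, clipped to avoid overflow either way."""
    with np.errstate(over="ignore"):
        r = np.exp(logphi1 - logphi0)
    return np.clip(r, _RATIO_FLOOR, _RATIO_CEIL)


def _score_from_ratios(lam: float, r: np.ndarray) -> float:
    # (phi1 - phi0)/(lam*phi1 + (1-lam)*phi0) == (r - 1)/(lam*r + 1 - lam)
    return float(np.sum((r - 1.0) / (lam * r + (1.0 - lam))))


def mixture_score(lam: float, dens1, dens0) -> float:
    """First derivative of the mixture log-likelihood in ``lambda``,
    evaluated from per-observation class densities.

    Accepts raw densities; rows with both densities zero raise
    :class:`ImpossibleObservationError`.
    """
    dens1 = np.asarray(dens1, dtype=float)
    dens0 = np.asarray(dens0, dtype=float)
    if dens1.shape != dens0.shape:
        raise ValueError("density vectors must have equal length")
    if not (np.isfinite(dens1).all() and np.isfinite(dens0).all()):
        raise ValueError("densities must be finite")
    if (dens1 < 0).any() or (dens0 < 0).any():
        raise ValueError("densities must be non-negative")
    both_zero = (dens1 == 0) & (dens0 == 0)
    if both_zero.any():
        raise ImpossibleObservationError(
            f"{int(both_zero.sum())} observation(s) have zero density under "
            f"both classes (rows {np.flatnonzero(both_zero)[:5].tolist()}); "
            f"check for underflow or out-of-model feature points"
        )
    with np.errstate(divide="ignore"):
        r = _density_ratios(np.log(dens1), np.log(dens0))
    return _score_from_ratios(lam, r)


def mixture_loglik(lam: float, logphi1: np.ndarray, logphi0: np.ndarray) -> float:
    """Mixture log-likelihood at ``lam``, stable in log space."""
    if lam <= 0.0:
        return float(np.sum(logphi0))
    if lam >= 1.0:
        return float(np.sum(logphi1))
    return float(np.sum(np.logaddexp(np.log(lam) + logphi1,
                                     np.log1p(-lam) + logphi0)))


def estimate_lambda(target_features, params: GaussianClassParams, *,
                    tol: float = 1e-8, max_iter: int = 200) -> GaussianMixtureFit:
    """Maximum-likelihood contamination rate on [0, 1].

    The log-likelihood is concave, so: if the score at both endpoints
    shares a sign, the likelihood-maximizing endpoint is returned
    (``score(0) <= 0`` gives 0, ``score(1) >= 0`` gives 1); otherwise
    the unique root of the score is found by bisection to ``tol``.
    """
    logphi1, logphi0 = class_log_densities(target_features, params)
    if not (np.isfinite(logphi1).all() and np.isfinite(logphi0).all()):
        raise ImpossibleObservationError(
            "non-finite log-densities on the target sample"
        )
    r = _density_ratios(logphi1, logphi0)

    score0 = _score_from_ratios(0.0, r)
    score1 = _score_from_ratios(1.0, r)
    iterations = 0
    bracket = (0.0, 1.0)
    at_endpoint = False
    if score0 <= 0.0:
        lam_hat = 0.0
        at_endpoint = True
    elif score1 >= 0.0:
        lam_hat = 1.0
        at_endpoint = True
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol and iterations < max_iter:
            mid = 0.5 * (lo + hi)
            if _score_from_ratios(mid, r) > 0.0:
                lo = mid
            else:
                hi = mid
            iterations += 1
        bracket = (lo, hi)
        lam_hat = 0.5 * (lo + hi)
    return GaussianMixtureFit(
        params=params,
        lambda_hat=lam_hat,
        loglik_at_max=mixture_loglik(lam_hat, logphi1, logphi0),
        iterations=iterations,
        bracket=bracket,
        tol=tol,
        at_endpoint=at_endpoint,
        extra={"score_at_0": score0, "score_at_1": score1},
    )


def bayes_classify(target_features, fit: GaussianMixtureFit) -> ClassificationReport:
    """Flag row ``i`` iff ``lambda_hat * phi1_i > (1 - lambda_hat) * phi0_i``
    (strict; ties are spared), evaluated in log space.

    The report carries the composite score ``v_i = lambda_hat * phi1_i -
    (1 - lambda_hat) * phi0_i`` with threshold 0 and the posterior
    probability of the bot class, which is the suspicion-increasing
    score used for ROC/AUC.
    """
    logphi1, logphi0 = class_log_densities(target_features, fit.params)
    lam = fit.lambda_hat
    with np.errstate(divide="ignore"):
        log_w1 = (np.log(lam) if lam > 0 else -np.inf) + logphi1
        log_w0 = (np.log1p(-lam) if lam < 1 else -np.inf) + logphi0
    predicted = (log_w1 > log_w0).astype(np.int64)
    # composite on the raw density scale, for the tau = 0 threshold form
    with np.errstate(over="ignore", under="ignore"):
        composite = np.exp(log_w1) - np.exp(log_w0)
    # posterior of class 1; monotone in log_w1 - log_w0
    with np.errstate(over="ignore"):
        posterior = 1.0 / (1.0 + np.exp(np.clip(log_w0 - log_w1, -745.0, 745.0)))
    return ClassificationReport(
        predicted=predicted,
        scores=posterior,
        threshold=0.0,
        posterior=posterior,
        extra={"lambda_hat": lam, "composite": composite.tolist()},
    )


@dataclass(frozen=True)
class PipelineResult:
    report: ClassificationReport
    fit: GaussianMixtureFit
    calibration_features: FeatureMatrix
    target_features: FeatureMatrix


def scump_pipeline(cal: LabeledSample, target: ResponseMatrix, *,
                   indices=DEFAULT_INDICES, settings: dict | None = None,
                   ridge: float | None = None, tol: float = 1e-8,
                   truth=None) -> PipelineResult:
    """End-to-end SCUMP run.

    Imputes, builds the human reference from the calibration sample,
    featurizes both samples, fits the class densities supervised and the
    mixing proportion unsupervised on the target, then applies the Bayes
    rule.  Every prediction depends on the whole target sample through
    ``lambda_hat``.  Optional ``truth`` labels add confusion metrics and
    AUC to the report.
    """
    cal_imputed = LabeledSample(responses=impute_middle(cal.responses),
                                labels=cal.labels)
    target_imputed = impute_middle(target)
    ref = reference_from_humans(cal_imputed)
    reference_rm = cal_imputed.humans()
    settings = dict(settings or {})
    if ridge is not None:
        settings.setdefault("ridge", ridge)
    cal_fm = featurize(cal_imputed.responses, ref, reference_rm,
                       indices=indices, settings=settings)
    target_fm = featurize(target_imputed, ref, reference_rm,
                          indices=indices, settings=settings)
    params = estimate_class_params(cal_fm, cal_imputed.labels, ridge=ridge)
    fit = estimate_lambda(target_fm, params, tol=tol)
    report = bayes_classify(target_fm, fit)
    if truth is not None:
        scored = confusion_metrics(truth, report.predicted,
                                   scores=report.scores, threshold=0.0)
        report = ClassificationReport(
            predicted=scored.predicted, scores=scored.scores,
            threshold=0.0, posterior=report.posterior,
            tp=scored.tp, fp=scored.fp, tn=scored.tn, fn=scored.fn,
            auc=scored.auc, extra=report.extra)
    return PipelineResult(report=report, fit=fit,
                          calibration_features=cal_fm, target_features=target_fm)


# ---------------------------------------------------------------------------
# Model serialization.

MODEL_SCHEMA_VERSION = 1


def calibration_provenance_hash(cal: LabeledSample) -> str:
    h = hashlib.sha256()
    h.update(cal.responses.values.tobytes())
    h.update(cal.labels.tobytes())
    return h.hexdigest()[:16]


def model_to_dict(params: GaussianClassParams, *, indices, settings=None,
                  reference=None, provenance: str | None = None) -> dict:
    out = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "indices": list(indices),
        "settings": dict(settings or {}),
        "provenance": provenance,
        "params": {
            "mean0": params.mean0.tolist(), "cov0": params.cov0.tolist(),
            "mean1": params.mean1.tolist(), "cov1": params.cov1.tolist(),
            "n0": params.n0, "n1": params.n1,
        },
    }
    if reference is not None:
        out["reference"] = {
            "mean": reference.mean.tolist(),
            "covariance": reference.covariance.tolist(),
            "source_n": reference.source_n,
        }
    return out


def save_model(path, **kwargs) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(**kwargs), fh, indent=2)


def load_model(path):
    """Load a serialized model; returns ``(params, reference, meta)``."""
    from .nri import ReferenceStats

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    p = doc["params"]
    params = GaussianClassParams(
        mean0=np.array(p["mean0"]), cov0=np.array(p["cov0"]),
        mean1=np.array(p["mean1"]), cov1=np.array(p["cov1"]),
        n0=int(p["n0"]), n1=int(p["n1"]))
    reference = None
    if "reference" in doc:
        r = doc["reference"]
        reference = ReferenceStats(mean=np.array(r["mean"]),
                                   covariance=np.array(r["covariance"]),
                                   source_n=int(r["source_n"]))
    meta = {k: doc[k] for k in ("indices", "settings", "provenance")}
    return params, reference, meta
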