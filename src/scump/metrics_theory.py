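"""Confusion metrics, AUC, and the closed-form two-normal theory.

The two-normal model describes a single suspicion-increasing index whose
human and bot class distributions are both normal.  Its closed forms
give the specificity/sensitivity/accuracy of any specificity-calibrated
cutoff, the ROC area, and the accuracy-maximizing cutoff at a given
contamination rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Two-normal parameters for the worked single-index example, with the
#: human class standardized to N(0, 1).  The bot parameters were
#: back-solved by grid search (see ``scripts/solve_two_normal.py``)
#: against the published accuracy table and ROC area.
TWO_NORMAL_EXAMPLE_PARAMS = {
    "human_mean": 0.0,
    "human_sd": 1.0,
    "bot_mean": 2.5,
    "bot_sd": 1.0,
}


@dataclass(frozen=True)
class ClassificationReport:
    """Predictions plus (when truth is known) confusion counts and rates.

    ``scores`` are suspicion-increasing composites; ``threshold`` is the
    decision threshold on that composite.  Rates for an absent class are
    ``None`` rather than NaN.
    """

    predicted: np.ndarray
    scores: np.ndarray | None = None
    threshold: float | None = None
    posterior: np.ndarray | None = field(default=None, repr=False)
    tp: int | None = None
    fp: int | None = None
    tn: int | None = None
    fn: int | None = None
    auc: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        predicted = np.asarray(self.predicted).astype(np.int64)
        if predicted.ndim != 1:
            raise ValueError("predicted labels must be a vector")
        if not np.isin(predicted, (0, 1)).all():
            raise ValueError("predicted labels must be binary 0/1")
        object.__setattr__(self, "predicted", predicted)

    @property
    def n(self) -> int:
        return self.predicted.size

    @property
    def has_truth(self) -> bool:
        return self.tp is not None

    @property
    def flag_rate(self) -> float:
        return float(self.predicted.mean())

    @property
    def accuracy(self) -> float | None:
        if not self.has_truth:
            return None
        return (self.tp + self.tn) / self.n

    @property
    def specificity(self) -> float | None:
        if not self.has_truth or (self.tn + self.fp) == 0:
            return None
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity(self) -> float | None:
        if not self.has_truth or (self.tp + self.fn) == 0:
            return None
        return self.tp / (self.tp + self.fn)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "flag_rate": self.flag_rate,
            "threshold": self.threshold,
            "predicted": self.predicted.tolist(),
        }
        if self.scores is not None:
            out["scores"] = np.asarray(self.scores, dtype=float).tolist()
        if self.has_truth:
            out.update(tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn,
                       accuracy=self.accuracy, specificity=self.specificity,
                       sensitivity=self.sensitivity, auc=self.auc)
        out.update(self.extra)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_metrics(truth, predicted, *, scores=None,
                      threshold: float | None = None) -> ClassificationReport:
    """Exact confusion counts and rates from true and predicted labels."""
    truth = np.asarray(truth).astype(np.int64)
    predicted = np.asarray(predicted).astype(np.int64)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("truth and predicted must be equal-length vectors")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth labels must be binary 0/1")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    auc = None
    if scores is not None and 0 < truth.sum() < truth.size:
        auc = empirical_auc(scores, truth)
    return ClassificationReport(predicted=predicted, scores=scores,
                                threshold=threshold, tp=tp, fp=fp, tn=tn,
                                fn=fn, auc=auc)


def report_from_counts(tp: int, fn: int, fp: int, tn: int) -> ClassificationReport:
    """Build a report directly from a printed 2x2 confusion table."""
    truth = np.concatenate([np.ones(tp + fn, dtype=int), np.zeros(fp + tn, dtype=int)])
    predicted = np.concatenate([
        np.ones(tp, dtype=int), np.zeros(fn, dtype=int),
        np.ones(fp, dtype=int), np.zeros(tn, dtype=int),
    ])
    return confusion_metrics(truth, predicted)


def weighted_accuracy(lam: float, sensitivity: float, specificity: float) -> float:
    """Accuracy as the contamination-weighted mean of sensitivity and
    specificity: ``lam * sensitivity + (1 - lam) * specificity``."""
    for name, val in (("lam", lam), ("sensitivity", sensitivity),
                      ("specificity", specificity)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    return lam * sensitivity + (1.0 - lam) * specificity


def empirical_auc(scores, truth) -> float:
    """Probability a random class-1 score exceeds a random class-0 score,
    ties counted 1/2 (rank-sum formulation).  Scores must be
    suspicion-increasing."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(np.int64)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length vectors")
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class TwoNormalNRI:
    """A single suspicion-increasing index with normal class densities."""

    human_mean: float = TWO_NORMAL_EXAMPLE_PARAMS["human_mean"]
    human_sd: float = TWO_NORMAL_EXAMPLE_PARAMS["human_sd"]
    bot_mean: float = TWO_NORMAL_EXAMPLE_PARAMS["bot_mean"]
    bot_sd: float = TWO_NORMAL_EXAMPLE_PARAMS["bot_sd"]
    contamination: float = 0.5

    def __post_init__(self) -> None:
        if self.human_sd <= 0 or self.bot_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0, 1]")


def two_normal_operating_point(model: TwoNormalNRI,
                               specificity: float) -> tuple[float, float, float]:
    """Cutoff, sensitivity, and accuracy of a specificity-calibrated
    cutoff under the two-normal model.

    The cutoff is placed at the requested human-class quantile; the
    implied sensitivity is the bot-class upper tail beyond it; accuracy
    is the contamination-weighted mean of the two rates.
    """
    if not 0.0 < specificity < 1.0:
        raise ValueError("specificity must be in (0, 1)")
    cutoff = model.human_mean + model.human_sd * stats.norm.ppf(specificity)
    sensitivity = 1.0 - stats.norm.cdf((cutoff - model.bot_mean) / model.bot_sd)
    accuracy = weighted_accuracy(model.contamination, sensitivity, specificity)
    return float(cutoff), float(sensitivity), float(accuracy)


def two_normal_auc(model: TwoNormalNRI) -> float:
    """Closed-form ROC area: ``Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2))``."""
    delta = model.bot_mean - model.human_mean
    scale = math.hypot(model.human_sd, model.bot_sd)
    return float(stats.norm.cdf(delta / scale))


def two_normal_optimal_cutoff(model: TwoNormalNRI) -> float:
    """Accuracy-maximizing cutoff: where the contamination-weighted
    class densities cross, on the between-means branch."""
    lam = model.contamination
    if not 0.0 < lam < 1.0:
        raise ValueError("optimal cutoff needs contamination strictly in (0, 1)")
    mu0, s0 = model.human_mean, model.human_sd
    mu1, s1 = model.bot_mean, model.bot_sd
    if math.isclose(s0, s1):
        if math.isclose(mu0, mu1):
            raise ValueError("identical class densities: no crossing exists")
        # log lam * f1(c) = log (1-lam) * f0(c) with equal sds is linear in c
        s2 = s0 * s0
        return float((mu0 + mu1) / 2.0 + s2 * math.log((1 - lam) / lam) / (mu1 - mu0))

    def log_ratio(c: float) -> float:
        return (math.log(lam) + stats.norm.logpdf(c, mu1, s1)
                - math.log1p(-lam) - stats.norm.logpdf(c, mu0, s0))

    from scipy.optimize import brentq

    lo, hi = sorted((mu0, mu1))
    span = hi - lo if hi > lo else max(s0, s1)
    a, b = lo, hi
    fa, fb = log_ratio(a), log_ratio(b)
    # widen until the weighted densities bracket a crossing
    for _ in range(60):
        if fa * fb <= 0:
            break
        a -= 0.5 * span
        b += 0.5 * span
        fa, fb = log_ratio(a), log_ratio(b)
    else:
        raise ValueError("no density crossing found in a bracketable range")
    return float(brentq(log_ratio, a, b, xtol=1e-12))


def two_normal_accuracy_at_cutoff(model: TwoNormalNRI, cutoff: float) -> float:
    """Accuracy of flagging above ``cutoff`` under the two-normal model."""
    specificity = float(stats.norm.cdf((cutoff - model.human_mean) / model.human_sd))
    sensitivity = 1.0 - float(stats.norm.cdf((cutoff - model.bot_mean) / model.bot_sd))
    return weighted_accuracy(model.contamination, sensitivity, specificity)


#: Row/column layout of the published accuracy table for the example model.
TABLE1_CONTAMINATION_ROWS = (0.05, 0.25, 0.50, 0.75, 0.95)
TABLE1_SPECIFICITY_COLS = (0.85, 0.90, 0.95, 0.99)


def theory_accuracy_table(model: TwoNormalNRI | None = None,
                          contaminations=TABLE1_CONTAMINATION_ROWS,
                          specificities=TABLE1_SPECIFICITY_COLS) -> np.ndarray:
    """Accuracy (percent, one decimal, round-half-even) of each
    specificity cutoff at each contamination rate."""
    if model is None:
        model = TwoNormalNRI()
    from dataclasses import replace as _replace

    out = np.empty((len(contaminations), len(specificities)))
    for i, lam in enumerate(contaminations):
        m = _replace(model, contamination=lam)
        for j, spec in enumerate(specificities):
            _, _, acc = two_normal_operating_point(m, spec)
            out[i, j] = np.round(100.0 * acc, 1)
    return out


def format_accuracy_table(table: np.ndarray,
                          contaminations=TABLE1_CONTAMINATION_ROWS,
                          specificities=TABLE1_SPECIFICITY_COLS) -> str:
    header = "Contamination (%)  " + "  ".join(
        f"{100 * s:.0f}% spec" for s in specificities)
    lines = [header]
    for lam, row in zip(contaminations, table):
        cells = "  ".join(f"{v:8.1f}" for v in row)
        lines.append(f"{100 * lam:17.0f}  {cells}")
    return "\n".join(lines)
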