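"""Synthetic data generators and the Monte Carlo replicate engine.

Bots draw every response i.i.d. from a programmed category distribution
(uniform, or a middle-preferring alternative).  Humans come either from
a multidimensional graded response model — a download-free stand-in
with a multi-factor correlational structure — or by resampling rows of
a user-supplied response matrix.

The replicate engine rebuilds, per replicate, a stratified calibration
sample (``n0tr`` humans plus an arbitrarily large bot sample from the
assumed bot distribution) and a target sample with exact class counts,
then featurizes, classifies, and scores.  A full factorial design is a
grid over calibration sizes, target sizes, contamination rates, bot
models, and classifiers, with per-cell RNG streams derived from the
base seed and the cell coordinates so any cell reproduces independently.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .baselines import fit_predict_mahalanobis_cutoff, fit_univariate_union, predict_univariate_union
from .estimator import bayes_classify, estimate_class_params, estimate_lambda
from .metrics_theory import confusion_metrics
from .nri import (
    DEFAULT_INDICES,
    SingularCovarianceError,
    featurize,
    reference_from_humans,
    to_suspicion_increasing,
)

from .response_data import LabeledSample, ResponseMatrix, impute_middle

logger = logging.getLogger(__name__)

#: Middle-preferring bot category distribution on a 5-point scale.
MIDDLE_PMF_5 = (0.1, 0.2, 0.4, 0.2, 0.1)

#: Default size of the generated calibration bot sample.
DEFAULT_N1TR = 2000

CLASSIFIERS = ("scump", "mahalanobis", "union", "oracle")


@dataclass(frozen=True)
class BotModel:
    """A named pmf over the ``K`` response categories."""

    name: str
    pmf: tuple[float, ...]

    def __post_init__(self) -> None:
        pmf = tuple(float(p) for p in self.pmf)
        if any(p < 0 for p in pmf):
            raise ValueError("pmf entries must be non-negative")
        if abs(sum(pmf) - 1.0) > 1e-12:
            raise ValueError(f"pmf must sum to 1, got {sum(pmf)!r}")
        object.__setattr__(self, "pmf", pmf)

    @property
    def n_categories(self) -> int:
        return len(self.pmf)


def uniform_bot(n_categories: int = 5) -> BotModel:
    return BotModel("uniform", (1.0 / n_categories,) * n_categories)


def middle_bot() -> BotModel:
    return BotModel("middle", MIDDLE_PMF_5)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_bots(model: BotModel, n: int, d: int, seed,
                  categories: tuple[int, int] = (1, 5)) -> ResponseMatrix:
    """``n`` rows of ``d`` i.i.d. categorical draws from the bot pmf."""
    if n < 1:
        raise ValueError("need n >= 1 bots")
    low, high = categories
    if model.n_categories != high - low + 1:
        raise ValueError(
            f"pmf length {model.n_categories} does not match {high - low + 1} "
            f"categories")
    rng = _as_rng(seed)
    values = rng.choice(np.arange(low, high + 1), size=(n, d), p=model.pmf)
    return ResponseMatrix(values=values, categories=categories)


@dataclass(frozen=True)
class GRMParams:
    """Simple-structure multidimensional graded response model.

    Item ``j`` loads on factor ``factor_of[j]`` with discrimination
    ``discriminations[j]``; ``thresholds[j]`` are its ``K - 1`` strictly
    increasing category boundaries.  Latent traits are jointly normal
    with the given factor correlation matrix.
    """

    discriminations: np.ndarray
    thresholds: np.ndarray  # (d, K-1)
    factor_of: np.ndarray
    factor_corr: np.ndarray
    categories: tuple[int, int] = (1, 5)
    #: Per-person trait-magnitude range (uniform draw); widths > 0 make
    #: the population heterogeneous the way real samples are.
    trait_scale_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.discriminations, dtype=float)
        b = np.asarray(self.thresholds, dtype=float)
        f = np.asarray(self.factor_of, dtype=np.int64)
        R = np.asarray(self.factor_corr, dtype=float)
        d = a.size
        low, high = self.categories
        if b.shape != (d, high - low):
            raise ValueError("thresholds must be (d, K-1)")
        if not np.all(np.diff(b, axis=1) > 0):
            raise ValueError("item thresholds must be strictly increasing")
        if f.shape != (d,) or f.min() < 0 or f.max() >= R.shape[0]:
            raise ValueError("factor_of must index into the factor set")
        if not np.allclose(R, R.T):
            raise ValueError("factor correlation matrix must be symmetric")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("factor correlation matrix must be positive definite")
        lo_s, hi_s = self.trait_scale_range
        if not (0 < lo_s <= hi_s):
            raise ValueError("trait_scale_range must satisfy 0 < low <= high")
        for name, arr in (("discriminations", a), ("thresholds", b),
                          ("factor_of", f), ("factor_corr", R)):
            object.__setattr__(self, name, arr)

    @property
    def n_items(self) -> int:
        return self.discriminations.size

    @property
    def n_factors(self) -> int:
        return self.factor_corr.shape[0]


@dataclass(frozen=True)
class HumanModel:
    """Human response generator: ``grm`` simulation or ``resample``
    with replacement from a source matrix."""

    variant: str
    grm: GRMParams | None = None
    source: ResponseMatrix | None = None

    def __post_init__(self) -> None:
        if self.variant == "grm":
            if self.grm is None:
                raise ValueError("grm variant requires GRMParams")
        elif self.variant == "resample":
            if self.source is None:
                raise ValueError("resample variant requires a source matrix")
        else:
            raise ValueError(f"unknown human model variant {self.variant!r}")

    @property
    def n_items(self) -> int:
        return self.grm.n_items if self.variant == "grm" else self.source.n_items

    @property
    def categories(self) -> tuple[int, int]:
        return self.grm.categories if self.variant == "grm" else self.source.categories


def default_grm_params(n_items: int = 32, n_factors: int = 4,
                       factor_r: float = 0.3, n_categories: int = 5,
                       trait_scale_range: tuple[float, float] = (1.0, 1.0),
                       seed: int = 20220730) -> GRMParams:
    """Deterministic default human population: ``n_items`` items split
    evenly over ``n_factors`` correlated factors (r = ``factor_r``),
    discriminations U(1.5, 2.5), and item thresholds built from an
    item-specific location shift N(0, 2.5) plus sorted N(0, 1) draws, so
    item means vary across the scale the way they do on real
    instruments (many items skewed toward an end category).  Items are
    re-drawn until no single category carries more than 92% of an
    item's marginal mass, so no item can be constant in a few-hundred-row
    human sample.  These parameters are this package's non-canonical
    stand-in for a real calibration instrument.
    """
    if n_items % n_factors:
        raise ValueError("n_items must be divisible by n_factors")
    rng = np.random.default_rng(seed)
    a = rng.uniform(1.5, 2.5, size=n_items)
    loc = 2.5 * rng.standard_normal((n_items, 1))
    b = loc + np.sort(rng.standard_normal((n_items, n_categories - 1)), axis=1)

    def _bad_items(b: np.ndarray) -> np.ndarray:
        # strictly increasing thresholds and a 92% cap on the largest
        # marginal category probability (Gauss-Hermite over theta)
        bad = ~np.all(np.diff(b, axis=1) > 1e-6, axis=1)
        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        weights = weights / weights.sum()
        eta = a[:, None] * nodes[None, :]  # (d, q)
        p_ge = expit(eta[:, None, :] - b[:, :, None])  # (d, K-1, q)
        probs = np.concatenate([
            1.0 - p_ge[:, :1, :],
            p_ge[:, :-1, :] - p_ge[:, 1:, :],
            p_ge[:, -1:, :],
        ], axis=1) @ weights
        return bad | (probs.max(axis=1) > 0.92)

    bad = _bad_items(b)
    while bad.any():
        k = int(bad.sum())
        loc[bad] = 2.5 * rng.standard_normal((k, 1))
        b[bad] = loc[bad] + np.sort(rng.standard_normal((k, n_categories - 1)), axis=1)
        bad = _bad_items(b)
    factor_of = np.repeat(np.arange(n_factors), n_items // n_factors)
    R = np.full((n_factors, n_factors), factor_r)
    np.fill_diagonal(R, 1.0)
    return GRMParams(discriminations=a, thresholds=b, factor_of=factor_of,
                     factor_corr=R, categories=(1, n_categories),
                     trait_scale_range=trait_scale_range)


def default_human_model(**kwargs) -> HumanModel:
    return HumanModel(variant="grm", grm=default_grm_params(**kwargs))


def generate_humans(model: HumanModel, n: int, seed) -> ResponseMatrix:
    """``n`` human rows from the model."""
    if n < 1:
        raise ValueError("need n >= 1 humans")
    rng = _as_rng(seed)
    if model.variant == "resample":
        idx = rng.integers(0, model.source.n_respondents, size=n)
        return model.source.take_rows(idx)
    grm = model.grm
    chol = np.linalg.cholesky(grm.factor_corr)
    theta = rng.standard_normal((n, grm.n_factors)) @ chol.T
    lo_s, hi_s = grm.trait_scale_range
    if hi_s > lo_s:
        theta = theta * rng.uniform(lo_s, hi_s, size=(n, 1))
    elif lo_s != 1.0:
        theta = theta * lo_s
    eta = grm.discriminations * theta[:, grm.factor_of]  # (n, d)
    # graded-response link: P(response >= k+1) = logistic(a*theta - b_k)
    p_ge = expit(eta[:, :, None] - grm.thresholds[None, :, :])  # (n, d, K-1)
    u = rng.random((n, grm.n_items))
    low, _ = grm.categories
    values = low + (u[:, :, None] < p_ge).sum(axis=2)
    return ResponseMatrix(values=values, categories=grm.categories)


# ---------------------------------------------------------------------------
# Replicates and designs.

@dataclass(frozen=True)
class SimulationDesign:
    """Fully crossed factorial over the five study factors."""

    calibration_sizes: tuple[int, ...]
    target_sizes: tuple[int, ...]
    contaminations: tuple[float, ...]
    bot_models: tuple[BotModel, ...]
    classifiers: tuple[str, ...]
    replicates: int = 1000
    base_seed: int = 0
    n1tr: int = DEFAULT_N1TR

    def __post_init__(self) -> None:
        for name in ("calibration_sizes", "target_sizes", "contaminations",
                     "bot_models", "classifiers"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}; choose from {CLASSIFIERS}")

    @property
    def n_cells(self) -> int:
        return (len(self.calibration_sizes) * len(self.target_sizes)
                * len(self.contaminations) * len(self.bot_models)
                * len(self.classifiers))

    def cells(self):
        return itertools.product(self.calibration_sizes, self.target_sizes,
                                 self.contaminations, self.bot_models,
                                 self.classifiers)


@dataclass(frozen=True)
class CellResult:
    """Monte Carlo means of the outcome measures for one design cell."""

    n0tr: int
    n: int
    contamination: float
    bot_model: str
    classifier: str
    replicates: int
    accuracy: float
    specificity: float | None
    sensitivity: float | None
    flag_rate: float
    auc: float | None
    lambda_hat_mean: float | None = None
    extra: dict = field(default_factory=dict)


def replicate_seed(base_seed: int, *coords) -> np.random.SeedSequence:
    """Stable, order-sensitive stream key for one replicate of one cell."""
    digest = hashlib.sha256(repr(coords).encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.SeedSequence([base_seed, key])


def run_replicate(*, n0tr: int, n: int, contamination: float,
                  human_model: HumanModel, bot_model: BotModel,
                  classifier: str, seed,
                  n1tr: int = DEFAULT_N1TR,
                  calibration_bot_model: BotModel | None = None,
                  indices=DEFAULT_INDICES, settings: dict | None = None,
                  nominal_specificity: float = 0.99,
                  ridge: float | None = None, tol: float = 1e-8) -> dict:
    """One simulation replicate; returns the outcome measures.

    The target has exactly ``round(n * contamination)`` bots (fixed class
    counts, not a mixture draw).  The calibration sample has ``n0tr``
    humans and ``n1tr`` bots from ``calibration_bot_model`` (uniform by
    default) regardless of the true target bot model, so misspecification
    is expressed by choosing a different target ``bot_model``.
    """
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    rng = _as_rng(seed)
    d = human_model.n_items
    categories = human_model.categories
    if calibration_bot_model is None:
        calibration_bot_model = uniform_bot(categories[1] - categories[0] + 1)

    n1 = int(round(n * contamination))
    n0 = n - n1
    target_parts, truth_parts = [], []
    if n0 > 0:
        target_parts.append(generate_humans(human_model, n0, rng).values)
        truth_parts.append(np.zeros(n0, dtype=int))
    if n1 > 0:
        target_parts.append(generate_bots(bot_model, n1, d, rng, categories).values)
        truth_parts.append(np.ones(n1, dtype=int))
    target = ResponseMatrix(values=np.vstack(target_parts), categories=categories)
    truth = np.concatenate(truth_parts)

    cal_humans = generate_humans(human_model, n0tr, rng)
    cal_bots = generate_bots(calibration_bot_model, n1tr, d, rng, categories)
    cal = LabeledSample(
        responses=ResponseMatrix(
            values=np.vstack([cal_humans.values, cal_bots.values]),
            categories=categories),
        labels=np.concatenate([np.zeros(n0tr, dtype=int), np.ones(n1tr, dtype=int)]),
    )

    cal_imputed = LabeledSample(responses=impute_middle(cal.responses), labels=cal.labels)
    target_imputed = impute_middle(target)
    ref = reference_from_humans(cal_imputed)
    reference_rm = cal_imputed.humans()
    settings = dict(settings or {})
    if ridge is not None:
        settings.setdefault("ridge", ridge)
    try:
        cal_fm = featurize(cal_imputed.responses, ref, reference_rm,
                           indices=indices, settings=settings)
    except SingularCovarianceError:
        # a zero-variance item can occur in a tiny calibration human
        # sample; fall back to a small ridge rather than abort the cell
        settings["ridge"] = max(settings.get("ridge") or 0.0,
                                1e-6 * float(np.mean(np.diag(ref.covariance))))
        logger.warning("singular human reference covariance; retrying with "
                       "ridge %.3g", settings["ridge"])
        cal_fm = featurize(cal_imputed.responses, ref, reference_rm,
                           indices=indices, settings=settings)
    target_fm = featurize(target_imputed, ref, reference_rm,
                          indices=indices, settings=settings)

    lambda_hat = None
    if classifier == "scump":
        params = estimate_class_params(cal_fm, cal_imputed.labels, ridge=ridge)
        fit = estimate_lambda(target_fm, params, tol=tol)
        lambda_hat = fit.lambda_hat
        pred = bayes_classify(target_fm, fit)
        report = confusion_metrics(truth, pred.predicted, scores=pred.scores,
                                   threshold=0.0)
    elif classifier == "mahalanobis":
        report = fit_predict_mahalanobis_cutoff(
            cal_fm, cal_imputed.labels, target_fm, nominal_specificity,
            ridge=ridge, truth=truth)
    elif classifier == "union":
        cuts = fit_univariate_union(to_suspicion_increasing(cal_fm),
                                    cal_imputed.labels, nominal_specificity)
        report = predict_univariate_union(to_suspicion_increasing(target_fm),
                                          cuts, truth=truth)
    else:  # oracle: harness sanity check
        report = confusion_metrics(truth, truth, scores=truth.astype(float),
                                   threshold=0.5)

    return {
        "accuracy": report.accuracy,
        "specificity": report.specificity,
        "sensitivity": report.sensitivity,
        "flag_rate": report.flag_rate,
        "auc": report.auc,
        "lambda_hat": lambda_hat,
        "n0": n0,
        "n1": n1,
    }


def _nanmean(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def run_design(design: SimulationDesign, human_model: HumanModel, *,
               indices=DEFAULT_INDICES, settings: dict | None = None,
               nominal_specificity: float = 0.99,
               ridge: float | None = None,
               progress=None) -> list[CellResult]:
    """Monte Carlo means for every cell of the design.

    Deterministic given ``design.base_seed``: each replicate's RNG
    stream is derived from the base seed and its cell coordinates.
    """
    results = []
    for n0tr, n, lam, bot, clf in design.cells():
        rows = []
        for rep in range(design.replicates):
            seed = replicate_seed(design.base_seed, n0tr, n, lam, bot.name,
                                  clf, rep)
            rows.append(run_replicate(
                n0tr=n0tr, n=n, contamination=lam, human_model=human_model,
                bot_model=bot, classifier=clf, seed=seed, n1tr=design.n1tr,
                indices=indices, settings=settings,
                nominal_specificity=nominal_specificity, ridge=ridge))
        results.append(CellResult(
            n0tr=n0tr, n=n, contamination=lam, bot_model=bot.name,
            classifier=clf, replicates=design.replicates,
            accuracy=_nanmean(r["accuracy"] for r in rows),
            specificity=_nanmean(r["specificity"] for r in rows),
            sensitivity=_nanmean(r["sensitivity"] for r in rows),
            flag_rate=_nanmean(r["flag_rate"] for r in rows),
            auc=_nanmean(r["auc"] for r in rows),
            lambda_hat_mean=_nanmean(r["lambda_hat"] for r in rows),
        ))
        if progress is not None:
            progress(results[-1])
    return results


def results_to_frame(results: list[CellResult]) -> pd.DataFrame:
    """Tidy table: one row per design cell per classifier."""
    return pd.DataFrame([{
        "n0tr": r.n0tr, "n": r.n, "contamination": r.contamination,
        "bot_model": r.bot_model, "classifier": r.classifier,
        "replicates": r.replicates, "accuracy": r.accuracy,
        "specificity": r.specificity, "sensitivity": r.sensitivity,
        "flag_rate": r.flag_rate, "auc": r.auc,
        "lambda_hat_mean": r.lambda_hat_mean,
    } for r in results])
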