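"""The three-layer hierarchical accessibility classifier.

Architecture
------------
* ``L_B`` (bottom): per training sample, an ensemble of classification
  trees, each grown on a fresh uniform subsample (without replacement) of
  the sample's genes.  Trees see the three-column feature vector
  ``[e, d_open, d_closed]`` built from raw FPKM and the Mahalanobis
  distances to the two class distributions.  A tree's score for a gene is
  the open-class posterior of the leaf the gene falls into.
* ``L_M`` (middle): per sample, the gene x tree score matrix is compressed
  by PCA to the smallest number of components explaining at least a target
  fraction of its variance (95% by default), and a RUSBoost classifier is
  fit on the projections.
* ``L_U`` (upper): a single RUSBoost classifier over the vector of all
  per-sample L_M scores, trained on rows pooled across training samples,
  produces the final score in [0, 1]; a gene is called open when the score
  reaches the decision threshold (0.5 by default).

RUSBoost (random-undersampling boosting) is AdaBoost in which every round
first draws, under the current boosting weights, a random undersample of
the majority class down to the minority count, so each weak learner trains
on a class-balanced set while weighted error and weight updates use the
full training set.

Everything is driven by a single integer seed: identical (data, config,
seed) yields bit-identical models, and predictions depend on a gene only
through its expression value.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .feature_engineering import (
    ClassDistributionStats,
    build_feature_matrix,
    fit_class_distributions,
)
from .gene_labeling import AccessibilityLabels

logger = logging.getLogger(__name__)

_SEED_MAX = 2**31 - 1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the hierarchical model.

    Defaults keep the original training scale: 1000 bottom-layer trees per
    sample, each grown on a uniform subsample of 1000 genes, and PCA
    retaining >= 95% of score variance.  ``max_tree_depth`` limits the
    bottom-layer trees (None = fully grown); ``weak_learner_depth`` limits
    the RUSBoost weak learners.
    """

    n_lb_trees: int = 1000
    subsample_size: int = 1000
    pca_variance: float = 0.95
    boost_rounds: int = 50
    learning_rate: float = 1.0
    max_tree_depth: int | None = None
    weak_learner_depth: int = 3
    decision_threshold: float = 0.5
    seed: int = 0
    log1p: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must be in (0, 1]")
        if self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")
        if self.n_lb_trees < 1:
            raise ValueError("n_lb_trees must be >= 1")
        if self.boost_rounds < 1:
            raise ValueError("boost_rounds must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.decision_threshold <= 1:
            raise ValueError("decision_threshold must be in [0, 1]")


@dataclass
class RusBoost:
    """A fitted RUSBoost ensemble: weak trees with AdaBoost coefficients."""

    learners: list[DecisionTreeClassifier]
    alphas: np.ndarray

    def score(self, X: np.ndarray) -> np.ndarray:
        """Normalized weighted vote for the positive (open) class, in [0, 1]."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        total = float(self.alphas.sum())
        votes = np.zeros(X.shape[0])
        for tree, alpha in zip(self.learners, self.alphas):
            votes += alpha * (tree.predict(X) == True)  # noqa: E712
        return votes / total

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return self.score(X) >= threshold


@dataclass
class LBEnsemble:
    """Bottom-layer tree ensemble for one training sample."""

    sample_id: str
    trees: list[DecisionTreeClassifier]
    stats_open: ClassDistributionStats
    stats_closed: ClassDistributionStats
    subsample_seeds: np.ndarray
    subsample_size: int


@dataclass
class LMClassifier:
    """Middle-layer classifier: stored PCA basis plus a RUSBoost model."""

    sample_id: str
    pca_mean: np.ndarray
    pca_loadings: np.ndarray  # k x n_lb_trees, rows orthonormal
    k: int
    booster: RusBoost


@dataclass
class LUClassifier:
    """Upper-layer combiner over the vector of per-sample L_M scores."""

    booster: RusBoost
    n_inputs: int


@dataclass
class SampleComponent:
    lb: LBEnsemble
    lm: LMClassifier


@dataclass
class HierarchicalModel:
    config: TrainingConfig
    per_sample: list[SampleComponent]
    lu: LUClassifier
    training_sample_ids: list[str]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _proba_open(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Open-class posterior of the leaf each row reaches (leaf class fraction)."""
    proba = tree.predict_proba(X, check_input=False)
    classes = list(tree.classes_)
    if True in classes:
        return proba[:, classes.index(True)]
    return np.zeros(X.shape[0])


def _as_float32(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(X, dtype=np.float32))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of k items drawn without replacement with prob ∝ weights.

    Uses the Gumbel top-k trick, which is exact for weighted sampling
    without replacement and O(n log n).
    """
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.shape[0])
    if k >= weights.shape[0]:
        return np.arange(weights.shape[0])
    part = np.argpartition(keys, -k)[-k:]
    return np.sort(part)


def _transform_profile(expression: pd.Series, config: TrainingConfig) -> pd.Series:
    if config.log1p:
        return pd.Series(np.log1p(expression.to_numpy(float)), index=expression.index)
    return expression


# ---------------------------------------------------------------------------
# Sizing utility
# ---------------------------------------------------------------------------


def estimate_num_lb_trees(
    n_genes: int, subsample_size: int, reps: int = 100, seed: int = 0
) -> int:
    """Monte-Carlo estimate of the bottom-layer ensemble size.

    Estimates the mean number of uniform without-replacement batches of
    ``subsample_size`` genes needed until every one of ``n_genes`` genes
    has been drawn at least once (a batched coupon-collector process),
    multiplies by four for well-mixed training sets, and rounds up.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if subsample_size > n_genes:
        raise ValueError("subsample_size must be <= n_genes")
    rng = np.random.default_rng(seed)
    batches = np.empty(reps)
    for r in range(reps):
        covered = np.zeros(n_genes, dtype=bool)
        count = 0
        remaining = n_genes
        while remaining > 0:
            idx = rng.choice(n_genes, size=subsample_size, replace=False)
            newly = np.count_nonzero(~covered[idx])
            covered[idx] = True
            remaining -= newly
            count += 1
        batches[r] = count
    return int(math.ceil(4.0 * float(batches.mean())))


# ---------------------------------------------------------------------------
# Layer fits
# ---------------------------------------------------------------------------


def draw_subsample(seed: int, n: int, size: int) -> np.ndarray:
    """Deterministic uniform subsample without replacement for one tree."""
    return np.random.default_rng(seed).choice(n, size=size, replace=False)


def fit_lb_ensemble(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: TrainingConfig,
    seed: int,
    sample_id: str = "",
    stats_open: ClassDistributionStats | None = None,
    stats_closed: ClassDistributionStats | None = None,
) -> LBEnsemble:
    """Fit the bottom-layer ensemble: n_lb_trees trees on fresh subsamples."""
    labels = np.asarray(labels, dtype=bool)
    n = len(features)
    if labels.all() or not labels.any():
        raise ValueError("bottom-layer training labels contain a single class")
    size = min(config.subsample_size, n)
    if size < config.subsample_size:
        logger.warning(
            "subsample_size %d clamped to %d available genes",
            config.subsample_size,
            n,
        )
    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, _SEED_MAX, size=config.n_lb_trees)
    X = features.to_numpy(dtype=np.float64)
    trees: list[DecisionTreeClassifier] = []
    for tseed in tree_seeds:
        idx = draw_subsample(int(tseed), n, size)
        tree = DecisionTreeClassifier(
            max_depth=config.max_tree_depth, random_state=int(tseed)
        )
        tree.fit(X[idx], labels[idx])
        trees.append(tree)
    return LBEnsemble(
        sample_id=sample_id,
        trees=trees,
        stats_open=stats_open,
        stats_closed=stats_closed,
        subsample_seeds=tree_seeds,
        subsample_size=size,
    )


def score_lb(ensemble: LBEnsemble, features: pd.DataFrame) -> np.ndarray:
    """Gene x tree matrix of leaf open-class posteriors, values in [0, 1]."""
    X = _as_float32(features)
    out = np.empty((X.shape[0], len(ensemble.trees)))
    for t, tree in enumerate(ensemble.trees):
        out[:, t] = _proba_open(tree, X)
    return out


def fit_pca(
    score_matrix: np.ndarray, variance_threshold: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """PCA of the score matrix, keeping the fewest components reaching the
    cumulative explained-variance threshold.

    Returns (column means, k x n_trees orthonormal loadings, k).
    """
    S = np.asarray(score_matrix, dtype=np.float64)
    if S.shape[0] < 2:
        raise ValueError("PCA needs >= 2 rows")
    mean = S.mean(axis=0)
    centered = S - mean
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("score matrix has zero variance; PCA is undefined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    ratio = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(ratio, variance_threshold - 1e-12) + 1)
    k = min(k, vt.shape[0])
    return mean, vt[:k], k


def fit_rusboost(
    X: np.ndarray,
    y: np.ndarray,
    boost_rounds: int = 50,
    learning_rate: float = 1.0,
    seed: int = 0,
    max_depth: int = 3,
    round_hook: Callable[[int, int, int], None] | None = None,
) -> RusBoost:
    """Boost weak trees with per-round random undersampling of the majority.

    Each round draws (under the current boosting weights) a majority-class
    undersample matching the minority count, fits a weak tree on the
    balanced set, then computes the weighted error on the *full* training
    set and applies the AdaBoost weight/coefficient update.  ``round_hook``
    receives ``(round, n_positive, n_negative)`` of every round's training
    subsample, for balance instrumentation.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=bool)
    n = len(y)
    if y.all() or not y.any():
        raise ValueError("RUSBoost needs both classes present")
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    learners: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    best_reject: tuple[float, DecisionTreeClassifier] | None = None
    for r in range(boost_rounds):
        if len(pos_idx) <= len(neg_idx):
            minority, majority = pos_idx, neg_idx
        else:
            minority, majority = neg_idx, pos_idx
        sel = majority[
            _weighted_sample_without_replacement(rng, w[majority], len(minority))
        ]
        train_idx = np.concatenate([minority, sel])
        if round_hook is not None:
            round_hook(
                r,
                int(np.count_nonzero(y[train_idx])),
                int(np.count_nonzero(~y[train_idx])),
            )
        tree = DecisionTreeClassifier(
            max_depth=max_depth, random_state=int(rng.integers(0, _SEED_MAX))
        )
        tree.fit(X[train_idx], y[train_idx], sample_weight=w[train_idx])
        miss = tree.predict(X) != y
        eps = float(w @ miss)
        if eps >= 0.5:
            if best_reject is None or eps < best_reject[0]:
                best_reject = (eps, tree)
            continue
        eps_c = max(eps, 1e-10)
        alpha = learning_rate * math.log((1.0 - eps_c) / eps_c)
        learners.append(tree)
        alphas.append(alpha)
        if eps <= 1e-10:
            break  # perfect weak learner; further rounds leave weights unchanged
        w = w * np.exp(alpha * miss)
        w = w / w.sum()
    if not learners:
        warnings.warn(
            "RUSBoost: no round achieved weighted error < 0.5; "
            "returning best-effort single-learner model",
            stacklevel=2,
        )
        learners = [best_reject[1]]
        alphas = [1.0]
    return RusBoost(learners=learners, alphas=np.asarray(alphas))


def fit_lm(
    ensemble_scores: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    seed: int,
    sample_id: str = "",
) -> LMClassifier:
    """PCA-compress L_B scores, then fit the middle-layer RUSBoost."""
    mean, loadings, k = fit_pca(ensemble_scores, config.pca_variance)
    Z = (ensemble_scores - mean) @ loadings.T
    booster = fit_rusboost(
        Z,
        labels,
        boost_rounds=config.boost_rounds,
        learning_rate=config.learning_rate,
        seed=seed,
        max_depth=config.weak_learner_depth,
    )
    return LMClassifier(
        sample_id=sample_id, pca_mean=mean, pca_loadings=loadings, k=k, booster=booster
    )


# ---------------------------------------------------------------------------
# Full hierarchy
# ---------------------------------------------------------------------------


def _component_scores(comp: SampleComponent, expression: pd.Series) -> np.ndarray:
    """One sample's L_M score for every gene of an expression profile.

    Features are built with the component's *stored* training-time class
    statistics, and the stored PCA basis projects the L_B scores: the
    output therefore depends on a gene only through its FPKM value.
    """
    feats = build_feature_matrix(expression, comp.lb.stats_open, comp.lb.stats_closed)
    scores = score_lb(comp.lb, feats)
    Z = (scores - comp.lm.pca_mean) @ comp.lm.pca_loadings.T
    return comp.lm.booster.score(Z)


def fit_hierarchical(
    training_samples: Sequence[tuple[pd.Series, AccessibilityLabels]],
    config: TrainingConfig,
    sample_ids: Sequence[str] | None = None,
) -> HierarchicalModel:
    """Fit per-sample (L_B, L_M) components plus the L_U combiner.

    Gene universes are restricted to the intersection across samples (with
    a logged count of dropped genes).  The L_U training set pools, for
    every training sample s and gene g, the vector of all samples' L_M
    scores on s's expression, labeled with s's accessibility of g.
    """
    if len(training_samples) < 2:
        raise ValueError("need >= 2 training samples")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(training_samples))]
    if len(sample_ids) != len(training_samples):
        raise ValueError("sample_ids length mismatch")

    common = None
    for expr, labels in training_samples:
        universe = expr.index.intersection(labels.labels.index)
        common = universe if common is None else common.intersection(universe)
    n_total = max(len(expr) for expr, _ in training_samples)
    if len(common) == 0:
        raise ValueError("no genes shared across all training samples")
    if len(common) < n_total:
        logger.info(
            "restricted to %d genes shared across samples (%d dropped)",
            len(common),
            n_total - len(common),
        )

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(training_samples) + 1)

    components: list[SampleComponent] = []
    profiles: list[pd.Series] = []
    label_arrays: list[np.ndarray] = []
    for i, (expr, labels) in enumerate(training_samples):
        profile = _transform_profile(expr.loc[common], config)
        y = labels.labels.loc[common].to_numpy(dtype=bool)
        raw_labels = AccessibilityLabels(
            labels=pd.Series(y, index=common), source=labels.source
        )
        stats_open, stats_closed = fit_class_distributions(profile, raw_labels)
        feats = build_feature_matrix(profile, stats_open, stats_closed)
        rng = np.random.default_rng(children[i])
        lb_seed = int(rng.integers(0, _SEED_MAX))
        lm_seed = int(rng.integers(0, _SEED_MAX))
        lb = fit_lb_ensemble(
            feats,
            y,
            config,
            seed=lb_seed,
            sample_id=sample_ids[i],
            stats_open=stats_open,
            stats_closed=stats_closed,
        )
        own_scores = score_lb(lb, feats)
        lm = fit_lm(own_scores, y, config, seed=lm_seed, sample_id=sample_ids[i])
        components.append(SampleComponent(lb=lb, lm=lm))
        profiles.append(profile)
        label_arrays.append(y)

    # Upper layer: pooled rows of all samples' L_M scores on each sample.
    blocks = []
    for profile in profiles:
        block = np.column_stack([_component_scores(c, profile) for c in components])
        blocks.append(block)
    X_u = np.vstack(blocks)
    y_u = np.concatenate(label_arrays)
    lu_seed = int(np.random.default_rng(children[-1]).integers(0, _SEED_MAX))
    lu_boost = fit_rusboost(
        X_u,
        y_u,
        boost_rounds=config.boost_rounds,
        learning_rate=config.learning_rate,
        seed=lu_seed,
        max_depth=config.weak_learner_depth,
    )
    lu = LUClassifier(booster=lu_boost, n_inputs=len(components))
    return HierarchicalModel(
        config=config,
        per_sample=components,
        lu=lu,
        training_sample_ids=list(sample_ids),
    )


def predict(
    model: HierarchicalModel, expression: pd.Series
) -> tuple[pd.Series, AccessibilityLabels]:
    """Final L_U scores and open/closed labels for an expression profile."""
    if len(expression) == 0:
        raise ValueError("empty expression profile")
    profile = _transform_profile(expression, model.config)
    M = np.column_stack(
        [_component_scores(c, profile) for c in model.per_sample]
    )
    scores = pd.Series(model.lu.booster.score(M), index=expression.index, name="score")
    is_open = scores >= model.config.decision_threshold
    labels = AccessibilityLabels(labels=is_open, source="predicted")
    return scores, labels
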