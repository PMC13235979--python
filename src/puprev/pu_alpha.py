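"""Class-prior (alpha) estimation under SCAR via balanced undersampling.

The unlabeled set is split into k = floor(|U|/|P|) disjoint partitions;
each partition is paired with all labeled positives to form a balanced
dataset, scored with an out-of-fold gradient-boosted classifier, and an
alpha estimate is read off the score densities as the tightest
nonnegative-mixture bound min_s f_U(s)/f_P(s).  The final alpha is the
mean of the per-partition estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .synthetic import PUDataset, split_pu

__all__ = [
    "ClassifierConfig",
    "PartitionPlan",
    "ScoreSet",
    "ScoreDensities",
    "AlphaEstimate",
    "make_partition_plan",
    "fit_pu_scores",
    "estimate_densities",
    "estimate_alpha_scar",
    "pulscar",
]

SCORE_CLIP = 1e-6


@dataclass(frozen=True)
class ClassifierConfig:
    """Gradient-boosted tree settings plus cross-fitting controls.

    The defaults mirror the full-scale analysis profile; ``test_profile``
    returns a reduced configuration for desk-scale runs.  Any classifier
    exposing fit/predict_proba could be substituted; this config is bound
    to the histogram gradient-boosting implementation in scikit-learn.
    """

    max_depth: int = 12
    n_estimators: int = 400
    learning_rate: float = 0.05
    min_child_weight: int = 1
    colsample_bytree: float = 0.3
    colsample_bylevel: float = 0.6
    v_folds: int = 5
    max_bins: int = 16
    n_bins_density: Optional[int] = None  # None = auto
    tau: float = 0.05
    pseudocount: float = 0.0
    ucb_z: float = 1.5

    @classmethod
    def test_profile(cls, **overrides) -> "ClassifierConfig":
        base = dict(max_depth=4, n_estimators=50, learning_rate=0.1,
                    colsample_bytree=1.0, colsample_bylevel=0.6)
        base.update(overrides)
        return cls(**base)

    def build(self, seed: int) -> HistGradientBoostingClassifier:
        # colsample_bytree*colsample_bylevel approximates per-split
        # feature subsampling with a single max_features fraction
        max_features = max(min(self.colsample_bytree * self.colsample_bylevel, 1.0), 1e-3)
        return HistGradientBoostingClassifier(
            max_iter=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            min_samples_leaf=max(1, self.min_child_weight),
            max_features=max_features,
            max_bins=self.max_bins,
            early_stopping=False,
            random_state=seed,
        )


@dataclass
class PartitionPlan:
    """Disjoint split of the unlabeled ids into k balanced-partner groups."""

    k: int
    assignments: Dict[object, int]
    seed: int
    partition_ids: List[np.ndarray] = field(repr=False, default_factory=list)


@dataclass
class ScoreSet:
    """Out-of-fold classifier probabilities for one balanced dataset."""

    scores_P: np.ndarray
    scores_U: np.ndarray
    fold_map: np.ndarray  # over rows of the balanced dataset (P then U)
    models: list = field(default_factory=list, repr=False)


@dataclass
class ScoreDensities:
    grid: np.ndarray  # bin edges, length n_bins + 1
    f_P: np.ndarray
    f_U: np.ndarray
    support_mask: np.ndarray
    # Poisson-style upper envelope of f_U accounting for finite bin counts;
    # same normalization as f_U but does not itself integrate to 1.
    f_U_upper: Optional[np.ndarray] = None


@dataclass
class AlphaEstimate:
    alpha: float
    per_partition: List[float]
    sd: float
    method: str
    per_cluster: Optional[Dict[int, float]] = None


def make_partition_plan(
    n_labeled: int, unlabeled_ids: Sequence, seed: int
) -> PartitionPlan:
    """Shuffle the unlabeled ids into k = floor(|U|/|P|) disjoint groups.

    Every group has exactly ``n_labeled`` members except the last, which
    absorbs the remainder.
    """
    if n_labeled < 1:
        raise ValueError("need at least one labeled record")
    unlabeled_ids = np.asarray(unlabeled_ids)
    n_u = len(unlabeled_ids)
    k = n_u // n_labeled
    if k < 1:
        raise ValueError(
            f"|unlabeled|={n_u} < |labeled|={n_labeled}: k=0 is invalid; "
            "use a single balanced dataset with all unlabeled records instead"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_u)
    shuffled = unlabeled_ids[order]
    partitions: List[np.ndarray] = []
    for j in range(k):
        hi = (j + 1) * n_labeled if j < k - 1 else n_u
        partitions.append(shuffled[j * n_labeled : hi])
    assignments = {rid: j for j, part in enumerate(partitions) for rid in part}
    return PartitionPlan(k=k, assignments=assignments, seed=seed, partition_ids=partitions)


def _densify(X) -> np.ndarray:
    if sp.issparse(X):
        return X.toarray().astype(np.float32)
    return np.asarray(X, dtype=np.float32)


def fit_pu_scores(
    balanced: PUDataset,
    classifier_config: ClassifierConfig,
    v_folds: Optional[int] = None,
    seed: int = 0,
) -> ScoreSet:
    """Stratified v-fold cross-fitting on one balanced dataset.

    Every record's probability comes from the model whose training fold
    excluded it.  Scores are clipped into [1e-6, 1-1e-6] so downstream
    logits stay finite.
    """
    v = v_folds if v_folds is not None else classifier_config.v_folds
    if v < 2:
        raise ValueError("v_folds must be >= 2")
    y = np.asarray(balanced.labels)
    n_pos = int((y == 1).sum())
    n_unl = int((y == 0).sum())
    if n_pos == 0 or n_unl == 0:
        raise ValueError("balanced dataset must contain labeled and unlabeled records")
    if min(n_pos, n_unl) < v:
        raise ValueError(
            f"cannot stratify {v} folds with class counts ({n_pos}, {n_unl})"
        )
    X = _densify(balanced.features)
    scores = np.empty(len(y), dtype=float)
    fold_map = np.empty(len(y), dtype=int)
    models = []
    skf = StratifiedKFold(n_splits=v, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = classifier_config.build(seed)
        clf.fit(X[tr], y[tr])
        p = clf.predict_proba(X[te])[:, 1]
        scores[te] = p
        fold_map[te] = fold
        models.append(clf)
    if not np.all(np.isfinite(scores)):
        raise ValueError("classifier produced non-finite scores")
    scores = np.clip(scores, SCORE_CLIP, 1 - SCORE_CLIP)
    return ScoreSet(
        scores_P=scores[y == 1],
        scores_U=scores[y == 0],
        fold_map=fold_map,
        models=models,
    )


def _auto_bins(n_p: int, n_u: int) -> int:
    # coarse bins: the min-ratio bound degrades quickly once per-cell
    # counts get small, so cap well below sqrt(n)
    return int(max(10, min(25, round(np.sqrt(min(n_p, n_u)) / 2))))


def estimate_densities(
    scores: ScoreSet,
    n_bins: Optional[int] = None,
    tau: float = 0.05,
    pseudocount: float = 0.0,
    ucb_z: float = 1.5,
) -> ScoreDensities:
    """Shared-bin histogram densities of the two score arms on [0, 1].

    ``pseudocount`` adds a uniform count to every bin of both arms before
    normalization (regularizes tiny samples; 0 keeps raw histograms).
    The support mask marks cells where f_P >= tau * max(f_P).
    """
    s_p = np.asarray(scores.scores_P, dtype=float)
    s_u = np.asarray(scores.scores_U, dtype=float)
    if len(s_p) < 30 or len(s_u) < 30:
        raise ValueError("need at least 30 scores in each arm")
    nb = n_bins if n_bins is not None else _auto_bins(len(s_p), len(s_u))
    edges = np.linspace(0.0, 1.0, nb + 1)
    c_p, _ = np.histogram(s_p, bins=edges)
    c_u, _ = np.histogram(s_u, bins=edges)
    nonempty = int(np.count_nonzero(c_p + c_u))
    if nonempty < 5:
        raise ValueError(
            f"only {nonempty} nonempty bins: provide more data or fewer bins"
        )
    width = 1.0 / nb
    f_p = (c_p + pseudocount) / ((len(s_p) + pseudocount * nb) * width)
    f_u = (c_u + pseudocount) / ((len(s_u) + pseudocount * nb) * width)
    z = ucb_z
    f_u_upper = (c_u + pseudocount + z * np.sqrt(c_u) + z * z / 2) / (
        (len(s_u) + pseudocount * nb) * width
    )
    mask = f_p >= tau * f_p.max()
    return ScoreDensities(
        grid=edges, f_P=f_p, f_U=f_u, support_mask=mask, f_U_upper=f_u_upper
    )


def estimate_alpha_scar(densities: ScoreDensities, regularized: bool = True) -> float:
    """Mixture-proportion bound: min over the f_P support of f_U/f_P.

    Under f_U = alpha*f_P + (1-alpha)*f_N with f_N >= 0, the ratio
    f_U(s)/f_P(s) upper-bounds alpha pointwise, so its minimum is the
    tightest such bound.  With finite bin counts the raw minimum is
    biased toward 0 (any undershooting cell drags it down), so by
    default the Poisson upper envelope of f_U is used in the ratio.
    """
    mask = densities.support_mask
    if not np.any(mask):
        raise ValueError("empty support mask: cannot bound the class prior")
    f_u = densities.f_U
    if regularized and densities.f_U_upper is not None:
        f_u = densities.f_U_upper
    ratio = f_u[mask] / densities.f_P[mask]
    return float(np.clip(ratio.min(), 0.0, 1.0))


def _partition_alpha(
    balanced: PUDataset,
    classifier_config: ClassifierConfig,
    seed: int,
) -> tuple[float, ScoreSet]:
    scores = fit_pu_scores(balanced, classifier_config, seed=seed)
    dens = estimate_densities(
        scores,
        n_bins=classifier_config.n_bins_density,
        tau=classifier_config.tau,
        pseudocount=classifier_config.pseudocount,
        ucb_z=classifier_config.ucb_z,
    )
    return estimate_alpha_scar(dens), scores


def _predict_mean(models, X: np.ndarray) -> np.ndarray:
    p = np.mean([m.predict_proba(X)[:, 1] for m in models], axis=0)
    return np.clip(p, SCORE_CLIP, 1 - SCORE_CLIP)


def pulscar(
    dataset: PUDataset,
    classifier_config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    max_partitions: Optional[int] = None,
) -> tuple[AlphaEstimate, np.ndarray]:
    """Balanced-undersampling ensemble alpha estimate plus raw probabilities.

    Returns the mean-of-partitions AlphaEstimate and a probability for
    every record of ``dataset`` (aligned with its row order): unlabeled
    records in a fitted partition get their own out-of-fold score, other
    unlabeled records get the mean prediction of the fitted partitions'
    fold models, and labeled records get their out-of-fold score averaged
    across fitted partitions.

    ``max_partitions`` caps how many of the k partitions are actually
    fitted (sampled without replacement); the estimate then averages the
    fitted subset.
    """
    if classifier_config is None:
        classifier_config = ClassifierConfig()
    pos, unl = split_pu(dataset)
    pos_rows = np.flatnonzero(dataset.labels == 1)
    unl_rows = np.flatnonzero(dataset.labels == 0)
    plan = make_partition_plan(pos.n_records, unl_rows, seed)

    rng = np.random.default_rng(seed)
    if max_partitions is not None and plan.k > max_partitions:
        fitted = np.sort(rng.choice(plan.k, size=max_partitions, replace=False))
    else:
        fitted = np.arange(plan.k)

    raw = np.full(dataset.n_records, np.nan)
    pos_scores_acc = np.zeros(pos.n_records)
    alphas: List[float] = []
    all_models = []
    for j in fitted:
        part_rows = plan.partition_ids[j]
        rows = np.concatenate([pos_rows, part_rows])
        balanced = dataset.take(rows)
        alpha_j, scores = _partition_alpha(
            balanced, classifier_config, seed=seed + int(j)
        )
        alphas.append(alpha_j)
        raw[part_rows] = scores.scores_U
        pos_scores_acc += scores.scores_P
        all_models.extend(scores.models)
    raw[pos_rows] = pos_scores_acc / len(fitted)

    missing = np.flatnonzero(np.isnan(raw))
    if missing.size:
        X_missing = _densify(dataset.features[missing])
        raw[missing] = _predict_mean(all_models, X_missing)

    alpha = float(np.mean(alphas))
    est = AlphaEstimate(
        alpha=alpha,
        per_partition=[float(a) for a in alphas],
        sd=float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0,
        method="PULSCAR",
    )
    return est, raw
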