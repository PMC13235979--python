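"""Subtype-aware class-prior estimation for SNAR labeling.

When the probability of a positive being labeled depends on its subtype,
a single SCAR estimate undercounts the weakly-labeled subtypes.  Here
labeled positives are clustered on the informative covariates, the SCAR
estimator is run once per cluster against the full unlabeled set, the
per-cluster priors are summed (capped at 1), and each cluster's unlabeled
probabilities are anchored to its own prior with a logit shift before
being combined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import silhouette_score

from .calibration import calibrate_to_alpha
from .pu_alpha import (
    AlphaEstimate,
    ClassifierConfig,
    _densify,
    make_partition_plan,
    pulscar,
)
from .synthetic import PUDataset, split_pu

__all__ = [
    "SubtypeClustering",
    "FeatureImportance",
    "rank_features",
    "cluster_positives",
    "pulsnar_alpha",
    "calibrate_to_alpha",
    "combine_cluster_probs",
]

logger = logging.getLogger(__name__)


@dataclass
class SubtypeClustering:
    n_clusters: int
    assignment: np.ndarray  # labeled record -> cluster index
    feature_subset: np.ndarray  # covariate ids used for clustering
    selection_scores: Dict[int, float]
    seed: int


@dataclass
class FeatureImportance:
    """Per-covariate gain averaged over the ensemble partitions."""

    gains: np.ndarray
    covariate_ids: np.ndarray

    @property
    def n_informative(self) -> int:
        return int(np.count_nonzero(self.gains > 0))

    def ranking(self) -> np.ndarray:
        """Covariate indices by descending gain."""
        return np.argsort(-self.gains, kind="stable")


def rank_features(
    dataset: PUDataset,
    classifier_config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    max_partitions: int = 5,
) -> FeatureImportance:
    """Average split-gain importance over balanced-partition models.

    One gradient-boosted model is trained per fitted partition on the
    full balanced dataset; impurity-gain importances are averaged across
    partitions.  Covariates that are never split on get gain exactly 0.
    """
    if classifier_config is None:
        classifier_config = ClassifierConfig.test_profile()
    pos, _ = split_pu(dataset)
    pos_rows = np.flatnonzero(dataset.labels == 1)
    unl_rows = np.flatnonzero(dataset.labels == 0)
    plan = make_partition_plan(pos.n_records, unl_rows, seed)
    rng = np.random.default_rng(seed)
    if plan.k > max_partitions:
        fitted = np.sort(rng.choice(plan.k, size=max_partitions, replace=False))
    else:
        fitted = np.arange(plan.k)
    gains = np.zeros(dataset.n_covariates)
    for j in fitted:
        rows = np.concatenate([pos_rows, plan.partition_ids[j]])
        X = _densify(dataset.features[rows])
        y = dataset.labels[rows]
        if y.min() == y.max():
            raise ValueError("single-class partition: cannot rank features")
        clf = GradientBoostingClassifier(
            n_estimators=classifier_config.n_estimators,
            max_depth=classifier_config.max_depth,
            learning_rate=classifier_config.learning_rate,
            max_features=classifier_config.colsample_bylevel,
            random_state=seed + int(j),
        )
        clf.fit(X, y)
        gains += clf.feature_importances_
    gains /= len(fitted)
    return FeatureImportance(gains=gains, covariate_ids=np.asarray(dataset.covariate_ids))


def cluster_positives(
    positives: PUDataset,
    importance: FeatureImportance,
    max_clusters: int = 25,
    seed: int = 0,
    n_clusters_override: Optional[int] = None,
    min_silhouette: float = 0.05,
) -> SubtypeClustering:
    """Partition the labeled positives into subtypes.

    K-means on the gain-positive covariate submatrix; the cluster count
    maximizes the mean silhouette over 2..max_clusters, falling back to a
    single cluster when the best silhouette is below ``min_silhouette``.
    """
    if positives.n_records < 2:
        raise ValueError("need at least 2 labeled positives to cluster")
    keep = np.flatnonzero(importance.gains > 0)
    if keep.size == 0:
        raise ValueError("no informative covariates: cannot cluster subtypes")
    X = _densify(positives.features[:, keep])
    n = X.shape[0]

    if n_clusters_override is not None:
        kc = int(n_clusters_override)
        if kc < 1 or kc > n:
            raise ValueError("n_clusters_override out of range")
        if kc == 1:
            assignment = np.zeros(n, dtype=int)
        else:
            assignment = KMeans(n_clusters=kc, n_init=10, random_state=seed).fit_predict(X)
        return SubtypeClustering(
            n_clusters=kc,
            assignment=assignment,
            feature_subset=np.asarray(positives.covariate_ids)[keep],
            selection_scores={},
            seed=seed,
        )

    if max_clusters < 2:
        warnings.warn("max_clusters < 2: forcing a single cluster", UserWarning)
        return SubtypeClustering(
            n_clusters=1,
            assignment=np.zeros(n, dtype=int),
            feature_subset=np.asarray(positives.covariate_ids)[keep],
            selection_scores={},
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    sample = None
    if n > 2000:  # silhouette is O(n^2); subsample for the selection metric
        sample = rng.choice(n, size=2000, replace=False)
    scores: Dict[int, float] = {}
    labels_by_k: Dict[int, np.ndarray] = {}
    upper = min(max_clusters, n - 1)
    for kc in range(2, upper + 1):
        km = KMeans(n_clusters=kc, n_init=10, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        if sample is not None and len(np.unique(lab[sample])) > 1:
            scores[kc] = float(silhouette_score(X[sample], lab[sample]))
        else:
            scores[kc] = float(silhouette_score(X, lab))
        labels_by_k[kc] = lab
    if not scores:
        best_k, best_s = 1, -1.0
    else:
        best_k = max(scores, key=lambda kc: scores[kc])
        best_s = scores[best_k]
    if best_s < min_silhouette:
        logger.info("best silhouette %.3f < %.3f: single cluster", best_s, min_silhouette)
        assignment = np.zeros(n, dtype=int)
        best_k = 1
    else:
        assignment = labels_by_k[best_k]
    return SubtypeClustering(
        n_clusters=best_k,
        assignment=assignment,
        feature_subset=np.asarray(positives.covariate_ids)[keep],
        selection_scores=scores,
        seed=seed,
    )


def combine_cluster_probs(
    raw_probs_by_cluster: Dict[int, np.ndarray],
) -> np.ndarray:
    """Capped sum of per-cluster (already alpha-anchored) probabilities.

    Subtypes are modeled as disjoint events, so per-record membership
    probabilities add; sums above 1 are capped and counted.
    """
    if not raw_probs_by_cluster:
        raise ValueError("no cluster probabilities to combine")
    mats = [np.asarray(v, dtype=float) for v in raw_probs_by_cluster.values()]
    n = mats[0].size
    for m in mats:
        if m.size != n:
            raise ValueError("cluster probability vectors differ in length")
    total = np.sum(mats, axis=0)
    n_capped = int(np.count_nonzero(total > 1.0))
    if n_capped:
        logger.info("capped %d combined probabilities at 1", n_capped)
    return np.minimum(total, 1.0)


def pulsnar_alpha(
    dataset: PUDataset,
    clustering: SubtypeClustering,
    classifier_config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    max_partitions: Optional[int] = 10,
) -> Tuple[AlphaEstimate, Dict[int, np.ndarray]]:
    """Per-subtype SCAR runs combined into a SNAR-valid class prior.

    For each cluster c the PU problem (labeled = cluster-c positives,
    unlabeled = the full unlabeled set) is solved with the SCAR
    estimator, giving alpha_c = estimated fraction of the unlabeled set
    in subtype c.  The overall prior is min(1, sum_c alpha_c).  The
    returned per-cluster probabilities (over the unlabeled records, in
    dataset row order) are each anchored to alpha_c by a logit shift.
    """
    if classifier_config is None:
        classifier_config = ClassifierConfig()
    pos_rows = np.flatnonzero(dataset.labels == 1)
    unl_rows = np.flatnonzero(dataset.labels == 0)
    if len(clustering.assignment) != pos_rows.size:
        raise ValueError("clustering does not cover all labeled positives")

    alphas: Dict[int, float] = {}
    probs_by_cluster: Dict[int, np.ndarray] = {}
    per_partition_all = []
    for c in range(clustering.n_clusters):
        members = pos_rows[clustering.assignment == c]
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        rows = np.concatenate([members, unl_rows])
        sub = dataset.take(rows)
        est_c, raw_c = pulscar(
            sub,
            classifier_config,
            seed=seed + c,
            max_partitions=max_partitions,
        )
        alphas[c] = est_c.alpha
        per_partition_all.append(est_c.per_partition)
        raw_u = raw_c[members.size :]  # unlabeled block, in unl_rows order
        probs_by_cluster[c] = calibrate_to_alpha(raw_u, est_c.alpha)

    total = sum(alphas.values())
    if total > 1.0:
        warnings.warn(
            f"sum of per-cluster priors {total:.3f} exceeds 1; capping",
            UserWarning,
        )
    per_partition = (
        per_partition_all[0]
        if clustering.n_clusters == 1
        else [float(sum(alphas.values()))]
    )
    est = AlphaEstimate(
        alpha=float(min(1.0, total)),
        per_partition=per_partition,
        sd=float(np.std(list(alphas.values()), ddof=1)) if len(alphas) > 1 else 0.0,
        method="PULSNAR",
        per_cluster={c: float(a) for c, a in alphas.items()},
    )
    return est, probs_by_cluster
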