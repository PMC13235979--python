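"""Synthetic positive-unlabeled cohorts with latent subtypes.

Generates sparse binary record-by-covariate matrices in which a latent
fraction of records is positive, positives fall into one or more subtypes,
and only some positives carry a label.  Labeling can be constant across
subtypes (SCAR: selected completely at random) or subtype-dependent
(SNAR: selected not at random).  Ground truth is retained so that
class-prior estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["SyntheticConfig", "PUDataset", "generate_cohort", "split_pu"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the Bernoulli-mixture cohort generator.

    ``true_alpha`` is the latent positive fraction of the whole cohort;
    ``coded_fraction`` is the marginal probability that a latent positive
    is labeled.  ``label_propensities`` give the *relative* per-subtype
    labeling propensity; they are rescaled internally so the expected
    labeled fraction among positives equals ``coded_fraction``.
    """

    n_records: int
    n_covariates: int
    true_alpha: float
    coded_fraction: float
    n_subtypes: int = 1
    subtype_weights: Optional[Sequence[float]] = None
    label_propensities: Optional[Sequence[float]] = None
    n_informative: int = 50
    baseline_rate: float = 0.02
    lift: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if self.n_informative > self.n_covariates:
            raise ValueError("n_informative cannot exceed n_covariates")
        if self.n_subtypes > self.n_informative:
            raise ValueError(
                "n_subtypes > n_informative: each subtype needs at least "
                "one informative covariate"
            )
        for name in ("true_alpha", "coded_fraction", "baseline_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lift < 0:
            raise ValueError("lift must be nonnegative")
        w = self.weights
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_weights must sum to 1 within 1e-9")
        if np.any(w < 0):
            raise ValueError("subtype_weights must be nonnegative")
        p = self.propensities
        if len(p) != self.n_subtypes:
            raise ValueError("label_propensities length must equal n_subtypes")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("label_propensities must lie in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        if self.subtype_weights is None:
            return np.full(self.n_subtypes, 1.0 / self.n_subtypes)
        return np.asarray(self.subtype_weights, dtype=float)

    @property
    def propensities(self) -> np.ndarray:
        if self.label_propensities is None:
            return np.full(self.n_subtypes, self.coded_fraction)
        return np.asarray(self.label_propensities, dtype=float)

    @property
    def is_scar(self) -> bool:
        p = self.propensities
        return bool(np.all(np.abs(p - p[0]) < 1e-12))


@dataclass
class PUDataset:
    """A positive-unlabeled dataset: binary CSR features plus labels.

    ``labels`` uses 1 = labeled positive, 0 = unlabeled.  When the data
    are synthetic, ``latent_status`` (1 = latent positive) and
    ``latent_subtype`` (subtype index for positives, -1 otherwise) carry
    the generator's ground truth.
    """

    features: sp.csr_matrix
    labels: np.ndarray
    record_ids: np.ndarray
    covariate_ids: np.ndarray
    latent_status: Optional[np.ndarray] = None
    latent_subtype: Optional[np.ndarray] = None
    covariate_meta: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, d = self.features.shape
        if len(self.labels) != n:
            raise ValueError("labels length must equal number of feature rows")
        if len(self.record_ids) != n:
            raise ValueError("record_ids length must equal number of rows")
        if len(self.covariate_ids) != d:
            raise ValueError("covariate_ids length must equal number of columns")
        if self.features.nnz and not np.all(np.isin(self.features.data, (0, 1))):
            raise ValueError("feature values must be exactly 0 or 1")
        if self.latent_status is not None:
            if np.any((self.labels == 1) & (self.latent_status == 0)):
                raise ValueError("labeled record with latent_status=0")

    @property
    def n_records(self) -> int:
        return self.features.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.features.shape[1]

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labels == 1))

    def take(self, idx: np.ndarray) -> "PUDataset":
        """Row-subset view preserving record identifiers."""
        return PUDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            record_ids=self.record_ids[idx],
            covariate_ids=self.covariate_ids,
            latent_status=None if self.latent_status is None else self.latent_status[idx],
            latent_subtype=None if self.latent_subtype is None else self.latent_subtype[idx],
            covariate_meta=self.covariate_meta,
        )


def _activation_rates(config: SyntheticConfig) -> np.ndarray:
    lifted = config.baseline_rate * config.lift
    if lifted > 1.0:
        warnings.warn(
            f"lift*baseline_rate={lifted:.3f} exceeds 1; capping activation at 1",
            UserWarning,
            stacklevel=3,
        )
        lifted = 1.0
    return np.array([config.baseline_rate, lifted])


def generate_cohort(config: SyntheticConfig) -> PUDataset:
    """Draw a synthetic PU cohort under ``config``.

    Latent positives are Bernoulli(true_alpha); each positive gets a
    subtype from ``subtype_weights``; labels are assigned with rescaled
    subtype propensities.  Informative covariates are partitioned over
    subtypes round-robin; a positive of subtype t activates its subtype's
    informative covariates at rate ``baseline_rate*lift`` (capped at 1)
    and everything else at ``baseline_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_records, config.n_covariates

    latent = (rng.random(n) < config.true_alpha).astype(np.int8)
    pos_idx = np.flatnonzero(latent == 1)

    subtype = np.full(n, -1, dtype=np.int32)
    if pos_idx.size:
        subtype[pos_idx] = rng.choice(
            config.n_subtypes, size=pos_idx.size, p=config.weights
        )

    # Rescale relative propensities so E[labeled | positive] = coded_fraction.
    prop = config.propensities
    mean_prop = float(config.weights @ prop)
    if mean_prop > 0 and config.coded_fraction > 0:
        scaled = prop * (config.coded_fraction / mean_prop)
        if np.any(scaled > 1.0):
            warnings.warn(
                "rescaled label propensities exceed 1; capping at 1 "
                "(marginal coded fraction will fall short)",
                UserWarning,
                stacklevel=2,
            )
            scaled = np.minimum(scaled, 1.0)
    else:
        scaled = np.zeros_like(prop)

    labels = np.zeros(n, dtype=np.int8)
    if pos_idx.size:
        u = rng.random(pos_idx.size)
        labels[pos_idx] = (u < scaled[subtype[pos_idx]]).astype(np.int8)

    base_rate, lifted_rate = _activation_rates(config)

    # informative covariate j (j < n_informative) belongs to subtype j % n_subtypes
    informative = np.zeros(d, dtype=bool)
    informative[: config.n_informative] = True
    cov_subtype = np.full(d, -1, dtype=np.int32)
    cov_subtype[: config.n_informative] = (
        np.arange(config.n_informative) % config.n_subtypes
    )

    # per-row activation thresholds; memory is fine at desk scale
    thresh = np.full((n, d), base_rate, dtype=np.float32)
    for t in range(config.n_subtypes):
        rows = np.flatnonzero(subtype == t)
        cols = np.flatnonzero(cov_subtype == t)
        if rows.size and cols.size:
            thresh[np.ix_(rows, cols)] = lifted_rate

    dense = rng.random((n, d), dtype=np.float32) < thresh
    features = sp.csr_matrix(dense, dtype=np.int8)

    record_ids = np.array([f"r{i:07d}" for i in range(n)])
    covariate_ids = np.array([f"c{j:06d}" for j in range(d)])
    covariate_meta = pd.DataFrame(
        {
            "covariate_id": covariate_ids,
            "informative_flag": informative.astype(int),
            "subtype": cov_subtype,
        }
    )
    return PUDataset(
        features=features,
        labels=labels,
        record_ids=record_ids,
        covariate_ids=covariate_ids,
        latent_status=latent,
        latent_subtype=subtype,
        covariate_meta=covariate_meta,
    )


def split_pu(dataset: PUDataset) -> tuple[PUDataset, PUDataset]:
    """Partition a dataset into (labeled-positive view, unlabeled view)."""
    pos = np.flatnonzero(dataset.labels == 1)
    unl = np.flatnonzero(dataset.labels == 0)
    if pos.size == 0:
        raise ValueError(
            "no labeled positives: positive-unlabeled estimation is undefined"
        )
    return dataset.take(pos), dataset.take(unl)
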