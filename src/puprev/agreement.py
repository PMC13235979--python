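"""Inter-rater agreement, risk stratification, and review-vs-model metrics.

Covers pairwise percent agreement, Cohen and Fleiss kappa (with the
large-sample z test for Fleiss), a three-way review outcome
(unanimous-no / dissenting / unanimous-yes) crossed against probability
risk categories with a Monte-Carlo Fisher exact test, and standard
classification metrics of model probabilities against consensus labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

__all__ = [
    "RatingsMatrix",
    "RiskCategory",
    "AgreementReport",
    "consensus_labels",
    "pairwise_agreement",
    "cohen_kappa",
    "fleiss_kappa",
    "review_outcome_3way",
    "risk_categories",
    "stratify_and_test",
    "classification_metrics",
    "f1_from_precision_recall",
    "build_agreement_report",
]

RISK_CUTS = (0.25, 0.75)
RISK_LABELS = ("low", "intermediate", "high")
OUTCOME_LABELS = ("unanimous_no", "dissenting", "unanimous_yes")


@dataclass
class RatingsMatrix:
    """Binary case-by-rater ratings with an optional consensus column."""

    cases: np.ndarray
    raters: np.ndarray
    values: np.ndarray
    consensus: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        n, r = self.values.shape
        if len(self.cases) != n or len(self.raters) != r:
            raise ValueError("ratings shape does not match case/rater lists")
        if not np.all(np.isin(self.values, (0, 1))):
            raise ValueError("ratings must be 0/1 with no missing entries")
        if self.consensus is not None and len(self.consensus) != n:
            raise ValueError("consensus length must match number of cases")


@dataclass
class RiskCategory:
    cuts: Tuple[float, float] = RISK_CUTS
    labels: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class AgreementReport:
    pairwise_pct: pd.DataFrame
    cohen_kappa: pd.DataFrame
    fleiss: Tuple[float, float, float]
    strata_table: pd.DataFrame
    fisher_p: float
    metrics: Dict[str, float]


def consensus_labels(
    ratings: RatingsMatrix,
    rule: str = "majority",
    tie: str = "positive",
) -> np.ndarray:
    """Collapse per-rater votes into a single 0/1 consensus per case."""
    v = ratings.values
    if rule == "provided":
        if ratings.consensus is None:
            raise ValueError("rule='provided' requires a consensus column")
        return np.asarray(ratings.consensus, dtype=int)
    if rule == "unanimous":
        return (v.sum(axis=1) == v.shape[1]).astype(int)
    if rule == "majority":
        s = 2 * v.sum(axis=1)
        r = v.shape[1]
        if tie == "positive":
            return (s >= r).astype(int)
        if tie == "negative":
            return (s > r).astype(int)
        raise ValueError(f"unknown tie rule {tie!r}")
    raise ValueError(f"unknown consensus rule {rule!r}")


def pairwise_agreement(a: Sequence[int], b: Sequence[int]) -> float:
    """Percent of cases on which two label vectors agree, to 1 decimal."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return round(100.0 * float(np.mean(a == b)), 1)


def cohen_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Chance-corrected pairwise agreement."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if len(np.unique(np.concatenate([a, b]))) < 2:
        raise ValueError("kappa undefined: only one category present")
    return float(cohen_kappa_score(a, b))


def fleiss_kappa(values: np.ndarray) -> Tuple[float, float, float]:
    """Fleiss kappa over a case-by-rater matrix, with z and two-sided p.

    The z statistic uses the large-sample null variance
    se0 = sqrt(2/(N n (n-1))) * sqrt((sum p_j q_j)^2 - sum p_j q_j (q_j - p_j))
          / (sum p_j q_j).
    """
    v = np.asarray(values, dtype=int)
    N, n = v.shape
    cats = np.unique(v)
    if cats.size < 2:
        raise ValueError("kappa undefined: only one category present")
    counts = np.stack([(v == c).sum(axis=1) for c in cats], axis=1)
    p_j = counts.sum(axis=0) / (N * n)
    P_i = (np.sum(counts**2, axis=1) - n) / (n * (n - 1))
    P_bar = float(P_i.mean())
    P_e = float(np.sum(p_j**2))
    if P_e >= 1.0:
        raise ValueError("degenerate marginal distribution")
    kappa = (P_bar - P_e) / (1 - P_e)
    q_j = 1 - p_j
    pq = float(np.sum(p_j * q_j))
    se0 = (
        np.sqrt(2.0 / (N * n * (n - 1)))
        * np.sqrt(pq**2 - float(np.sum(p_j * q_j * (q_j - p_j))))
        / pq
    )
    z = kappa / se0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(z), float(p)


def risk_categories(
    probs: Sequence[float], cuts: Tuple[float, float] = RISK_CUTS
) -> np.ndarray:
    """Map probabilities to low / intermediate / high.

    Boundaries are inclusive for the intermediate band:
    low iff p < cuts[0]; intermediate iff cuts[0] <= p <= cuts[1];
    high iff p > cuts[1].
    """
    p = np.asarray(probs, dtype=float)
    out = np.where(p < cuts[0], 0, np.where(p > cuts[1], 2, 1))
    return out


def review_outcome_3way(values: np.ndarray) -> np.ndarray:
    """0 = unanimous no, 1 = dissenting, 2 = unanimous yes, per case."""
    v = np.asarray(values, dtype=int)
    s = v.sum(axis=1)
    r = v.shape[1]
    return np.where(s == 0, 0, np.where(s == r, 2, 1))


def _table_logpmf(table: np.ndarray) -> float:
    """Log-probability of an r x c table under fixed margins."""
    from scipy.special import gammaln

    t = np.asarray(table)
    rs, cs = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(rs + 1).sum()
        + gammaln(cs + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact_mc(
    table: np.ndarray, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher exact p for an r x c table.

    Samples tables with the observed margins and accumulates the
    probability mass of tables no more likely than the observed one;
    2 x 2 inputs are validated against the closed-form test elsewhere.
    """
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("table has an empty margin; drop it first")
    dist = stats.random_table(rows, cols)
    obs = _table_logpmf(t)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 100_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        samples = dist.rvs(m, random_state=rng)
        lp = np.array([_table_logpmf(s) for s in samples])
        hits += int(np.count_nonzero(lp <= obs + 1e-9))
        done += m
    return (hits + 1) / (n_draws + 1)


def stratify_and_test(
    probs: Sequence[float],
    ratings_values: np.ndarray,
    cuts: Tuple[float, float] = RISK_CUTS,
    n_draws: int = 200_000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, float]:
    """Cross review outcome (3-way) with risk category and test association."""
    p = np.asarray(probs, dtype=float)
    v = np.asarray(ratings_values, dtype=int)
    if p.size != v.shape[0]:
        raise ValueError("probs and ratings must cover the same cases")
    outcome = review_outcome_3way(v)
    risk = risk_categories(p, cuts)
    table = np.zeros((3, 3), dtype=int)
    for o, r in zip(outcome, risk):
        table[o, r] += 1
    df = pd.DataFrame(table, index=list(OUTCOME_LABELS), columns=list(RISK_LABELS))
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping empty strata before the exact test", UserWarning)
    trimmed = table[np.ix_(keep_rows, keep_cols)]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        return df, 1.0
    pval = fisher_exact_mc(trimmed, n_draws=n_draws, seed=seed)
    return df, float(pval)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(
    probs: Sequence[float],
    consensus: Sequence[int],
    threshold: float = 0.5,
) -> Dict[str, float]:
    """AUC (midrank ties) plus thresholded precision/recall/F1."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(consensus, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: consensus contains a single class")
    pred = (p >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y, p)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
    }


def build_agreement_report(
    ratings: RatingsMatrix,
    probs: Sequence[float],
    threshold: float = 0.5,
    consensus_rule: str = "provided",
    seed: int = 0,
    n_draws: int = 200_000,
) -> AgreementReport:
    """Assemble the full agreement analysis for a reviewed sample."""
    p = np.asarray(probs, dtype=float)
    cons = consensus_labels(ratings, rule=consensus_rule)
    model = (p >= threshold).astype(int)
    columns = [str(r) for r in ratings.raters] + ["model", "consensus"]
    vectors = [ratings.values[:, j] for j in range(ratings.values.shape[1])]
    vectors += [model, cons]
    m = len(columns)
    pct = np.zeros((m, m))
    kap = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            pct[i, j] = pairwise_agreement(vectors[i], vectors[j])
            if i != j:
                try:
                    kap[i, j] = cohen_kappa(vectors[i], vectors[j])
                except ValueError:
                    pass
            else:
                kap[i, j] = 1.0
    fleiss = fleiss_kappa(ratings.values)
    strata, fisher_p = stratify_and_test(p, ratings.values, seed=seed, n_draws=n_draws)
    metrics = classification_metrics(p, cons, threshold)
    return AgreementReport(
        pairwise_pct=pd.DataFrame(pct, index=columns, columns=columns),
        cohen_kappa=pd.DataFrame(kap, index=columns, columns=columns),
        fleiss=fleiss,
        strata_table=strata,
        fisher_p=fisher_p,
        metrics=metrics,
    )
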