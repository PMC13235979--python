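"""Audit design and bias-only logit-shift recalibration.

A stratified chart-review sample (one record per probability bin) yields
a gold-standard positive count; a single constant c added to all logits
makes the probability sum match that count, and a with-replacement
bootstrap over the reviewed cases gives a percentile CI for c.  Applying
the fitted shift to the full unlabeled population extrapolates the
audited prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ProbabilityRecord",
    "ShiftCalibration",
    "ReviewDesign",
    "sample_review_bins",
    "solve_shift",
    "apply_shift",
    "bootstrap_shift",
    "extrapolate_prevalence",
]

_C_BOUND = 60.0  # probabilities are clipped to 1e-6, so |logit| < 14 and any
# attainable target sum has its root well inside +-60


@dataclass(frozen=True)
class ProbabilityRecord:
    record_id: str
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("probability must lie strictly inside (0, 1)")

    @property
    def l(self) -> float:
        return float(logit(self.p))


@dataclass
class ShiftCalibration:
    c_hat: float
    target_sum: float
    bootstrap_c: np.ndarray
    ci_95: Tuple[float, float]
    B: int
    n_redraws: int = 0


@dataclass
class ReviewDesign:
    bin_width: float
    bins: Dict[int, str]  # bin index -> sampled record_id
    probs: Dict[int, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_sampled(self) -> int:
        return len(self.bins)


def sample_review_bins(
    calibrated_probs: Sequence[float],
    record_ids: Optional[Sequence[str]] = None,
    bin_width: float = 0.01,
    seed: int = 0,
) -> ReviewDesign:
    """Pick one uniformly random record from every nonempty probability bin.

    Bins are half-open [j*w, (j+1)*w) with the final bin closed at 1.
    """
    p = np.asarray(calibrated_probs, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability set")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if record_ids is None:
        record_ids = np.array([str(i) for i in range(p.size)])
    record_ids = np.asarray(record_ids)
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((p / bin_width).astype(int), n_bins - 1)
    rng = np.random.default_rng(seed)
    bins: Dict[int, str] = {}
    probs: Dict[int, float] = {}
    for j in np.unique(idx):
        members = np.flatnonzero(idx == j)
        pick = members[rng.integers(members.size)]
        bins[int(j)] = str(record_ids[pick])
        probs[int(j)] = float(p[pick])
    return ReviewDesign(bin_width=bin_width, bins=bins, probs=probs, seed=seed)


def _shift_sum(logits: np.ndarray, c) -> np.ndarray:
    return expit(logits + c).sum(axis=-1)


def solve_shift(logits: Sequence[float], target_sum: float) -> float:
    """Solve sum_i sigmoid(l_i + c) = target_sum for the unique c.

    The sum is continuous and strictly increasing in c, so a bracketed
    root-finder applies; the root is polished until the residual is at
    most 1e-9 in the sum.
    """
    l = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(l)):
        raise ValueError("logits must be finite (clip probabilities first)")
    n = l.size
    if not 0.0 < target_sum < n:
        raise ValueError(
            f"target_sum must lie strictly between 0 and n={n}; got {target_sum}"
        )
    f = lambda c: _shift_sum(l, c) - target_sum
    c = brentq(f, -_C_BOUND, _C_BOUND, xtol=1e-13, rtol=8.9e-16)
    # Newton polish: derivative sum p(1-p) > 0
    for _ in range(8):
        resid = f(c)
        if abs(resid) <= 1e-10:
            break
        p = expit(l + c)
        deriv = np.sum(p * (1 - p))
        if deriv <= 0:
            break
        c -= resid / deriv
    if abs(f(c)) > 1e-9:
        raise RuntimeError("shift root residual exceeds 1e-9")
    return float(c)


def solve_shift_many(logit_rows: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Vectorized bisection: one shift per row of ``logit_rows``.

    Used by the bootstrap, where many small root problems are solved at
    once; 90 bisection steps bound the root error below 1e-25.
    """
    lo = np.full(len(targets), -_C_BOUND)
    hi = np.full(len(targets), _C_BOUND)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        s = _shift_sum(logit_rows, mid[:, None])
        too_low = s < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def apply_shift(probs: Sequence[float], c: float) -> np.ndarray:
    """Elementwise sigmoid(logit(p) + c); strictly order-preserving."""
    p = np.asarray(probs, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if c == 0:
        return p.copy()
    return expit(logit(p) + c)


def bootstrap_shift(
    probs: Sequence[float],
    labels: Sequence[int],
    B: int = 100_000,
    seed: int = 0,
) -> ShiftCalibration:
    """Point shift plus percentile bootstrap over the reviewed cases.

    ``probs`` are the model probabilities of the reviewed records and
    ``labels`` their consensus 0/1 outcomes.  Resamples with a degenerate
    label sum (0 or n) admit no finite root and are redrawn; the count of
    redraws is recorded.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size != y.size:
        raise ValueError("probs and labels must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 reviewed records")
    if y.min() == y.max():
        raise ValueError("all consensus labels identical: no finite shift exists")
    l = logit(p)
    target = float(y.sum())
    c_hat = solve_shift(l, target)

    rng = np.random.default_rng(seed)
    n = p.size
    idx = rng.integers(0, n, size=(B, n))
    sums = y[idx].sum(axis=1)
    n_redraws = 0
    bad = np.flatnonzero((sums == 0) | (sums == n))
    while bad.size:
        n_redraws += bad.size
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        sums[bad] = y[idx[bad]].sum(axis=1)
        bad = np.flatnonzero((sums == 0) | (sums == n))

    # chunked vectorized solve to bound memory at large B
    boot = np.empty(B)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    for start in range(0, B, chunk):
        sl = slice(start, min(start + chunk, B))
        boot[sl] = solve_shift_many(l[idx[sl]], sums[sl].astype(float))
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return ShiftCalibration(
        c_hat=c_hat,
        target_sum=target,
        bootstrap_c=boot,
        ci_95=ci,
        B=B,
        n_redraws=n_redraws,
    )


def extrapolate_prevalence(
    all_unlabeled_probs: Sequence[float],
    calib: ShiftCalibration,
) -> tuple[float, float, Tuple[float, float]]:
    """Apply the fitted shift (and its CI bounds) to the full population.

    Returns (adjusted_sum, rate, (rate_low, rate_high)).
    """
    p = np.asarray(all_unlabeled_probs, dtype=float)
    adjusted = apply_shift(p, calib.c_hat)
    adjusted_sum = float(adjusted.sum())
    n = p.size
    rate = adjusted_sum / n
    lo = float(apply_shift(p, calib.ci_95[0]).sum()) / n
    hi = float(apply_shift(p, calib.ci_95[1]).sum()) / n
    return adjusted_sum, rate, (lo, hi)


def calibrate_to_alpha(raw_probs_U: Sequence[float], alpha: float) -> np.ndarray:
    """Shift unlabeled probabilities so they sum to alpha * |U|.

    The same bias-only logit-shift primitive used for chart-review
    calibration, anchored to an estimated class prior instead of an
    audited count.  Ordering is preserved.
    """
    p = np.asarray(raw_probs_U, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n = p.size
    if n == 0:
        raise ValueError("empty probability vector")
    target = alpha * n
    eps = 1e-6
    if target <= 0:
        warnings.warn(
            "alpha*|U| is zero; shifting to the minimal positive target",
            UserWarning,
            stacklevel=2,
        )
        target = eps * n
    elif target >= n:
        warnings.warn(
            "alpha*|U| equals |U|; shifting to the maximal attainable target",
            UserWarning,
            stacklevel=2,
        )
        target = n * (1 - eps)
    c = solve_shift(logit(np.clip(p, 1e-12, 1 - 1e-12)), target)
    return apply_shift(p, c)
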