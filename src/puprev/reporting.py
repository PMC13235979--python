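"""Cohort characterization and prevalence assembly.

Odds ratios with Wald CIs, proportion confidence intervals, and the
arithmetic that combines a coded count, an estimated class prior, and a
calibrated adjusted-probability sum into prevalence figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyStats",
    "PrevalenceReport",
    "odds_ratio",
    "proportion_ci",
    "assemble_prevalence",
    "ratio_percent",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencyStats:
    a: float
    b: float
    c: float
    d: float
    or_: float
    ci_95: Tuple[float, float]
    corrected: bool = False


@dataclass
class PrevalenceReport:
    n_total: int
    n_coded: int
    coded_rate: float
    coded_rate_ci: Tuple[float, float]
    alpha: float
    imputed_sum: float
    combined_rate: float
    calibrated_combined_rate: Optional[float] = None
    calibrated_combined_rate_ci: Optional[Tuple[float, float]] = None
    coded_fraction_of_documented: Optional[float] = None
    coded_fraction_ci: Optional[Tuple[float, float]] = None


def ratio_percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """A printed-ratio helper: 100*num/den rounded half-to-even."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return float(np.round(100.0 * numerator / denominator, decimals))


def odds_ratio(a: float, b: float, c: float, d: float, correction: bool = False) -> ContingencyStats:
    """Cross-product odds ratio with a Wald CI on the log scale.

    Zero cells make the OR or its CI undefined; with ``correction`` 0.5
    is added to every cell (flagged on the result), otherwise an error is
    raised.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("counts must be nonnegative")
    corrected = False
    if np.any(cells == 0):
        if not correction:
            raise ValueError(
                "zero cell makes the odds ratio undefined; "
                "enable correction to add 0.5 to all cells"
            )
        cells = cells + 0.5
        corrected = True
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = float(np.exp(np.log(or_) - Z_95 * se))
    hi = float(np.exp(np.log(or_) + Z_95 * se))
    return ContingencyStats(a=a, b=b, c=c, d=d, or_=float(or_), ci_95=(lo, hi), corrected=corrected)


def proportion_ci(
    x: int, n: int, method: str = "wald"
) -> Tuple[float, Tuple[float, float]]:
    """Point proportion and 95% CI (Wald default, Wilson available)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    p = x / n
    if method == "wald":
        half = Z_95 * np.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    elif method == "wilson":
        lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(p), (float(lo), float(hi))


def assemble_prevalence(
    n_total: int,
    n_coded: int,
    alpha: float,
    adjusted_sum: Optional[float] = None,
    adjusted_sum_ci: Optional[Tuple[float, float]] = None,
) -> PrevalenceReport:
    """Combine coded counts, a class prior, and a calibrated sum.

    combined_rate = (n_coded + alpha * (n_total - n_coded)) / n_total.
    With a calibrated ``adjusted_sum`` over the unlabeled records, also
    reports (n_coded + adjusted_sum) / n_total and the coded fraction of
    all documented cases n_coded / (n_coded + adjusted_sum); CI bounds
    propagate from ``adjusted_sum_ci`` when given.
    """
    if not 0 <= n_coded <= n_total:
        raise ValueError("n_coded must lie in [0, n_total]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n_unl = n_total - n_coded
    coded_rate, coded_ci = proportion_ci(n_coded, n_total)
    imputed = alpha * n_unl
    combined = (n_coded + imputed) / n_total

    cal_rate = cal_ci = frac = frac_ci = None
    if adjusted_sum is not None:
        cal_rate = (n_coded + adjusted_sum) / n_total
        denom = n_coded + adjusted_sum
        frac = 1.0 if denom == 0 else n_coded / denom
        if adjusted_sum_ci is not None:
            lo_s, hi_s = adjusted_sum_ci
            cal_ci = ((n_coded + lo_s) / n_total, (n_coded + hi_s) / n_total)
            # a larger adjusted sum means a smaller coded share
            frac_ci = (n_coded / (n_coded + hi_s), n_coded / (n_coded + lo_s))
    return PrevalenceReport(
        n_total=n_total,
        n_coded=n_coded,
        coded_rate=coded_rate,
        coded_rate_ci=coded_ci,
        alpha=alpha,
        imputed_sum=imputed if adjusted_sum is None else float(adjusted_sum),
        combined_rate=combined,
        calibrated_combined_rate=cal_rate,
        calibrated_combined_rate_ci=cal_ci,
        coded_fraction_of_documented=frac,
        coded_fraction_ci=frac_ci,
    )
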