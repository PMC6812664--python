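"""Correlation inference, correlation comparison, skewness, and the
logistic summarisation of verification outcomes.

``fisher_z_compare`` tests whether two independent Pearson correlations
differ, using the variance-stabilising atanh transform:

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))

``fit_verification_curve`` summarises a batch of Monte-Carlo replicates:
a single-predictor logistic regression of the binary "threshold
hypothesis verified" outcome on the population correlation rho, giving
the predicted verification probability across the rho range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "ConditionSummary",
    "pearson_test",
    "fisher_z_compare",
    "sample_skewness",
    "fit_verification_curve",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input
    (constant vector, |r| = 1 in the atanh transform, n too small)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class CorrelationComparison:
    r_below: float
    n_below: int
    r_above: float
    n_above: int
    z_stat: float
    p: float


@dataclass(frozen=True)
class ConditionSummary:
    """Logistic summary of one simulation condition.

    When the outcomes carry no information for a logistic fit (all
    verified, none verified, or perfect separation) the summary is
    flagged ``degenerate`` and only the empirical rate is meaningful.
    """

    condition_id: str
    n: int
    skew_profile: str
    n_reps: int
    empirical_rate: float
    degenerate: bool
    intercept: float = float("nan")
    slope: float = float("nan")
    rho_grid: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    prob_curve: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def predicted_probability(self, rho) -> np.ndarray:
        """Verification probability at rho from the fitted logistic curve
        (constant empirical rate when degenerate)."""
        rho = np.asarray(rho, dtype=float)
        if self.degenerate:
            return np.full_like(rho, self.empirical_rate)
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * rho)))

    def to_row(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "n": self.n,
            "skew_profile": self.skew_profile,
            "n_reps": self.n_reps,
            "empirical_rate": self.empirical_rate,
            "degenerate": self.degenerate,
            "intercept": self.intercept,
            "slope": self.slope,
        }


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with the two-sided t-based p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 4:
        raise UndefinedStatisticError(f"correlation inference requires n >= 4, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=n, p=float(res.pvalue))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Normal-theory test that two independent correlations differ.

    ``z_stat`` is positive when r1 (the "below" group by convention)
    exceeds r2, and is exactly antisymmetric under swapping the groups;
    ``p`` is two-sided.
    """
    if n1 < 4 or n2 < 4:
        raise UndefinedStatisticError(f"both groups need n >= 4, got ({n1}, {n2})")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise UndefinedStatisticError("|r| = 1 has an infinite atanh transform")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(
        r_below=float(r1), n_below=int(n1), r_above=float(r2), n_above=int(n2),
        z_stat=float(z), p=float(p),
    )


def sample_skewness(x) -> float:
    """Standardised third central moment, m3 / m2^(3/2).

    The population-moment form with no small-sample bias correction.
    Cross-checked against ``scipy.stats.skew`` in the test suite.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise UndefinedStatisticError(f"skewness requires n >= 3, got {len(x)}")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0.0:
        raise UndefinedStatisticError("skewness undefined for constant input")
    m3 = np.mean(d * d * d)
    return float(m3 / m2 ** 1.5)


def fit_verification_curve(
    rhos,
    verified,
    *,
    condition_id: str = "",
    n: int = 0,
    skew_profile: str = "",
    grid_points: int = 101,
) -> ConditionSummary:
    """Logistic regression of the verification outcome on rho.

    Fits logit(P(verified)) = intercept + slope * rho by maximum
    likelihood and evaluates the probability curve on an even rho grid
    over [0, 1].  All-identical outcomes or perfect separation yield a
    degenerate summary carrying only the empirical rate.
    """
    rhos = np.asarray(rhos, dtype=float)
    verified = np.asarray(verified, dtype=bool)
    if len(rhos) != len(verified):
        raise ValueError(f"length mismatch: {len(rhos)} vs {len(verified)}")
    if len(rhos) == 0:
        raise ValueError("no replicates to summarise")
    rate = float(verified.mean())
    grid = np.linspace(0.0, 1.0, grid_points)
    common = dict(
        condition_id=condition_id, n=n, skew_profile=skew_profile,
        n_reps=len(rhos), empirical_rate=rate, rho_grid=grid,
    )
    if verified.all() or not verified.any():
        return ConditionSummary(degenerate=True, prob_curve=np.full(grid_points, rate),
                                **common)
    X = sm.add_constant(rhos)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(verified.astype(float), X).fit(disp=0, maxiter=200)
        separated = not np.isfinite(fit.bse).all() or np.abs(fit.params).max() > 1e3
    except Exception:
        separated = True
    if separated:
        return ConditionSummary(degenerate=True, prob_curve=np.full(grid_points, rate),
                                **common)
    intercept, slope = (float(v) for v in fit.params)
    curve = 1.0 / (1.0 + np.exp(-(intercept + slope * grid)))
    return ConditionSummary(degenerate=False, intercept=intercept, slope=slope,
                            prob_curve=curve, **common)
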