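"""The three-criterion threshold-hypothesis verdict for one cohort.

A cohort is said to support the threshold hypothesis if, and only if:

1. segmented regression of observed creativity on observed IQ finds a
   significant breakpoint (Wald p for the slope change < alpha);
2. the observed IQ-creativity correlation below the breakpoint is
   positive and significant;
3. that correlation is significantly larger below than above the
   breakpoint (Fisher r-to-z comparison), with the direction
   r_below > r_above enforced explicitly.

The breakpoint is never pre-specified; it is estimated from the same
data being tested.  A significant correlation *above* the breakpoint
does not veto verification.  Cohorts on which the breakpoint or either
side's correlation cannot be computed (too few points per side, constant
scores) are flagged ``estimable=False`` and count as unverified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import UndefinedStatisticError, fisher_z_compare, pearson_test
from .cohort import Cohort
from .segmented import BreakpointNotEstimable, SegmentedRegression, SegmentedResults

__all__ = ["VerificationResult", "verify_threshold", "MIN_SIDE_N"]

#: smallest per-side group size at which the correlation tests are defined
MIN_SIDE_N = 4


@dataclass(frozen=True)
class VerificationResult:
    """Three criterion booleans and their conjunction for one cohort."""

    psi: float
    breakpoint_significant: bool
    below_positive_significant: bool
    below_greater_above: bool
    verified: bool
    estimable: bool
    fit: SegmentedResults | None = None
    r_overall: float = float("nan")
    p_overall: float = float("nan")
    r_below: float = float("nan")
    p_below: float = float("nan")
    n_below: int = 0
    r_above: float = float("nan")
    p_above: float = float("nan")
    n_above: int = 0
    z_compare: float = float("nan")
    p_compare: float = float("nan")

    def to_row(self) -> dict:
        return {
            "psi": self.psi,
            "crit1": self.breakpoint_significant,
            "crit2": self.below_positive_significant,
            "crit3": self.below_greater_above,
            "verified": self.verified,
            "estimable": self.estimable,
            "r_overall": self.r_overall,
            "p_overall": self.p_overall,
            "r_below": self.r_below,
            "p_below": self.p_below,
            "n_below": self.n_below,
            "r_above": self.r_above,
            "p_above": self.p_above,
            "n_above": self.n_above,
            "z_compare": self.z_compare,
            "p_compare": self.p_compare,
        }


def _not_estimable(psi: float = float("nan"), **extra) -> VerificationResult:
    return VerificationResult(
        psi=psi,
        breakpoint_significant=False,
        below_positive_significant=False,
        below_greater_above=False,
        verified=False,
        estimable=False,
        **extra,
    )


def verify_threshold(cohort: Cohort, alpha_level: float = 0.05) -> VerificationResult:
    """Apply the three-criterion rule to one cohort's observed scores.

    Deterministic: the same cohort and alpha always give the same
    verdict, and raising alpha can only flip the verdict from False to
    True (every criterion is a ``p < alpha`` comparison combined with
    alpha-free direction checks).
    """
    x = np.asarray(cohort.observed_iq, dtype=float)
    y = np.asarray(cohort.observed_creativity, dtype=float)
    try:
        fit = SegmentedRegression(y, x).fit()
    except (BreakpointNotEstimable, ValueError):
        return _not_estimable()

    psi = fit.psi
    below = x <= psi
    above = ~below
    n_below, n_above = int(below.sum()), int(above.sum())
    if n_below < MIN_SIDE_N or n_above < MIN_SIDE_N:
        return _not_estimable(psi=psi, fit=fit, n_below=n_below, n_above=n_above)

    try:
        overall = pearson_test(x, y)
        cor_below = pearson_test(x[below], y[below])
        cor_above = pearson_test(x[above], y[above])
        comparison = fisher_z_compare(
            cor_below.r, cor_below.n, cor_above.r, cor_above.n
        )
    except UndefinedStatisticError:
        return _not_estimable(psi=psi, fit=fit, n_below=n_below, n_above=n_above)

    crit1 = fit.p_beta2 < alpha_level
    crit2 = cor_below.r > 0.0 and cor_below.p < alpha_level
    crit3 = cor_below.r > cor_above.r and comparison.p < alpha_level
    return VerificationResult(
        psi=psi,
        breakpoint_significant=crit1,
        below_positive_significant=crit2,
        below_greater_above=crit3,
        verified=crit1 and crit2 and crit3,
        estimable=True,
        fit=fit,
        r_overall=overall.r,
        p_overall=overall.p,
        r_below=cor_below.r,
        p_below=cor_below.p,
        n_below=n_below,
        r_above=cor_above.r,
        p_above=cor_above.p,
        n_above=n_above,
        z_compare=comparison.z_stat,
        p_compare=comparison.p,
    )
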