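"""Broken-line (segmented) regression with an empirically chosen breakpoint.

The mean function is continuous piecewise-linear with a single knot:

    E[y | z] = beta0 + beta1 * z + beta2 * (z - psi) * I(z > psi)

where ``psi`` is the breakpoint, ``beta1`` the slope below it and
``beta2`` the slope *change* above it; the two fitted lines join at
``psi``.  The breakpoint is not pre-specified: every distinct observed
predictor value inside an admissible central range is profiled as a
candidate knot, an OLS fit is evaluated at each, and the candidate
optimising the selection criterion (minimum residual sum of squares by
default, largest ``|beta2|`` as an option) is chosen.  Inference on
``beta2`` is the Wald t-test from the OLS fit at the selected knot,
treating the knot as known — see the methods note for the caveat this
carries.

The candidate profile is computed in closed form from one pass of
cumulative sums (per-candidate normal equations are 3x3 and share two
columns), so profiling scales as O(n log n + m) rather than m separate
regressions.  Tests verify it against a naive per-candidate
least-squares loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SegmentedRegression",
    "SegmentedResults",
    "BreakpointNotEstimable",
    "fit_segmented",
    "predict_segmented",
]


class BreakpointNotEstimable(Exception):
    """No admissible candidate breakpoint exists for this dataset.

    Distinct from a *non-significant* breakpoint: raised when the data
    cannot support the profile at all (too few points, too few distinct
    predictor values, or every candidate leaves a degenerate design).
    """


@dataclass(frozen=True)
class SegmentedResults:
    """Parameter estimates and inference for one segmented fit.

    Attributes mirror the broken-line model: ``beta0`` intercept,
    ``beta1`` below-knot slope, ``beta2`` slope change above the knot,
    ``psi`` the selected breakpoint, with the Wald standard error and
    two-sided p-value for ``beta2`` and a profile-based 95% interval for
    ``psi``.
    """

    beta0: float
    beta1: float
    beta2: float
    psi: float
    se_beta2: float
    p_beta2: float
    sse: float
    n: int
    psi_ci_low: float
    psi_ci_high: float
    #: full candidate profile: columns psi, sse, beta2
    profile: pd.DataFrame
    selection: str

    def predict(self, z) -> np.ndarray:
        """Evaluate the fitted broken-line mean function at ``z``."""
        z = np.asarray(z, dtype=float)
        hinge = np.where(z > self.psi, z - self.psi, 0.0)
        return self.beta0 + self.beta1 * z + self.beta2 * hinge

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"beta0": self.beta0, "beta1": self.beta1, "beta2": self.beta2, "psi": self.psi}
        )

    def to_row(self) -> dict:
        """Flatten to the canonical one-row CSV schema."""
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "psi": self.psi,
            "se_beta2": self.se_beta2,
            "p_beta2": self.p_beta2,
            "sse": self.sse,
            "n": self.n,
            "psi_ci_low": self.psi_ci_low,
            "psi_ci_high": self.psi_ci_high,
        }

    def summary(self) -> str:
        lines = [
            "Segmented (broken-line) regression",
            "==================================",
            f"n observations      {self.n:>12d}",
            f"selection           {self.selection:>12s}",
            f"breakpoint psi      {self.psi:>12.4f}   95% CI [{self.psi_ci_low:.4f}, {self.psi_ci_high:.4f}]",
            f"beta0 (intercept)   {self.beta0:>12.4f}",
            f"beta1 (slope below) {self.beta1:>12.4f}",
            f"beta2 (slope change){self.beta2:>12.4f}   SE {self.se_beta2:.4f}   p {self.p_beta2:.4g}",
            f"residual SS         {self.sse:>12.4f}",
        ]
        return "\n".join(lines)


class SegmentedRegression:
    """Model object for a single-knot broken-line regression.

    Parameters
    ----------
    endog : array-like
        Outcome vector ``y``.
    exog : array-like
        Predictor vector ``z`` (one-dimensional; the design with
        intercept and hinge column is built internally).
    min_per_side : int
        Minimum observations required on each side of a candidate knot
        (default 5), so no candidate leaves a near-empty segment.
    quantile_range : (float, float)
        Candidate knots are distinct observed predictor values between
        these quantiles of ``exog`` (default 10th-90th percentile).
    """

    #: relative tolerance within which candidates count as tied; ties
    #: resolve to the smallest psi, deterministically
    TIE_RTOL = 1e-10

    def __init__(self, endog, exog, *, min_per_side: int = 5,
                 quantile_range: tuple[float, float] = (0.10, 0.90)):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("endog and exog must be one-dimensional")
        if len(x) != len(y):
            raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("endog and exog must be finite")
        self.endog = y
        self.exog = x
        self.min_per_side = int(min_per_side)
        self.quantile_range = quantile_range
        self.nobs = len(x)

    @classmethod
    def from_cohort(cls, cohort, use: str = "observed", **kwargs) -> "SegmentedRegression":
        """Build the model from a Cohort: predictor IQ, outcome creativity."""
        if use == "observed":
            return cls(cohort.observed_creativity, cohort.observed_iq, **kwargs)
        if use == "true":
            return cls(cohort.true_creativity, cohort.true_iq, **kwargs)
        raise ValueError(f"use must be 'observed' or 'true', got {use!r}")

    def candidate_breakpoints(self) -> np.ndarray:
        """Admissible candidate knots, ascending.

        Distinct observed predictor values v with
        ``q10 <= v <= q90``, at least ``min_per_side`` observations at or
        below v and at least ``min_per_side`` strictly above v.
        """
        x = self.exog
        lo, hi = np.quantile(x, self.quantile_range)
        values = np.unique(x)
        values = values[(values >= lo) & (values <= hi)]
        if values.size == 0:
            return values
        xs = np.sort(x)
        n_at_or_below = np.searchsorted(xs, values, side="right")
        ok = (n_at_or_below >= self.min_per_side) & (
            self.nobs - n_at_or_below >= self.min_per_side
        )
        return values[ok]

    # -- closed-form candidate profile -------------------------------------

    def _profile(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """SSE and coefficients at every admissible candidate knot.

        Returns ``(candidates, sse, betas)`` with ``betas`` of shape
        (m, 3) in original units.  Works on centred x and y for
        conditioning; only the intercept needs translating back.
        """
        cands = self.candidate_breakpoints()
        if cands.size == 0:
            raise BreakpointNotEstimable(
                f"no admissible candidate breakpoint (n={self.nobs}, "
                f"min_per_side={self.min_per_side})"
            )
        xbar = self.exog.mean()
        ybar = self.endog.mean()
        order = np.argsort(self.exog, kind="stable")
        xc = self.exog[order] - xbar
        yc = self.endog[order] - ybar
        cc = cands - xbar
        n = float(self.nobs)

        # shared moments
        Sx, Sx2 = xc.sum(), (xc * xc).sum()
        Sy, Sxy, Syy = yc.sum(), (xc * yc).sum(), (yc * yc).sum()

        # suffix sums over subjects strictly above each candidate
        idx = np.searchsorted(xc, cc, side="right")
        rx = np.concatenate([np.cumsum(xc[::-1])[::-1], [0.0]])
        rx2 = np.concatenate([np.cumsum((xc * xc)[::-1])[::-1], [0.0]])
        ry = np.concatenate([np.cumsum(yc[::-1])[::-1], [0.0]])
        rxy = np.concatenate([np.cumsum((xc * yc)[::-1])[::-1], [0.0]])
        rn = (len(xc) - idx).astype(float)

        T1, T2 = rx[idx], rx2[idx]
        Ty, Txy = ry[idx], rxy[idx]
        # hinge-column moments: h_i = (x_i - psi) for x_i > psi
        S1 = T1 - cc * rn
        S2 = T2 - 2.0 * cc * T1 + cc * cc * rn
        Sxh = T2 - cc * T1
        Syh = Txy - cc * Ty

        m = cands.size
        XtX = np.empty((m, 3, 3))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = Sx
        XtX[:, 0, 2] = XtX[:, 2, 0] = S1
        XtX[:, 1, 1] = Sx2
        XtX[:, 1, 2] = XtX[:, 2, 1] = Sxh
        XtX[:, 2, 2] = S2
        Xty = np.stack([np.full(m, Sy), np.full(m, Sxy), Syh], axis=1)

        # mask candidates whose design is numerically singular
        dets = np.linalg.det(XtX)
        scale = n * Sx2 * np.maximum(S2, 1.0)
        good = np.abs(dets) > 1e-12 * np.maximum(scale, 1.0)
        if not good.any():
            raise BreakpointNotEstimable("all candidate designs are singular")
        betas_c = np.full((m, 3), np.nan)
        betas_c[good] = np.linalg.solve(XtX[good], Xty[good][:, :, None])[:, :, 0]
        sse = np.full(m, np.inf)
        sse[good] = Syy - np.einsum("ij,ij->i", betas_c[good], Xty[good])
        sse = np.maximum(sse, 0.0)

        # translate centred coefficients back to original units
        betas = betas_c.copy()
        betas[:, 0] = betas_c[:, 0] + ybar - betas_c[:, 1] * xbar
        return cands, sse, betas

    def fit(self, selection: str = "sse") -> SegmentedResults:
        """Profile all candidate knots and return the fit at the optimum.

        ``selection="sse"`` (default) minimises the residual sum of
        squares; ``selection="max_beta2"`` picks the candidate with the
        largest absolute slope change.  Ties within relative tolerance
        resolve to the smallest breakpoint.
        """
        cands, sse, betas = self._profile()
        finite = np.isfinite(sse)
        if selection == "sse":
            best = sse[finite].min()
            tied = finite & (sse <= best * (1.0 + self.TIE_RTOL) + 1e-300)
        elif selection == "max_beta2":
            absb2 = np.where(finite, np.abs(betas[:, 2]), -np.inf)
            best = absb2.max()
            tied = absb2 >= best * (1.0 - self.TIE_RTOL)
        else:
            raise ValueError(f"selection must be 'sse' or 'max_beta2', got {selection!r}")
        psi = float(cands[tied].min())
        k = int(np.flatnonzero(tied & (cands == psi))[0])

        # Wald inference at the selected knot, treating psi as known
        hinge = np.where(self.exog > psi, self.exog - psi, 0.0)
        X = np.column_stack([np.ones(self.nobs), self.exog, hinge])
        ols = sm.OLS(self.endog, X).fit()
        ci_low, ci_high = self._psi_interval(cands, sse)
        return SegmentedResults(
            beta0=float(ols.params[0]),
            beta1=float(ols.params[1]),
            beta2=float(ols.params[2]),
            psi=psi,
            se_beta2=float(ols.bse[2]),
            p_beta2=float(ols.pvalues[2]),
            sse=float(ols.ssr),
            n=self.nobs,
            psi_ci_low=ci_low,
            psi_ci_high=ci_high,
            profile=pd.DataFrame({"psi": cands, "sse": sse, "beta2": betas[:, 2]}),
            selection=selection,
        )

    def _psi_interval(self, cands, sse, level: float = 0.95) -> tuple[float, float]:
        """Profile interval for psi from the SSE profile.

        Under Gaussian errors, 2*(l_max - l(psi)) = n*log(SSE(psi)/SSE_min);
        candidates below the chi-square(1) cut form the interval.  With a
        zero-SSE optimum the interval degenerates to the knot itself.
        """
        finite = np.isfinite(sse)
        sse_min = sse[finite].min()
        if sse_min <= 0.0:
            psi = cands[finite][np.argmin(sse[finite])]
            return float(psi), float(psi)
        cut = sse_min * np.exp(stats.chi2.ppf(level, df=1) / self.nobs)
        inside = cands[finite & (sse <= cut)]
        return float(inside.min()), float(inside.max())


def fit_segmented(x, y, *, selection: str = "sse", min_per_side: int = 5,
                  quantile_range: tuple[float, float] = (0.10, 0.90)) -> SegmentedResults:
    """Functional one-shot interface: fit y on x with an estimated knot."""
    return SegmentedRegression(
        y, x, min_per_side=min_per_side, quantile_range=quantile_range
    ).fit(selection=selection)


def predict_segmented(fit: SegmentedResults, z) -> np.ndarray:
    """Evaluate a fitted broken-line mean function at predictor value(s) z."""
    return fit.predict(z)
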