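import numpy as np
import pytest

from thresholdsim import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def piecewise_exact():
    """Noiseless broken line: slope 1 up to the knot at 50, flat above."""
    x = np.linspace(0.0, 100.0, 101)
    y = np.where(x < 50.0, x, 50.0)
    return x, y


@pytest.fixture
def null_cohort():
    """A no-disturbance cohort: observed scores identical to true scores."""
    config = SimulationConfig(n=400, rho=0.6, disturbance_enabled=False, seed=99)
    return generate_cohort(config)


@pytest.fixture
def disturbed_cohort():
    """A weak-correlation cohort under negatively skewed disturbance."""
    config = SimulationConfig(
        n=400, rho=0.1, beta_alpha=9.0, beta_beta=1.0, seed=42
    )
    return generate_cohort(config)


def brute_force_breakpoint(x, y, min_per_side=5, quantile_range=(0.10, 0.90)):
    """Independent oracle: exhaustive per-candidate least-squares profile.

    Returns (psi, sse) at the SSE-minimising candidate knot, scanning
    candidates in ascending order so ties resolve to the smallest psi,
    with each candidate fitted by a separate lstsq call.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = np.quantile(x, quantile_range)
    xs = np.sort(x)
    best_psi, best_sse = None, np.inf
    for v in np.unique(x):
        if not (lo <= v <= hi):
            continue
        n_below = np.searchsorted(xs, v, side="right")
        if n_below < min_per_side or len(x) - n_below < min_per_side:
            continue
        hinge = np.where(x > v, x - v, 0.0)
        X = np.column_stack([np.ones_like(x), x, hinge])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ beta) ** 2).sum())
        if sse < best_sse * (1.0 - 1e-12):
            best_psi, best_sse = float(v), sse
    return best_psi, best_sse
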