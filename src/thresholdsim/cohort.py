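"""Virtual-cohort generation under a shared multiplicative disturbance.

A cohort consists of paired "true" ability scores (intelligence and
creativity) drawn from a bivariate normal distribution with a specified
population correlation, plus a per-subject disturbance factor in [0, 1]
drawn from a beta distribution.  Observed scores are the elementwise
product ``true * disturbance`` — the *same* disturbance value attenuates
both traits of a subject, so a low value (high disturbance: low
motivation, illness, linguistic confusion, ...) drags both observed
scores toward zero simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "Cohort",
    "draw_true_scores",
    "draw_disturbance",
    "apply_disturbance",
    "generate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "OSF_COLUMN_MAP",
]

#: Column-rename table mapping the deposited worked-example dataset's
#: column names onto the canonical cohort schema.  The deposited CSV uses
#: abbreviated names; any of the aliases on the left is accepted.
OSF_COLUMN_MAP: dict[str, str] = {
    "true.iq": "true_iq",
    "true.crea": "true_creativity",
    "true.creativity": "true_creativity",
    "dist": "disturbance",
    "disturb": "disturbance",
    "obs.iq": "observed_iq",
    "obs.crea": "observed_creativity",
    "obs.creativity": "observed_creativity",
    "iq": "observed_iq",
    "crea": "observed_creativity",
}

_CANONICAL_COLUMNS = (
    "true_iq",
    "true_creativity",
    "disturbance",
    "observed_iq",
    "observed_creativity",
)


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is outside its admissible range."""


@dataclass(frozen=True)
class SimulationConfig:
    """All generative and inferential knobs for one virtual cohort.

    Parameters
    ----------
    n : int
        Number of virtual subjects (>= 4).
    true_mean, true_sd : float
        Mean and SD of both true-score marginals, in IQ-style score units.
        Defaults 100 and 15; the worked example uses mean 120.
    rho : float or "uniform"
        Population correlation between the two true scores, in [0, 1].
        The token ``"uniform"`` means: draw rho ~ U(0, 1) afresh for each
        generated cohort (the per-replicate design of the Monte-Carlo
        arms).
    beta_alpha, beta_beta : float
        Shape parameters of the Beta disturbance distribution.  (9, 1) is
        negatively skewed (most subjects barely disturbed), (1, 9)
        positively skewed, (9, 9) approximately symmetric.
    disturbance_enabled : bool
        If False the disturbance vector is all ones and observed scores
        equal true scores exactly (the null arm).
    alpha_level : float
        Significance level used by downstream verification, in (0, 1).
    seed : int or None
        Root RNG seed; ``rng()`` builds a generator from it.
    """

    n: int
    true_mean: float = 100.0
    true_sd: float = 15.0
    rho: Union[float, str] = "uniform"
    beta_alpha: float = 9.0
    beta_beta: float = 1.0
    disturbance_enabled: bool = True
    alpha_level: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 4:
            raise ConfigurationError(f"n must be an integer >= 4, got {self.n!r}")
        if self.true_sd <= 0:
            raise ConfigurationError(f"true_sd must be positive, got {self.true_sd!r}")
        if isinstance(self.rho, str):
            if self.rho != "uniform":
                raise ConfigurationError(
                    f"rho must be a number in [0, 1] or 'uniform', got {self.rho!r}"
                )
        elif not 0.0 <= float(self.rho) <= 1.0:
            raise ConfigurationError(f"rho must lie in [0, 1], got {self.rho!r}")
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ConfigurationError(
                f"beta shapes must be positive, got ({self.beta_alpha!r}, {self.beta_beta!r})"
            )
        if not 0.0 < self.alpha_level < 1.0:
            raise ConfigurationError(
                f"alpha_level must lie in (0, 1), got {self.alpha_level!r}"
            )

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded from ``seed`` (or OS entropy if None)."""
        return np.random.default_rng(self.seed)

    def with_rho(self, rho: float) -> "SimulationConfig":
        return replace(self, rho=float(rho))


@dataclass(frozen=True)
class Cohort:
    """One virtual sample: true, disturbance and observed score vectors.

    Invariants (enforced at construction): all five vectors share one
    length; disturbance lies in [0, 1]; observed scores are the
    elementwise product of true scores and disturbance.
    """

    true_iq: np.ndarray
    true_creativity: np.ndarray
    disturbance: np.ndarray
    observed_iq: np.ndarray
    observed_creativity: np.ndarray
    #: population correlation used to generate the true scores (NaN when
    #: the cohort was loaded from a file and the value is unknown).
    rho: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        lengths = {
            len(self.true_iq),
            len(self.true_creativity),
            len(self.disturbance),
            len(self.observed_iq),
            len(self.observed_creativity),
        }
        if len(lengths) != 1:
            raise ValueError(f"cohort vectors have unequal lengths: {sorted(lengths)}")
        d = np.asarray(self.disturbance)
        if d.size and (d.min() < 0.0 or d.max() > 1.0):
            raise ValueError("disturbance values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.true_iq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _CANONICAL_COLUMNS})


def draw_true_scores(
    n: int,
    mean: float,
    sd: float,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two length-``n`` normal vectors with population correlation ``rho``.

    Both marginals are Normal(mean, sd).  The pair is built by the
    conditional-normal construction: with z1, e independent standard
    normals, ``z2 = rho*z1 + sqrt(1 - rho^2)*e`` has unit variance and
    correlation rho with z1; both are then rescaled to (mean, sd).
    """
    if n < 2:
        raise ConfigurationError(f"n must be >= 2, got {n}")
    if sd <= 0:
        raise ConfigurationError(f"sd must be positive, got {sd}")
    if not 0.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must lie in [0, 1], got {rho}")
    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * e
    return mean + sd * z1, mean + sd * z2


def draw_disturbance(
    n: int,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` disturbance factors from Beta(alpha, beta) on [0, 1].

    Low value = high disturbance.  Beta(9, 1) concentrates near 1 (most
    subjects nearly undisturbed, a negatively skewed factor); Beta(1, 9)
    is its mirror; Beta(9, 9) is approximately normal around 0.5.
    """
    if alpha <= 0 or beta <= 0:
        raise ConfigurationError(
            f"beta shapes must be positive, got ({alpha}, {beta})"
        )
    return rng.beta(alpha, beta, size=n)


def apply_disturbance(true_scores: np.ndarray, disturbance: np.ndarray) -> np.ndarray:
    """Elementwise attenuation: observed = true * disturbance.

    With all-positive true scores the observed score lies between zero
    and the true score.
    """
    t = np.asarray(true_scores, dtype=float)
    d = np.asarray(disturbance, dtype=float)
    if t.shape != d.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {d.shape}")
    return t * d


def generate_cohort(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Generate one cohort under ``config``.

    Draw order is fixed (rho if "uniform", then true scores, then
    disturbance) so a given seed always yields the same cohort.  With
    ``disturbance_enabled=False`` the disturbance is all ones and the
    observed vectors are bit-identical to the true vectors.
    """
    if rng is None:
        rng = config.rng()
    rho = rng.uniform(0.0, 1.0) if config.rho == "uniform" else float(config.rho)
    true_iq, true_cr = draw_true_scores(
        config.n, config.true_mean, config.true_sd, rho, rng
    )
    if config.disturbance_enabled:
        dist = draw_disturbance(config.n, config.beta_alpha, config.beta_beta, rng)
        obs_iq = apply_disturbance(true_iq, dist)
        obs_cr = apply_disturbance(true_cr, dist)
    else:
        dist = np.ones(config.n)
        obs_iq = true_iq
        obs_cr = true_cr
    return Cohort(true_iq, true_cr, dist, obs_iq, obs_cr, rho=rho)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as plain CSV with the canonical five-column header."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV, accepting the deposited dataset's column names.

    Columns are renamed via :data:`OSF_COLUMN_MAP`; any canonical column
    still missing after renaming is reconstructed where possible
    (observed = true * disturbance, or disturbance = observed / true).
    """
    df = pd.read_csv(path)
    df = df.rename(columns={c: OSF_COLUMN_MAP.get(c.lower().strip(), c) for c in df.columns})
    if "disturbance" not in df.columns:
        if {"true_iq", "observed_iq"} <= set(df.columns):
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.asarray(df["observed_iq"] / df["true_iq"], dtype=float)
            df["disturbance"] = np.clip(np.nan_to_num(d, nan=1.0), 0.0, 1.0)
        else:
            df["disturbance"] = 1.0
    for true_col, obs_col in (
        ("true_iq", "observed_iq"),
        ("true_creativity", "observed_creativity"),
    ):
        if obs_col not in df.columns and true_col in df.columns:
            df[obs_col] = df[true_col] * df["disturbance"]
        if true_col not in df.columns and obs_col in df.columns:
            df[true_col] = df[obs_col]
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    return Cohort(*(np.asarray(df[c], dtype=float) for c in _CANONICAL_COLUMNS))
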