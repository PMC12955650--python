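"""Core unequal-variance signal detection model.

The model describes a yes/no detection observer whose internal evidence on
target-absent trials is distributed N(0, 1) and on target-present trials
N(mu, sigma).  A set of 2n - 1 strictly increasing criteria partitions the
evidence axis into 2n ordered response categories (n rating levels crossed
with the yes/no decision).  This module holds the parameter and data
containers, the closed-form sensitivity and bias indices (d', d_a, c), the
model-implied cell probabilities and rating-model log-likelihood, and the
model-implied ROC.

Conventions
-----------
* Response categories are indexed from the strongest "yes" (highest
  confidence / fastest yes) at index 0 to the strongest "no" at index
  2n - 1.  Category j therefore corresponds to the evidence interval
  between criteria counted from the top of the axis downwards.
* Larger criterion values are more conservative: a "yes" requires evidence
  above the middle (decision) criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "UVSDTParams",
    "RatingTable",
    "SensitivityReport",
    "d_prime",
    "d_a",
    "criterion_c",
    "cell_probabilities",
    "log_likelihood",
    "model_roc",
    "model_auc",
    "PROB_FLOOR",
]

#: floor applied to predicted cell probabilities inside the log; keeps the
#: likelihood finite without materially moving optima.
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class UVSDTParams:
    """Parameters of the unequal-variance Gaussian rating model.

    Attributes
    ----------
    mu : float
        Mean of the target-present evidence distribution (target-absent
        mean is fixed at 0).
    sigma : float
        SD of the target-present distribution (target-absent SD fixed at
        1); must be positive.
    criteria : ndarray
        Strictly increasing vector of 2n - 1 decision/rating cutpoints on
        the evidence axis; the middle one is the yes/no decision criterion.
    """

    mu: float
    sigma: float
    criteria: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", np.asarray(self.criteria, dtype=float))
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise ValueError("sigma must be a positive finite number")
        c = self.criteria
        if c.ndim != 1 or c.size < 1 or c.size % 2 != 1:
            raise ValueError("criteria must be a 1-D vector of odd length 2n-1")
        if not np.all(np.diff(c) > 0):
            raise ValueError("criteria must be strictly increasing")

    @property
    def n_levels(self) -> int:
        """Number of rating levels n (criteria has length 2n - 1)."""
        return (self.criteria.size + 1) // 2

    @property
    def decision_criterion(self) -> float:
        """The middle (yes/no) criterion."""
        return float(self.criteria[self.n_levels - 1])


@dataclass
class RatingTable:
    """2 x 2n response-frequency table for one subject.

    Row 0 is the target-absent stimulus class, row 1 target-present.
    Columns run from the strongest "yes" category (index 0) to the
    strongest "no" (index 2n - 1).
    """

    n_levels: int
    freq: np.ndarray
    padded: bool = False
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.freq.shape != (2, 2 * self.n_levels):
            raise ValueError(
                f"freq must have shape (2, {2 * self.n_levels}), got {self.freq.shape}"
            )
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be nonnegative")
        if not self.padded and not np.allclose(self.freq, np.round(self.freq)):
            raise ValueError("unpadded frequencies must be integers")
        if np.any(self.freq.sum(axis=1) <= 0):
            raise ValueError("each stimulus class must have at least one trial")

    @property
    def total(self) -> float:
        return float(self.freq.sum())

    def cumulative_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative (fa, hit) proportions of the k strongest-yes
        categories, k = 1..2n-1 (the empirical ROC coordinates)."""
        row_tot = self.freq.sum(axis=1, keepdims=True)
        cum = np.cumsum(self.freq, axis=1) / row_tot
        return cum[0, :-1].copy(), cum[1, :-1].copy()

    def midpoint_rates(self) -> tuple[float, float]:
        """Overall (fa, hit) yes-rates collapsed over rating levels."""
        fa, hit = self.cumulative_rates()
        return float(fa[self.n_levels - 1]), float(hit[self.n_levels - 1])


@dataclass
class SensitivityReport:
    """Sensitivity and bias indices for one subject.

    ``d_a`` and ``auc`` are model-based and only set when an
    unequal-variance fit is available; ``d_prime`` and ``criterion_c`` come
    from the ROC midpoint.
    """

    d_prime: Optional[float] = None
    d_a: Optional[float] = None
    criterion_c: Optional[float] = None
    auc: Optional[float] = None


def _check_rate(rate: float, name: str) -> float:
    rate = float(rate)
    if not (0.0 < rate < 1.0):
        raise ValueError(
            f"{name}={rate} is outside (0, 1); pad the frequency table "
            "(pad_table) before computing z-transformed indices"
        )
    return rate


def d_prime(hit_rate: float, fa_rate: float) -> float:
    """Equal-variance sensitivity d' = z(hit) - z(fa) from one ROC point."""
    hit = _check_rate(hit_rate, "hit_rate")
    fa = _check_rate(fa_rate, "fa_rate")
    return float(norm.ppf(hit) - norm.ppf(fa))


def d_a(mu: float, sigma: float) -> float:
    """Unequal-variance sensitivity: mean separation standardized by the
    root-mean-square of the two SDs, d_a = mu * sqrt(2 / (1 + sigma^2))."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return float(mu * np.sqrt(2.0 / (1.0 + sigma**2)))


def criterion_c(hit_rate: float, fa_rate: float) -> float:
    """Response-bias index c = -(z(hit) + z(fa)) / 2; positive values mean
    a conservative criterion ("yes" requires strong evidence)."""
    hit = _check_rate(hit_rate, "hit_rate")
    fa = _check_rate(fa_rate, "fa_rate")
    return float(-(norm.ppf(hit) + norm.ppf(fa)) / 2.0)


def cell_probabilities(
    params: UVSDTParams, n_levels: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied probabilities of the 2n ordered response categories.

    Returns ``(p_absent, p_present)``, each of length 2n and summing to 1,
    ordered from the strongest-"yes" category to the strongest-"no".
    Probabilities are Gaussian-CDF differences between consecutive criteria
    with +/- infinity end caps.
    """
    if n_levels is not None and n_levels != params.n_levels:
        raise ValueError(
            f"n_levels={n_levels} inconsistent with {params.criteria.size} criteria"
        )
    edges = np.concatenate(([-np.inf], params.criteria, [np.inf]))
    cdf_absent = norm.cdf(edges)
    cdf_present = norm.cdf(edges, loc=params.mu, scale=params.sigma)
    # diff gives intervals in ascending-evidence order; reverse so that
    # index 0 is the highest-evidence (strongest yes) category
    p_absent = np.diff(cdf_absent)[::-1]
    p_present = np.diff(cdf_present)[::-1]
    return p_absent, p_present


def log_likelihood(table: RatingTable, params: UVSDTParams) -> float:
    """Multinomial rating-model log-likelihood sum(freq * log(prob)).

    Predicted probabilities are floored at :data:`PROB_FLOOR` (with a
    warning) so the result stays finite for extreme parameter values.
    """
    if table.n_levels != params.n_levels:
        raise ValueError("table and params disagree on the number of rating levels")
    p_absent, p_present = cell_probabilities(params)
    probs = np.vstack([p_absent, p_present])
    if np.any(probs < PROB_FLOOR):
        warnings.warn(
            "predicted cell probability underflow; floored at PROB_FLOOR",
            RuntimeWarning,
            stacklevel=2,
        )
        probs = np.maximum(probs, PROB_FLOOR)
    return float(np.sum(table.freq * np.log(probs)))


@dataclass
class _ModelROC:
    """Internal carrier for model_roc output (duck-types roc.ROCCurve)."""

    points: np.ndarray
    source: str = "model"
    criteria_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def model_roc(params: UVSDTParams, n_grid: int = 513):
    """Model-implied type-1 ROC.

    Evaluates (FA, hit) = (1 - Phi(k), 1 - Phi((k - mu)/sigma)) on a dense
    criterion grid that includes the fitted criteria, ordered from the most
    conservative criterion (leftmost ROC point) to the most lenient.
    """
    from .roc import ROCCurve  # local import avoids a cycle

    lo = min(-4.0, params.mu - 4.0 * params.sigma, float(params.criteria.min()) - 1.0)
    hi = max(4.0, params.mu + 4.0 * params.sigma, float(params.criteria.max()) + 1.0)
    ks = np.union1d(np.linspace(lo, hi, n_grid), params.criteria)[::-1]
    fa = norm.sf(ks)
    hit = norm.sf((ks - params.mu) / params.sigma)
    points = np.column_stack([fa, hit])
    crit_fa = norm.sf(params.criteria)[::-1]
    crit_hit = norm.sf((params.criteria - params.mu) / params.sigma)[::-1]
    return ROCCurve(
        points=points,
        source="model",
        criteria_points=np.column_stack([crit_fa, crit_hit]),
    )


def model_auc(params: UVSDTParams) -> float:
    """Area under the model ROC by adaptive quadrature.

    Integrates hit(k) d FA(k) over the criterion axis; for the bi-Gaussian
    model this equals Phi(d_a / sqrt(2)).
    """
    val, _ = integrate.quad(
        lambda k: norm.sf((k - params.mu) / params.sigma) * norm.pdf(k),
        -np.inf,
        np.inf,
    )
    return float(val)
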