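"""Maximum-likelihood fitting of the unequal-variance rating model.

The 2n + 1 model parameters (mu, sigma, 2n - 1 ordered criteria) are
estimated from one padded rating table by maximizing the multinomial
log-likelihood.  The search runs on an unconstrained reparameterization

    theta = (mu, log sigma, c_1, log g_2, ..., log g_{2n-1})

where g_j are the positive gaps between consecutive criteria (plus a small
floor), which guarantees sigma > 0 and strict criterion ordering for any
real theta.  Optimization is derivative-free Nelder-Mead started from a
zROC-based initializer and a few jittered restarts; the best run wins.

The equal-variance companion (``fit_evsdt_midpoint``) reads conventional
d' and criterion c off the ROC midpoint alone, which is what standard
yes/no analyses report and what the misevaluation index compares d_a to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from . import core
from .core import PROB_FLOOR, RatingTable, SensitivityReport, UVSDTParams
from .roc import empirical_roc, zroc_line

__all__ = [
    "FitConfig",
    "FitResult",
    "initialize",
    "fit_uvsdt",
    "fit_evsdt_midpoint",
    "misevaluation_index",
]

_MIN_GAP = 1e-4
_SIGMA_BOUNDS = (0.05, 20.0)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings (documented defaults; no single canonical
    choice exists for this family of models)."""

    tol: float = 1e-8
    max_evals: int = 5000
    n_restarts: int = 3
    jitter_sd: float = 0.1
    seed: int = 0


@dataclass
class FitResult:
    params: UVSDTParams
    loglik: float
    converged: bool
    n_evals: int
    report: SensitivityReport
    evidence_source: str = "confidence"
    subject: Optional[str] = None
    seed: Optional[int] = None


def _pack(params: UVSDTParams) -> np.ndarray:
    gaps = np.diff(params.criteria)
    return np.concatenate(
        [
            [params.mu, np.log(params.sigma), params.criteria[0]],
            np.log(np.maximum(gaps - _MIN_GAP, _MIN_GAP)),
        ]
    )


def _unpack(theta: np.ndarray) -> UVSDTParams:
    mu = theta[0]
    sigma = np.exp(np.clip(theta[1], -30.0, 30.0))
    gaps = _MIN_GAP + np.exp(np.clip(theta[3:], -30.0, 30.0))
    criteria = theta[2] + np.concatenate(([0.0], np.cumsum(gaps)))
    return UVSDTParams(mu=float(mu), sigma=float(sigma), criteria=criteria)


def _neg_loglik(theta: np.ndarray, freq: np.ndarray) -> float:
    # hot loop: inline cell probabilities via the fast ndtr kernel
    mu = theta[0]
    sigma = np.exp(np.clip(theta[1], -30.0, 30.0))
    gaps = _MIN_GAP + np.exp(np.clip(theta[3:], -30.0, 30.0))
    criteria = theta[2] + np.concatenate(([0.0], np.cumsum(gaps)))
    edges = np.concatenate(([-np.inf], criteria, [np.inf]))
    pa = np.diff(ndtr(edges))[::-1]
    pp = np.diff(ndtr((edges - mu) / sigma))[::-1]
    probs = np.maximum(np.vstack([pa, pp]), PROB_FLOOR)
    return -float(np.sum(freq * np.log(probs)))


def initialize(table: RatingTable) -> UVSDTParams:
    """Starting values from the zROC least-squares line.

    sigma_0 = 1/slope (clipped to [0.2, 5]), mu_0 = intercept * sigma_0;
    criteria start at -z(cumulative FA rates), nudged to strict
    monotonicity.  Degenerate zROCs fall back to mu=1, sigma=1 with
    equally spaced criteria.
    """
    n = table.n_levels
    fa, hit = table.cumulative_rates()
    try:
        slope, intercept = zroc_line(empirical_roc(table))
        if slope <= 1e-6:
            raise ValueError("nonpositive zROC slope")
        sigma0 = float(np.clip(1.0 / slope, 0.2, 5.0))
        mu0 = intercept * sigma0
    except ValueError:
        return UVSDTParams(mu=1.0, sigma=1.0, criteria=np.linspace(-1, 1, 2 * n - 1))
    fa_clipped = np.clip(fa, 1e-6, 1 - 1e-6)
    crit = -norm.ppf(fa_clipped)[::-1]  # ascending along the evidence axis
    crit = np.maximum.accumulate(crit + np.arange(crit.size) * 1e-3)
    return UVSDTParams(mu=float(mu0), sigma=sigma0, criteria=crit)


def fit_uvsdt(
    table: RatingTable,
    init: Optional[UVSDTParams] = None,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit the unequal-variance model to one padded rating table by MLE.

    Runs Nelder-Mead from the initializer plus jittered restarts and keeps
    the best optimum.  ``converged`` requires optimizer success and a
    sigma estimate inside the plausible band [0.05, 20]; fits outside it
    are flagged so downstream analyses can drop the subject, matching the
    convergence screen applied before group summaries.
    """
    if not table.padded:
        raise ValueError("fit_uvsdt expects a padded table (see pad_table)")
    if np.any(table.freq.sum(axis=1) == 0):
        raise ValueError("a stimulus row is all zeros")
    config = config or FitConfig()
    init = init or initialize(table)
    theta0 = _pack(init)
    rng = np.random.default_rng(config.seed)

    best = None
    n_evals = 0
    starts = [theta0] + [
        theta0 + rng.normal(0.0, config.jitter_sd, size=theta0.size)
        for _ in range(config.n_restarts)
    ]
    for start in starts:
        res = minimize(
            _neg_loglik,
            start,
            args=(table.freq,),
            method="Nelder-Mead",
            options={
                "maxfev": config.max_evals,
                "xatol": config.tol**0.5,
                "fatol": config.tol,
            },
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res

    params = _unpack(best.x)
    loglik = -float(best.fun)
    sigma_ok = _SIGMA_BOUNDS[0] <= params.sigma <= _SIGMA_BOUNDS[1]
    converged = bool(best.success) and sigma_ok and np.isfinite(loglik)

    fa, hit = table.midpoint_rates()
    report = SensitivityReport(
        d_prime=core.d_prime(hit, fa),
        d_a=core.d_a(params.mu, params.sigma),
        criterion_c=core.criterion_c(hit, fa),
        auc=float(norm.cdf(core.d_a(params.mu, params.sigma) / np.sqrt(2.0))),
    )
    return FitResult(
        params=params,
        loglik=loglik,
        converged=converged,
        n_evals=n_evals,
        report=report,
        subject=table.subject,
        seed=config.seed,
    )


def fit_evsdt_midpoint(table: RatingTable) -> SensitivityReport:
    """Equal-variance indices from the ROC midpoint only.

    Collapses the rating levels to the overall yes/no rates and returns
    conventional d' and criterion c; d_a and auc are left unset because
    a single ROC point cannot identify the unequal-variance model.
    """
    fa, hit = table.midpoint_rates()
    return SensitivityReport(
        d_prime=core.d_prime(hit, fa),
        criterion_c=core.criterion_c(hit, fa),
    )


def misevaluation_index(fit: FitResult, ev: SensitivityReport) -> float:
    """Performance misevaluation d' - d_a for one subject.

    Positive when the equal-variance d' overestimates the bias-robust
    sensitivity (conservative criteria under sigma > 1), negative when it
    underestimates it (lenient criteria).
    """
    if ev.d_prime is None or fit.report.d_a is None:
        raise ValueError("both d' and d_a must be available")
    return float(ev.d_prime - fit.report.d_a)
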