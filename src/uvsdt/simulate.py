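"""Synthetic unequal-variance SDT observers.

Each simulated trial draws an internal evidence value (N(0,1) on
target-absent trials, N(mu, sigma) on target-present trials), thresholds
it against an ordered set of confidence criteria containing the yes/no
decision criterion c0 in the middle, and emits a yes/no response, an
ordinal confidence level, and a response time.

The RT mechanism is a modeling choice of this package: detection analyses
only assume that a faster response signals stronger evidence for the
chosen option, so we realize that monotone link with a log-linear form

    rt = exp(a - b * |x - c0| + eps),   eps ~ N(0, tau^2),   b > 0.

With tau = 0 the within-response RT order reproduces the evidence order
exactly; tau > 0 degrades RT as an evidence readout while leaving the
confidence route untouched, which is the mechanism by which RT-based
parameter estimates attenuate relative to confidence-based ones.
Alternative RT forms can be studied by replacing ``_rt_from_evidence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["RTModel", "SimConfig", "simulate_observer", "simulate_cohort"]


@dataclass(frozen=True)
class RTModel:
    """Log-linear evidence-to-RT map.

    a: baseline log-RT at the decision criterion (log seconds);
    b: evidence slope (> 0 so stronger evidence means faster responses);
    tau: SD of log-normal RT noise (>= 0).
    """

    a: float = 0.0
    b: float = 0.4
    tau: float = 0.2

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("RT slope b must be positive")
        if self.tau < 0:
            raise ValueError("RT noise tau must be nonnegative")


def _default_criteria(c0: float, n_levels: int, gap: float = 0.5) -> np.ndarray:
    """Symmetric confidence criteria around c0 at the given gap."""
    return c0 + gap * np.arange(-(n_levels - 1), n_levels)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of one synthetic observer.

    ``confidence_criteria`` must be strictly increasing, of odd length
    2n - 1, and contain the decision criterion ``c0`` at its middle
    position; when omitted it defaults to symmetric placement around c0
    at gaps of 0.5 for ``n_levels`` levels.
    """

    mu: float = 1.5
    sigma: float = 1.5
    c0: float = 0.0
    n_levels: int = 3
    confidence_criteria: Optional[np.ndarray] = None
    n_trials: int = 1000
    p_present: float = 0.5
    rt_model: RTModel = field(default_factory=RTModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.p_present < 1:
            raise ValueError("p_present must lie in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        crit = self.confidence_criteria
        if crit is None:
            crit = _default_criteria(self.c0, self.n_levels)
        crit = np.asarray(crit, dtype=float)
        if crit.size % 2 != 1 or crit.size != 2 * self.n_levels - 1:
            raise ValueError("confidence_criteria must have length 2*n_levels - 1")
        if not np.all(np.diff(crit) > 0):
            raise ValueError("confidence_criteria must be strictly increasing")
        if not np.isclose(crit[self.n_levels - 1], self.c0):
            raise ValueError(
                "the middle confidence criterion must equal the decision criterion c0"
            )
        object.__setattr__(self, "confidence_criteria", crit)


def _rt_from_evidence(
    x: np.ndarray, c0: float, model: RTModel, rng: np.random.Generator
) -> np.ndarray:
    eps = rng.normal(0.0, model.tau, size=x.size) if model.tau > 0 else 0.0
    return np.exp(model.a - model.b * np.abs(x - c0) + eps)


def simulate_observer(config: SimConfig) -> pd.DataFrame:
    """Generate one observer's trials; deterministic given config.seed.

    Returns a trial frame with columns subject, stimulus, response, rt,
    confidence (ordinal 1..n) and the latent evidence value.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_levels
    crit = config.confidence_criteria

    stimulus = (rng.random(config.n_trials) < config.p_present).astype(int)
    x = rng.normal(0.0, 1.0, size=config.n_trials)
    x = np.where(stimulus == 1, config.mu + config.sigma * x, x)

    # interval index along the evidence axis: 0 = below all criteria
    idx = np.searchsorted(crit, x, side="right")
    response = (idx >= n).astype(int)
    confidence = np.where(response == 1, idx - n + 1, n - idx)
    rt = _rt_from_evidence(x, config.c0, config.rt_model, rng)

    return pd.DataFrame(
        {
            "subject": "s0",
            "stimulus": stimulus,
            "response": response,
            "rt": rt,
            "confidence": confidence,
            "evidence": x,
        }
    )


def simulate_cohort(
    base: SimConfig,
    n_subjects: int,
    between_subject_sds: Optional[dict] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of observers with parameters scattered around ``base``.

    ``between_subject_sds`` may contain SDs for ``mu``, ``c0`` (normal on
    the natural scale) and ``sigma``, ``rt_b`` (log-normal scatter).  The
    confidence criteria shift rigidly with each subject's c0 so the
    decision criterion stays at their middle.  Returns the concatenated
    trial frame and a frame of the true per-subject parameters.
    """
    sds = between_subject_sds or {}
    for key in sds:
        if key not in ("mu", "sigma", "c0", "rt_b"):
            raise ValueError(f"unknown between-subject SD key {key!r}")
        if sds[key] < 0:
            raise ValueError("between-subject SDs must be nonnegative")
    rng = np.random.default_rng(seed)

    frames, truths = [], []
    for i in range(n_subjects):
        mu_i = base.mu + rng.normal(0.0, sds.get("mu", 0.0))
        sigma_i = base.sigma * np.exp(rng.normal(0.0, sds.get("sigma", 0.0)))
        c0_i = base.c0 + rng.normal(0.0, sds.get("c0", 0.0))
        b_i = base.rt_model.b * np.exp(rng.normal(0.0, sds.get("rt_b", 0.0)))
        cfg_i = replace(
            base,
            mu=float(mu_i),
            sigma=float(sigma_i),
            c0=float(c0_i),
            confidence_criteria=base.confidence_criteria + (c0_i - base.c0),
            rt_model=replace(base.rt_model, b=float(b_i)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trials = simulate_observer(cfg_i)
        sid = f"s{i:03d}"
        trials["subject"] = sid
        frames.append(trials)
        truths.append(
            {"subject": sid, "mu": mu_i, "sigma": sigma_i, "c0": c0_i, "rt_b": b_i}
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truths)
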