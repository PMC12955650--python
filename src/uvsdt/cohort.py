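"""Group-level summaries: RT-vs-confidence agreement and the
criterion-dependent misevaluation of sensitivity.

Given per-subject unequal-variance fits from the RT route and the
confidence route, plus the equal-variance midpoint indices, this module
assembles a tidy per-subject frame, paired comparisons between the two
evidence sources (t-tests and Pearson correlations per parameter), and
the correlation between each subject's criterion c and the misevaluation
index d' - d_a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SensitivityReport
from .fit import FitResult, misevaluation_index

__all__ = ["CohortSummary", "summarize", "bias_correlation"]

_PARAMS = ["mu", "sigma", "d_a"]


@dataclass
class CohortSummary:
    """Per-subject records plus group statistics.

    ``per_subject`` has one row per retained subject with fitted mu,
    sigma, d_a per evidence source, the midpoint d' and c, and the
    misevaluation index.  ``comparisons`` holds per-parameter paired
    statistics between sources; percent differences use the
    confidence-based mean as the denominator.
    """

    per_subject: pd.DataFrame
    n_subjects: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    bias_r: float | None = None
    bias_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "means": self.means,
            "sds": self.sds,
            "comparisons": self.comparisons,
            "bias_r": self.bias_r,
            "bias_p": self.bias_p,
        }


def _as_map(results) -> dict[str, FitResult]:
    if isinstance(results, dict):
        return {str(k): v for k, v in results.items()}
    return {str(r.subject): r for r in results}


def summarize(
    results_rt,
    results_conf,
    ev: dict[str, SensitivityReport] | None = None,
) -> CohortSummary:
    """Assemble the cohort summary from matched per-subject results.

    Only subjects with converged fits under both evidence sources enter
    the summary, mirroring the convergence screen applied to real
    cohorts.  ``ev`` maps subjects to their equal-variance midpoint
    indices; when omitted, the midpoint indices carried in the RT fit
    results are used.
    """
    rt_map, conf_map = _as_map(results_rt), _as_map(results_conf)
    subjects = [
        s
        for s in rt_map
        if s in conf_map and rt_map[s].converged and conf_map[s].converged
    ]
    rows = []
    for s in subjects:
        r, c = rt_map[s], conf_map[s]
        ev_s = ev[s] if ev is not None else SensitivityReport(
            d_prime=r.report.d_prime, criterion_c=r.report.criterion_c
        )
        rows.append(
            {
                "subject": s,
                "mu_rt": r.params.mu,
                "sigma_rt": r.params.sigma,
                "d_a_rt": r.report.d_a,
                "mu_conf": c.params.mu,
                "sigma_conf": c.params.sigma,
                "d_a_conf": c.report.d_a,
                "d_prime": ev_s.d_prime,
                "c": ev_s.criterion_c,
                "misevaluation_rt": misevaluation_index(r, ev_s),
                "misevaluation_conf": misevaluation_index(c, ev_s),
            }
        )
    per_subject = pd.DataFrame(
        rows,
        columns=[
            "subject", "mu_rt", "sigma_rt", "d_a_rt", "mu_conf", "sigma_conf",
            "d_a_conf", "d_prime", "c", "misevaluation_rt", "misevaluation_conf",
        ],
    )
    summary = CohortSummary(per_subject=per_subject, n_subjects=len(per_subject))

    for col in per_subject.columns[1:]:
        vals = per_subject[col].to_numpy(dtype=float)
        summary.means[col] = float(np.mean(vals)) if len(vals) else None
        summary.sds[col] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None

    if len(per_subject) < 3:
        warnings.warn(
            "fewer than 3 matched subjects; paired statistics unset",
            RuntimeWarning,
            stacklevel=2,
        )
        return summary

    for p in _PARAMS:
        a = per_subject[f"{p}_rt"].to_numpy(dtype=float)
        b = per_subject[f"{p}_conf"].to_numpy(dtype=float)
        t, tp = stats.ttest_rel(a, b)
        if np.std(a) > 0 and np.std(b) > 0:
            r, rp = stats.pearsonr(a, b)
        else:
            r, rp = np.nan, np.nan
        mean_conf = float(np.mean(b))
        summary.comparisons[p] = {
            "mean_rt": float(np.mean(a)),
            "mean_conf": mean_conf,
            "percent_diff": (
                100.0 * (mean_conf - float(np.mean(a))) / mean_conf
                if mean_conf != 0
                else None
            ),
            "t": float(t),
            "t_p": float(tp),
            "r": float(r),
            "r_p": float(rp),
        }

    summary.bias_r, summary.bias_p = bias_correlation(summary)
    return summary


def bias_correlation(
    summary: CohortSummary, source: str = "rt"
) -> tuple[float | None, float | None]:
    """Pearson correlation between criterion c and the misevaluation
    index d' - d_a across subjects.

    Returns (None, None) with a warning when fewer than 3 subjects are
    available or either variable has zero variance.
    """
    df = summary.per_subject
    if len(df) < 3:
        warnings.warn("need >= 3 subjects for a correlation", RuntimeWarning, stacklevel=2)
        return None, None
    c = df["c"].to_numpy(dtype=float)
    mis = df[f"misevaluation_{source}"].to_numpy(dtype=float)
    if np.std(c) == 0 or np.std(mis) == 0:
        warnings.warn(
            "zero variance in criterion or misevaluation index; correlation unset",
            RuntimeWarning,
            stacklevel=2,
        )
        return None, None
    r, p = stats.pearsonr(c, mis)
    return float(r), float(p)
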