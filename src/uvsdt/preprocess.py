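"""Trial-level preprocessing: ordinal evidence strength, rating tables,
padding, and subject exclusion.

Trials live in a pandas DataFrame with one row per trial and columns
``subject`` (identifier), ``stimulus`` (0 = target absent, 1 = present),
``response`` (0 = no, 1 = yes), ``rt`` (seconds, > 0), and optionally
``confidence`` (ordinal level or continuous rating).

Two routes produce an ordinal "evidence strength" per trial (1 = weakest,
n = strongest indication of the choice made):

* confidence ratings, discretized per subject into quantile levels when
  the scale is continuous (``discretize_confidence``), or used as-is when
  already ordinal;
* response times, binned per subject into n quantile bins with faster
  responses treated as stronger evidence (``bin_rt``).

``build_table`` tabulates one subject's trials into the 2 x 2n rating
table, ``pad_table`` adds the 1/N stabilizing constant, and
``exclude_below_chance`` applies the performance screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import RatingTable

__all__ = [
    "TRIAL_COLUMNS",
    "PreprocessReport",
    "validate_trials",
    "discretize_confidence",
    "bin_rt",
    "build_table",
    "build_tables",
    "pad_table",
    "exclude_below_chance",
]

#: required columns of a trial frame (confidence is optional)
TRIAL_COLUMNS = ["subject", "stimulus", "response", "rt"]


@dataclass
class PreprocessReport:
    """Bookkeeping of the subject-exclusion cascade."""

    n_input_subjects: int = 0
    n_below_chance_excluded: int = 0
    n_nonconverged_excluded: int = 0
    flags: dict = field(default_factory=dict)

    @property
    def n_final(self) -> int:
        return (
            self.n_input_subjects
            - self.n_below_chance_excluded
            - self.n_nonconverged_excluded
        )

    def to_dict(self) -> dict:
        return {
            "n_input_subjects": self.n_input_subjects,
            "n_below_chance_excluded": self.n_below_chance_excluded,
            "n_nonconverged_excluded": self.n_nonconverged_excluded,
            "n_final": self.n_final,
            "flags": self.flags,
        }


def validate_trials(trials: pd.DataFrame, require_confidence: bool = False) -> pd.DataFrame:
    """Check the trial-frame schema and value ranges; returns the frame."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(
            f"trial frame is missing columns {missing}; found {list(trials.columns)}"
        )
    if require_confidence and "confidence" not in trials.columns:
        raise ValueError("trial frame has no 'confidence' column")
    if not trials["stimulus"].isin([0, 1]).all():
        raise ValueError("stimulus must be binary (0 = absent, 1 = present)")
    if not trials["response"].isin([0, 1]).all():
        raise ValueError("response must be binary (0 = no, 1 = yes)")
    if not (trials["rt"] > 0).all():
        raise ValueError("all rt values must be positive")
    return trials


def _quantile_levels(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Map values to levels 1..n via type-7 quantile cutpoints at
    i/n_levels; ties at a cutpoint go to the lower level."""
    cuts = np.quantile(values, np.arange(1, n_levels) / n_levels)
    return np.searchsorted(cuts, values, side="left") + 1


def discretize_confidence(trials: pd.DataFrame, n_levels: int) -> pd.DataFrame:
    """Per-subject quantile discretization of continuous confidence.

    Adds a ``confidence_level`` column with ordinal levels 1 (lowest)
    to n (highest), using each subject's own quantile cutpoints.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    validate_trials(trials, require_confidence=True)
    out = trials.copy()
    out["confidence_level"] = 0
    for subject, grp in out.groupby("subject", sort=False):
        conf = grp["confidence"].to_numpy(dtype=float)
        if np.unique(conf).size < n_levels:
            raise ValueError(
                f"subject {subject!r} has fewer than {n_levels} distinct "
                "confidence values; cannot form quantile levels"
            )
        out.loc[grp.index, "confidence_level"] = _quantile_levels(conf, n_levels)
    return out


def bin_rt(
    trials: pd.DataFrame,
    n_bins: int,
    scheme: str = "pooled",
    on_degenerate: str = "error",
) -> pd.DataFrame:
    """Per-subject RT quantile binning into ordinal evidence strength.

    Adds an ``rt_strength`` column: the fastest bin maps to strength
    ``n_bins`` (strongest indication of the choice made), the slowest to
    1.  Under ``scheme="pooled"`` (default) quantile cutpoints are taken
    over all of a subject's RTs; ``"within_response"`` computes them
    separately for yes and no trials.  RT values tied with a cutpoint go
    to the slower (weaker) bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scheme not in ("pooled", "within_response"):
        raise ValueError(f"unknown binning scheme {scheme!r}")
    validate_trials(trials)
    out = trials.copy()
    out["rt_strength"] = 0

    def assign(idx: pd.Index, rts: np.ndarray, subject) -> None:
        if rts.size < n_bins:
            raise ValueError(
                f"subject {subject!r} has {rts.size} trials, fewer than "
                f"{n_bins} RT bins"
            )
        if np.unique(rts).size == 1:
            if on_degenerate == "error":
                raise ValueError(
                    f"subject {subject!r} has identical RTs on all trials"
                )
            out.loc[idx, "rt_strength"] = 1
            return
        cuts = np.quantile(rts, np.arange(1, n_bins) / n_bins)
        # side="right": a tie with a cutpoint falls in the slower bin
        slow_rank = np.searchsorted(cuts, rts, side="right")  # 0 = fastest
        out.loc[idx, "rt_strength"] = n_bins - slow_rank

    for subject, grp in out.groupby("subject", sort=False):
        if scheme == "pooled":
            assign(grp.index, grp["rt"].to_numpy(dtype=float), subject)
        else:
            for _, sub in grp.groupby("response", sort=False):
                assign(sub.index, sub["rt"].to_numpy(dtype=float), subject)
    return out


def _strength_column(trials: pd.DataFrame, evidence: str) -> np.ndarray:
    if evidence == "rt":
        if "rt_strength" not in trials.columns:
            raise ValueError("run bin_rt first: no 'rt_strength' column")
        return trials["rt_strength"].to_numpy(dtype=int)
    if evidence == "confidence":
        col = "confidence_level" if "confidence_level" in trials.columns else "confidence"
        if col not in trials.columns:
            raise ValueError("no ordinal confidence available")
        vals = trials[col].to_numpy(dtype=float)
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(
                "confidence is continuous; run discretize_confidence first"
            )
        return vals.astype(int)
    raise ValueError(f"unknown evidence source {evidence!r}")


def build_table(
    trials: pd.DataFrame, n_levels: int, evidence: str = "confidence"
) -> RatingTable:
    """Tabulate one subject's trials into a 2 x 2n rating table.

    Columns are ordered yes/strength-n ... yes/strength-1, no/strength-1
    ... no/strength-n, i.e. from the strongest "yes" to the strongest
    "no" along the evidence axis.
    """
    validate_trials(trials)
    subjects = trials["subject"].unique()
    if subjects.size > 1:
        raise ValueError("build_table expects a single subject; use build_tables")
    strength = _strength_column(trials, evidence)
    if np.any(strength < 1) or np.any(strength > n_levels):
        raise ValueError(f"strength levels must lie in 1..{n_levels}")
    stim = trials["stimulus"].to_numpy(dtype=int)
    resp = trials["response"].to_numpy(dtype=int)
    # yes: column n - s; no: column n - 1 + s
    col = np.where(resp == 1, n_levels - strength, n_levels - 1 + strength)
    freq = np.zeros((2, 2 * n_levels))
    np.add.at(freq, (stim, col), 1.0)
    if np.any(freq.sum(axis=1) == 0):
        raise ValueError("a stimulus class has no trials for this subject")
    return RatingTable(
        n_levels=n_levels, freq=freq, padded=False, subject=str(subjects[0])
    )


def build_tables(
    trials: pd.DataFrame, n_levels: int, evidence: str = "confidence"
) -> dict[str, RatingTable]:
    """Per-subject rating tables, keyed by subject identifier."""
    return {
        str(subject): build_table(grp, n_levels, evidence)
        for subject, grp in trials.groupby("subject", sort=False)
    }


def pad_table(table: RatingTable) -> RatingTable:
    """Add the stabilizing constant 1/N (N = grand total of unpadded
    frequencies) to every cell; marks the table as padded."""
    if table.padded:
        raise ValueError("table is already padded")
    pad = 1.0 / table.total
    return RatingTable(
        n_levels=table.n_levels,
        freq=table.freq + pad,
        padded=True,
        subject=table.subject,
    )


def exclude_below_chance(
    tables: dict[str, RatingTable], boundary_excludes: bool = True
) -> PreprocessReport:
    """Flag subjects whose overall yes/no performance is not above chance.

    Uses the padded midpoint rates: a subject with z(hit) - z(fa) <= 0
    (or < 0 when ``boundary_excludes`` is False) is flagged for exclusion
    from model fitting.
    """
    report = PreprocessReport(n_input_subjects=len(tables))
    for subject, table in tables.items():
        fa, hit = table.midpoint_rates()
        dp = norm.ppf(hit) - norm.ppf(fa)
        excluded = dp <= 0 if boundary_excludes else dp < 0
        report.flags[subject] = "below_chance" if excluded else "retained"
        if excluded:
            report.n_below_chance_excluded += 1
    return report
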