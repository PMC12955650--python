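"""File I/O and run configuration.

Trial data travel as delimited text with a header row and columns
subject, stimulus (0/1), response (0/1), rt (seconds by default), and
optionally confidence.  Per-subject fit results are written as a tidy
CSV; cohort summaries and preprocessing reports as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortSummary
from .fit import FitResult
from .preprocess import TRIAL_COLUMNS, PreprocessReport, validate_trials

logger = logging.getLogger("uvsdt")

__all__ = [
    "RunConfig",
    "read_trials",
    "write_trials",
    "results_frame",
    "write_results",
    "write_summary",
    "write_report",
]

#: column set of the per-subject results CSV (schema version 1)
RESULT_COLUMNS = [
    "subject", "evidence_source", "mu", "sigma", "d_a", "d_prime", "c",
    "auc", "loglik", "converged",
]


@dataclass
class RunConfig:
    """End-to-end pipeline settings (YAML-loadable)."""

    input: str | None = None
    output_dir: str = "uvsdt_out"
    evidence: str = "both"  # rt | confidence | both
    n_levels: int = 3
    binning_scheme: str = "pooled"
    discretize_confidence: bool = False
    rt_unit: str = "s"
    delimiter: str = ","
    seed: int = 0
    n_subjects: int = 20
    n_trials: int = 1000
    sim: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.evidence not in ("rt", "confidence", "both"):
            raise ValueError(f"invalid evidence source {self.evidence!r}")
        if self.binning_scheme not in ("pooled", "within_response"):
            raise ValueError(f"invalid binning scheme {self.binning_scheme!r}")
        if self.rt_unit not in ("s", "ms"):
            raise ValueError("rt_unit must be 's' or 'ms'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def read_trials(
    path: str | Path,
    delimiter: str = ",",
    rt_unit: str = "s",
    on_bad_rows: str = "warn",
) -> pd.DataFrame:
    """Read a trial CSV, validating schema and values.

    Rows with nonpositive or missing RT, or non-binary stimulus/response,
    are reported with their line numbers and dropped (``on_bad_rows=
    "warn"``) or raise (``"error"``).  RTs given in milliseconds are
    converted to seconds.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    bad = (
        ~df["stimulus"].isin([0, 1])
        | ~df["response"].isin([0, 1])
        | ~(pd.to_numeric(df["rt"], errors="coerce") > 0)
    )
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        msg = f"{path}: {bad.sum()} malformed rows at lines {lines[:20]}"
        if on_bad_rows == "error":
            raise ValueError(msg)
        logger.warning("%s (dropped)", msg)
        df = df[~bad].reset_index(drop=True)
    if rt_unit == "ms":
        df = df.assign(rt=df["rt"] / 1000.0)
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    cols = [c for c in trials.columns if c != "evidence"]
    trials[cols].to_csv(path, sep=delimiter, index=False)


def results_frame(results: list[FitResult]) -> pd.DataFrame:
    """Tidy per-subject results table (one row per subject x source)."""
    rows = [
        {
            "subject": r.subject,
            "evidence_source": r.evidence_source,
            "mu": r.params.mu,
            "sigma": r.params.sigma,
            "d_a": r.report.d_a,
            "d_prime": r.report.d_prime,
            "c": r.report.criterion_c,
            "auc": r.report.auc,
            "loglik": r.loglik,
            "converged": r.converged,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[FitResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, index=False)


def write_summary(summary: CohortSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, default=float)


def write_report(report: PreprocessReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
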