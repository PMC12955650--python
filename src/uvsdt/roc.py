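"""Empirical type-1 ROC construction, zROC transform, and model-free AUC.

The ROC is built from a 2 x 2n rating table by accumulating response
categories from the strongest "yes" outward: point k plots the cumulative
false-alarm and hit proportions of the k strongest-yes categories,
k = 1..2n-1.  Including all 2n categories would always give (1, 1), which
together with (0, 0) serves as an implicit anchor for area computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import RatingTable

__all__ = ["ROCCurve", "empirical_roc", "zroc", "zroc_line", "empirical_auc"]


@dataclass
class ROCCurve:
    """Ordered (fa_rate, hit_rate) points from most conservative to most
    lenient cutoff; anchors (0,0) and (1,1) are implicit."""

    points: np.ndarray
    source: str = "empirical"
    criteria_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be an (m, 2) array of (fa, hit) pairs")
        if np.any(self.points < -1e-12) or np.any(self.points > 1 + 1e-12):
            raise ValueError("rates must lie in [0, 1]")
        if np.any(np.diff(self.points, axis=0) < -1e-12):
            raise ValueError("fa and hit must be nondecreasing along the curve")

    @property
    def fa(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def hit(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self) -> pd.DataFrame:
        """Export as a tidy frame with z-transformed columns (NaN at
        boundary rates)."""
        with np.errstate(divide="ignore"):
            z = norm.ppf(self.points)
        return pd.DataFrame(
            {
                "fa": self.fa,
                "hit": self.hit,
                "z_fa": z[:, 0],
                "z_hit": z[:, 1],
            }
        )


def empirical_roc(table: RatingTable) -> ROCCurve:
    """Type-1 ROC from a rating table: 2n - 1 cumulative points.

    The leftmost point counts only the strongest-"yes" category; the n-th
    point (the midpoint) is the overall yes rate, untouched by confidence
    or RT information.
    """
    fa, hit = table.cumulative_rates()
    return ROCCurve(points=np.column_stack([fa, hit]), source="empirical")


def zroc(curve: ROCCurve) -> np.ndarray:
    """Normal-quantile transform of the ROC points -> (z_fa, z_hit) pairs.

    Requires all rates strictly inside (0, 1); pad the table first if any
    category has zero counts.
    """
    pts = curve.points
    if np.any(pts <= 0) or np.any(pts >= 1):
        raise ValueError(
            "zROC requires rates strictly inside (0, 1); pad the table first"
        )
    return norm.ppf(pts)


def zroc_line(curve: ROCCurve) -> tuple[float, float]:
    """Least-squares (slope, intercept) of z_hit on z_fa.

    Under the unequal-variance Gaussian model the zROC is a line with
    slope 1/sigma and intercept mu/sigma; this is a descriptive estimate
    only (the MLE fit is authoritative).
    """
    z = zroc(curve)
    if np.unique(z[:, 0]).size < 2:
        raise ValueError("zROC line needs at least 2 distinct z_fa values")
    slope, intercept = np.polyfit(z[:, 0], z[:, 1], 1)
    return float(slope), float(intercept)


def empirical_auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC, anchored at (0, 0) and (1, 1)."""
    fa = np.concatenate(([0.0], curve.fa, [1.0]))
    hit = np.concatenate(([0.0], curve.hit, [1.0]))
    return float(np.trapezoid(hit, fa))
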