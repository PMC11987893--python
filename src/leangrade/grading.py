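"""SEUROP classification and population-level comparison of prediction equations.

The EU grading scale assigns each carcass one of six classes by lean meat
percentage, lower bound inclusive::

    S >= 60 > E >= 55 > U >= 50 > R >= 45 > O >= 40 > P

The thresholds are configuration (member states print the scale in
regulation, not in trial reports); the defaults encode the standard scale.
``compare_equations`` evaluates two prediction equations on the same
measurement table and reports the mean LMP shift, the 6x6 class-migration
matrix and per-equation LMP histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equations import PredictionEquation

__all__ = [
    "SEUROP_CLASSES",
    "DEFAULT_SEUROP_THRESHOLDS",
    "SeuropClass",
    "ClassStructure",
    "EquationComparison",
    "seurop_scale",
    "classify_seurop",
    "class_structure",
    "predict_lmp",
    "compare_equations",
]

SEUROP_CLASSES = ("S", "E", "U", "R", "O", "P")

#: Lower LMP bound (inclusive) of each class above P; P takes the remainder.
DEFAULT_SEUROP_THRESHOLDS = {"S": 60.0, "E": 55.0, "U": 50.0, "R": 45.0, "O": 40.0}

# Histogram span for population LMP reports: 1-point bins over [30, 75].
HISTOGRAM_EDGES = np.arange(30.0, 76.0, 1.0)


@dataclass(frozen=True)
class SeuropClass:
    """One class of the scale with its half-open LMP interval [lower, upper)."""

    label: str
    lower: float
    upper: float


def seurop_scale(thresholds: dict[str, float] | None = None) -> list[SeuropClass]:
    """The ordered scale S..P as half-open intervals partitioning (0, 100]."""
    t = DEFAULT_SEUROP_THRESHOLDS if thresholds is None else thresholds
    lowers = [t[c] for c in SEUROP_CLASSES[:-1]]
    if lowers != sorted(lowers, reverse=True):
        raise ValueError("class thresholds must be strictly decreasing from S to O")
    uppers = [np.inf] + lowers
    return [
        SeuropClass(label=c, lower=lo, upper=up)
        for c, lo, up in zip(SEUROP_CLASSES, lowers + [0.0], uppers)
    ]


def classify_seurop(lmp: float, thresholds: dict[str, float] | None = None) -> str:
    """Class label for one lean meat percentage in (0, 100]."""
    if not np.isfinite(lmp) or not 0.0 < lmp <= 100.0:
        raise ValueError(f"LMP {lmp} outside (0, 100]")
    for cls in seurop_scale(thresholds):
        if lmp >= cls.lower:
            return cls.label
    return SEUROP_CLASSES[-1]  # pragma: no cover - lower bound of P is 0


def _classify_array(lmps: np.ndarray, thresholds: dict[str, float] | None) -> np.ndarray:
    """Vectorized classification; returns integer class indices (0 = S)."""
    scale = seurop_scale(thresholds)
    lowers = np.array([c.lower for c in scale])  # decreasing
    # class index = first i with lmp >= lowers[i]  <=>  -lmp <= -lowers[i]
    idx = np.searchsorted(-lowers, -np.asarray(lmps, dtype=float), side="left")
    return np.clip(idx, 0, len(scale) - 1)


@dataclass
class ClassStructure:
    """Counts and shares of a carcass population across the six classes."""

    counts: dict[str, int]
    shares: dict[str, float]
    n_total: int

    def share_pct(self, label: str, decimals: int = 2) -> float:
        return round(100.0 * self.shares[label], decimals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(SEUROP_CLASSES),
                "count": [self.counts[c] for c in SEUROP_CLASSES],
                "share_pct": [self.share_pct(c) for c in SEUROP_CLASSES],
            }
        )


def class_structure(
    lmps, thresholds: dict[str, float] | None = None
) -> ClassStructure:
    """Class structure of a list/array of lean meat percentages."""
    arr = np.asarray(lmps, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one LMP value")
    if np.any(~np.isfinite(arr)) or np.any((arr <= 0) | (arr > 100)):
        raise ValueError("all LMP values must lie in (0, 100]")
    idx = _classify_array(arr, thresholds)
    counts = np.bincount(idx, minlength=len(SEUROP_CLASSES))
    return ClassStructure(
        counts={c: int(counts[i]) for i, c in enumerate(SEUROP_CLASSES)},
        shares={c: float(counts[i] / arr.size) for i, c in enumerate(SEUROP_CLASSES)},
        n_total=int(arr.size),
    )


def predict_lmp(eq: PredictionEquation, f2, m2):
    """Evaluate a prediction equation; clamp to [0, 100] with a warning.

    Accepts scalars or numpy arrays (element-wise).
    """
    f2a = np.asarray(f2, dtype=float)
    m2a = np.asarray(m2, dtype=float)
    if np.any(~np.isfinite(f2a)) or np.any(~np.isfinite(m2a)):
        raise ValueError("measurements must be finite")
    if np.any(f2a <= 0) or np.any(m2a <= 0):
        raise ValueError("measurements must be positive")
    lmp = eq(f2a, m2a)
    out_of_range = (lmp < 0) | (lmp > 100)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.sum(out_of_range))} prediction(s) outside [0, 100] were clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        lmp = np.clip(lmp, 0.0, 100.0)
    return float(lmp) if np.isscalar(f2) and np.isscalar(m2) else lmp


@dataclass
class EquationComparison:
    """Population-level contrast of two prediction equations on one table."""

    mean_lmp_old: float
    mean_lmp_new: float
    mean_shift: float
    class_migration: pd.DataFrame  # rows: old class, cols: new class
    structure_old: ClassStructure
    structure_new: ClassStructure
    histogram_edges: np.ndarray = field(repr=False)
    histogram_old: np.ndarray = field(repr=False)
    histogram_new: np.ndarray = field(repr=False)
    n: int = 0


def compare_equations(
    measurements: pd.DataFrame,
    eq_old: PredictionEquation,
    eq_new: PredictionEquation,
    thresholds: dict[str, float] | None = None,
) -> EquationComparison:
    """Apply two equations to a measurement table and contrast the results.

    ``measurements`` needs columns ``f2_mm`` and ``m2_mm``.  The migration
    matrix row sums reproduce the old-equation class counts and column sums
    the new-equation counts.
    """
    if measurements.empty:
        raise ValueError("measurement table is empty")
    for col in ("f2_mm", "m2_mm"):
        if col not in measurements.columns:
            raise ValueError(f"measurement table lacks column {col!r}")
    f2 = measurements["f2_mm"].to_numpy(dtype=float)
    m2 = measurements["m2_mm"].to_numpy(dtype=float)
    lmp_old = predict_lmp(eq_old, f2, m2)
    lmp_new = predict_lmp(eq_new, f2, m2)

    idx_old = _classify_array(lmp_old, thresholds)
    idx_new = _classify_array(lmp_new, thresholds)
    k = len(SEUROP_CLASSES)
    migration = np.zeros((k, k), dtype=int)
    np.add.at(migration, (idx_old, idx_new), 1)

    return EquationComparison(
        mean_lmp_old=float(lmp_old.mean()),
        mean_lmp_new=float(lmp_new.mean()),
        mean_shift=float(lmp_new.mean() - lmp_old.mean()),
        class_migration=pd.DataFrame(
            migration, index=list(SEUROP_CLASSES), columns=list(SEUROP_CLASSES)
        ),
        structure_old=class_structure(lmp_old, thresholds),
        structure_new=class_structure(lmp_new, thresholds),
        histogram_edges=HISTOGRAM_EDGES.copy(),
        histogram_old=np.histogram(lmp_old, bins=HISTOGRAM_EDGES)[0],
        histogram_new=np.histogram(lmp_new, bins=HISTOGRAM_EDGES)[0],
        n=len(f2),
    )
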