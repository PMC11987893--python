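"""Linear lean-meat prediction equations for optical-probe carcass measurements.

A grading device measures backfat depth (F2, mm) and loin muscle depth
(M2, mm) at the third/fourth-last rib, 6 cm off the dorsal midline, and the
lean meat percentage (LMP) is predicted by a linear equation fitted during
the device's authorization trial::

    LMP = intercept + coef_f2 * F2 + coef_m2 * M2

Fat adds, muscle subtracts from the carcass lean fraction, so ``coef_f2``
is expected to be negative and ``coef_m2`` positive.  The two built-in
equations are the Polish CGM optical-needle equations from the 2011 and
2023 authorization trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PredictionEquation", "EQ_2011", "EQ_2023", "BUILTIN_EQUATIONS"]


@dataclass(frozen=True)
class PredictionEquation:
    """A linear LMP prediction equation on (F2, M2).

    Parameters
    ----------
    intercept : float
        Constant term, % lean meat.
    coef_f2 : float
        Slope on backfat depth, % per mm (typically negative).
    coef_m2 : float
        Slope on loin muscle depth, % per mm (typically positive).
    label : str
        Provenance of the equation (e.g. trial year or "fitted").
    """

    intercept: float
    coef_f2: float
    coef_m2: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("intercept", "coef_f2", "coef_m2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def __call__(self, f2, m2):
        """Evaluate the equation; accepts scalars or numpy arrays."""
        return self.intercept + self.coef_f2 * f2 + self.coef_m2 * m2

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_f2": self.coef_f2,
            "coef_m2": self.coef_m2,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionEquation":
        return cls(
            intercept=float(d["intercept"]),
            coef_f2=float(d["coef_f2"]),
            coef_m2=float(d["coef_m2"]),
            label=str(d.get("label", "")),
        )


#: CGM equation from the 2011 authorization trial.
EQ_2011 = PredictionEquation(59.42, -0.6275, 0.1322, label="2011")

#: CGM equation from the 2023 authorization trial.
EQ_2023 = PredictionEquation(60.7538, -0.6465, 0.1243, label="2023")

BUILTIN_EQUATIONS = {"2011": EQ_2011, "2023": EQ_2023}
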