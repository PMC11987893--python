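"""Lean meat percentage from partial and total dissection, and the scaling factor.

The EU reference method dissects four main cuts (shoulder, loin, ham,
belly) plus the tenderloin of the left half carcass::

    YPD = 100 * (tenderloin + lean of the four cuts)
              / (tenderloin + joint weights of the four cuts)

Total dissection separates lean from the entire half carcass::

    YTD = 100 * total lean weight / half-carcass weight

Partial dissection systematically over-states lean content (the four cuts
are leaner than the whole carcass), so the reference LMP applies a bias
correction estimated on a total-dissection subsample::

    SF = mean(YTD) / mean(YPD)          LMP_ref = YPD * SF

SF is conventionally rounded to two decimals before application.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .population import CutWeights

__all__ = ["ScalingFactor", "compute_ypd", "compute_ytd", "compute_sf", "apply_sf"]


@dataclass(frozen=True)
class ScalingFactor:
    """Partial-to-total dissection bias correction.

    ``value`` is the applied factor (rounded to ``decimals`` places when
    ``rounded``); the unrounded subsample means are kept for diagnostics.
    """

    value: float
    ytd_mean: float
    ypd_mean: float
    n_subsample: int
    rounded: bool = True
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"scaling factor must be positive, got {self.value}")


def _round_half_up(x: float, decimals: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def compute_ypd(cw: CutWeights) -> float:
    """Partial-dissection lean meat percentage of a half carcass."""
    joints = cw.joint_shoulder + cw.joint_loin + cw.joint_ham + cw.joint_belly
    leans = cw.lean_shoulder + cw.lean_loin + cw.lean_ham + cw.lean_belly
    denom = cw.tenderloin + joints
    if denom <= 0:
        raise ValueError("tenderloin + joint weights must be positive")
    return 100.0 * (cw.tenderloin + leans) / denom


def compute_ytd(total_lean_weight: float, half_carcass_weight: float) -> float:
    """Total-dissection lean meat percentage of a half carcass."""
    if half_carcass_weight <= 0:
        raise ValueError("half-carcass weight must be positive")
    if not 0.0 <= total_lean_weight <= half_carcass_weight:
        raise ValueError(
            f"total lean weight {total_lean_weight} kg must lie in "
            f"[0, {half_carcass_weight}] kg"
        )
    return 100.0 * total_lean_weight / half_carcass_weight


def compute_sf(
    ytd_values: Sequence[float],
    ypd_values: Sequence[float],
    round_to: Optional[int] = 2,
) -> ScalingFactor:
    """Scaling factor from paired subsample LMP values: mean(YTD) / mean(YPD).

    The ratio-of-means convention is used (not the mean of per-carcass
    ratios).  ``round_to`` rounds the applied value half-up to that many
    decimals; pass ``None`` to keep full precision.
    """
    ytd = np.asarray(ytd_values, dtype=float)
    ypd = np.asarray(ypd_values, dtype=float)
    if ytd.size == 0 or ypd.size == 0:
        raise ValueError("subsample LMP lists must be non-empty")
    if ytd.shape != ypd.shape:
        raise ValueError(f"paired lists must have equal length ({ytd.size} vs {ypd.size})")
    ypd_mean = float(ypd.mean())
    ytd_mean = float(ytd.mean())
    if ypd_mean == 0:
        raise ValueError("mean partial-dissection LMP is zero")
    raw = ytd_mean / ypd_mean
    value = _round_half_up(raw, round_to) if round_to is not None else raw
    return ScalingFactor(
        value=value,
        ytd_mean=ytd_mean,
        ypd_mean=ypd_mean,
        n_subsample=int(ytd.size),
        rounded=round_to is not None,
        decimals=round_to if round_to is not None else -1,
    )


def apply_sf(ypd: float, sf: ScalingFactor) -> float:
    """Bias-corrected reference LMP: YPD times the scaling factor."""
    if not 0.0 < ypd <= 100.0:
        raise ValueError(f"partial-dissection LMP {ypd} outside (0, 100]")
    return ypd * sf.value
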