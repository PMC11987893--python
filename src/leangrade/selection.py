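"""Stratified selection of carcasses for a dissection trial.

A grading-device trial samples carcasses across a 3x3 grid of backfat
(thin / medium / fat) by hot-carcass-weight (light / medium / heavy) cells,
with required counts per cell chosen so that both marginals follow a
1:2:1 ratio, plus a ~10% subsample flagged for total dissection.

The default plan uses backfat groups 1–3 with boundaries at 10 and 18 mm,
weight groups A–C with boundaries at 84.4 and 105.5 kg (plan range
60–120 kg), 126 partial-dissection carcasses and a 12-carcass subsample.
Boundaries are treated as upper-inclusive so every measurement in range
falls into exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import Carcass

__all__ = [
    "StratificationPlan",
    "SelectionResult",
    "PlanValidation",
    "default_plan",
    "assign_fat_group",
    "assign_weight_group",
    "select_sample",
    "validate_plan",
]

WEIGHT_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class StratificationPlan:
    """Bin edges and required counts for the fat x weight sampling grid.

    ``fat_edges`` are the inner upper boundaries of the fat groups (mm,
    upper-inclusive); ``weight_edges`` likewise for weight groups (kg);
    ``weight_range`` is the admissible hot-weight interval.  Count matrices
    are indexed [weight group, fat group].
    """

    fat_edges: tuple[float, ...] = (10.0, 18.0)
    weight_edges: tuple[float, ...] = (84.4, 105.5)
    weight_range: tuple[float, float] = (60.0, 120.0)
    required_counts: np.ndarray = field(
        default_factory=lambda: np.array([[7, 18, 7], [16, 30, 16], [7, 18, 7]])
    )
    required_subsample: np.ndarray = field(
        default_factory=lambda: np.array([[1, 2, 1], [1, 2, 1], [1, 2, 1]])
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_counts", np.asarray(self.required_counts, dtype=int))
        object.__setattr__(
            self, "required_subsample", np.asarray(self.required_subsample, dtype=int)
        )
        n_fat, n_weight = len(self.fat_edges) + 1, len(self.weight_edges) + 1
        if self.required_counts.shape != (n_weight, n_fat):
            raise ValueError(
                f"required_counts shape {self.required_counts.shape} does not match "
                f"{n_weight} weight x {n_fat} fat groups"
            )
        if self.required_subsample.shape != self.required_counts.shape:
            raise ValueError("required_subsample shape must match required_counts")
        if list(self.fat_edges) != sorted(self.fat_edges) or list(self.weight_edges) != sorted(
            self.weight_edges
        ):
            raise ValueError("bin edges must be increasing")
        if np.any(self.required_subsample > self.required_counts):
            raise ValueError("each subsample cell must not exceed its sample cell")
        if np.any(self.required_counts < 0):
            raise ValueError("required counts must be non-negative")

    @property
    def n_required(self) -> int:
        return int(self.required_counts.sum())

    @property
    def n_subsample(self) -> int:
        return int(self.required_subsample.sum())


def default_plan() -> StratificationPlan:
    """The 126-carcass / 12-subsample trial plan."""
    return StratificationPlan()


def assign_fat_group(f2: float, plan: StratificationPlan | None = None) -> int:
    """Map a backfat depth (mm) to its fat group (1-based).

    Group 1 <=> f2 <= 10, group 2 <=> 10 < f2 <= 18, group 3 <=> f2 > 18
    under the default plan.
    """
    if plan is None:
        plan = default_plan()
    if not np.isfinite(f2) or f2 <= 0:
        raise ValueError(f"backfat depth must be positive and finite, got {f2}")
    return int(np.searchsorted(plan.fat_edges, f2, side="left")) + 1


def assign_weight_group(hot_weight: float, plan: StratificationPlan | None = None) -> str:
    """Map a hot carcass weight (kg) to its weight group label ("A", "B", ...).

    Weights outside the plan range are rejected; boundaries are
    upper-inclusive (84.4 -> A, 84.5 -> B under the default plan).
    """
    if plan is None:
        plan = default_plan()
    lo, hi = plan.weight_range
    if not np.isfinite(hot_weight) or not lo <= hot_weight <= hi:
        raise ValueError(f"hot weight {hot_weight} kg outside the plan range [{lo}, {hi}] kg")
    idx = int(np.searchsorted(plan.weight_edges, hot_weight, side="left"))
    return WEIGHT_LABELS[idx] if idx < len(WEIGHT_LABELS) else str(idx)


@dataclass
class SelectionResult:
    """Outcome of a stratified draw.

    ``selected`` carries the drawn carcasses with parallel ``fat_groups`` /
    ``weight_groups`` labels and ``in_subsample`` flags; ``achieved_counts``
    is the [weight, fat] matrix of what was actually drawn; ``shortfalls``
    lists (weight label, fat group, deficit) for under-filled cells.
    """

    selected: list[Carcass]
    fat_groups: list[int]
    weight_groups: list[str]
    in_subsample: list[bool]
    achieved_counts: np.ndarray
    achieved_subsample: np.ndarray
    shortfalls: list[tuple[str, int, int]]

    @property
    def subsample(self) -> list[Carcass]:
        return [c for c, s in zip(self.selected, self.in_subsample) if s]


def select_sample(
    population: list[Carcass], plan: StratificationPlan, seed: int
) -> SelectionResult:
    """Draw the dissection sample and total-dissection subsample.

    Within each (weight, fat) cell, candidates are drawn uniformly at
    random without replacement up to the required count; cells with too few
    candidates are recorded as shortfalls, never raised.  The subsample is
    drawn from the selected carcasses of each cell.  Carcasses outside the
    plan's weight range are simply not candidates.
    """
    if not population:
        raise ValueError("population is empty")
    ids = [c.id for c in population]
    if len(set(ids)) != len(ids):
        raise ValueError("population contains duplicate carcass ids")

    rng = np.random.default_rng(seed)
    n_weight, n_fat = plan.required_counts.shape
    lo, hi = plan.weight_range
    cells: dict[tuple[int, int], list[Carcass]] = {
        (w, f): [] for w in range(n_weight) for f in range(n_fat)
    }
    for c in population:
        if not lo <= c.hot_weight <= hi:
            continue
        f = assign_fat_group(c.f2, plan) - 1
        w = WEIGHT_LABELS.index(assign_weight_group(c.hot_weight, plan))
        cells[(w, f)].append(c)

    selected: list[Carcass] = []
    fat_groups: list[int] = []
    weight_groups: list[str] = []
    in_subsample: list[bool] = []
    achieved = np.zeros_like(plan.required_counts)
    achieved_sub = np.zeros_like(plan.required_subsample)
    shortfalls: list[tuple[str, int, int]] = []

    for (w, f), members in cells.items():
        need = int(plan.required_counts[w, f])
        take = min(need, len(members))
        if take < need:
            shortfalls.append((WEIGHT_LABELS[w], f + 1, need - take))
        picked_idx = rng.choice(len(members), size=take, replace=False) if take else []
        picked = [members[i] for i in picked_idx]
        need_sub = min(int(plan.required_subsample[w, f]), take)
        sub_idx = set(rng.choice(take, size=need_sub, replace=False).tolist()) if need_sub else set()
        for j, c in enumerate(picked):
            selected.append(c)
            fat_groups.append(f + 1)
            weight_groups.append(WEIGHT_LABELS[w])
            in_subsample.append(j in sub_idx)
        achieved[w, f] = take
        achieved_sub[w, f] = need_sub

    return SelectionResult(
        selected=selected,
        fat_groups=fat_groups,
        weight_groups=weight_groups,
        in_subsample=in_subsample,
        achieved_counts=achieved,
        achieved_subsample=achieved_sub,
        shortfalls=sorted(shortfalls),
    )


@dataclass
class PlanValidation:
    """Report-only design checks on a stratification plan."""

    fat_ratio_ok: bool
    weight_ratio_ok: bool
    subsample_fraction_ok: bool
    fat_totals: list[int]
    weight_totals: list[int]
    subsample_fraction: float
    messages: list[str]

    @property
    def ok(self) -> bool:
        return self.fat_ratio_ok and self.weight_ratio_ok and self.subsample_fraction_ok


def _ratio_121_ok(totals: np.ndarray, tol: float) -> bool:
    """Do three group totals follow 1:2:1 within relative tolerance tol?"""
    if len(totals) != 3 or totals.sum() == 0:
        return False
    target = totals.sum() * np.array([0.25, 0.5, 0.25])
    return bool(np.all(np.abs(totals - target) <= tol * target))


def validate_plan(
    plan: StratificationPlan, ratio_tol: float = 0.2, subsample_target: float = 0.10
) -> PlanValidation:
    """Check the 1:2:1 marginal design and the ~10% total-dissection subsample.

    Both checks are report-only; ``ratio_tol`` is the relative deviation
    allowed from the ideal 1:2:1 split and from the subsample target.
    """
    fat_totals = plan.required_counts.sum(axis=0)
    weight_totals = plan.required_counts.sum(axis=1)
    frac = plan.n_subsample / plan.n_required if plan.n_required else 0.0
    fat_ok = _ratio_121_ok(fat_totals, ratio_tol)
    weight_ok = _ratio_121_ok(weight_totals, ratio_tol)
    sub_ok = abs(frac - subsample_target) <= ratio_tol * subsample_target
    messages = []
    if not fat_ok:
        messages.append(f"fat-group totals {fat_totals.tolist()} deviate from 1:2:1")
    if not weight_ok:
        messages.append(f"weight-group totals {weight_totals.tolist()} deviate from 1:2:1")
    if not sub_ok:
        messages.append(
            f"subsample is {100 * frac:.1f}% of the sample "
            f"(target {100 * subsample_target:.0f}%)"
        )
    return PlanValidation(
        fat_ratio_ok=fat_ok,
        weight_ratio_ok=weight_ok,
        subsample_fraction_ok=sub_ok,
        fat_totals=fat_totals.tolist(),
        weight_totals=weight_totals.tolist(),
        subsample_fraction=frac,
        messages=messages,
    )
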