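"""End-to-end trial pipeline: simulate, select, dissect, calibrate, grade, compare.

Mirrors the stages of a grading-device authorization trial: draw (or load)
a carcass population, select the stratified dissection sample plus the
total-dissection subsample, compute partial/total dissection LMP and the
scaling factor, fit and cross-validate the prediction equation, grade the
whole population with it, and contrast it against an incumbent equation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io
from .calibration import RMSEP_LIMIT, CalibrationDataset, CalibrationReport, calibrate
from .dissection import apply_sf, compute_sf, compute_ypd, compute_ytd
from .equations import BUILTIN_EQUATIONS, PredictionEquation
from .grading import EquationComparison, compare_equations
from .population import PopulationParams, generate_cut_weights, generate_population
from .selection import SelectionResult, StratificationPlan, select_sample, validate_plan

logger = logging.getLogger("leangrade")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "resolve_equation"]


def resolve_equation(spec) -> PredictionEquation:
    """Resolve an equation from ``builtin:<label>``, a dict, or pass-through."""
    if isinstance(spec, PredictionEquation):
        return spec
    if isinstance(spec, str):
        label = spec.removeprefix("builtin:")
        if label in BUILTIN_EQUATIONS:
            return BUILTIN_EQUATIONS[label]
        raise ValueError(f"unknown builtin equation {spec!r}; have {sorted(BUILTIN_EQUATIONS)}")
    if isinstance(spec, dict):
        return PredictionEquation.from_dict(spec)
    raise TypeError(f"cannot resolve equation from {type(spec).__name__}")


@dataclass
class PipelineConfig:
    """Everything a full trial run needs.

    ``population`` maps onto the generator parameters; ``plan`` (optional)
    onto the stratification plan; the old equation defaults to the 2011
    builtin and the comparison's "new" side to the freshly fitted equation.
    """

    population: PopulationParams = field(default_factory=PopulationParams)
    plan: StratificationPlan = field(default_factory=StratificationPlan)
    sf_round_to: Optional[int] = 2
    n_components: int = 2
    cv: str = "loo"
    rmsep_limit: float = RMSEP_LIMIT
    eq_old: str | dict | PredictionEquation = "builtin:2011"
    eq_new: Optional[str | dict | PredictionEquation] = None  # None -> fitted equation
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        seed = int(cfg.get("seed", 0))
        pop_cfg = dict(cfg.get("population", {}))
        pop_cfg.setdefault("seed", seed)
        kwargs = dict(
            population=PopulationParams(**pop_cfg),
            plan=io.plan_from_config(cfg.get("plan")),
            sf_round_to=cfg.get("sf_round_to", 2),
            n_components=int(cfg.get("n_components", 2)),
            cv=cfg.get("cv", "loo"),
            rmsep_limit=float(cfg.get("rmsep_limit", RMSEP_LIMIT)),
            eq_old=cfg.get("eq_old", "builtin:2011"),
            eq_new=cfg.get("eq_new"),
            seed=seed,
        )
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Artifacts and summary statistics of one full run."""

    population: list
    selection: SelectionResult
    sf: object
    calibration: CalibrationReport
    comparison: EquationComparison
    summary: dict


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> PipelineResult:
    """Execute all stages in order; deterministic for a fixed config/seed.

    When ``outdir`` is given, per-stage CSV artifacts plus ``report.json``
    and ``report.md`` are written there.  Stage failures propagate with the
    stage named in the log; artifacts written before the failure remain.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()
        return name

    def _done(name, msg, *args):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.2fs: " + msg, name, timings[name], *args)

    # -- simulate -----------------------------------------------------------
    s = _stage("simulate")
    params = config.population.with_(seed=config.seed)
    population = generate_population(params)
    _done(s, "%d carcasses", len(population))
    if out is not None:
        io.write_population_csv(population, out / "population.csv")

    # -- select -------------------------------------------------------------
    s = _stage("select")
    plan_report = validate_plan(config.plan)
    selection = select_sample(population, config.plan, seed=config.seed + 1)
    _done(s, "%d selected, %d subsample, %d shortfall cells",
          len(selection.selected), len(selection.subsample), len(selection.shortfalls))
    if out is not None:
        io.write_selection_csv(selection, out / "selection.csv")

    # -- dissect ------------------------------------------------------------
    s = _stage("dissect")
    cut_rows = []
    ypd: list[float] = []
    sub_ytd: list[float] = []
    sub_ypd: list[float] = []
    for j, c in enumerate(selection.selected):
        cw = generate_cut_weights(c, seed=config.seed + 1000 + j)
        cut_rows.append(io.cut_weights_to_row(c.id, cw))
        y = compute_ypd(cw)
        ypd.append(y)
        if selection.in_subsample[j]:
            sub_ypd.append(y)
            sub_ytd.append(compute_ytd(cw.total_lean_weight, cw.half_carcass_weight))
    if not sub_ytd:
        raise RuntimeError("dissect: no total-dissection subsample was drawn; cannot compute SF")
    sf = compute_sf(sub_ytd, sub_ypd, round_to=config.sf_round_to)
    lmp_ref = [apply_sf(y, sf) for y in ypd]
    _done(s, "SF=%.4f from %d subsample carcasses", sf.value, sf.n_subsample)
    if out is not None:
        io.write_cut_weights_csv(cut_rows, out / "dissection.csv")

    # -- calibrate ----------------------------------------------------------
    s = _stage("calibrate")
    data = CalibrationDataset(
        f2=np.array([c.f2 for c in selection.selected]),
        m2=np.array([c.m2 for c in selection.selected]),
        lmp_ref=np.array(lmp_ref),
    )
    report = calibrate(data, n_components=config.n_components, cv=config.cv,
                       limit=config.rmsep_limit)
    _done(s, "RMSEP=%.3f authorized=%s", report.rmsep, report.authorized)

    # -- grade + compare ----------------------------------------------------
    s = _stage("compare")
    eq_old = resolve_equation(config.eq_old)
    eq_new = resolve_equation(config.eq_new) if config.eq_new is not None else report.equation
    frame = io.population_to_frame(population, latent=False)
    comparison = compare_equations(frame, eq_old, eq_new)
    _done(s, "mean shift %+.3f pp over %d carcasses", comparison.mean_shift, comparison.n)

    summary = {
        "seed": config.seed,
        "n_population": len(population),
        "plan": {
            "required_total": config.plan.n_required,
            "required_subsample": config.plan.n_subsample,
            "design_checks_ok": plan_report.ok,
            "messages": plan_report.messages,
        },
        "selection": {
            "n_selected": len(selection.selected),
            "n_subsample": len(selection.subsample),
            "shortfalls": [
                {"weight_group": w, "fat_group": f, "deficit": d}
                for w, f, d in selection.shortfalls
            ],
        },
        "scaling_factor": {
            "value": sf.value,
            "ytd_mean": sf.ytd_mean,
            "ypd_mean": sf.ypd_mean,
            "n_subsample": sf.n_subsample,
        },
        "calibration": report.to_dict(),
        "comparison": {
            "eq_old": eq_old.to_dict(),
            "eq_new": eq_new.to_dict(),
            "mean_lmp_old": comparison.mean_lmp_old,
            "mean_lmp_new": comparison.mean_lmp_new,
            "mean_shift_pp": comparison.mean_shift,
            "class_shares_old_pct": {
                c: comparison.structure_old.share_pct(c) for c in comparison.structure_old.counts
            },
            "class_shares_new_pct": {
                c: comparison.structure_new.share_pct(c) for c in comparison.structure_new.counts
            },
        },
    }
    if out is not None:
        (out / "report.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
        (out / "report.md").write_text(_markdown_report(summary), encoding="utf-8")

    return PipelineResult(
        population=population,
        selection=selection,
        sf=sf,
        calibration=report,
        comparison=comparison,
        summary=summary,
    )


def _markdown_report(summary: dict) -> str:
    sel = summary["selection"]
    sf = summary["scaling_factor"]
    cal = summary["calibration"]
    cmp_ = summary["comparison"]
    eq = cal["equation"]
    lines = [
        "# Grading trial report",
        "",
        f"Population: {summary['n_population']} carcasses (seed {summary['seed']})",
        "",
        "## Selection",
        f"- selected {sel['n_selected']} of {summary['plan']['required_total']} required; "
        f"subsample {sel['n_subsample']} of {summary['plan']['required_subsample']}",
        f"- shortfall cells: {len(sel['shortfalls'])}",
        "",
        "## Scaling factor",
        f"- mean YTD {sf['ytd_mean']:.2f} %, mean YPD {sf['ypd_mean']:.2f} % "
        f"(n = {sf['n_subsample']}) -> SF = {sf['value']:.2f}",
        "",
        "## Calibration",
        f"- LMP = {eq['intercept']:.4f} + ({eq['coef_f2']:.4f})*F2 + ({eq['coef_m2']:.4f})*M2",
        f"- RMSEP (leave-one-out) = {cal['rmsep']:.3f} %  (limit {cal['limit']}) -> "
        f"{'AUTHORIZED' if cal['authorized'] else 'NOT AUTHORIZED'}",
        "",
        "## Equation comparison",
        f"- mean LMP old {cmp_['mean_lmp_old']:.2f} %, new {cmp_['mean_lmp_new']:.2f} %, "
        f"shift {cmp_['mean_shift_pp']:+.2f} pp",
        "- class shares (old -> new, %):",
    ]
    for c in cmp_["class_shares_old_pct"]:
        lines.append(
            f"  - {c}: {cmp_['class_shares_old_pct'][c]:.2f} -> "
            f"{cmp_['class_shares_new_pct'][c]:.2f}"
        )
    lines.append("")
    return "\n".join(lines)
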