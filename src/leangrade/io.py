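"""CSV and config file I/O.

All tables are plain CSV with dot decimal separators, UTF-8 and
unit-suffixed headers (``hot_weight_kg``, ``f2_mm``, ``m2_mm``) to keep
units unambiguous.  Configs are flat YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .population import Carcass, CutWeights
from .selection import SelectionResult, StratificationPlan

__all__ = [
    "CARCASS_COLUMNS",
    "read_carcass_csv",
    "write_population_csv",
    "write_selection_csv",
    "read_cut_weights_csv",
    "write_cut_weights_csv",
    "load_config",
    "plan_from_config",
]

CARCASS_COLUMNS = ["id", "sex", "hot_weight_kg", "f2_mm", "m2_mm"]
OPTIONAL_CARCASS_COLUMNS = ["ytd_true", "ypd_obs"]

CUT_COLUMNS = [
    "id",
    "tenderloin_kg",
    "joint_shoulder_kg",
    "joint_loin_kg",
    "joint_ham_kg",
    "joint_belly_kg",
    "lean_shoulder_kg",
    "lean_loin_kg",
    "lean_ham_kg",
    "lean_belly_kg",
    "half_carcass_kg",
    "total_lean_kg",
]


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row} (dot-decimal CSV expected)"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {row}")
        df[col] = parsed
    return df


def read_carcass_csv(path) -> list[Carcass]:
    """Read a carcass measurement table into typed records.

    Requires ``id, sex, hot_weight_kg, f2_mm, m2_mm``; ``ytd_true`` and
    ``ypd_obs`` are picked up when present.  Duplicate ids, missing columns
    and non-numeric fields are reported with their location.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, CARCASS_COLUMNS, path)
    numeric = ["hot_weight_kg", "f2_mm", "m2_mm"] + [
        c for c in OPTIONAL_CARCASS_COLUMNS if c in df.columns
    ]
    df = _numeric(df, numeric, path)
    dupes = df["id"][df["id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(f"{path}: duplicate carcass id(s): {', '.join(dupes.unique())}")
    out = []
    for _, r in df.iterrows():
        out.append(
            Carcass(
                id=str(r["id"]),
                sex=str(r["sex"]),
                hot_weight=float(r["hot_weight_kg"]),
                f2=float(r["f2_mm"]),
                m2=float(r["m2_mm"]),
                ytd_true=float(r["ytd_true"]) if "ytd_true" in df.columns else None,
                ypd_obs=float(r["ypd_obs"]) if "ypd_obs" in df.columns else None,
            )
        )
    return out


def population_to_frame(population: list[Carcass], latent: bool = True) -> pd.DataFrame:
    data = {
        "id": [c.id for c in population],
        "sex": [c.sex for c in population],
        "hot_weight_kg": [c.hot_weight for c in population],
        "f2_mm": [c.f2 for c in population],
        "m2_mm": [c.m2 for c in population],
    }
    if latent and all(c.ytd_true is not None for c in population):
        data["ytd_true"] = [c.ytd_true for c in population]
        data["ypd_obs"] = [c.ypd_obs for c in population]
    return pd.DataFrame(data)


def write_population_csv(population: list[Carcass], path, latent: bool = True) -> None:
    """Write a population table; floats at 6 significant digits."""
    population_to_frame(population, latent=latent).to_csv(
        path, index=False, float_format="%.6g"
    )


def write_selection_csv(result: SelectionResult, path) -> None:
    """Write the selected sample with stratum labels and subsample flags."""
    df = population_to_frame(result.selected)
    df["fat_group"] = result.fat_groups
    df["weight_group"] = result.weight_groups
    df["in_subsample"] = np.asarray(result.in_subsample, dtype=int)
    df.to_csv(path, index=False, float_format="%.6g")


def cut_weights_to_row(carcass_id: str, cw: CutWeights) -> dict:
    return {
        "id": carcass_id,
        "tenderloin_kg": cw.tenderloin,
        "joint_shoulder_kg": cw.joint_shoulder,
        "joint_loin_kg": cw.joint_loin,
        "joint_ham_kg": cw.joint_ham,
        "joint_belly_kg": cw.joint_belly,
        "lean_shoulder_kg": cw.lean_shoulder,
        "lean_loin_kg": cw.lean_loin,
        "lean_ham_kg": cw.lean_ham,
        "lean_belly_kg": cw.lean_belly,
        "half_carcass_kg": cw.half_carcass_weight,
        "total_lean_kg": cw.total_lean_weight if cw.total_lean_weight is not None else "",
    }


def write_cut_weights_csv(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=CUT_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_cut_weights_csv(path) -> dict[str, CutWeights]:
    """Read a dissection table keyed by carcass id."""
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, [c for c in CUT_COLUMNS if c != "total_lean_kg"], path)
    out: dict[str, CutWeights] = {}
    for _, r in df.iterrows():
        total = r.get("total_lean_kg")
        out[str(r["id"])] = CutWeights(
            tenderloin=float(r["tenderloin_kg"]),
            joint_shoulder=float(r["joint_shoulder_kg"]),
            joint_loin=float(r["joint_loin_kg"]),
            joint_ham=float(r["joint_ham_kg"]),
            joint_belly=float(r["joint_belly_kg"]),
            lean_shoulder=float(r["lean_shoulder_kg"]),
            lean_loin=float(r["lean_loin_kg"]),
            lean_ham=float(r["lean_ham_kg"]),
            lean_belly=float(r["lean_belly_kg"]),
            half_carcass_weight=float(r["half_carcass_kg"]),
            total_lean_weight=float(total) if total not in (None, "") and pd.notna(total) else None,
        )
    return out


def load_config(path) -> dict:
    """Load a flat YAML or JSON config file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def plan_from_config(cfg: Optional[dict]) -> StratificationPlan:
    """Build a stratification plan from a config mapping (defaults when None)."""
    if not cfg:
        return StratificationPlan()
    kwargs = {}
    if "fat_edges" in cfg:
        kwargs["fat_edges"] = tuple(float(x) for x in cfg["fat_edges"])
    if "weight_edges" in cfg:
        kwargs["weight_edges"] = tuple(float(x) for x in cfg["weight_edges"])
    if "weight_range" in cfg:
        kwargs["weight_range"] = tuple(float(x) for x in cfg["weight_range"])
    if "required_counts" in cfg:
        kwargs["required_counts"] = np.asarray(cfg["required_counts"], dtype=int)
    if "required_subsample" in cfg:
        kwargs["required_subsample"] = np.asarray(cfg["required_subsample"], dtype=int)
    return StratificationPlan(**kwargs)
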