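"""Scenario configs, PK CSV readers/writers and the end-to-end scenario runner.

Config files and CSV schemas are deliberately flat and human-diffable, with
units fixed by the package convention (μg / L / h; blood in ng/mL) and made
explicit in key names where a value crosses the interface in a different
unit (``dose_mg``).  Unit mistakes are the dominant failure mode of PK
reimplementation, so the readers validate units and reject unknown symbols.
"""

from __future__ import annotations

import json
import logging
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import ivive, pbpk
from .parameters import (
    CompoundParams,
    DoseRegimen,
    MICROGRAMS_PER_MILLIGRAM,
    Physiology,
    human_params,
    rat_cotinine_params,
    rat_nicotine_params,
)
from .synth import BLOOD, URINE, UNITS, PKDataset

logger = logging.getLogger("nicopbpk")

_COMPOUND_SYMBOLS = {"cl_h_int", "cl_r", "kp_h", "fu_p", "rb", "v1"}
_REGIMEN_SYMBOLS = {"ka", "fa_fg"}
VALID_OVERRIDES = sorted(
    {f"{c}.{s}" for c in ("nicotine", "cotinine") for s in _COMPOUND_SYMBOLS}
    | {f"regimen.{s}" for s in _REGIMEN_SYMBOLS}
    | {"physiology.q_h", "physiology.v_h"}
)


class ScenarioConfig(BaseModel):
    """A complete, reproducible simulation scenario."""

    model_config = ConfigDict(frozen=True)

    name: str
    species: Literal["rat", "human"]
    dose_mg: float
    n_doses: int = 1
    interval_h: float = 24.0
    t_end_h: float = 48.0
    grid_h: float = pbpk.DEFAULT_GRID
    overrides: dict[str, float] = {}
    formation_factor: float = 1.0
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")
        unknown = set(self.overrides) - set(VALID_OVERRIDES)
        if unknown:
            raise ValueError(
                f"unknown override symbols {sorted(unknown)}; "
                f"valid symbols: {VALID_OVERRIDES}"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def _build_parameter_sets(config: ScenarioConfig):
    if config.species == "rat":
        nic, phys, base_reg = rat_nicotine_params()
        cot = rat_cotinine_params()
    else:
        nic, cot, phys, base_reg = human_params()
    regimen = base_reg.model_copy(
        update={
            "dose_amount": config.dose_mg * MICROGRAMS_PER_MILLIGRAM,
            "n_doses": config.n_doses,
            "interval": config.interval_h,
        }
    )
    objs = {"nicotine": nic, "cotinine": cot, "regimen": regimen, "physiology": phys}
    for key, value in sorted(config.overrides.items()):
        section, symbol = key.split(".", 1)
        objs[section] = objs[section].model_copy(update={symbol: value})
        logger.info("override %s = %s (fixture value replaced)", key, value)
    for section in ("nicotine", "cotinine", "regimen", "physiology"):
        src = "override" if any(k.startswith(section + ".") for k in config.overrides) \
            else "fixture"
        logger.info("%s parameters: %s", section, src)
    return objs["nicotine"], objs["cotinine"], objs["physiology"], objs["regimen"]


def run_scenario(config: ScenarioConfig, profile_csv=None) -> tuple[pbpk.SimulationResult, dict]:
    """Simulate a scenario and summarize it.

    Returns the trajectory and a report with 1-h concentrations, Cmax/tmax,
    AUC, and the well-stirred hepatic clearance of nicotine, all with units
    in the key names.  Writes the tidy profile CSV when ``profile_csv`` is
    given.  Reports are byte-stable for identical configs.
    """
    nic, cot, phys, regimen = _build_parameter_sets(config)
    result = pbpk.simulate(
        nic, cot, phys, regimen,
        t_end=config.t_end_h,
        grid=config.grid_h,
        formation_factor=config.formation_factor,
    )
    cl = ivive.clearance_set(nic, phys)
    logger.info(
        "well-stirred CL_h <- q_h=%.4g * fu_p=%.4g * cl_h_int=%.4g L/h -> %.4g L/h",
        phys.q_h, nic.fu_p, nic.cl_h_int, cl.cl_h,
    )
    report: dict = {"scenario": config.name, "species": config.species,
                    "dose_mg": config.dose_mg, "n_doses": config.n_doses}
    t_last = regimen.dose_times[-1]
    for compound in (pbpk.NICOTINE, pbpk.COTININE):
        cmax, tmax = result.cmax(compound)
        report[f"{compound}_cmax_ng_per_ml"] = round(cmax, 6)
        report[f"{compound}_tmax_h"] = round(tmax, 6)
        report[f"{compound}_auc_ug_h_per_l"] = round(
            result.auc(compound, 0.0, config.t_end_h), 6
        )
        if t_last + 1.0 <= config.t_end_h:
            report[f"{compound}_c_1h_post_final_dose_ng_per_ml"] = round(
                result.concentration_at(compound, t_last + 1.0), 6
            )
    report["nicotine_cl_h_wellstirred_l_per_h"] = round(cl.cl_h, 6)
    report["nicotine_e_h"] = round(cl.e_h, 6)
    if regimen.n_doses > 1:
        # accumulation is ambiguous between "steady trough" and "gain over
        # day 1": report both readings, assert neither
        trough_day1 = result.concentration_at(pbpk.COTININE, regimen.interval)
        trough_final = result.concentration_at(pbpk.COTININE, t_last)
        report["cotinine_trough_day1_ng_per_ml"] = round(trough_day1, 6)
        report["cotinine_trough_pre_final_dose_ng_per_ml"] = round(trough_final, 6)
        report["cotinine_accumulation_ng_per_ml"] = round(
            trough_final - trough_day1, 6
        )
    if profile_csv is not None:
        result.to_csv(profile_csv)
    return result, report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a scenario report."""
    return json.dumps(report, sort_keys=True, indent=2)


# Shipped scenarios reproducing the package's reference simulations.
SHIPPED_SCENARIOS: dict[str, ScenarioConfig] = {
    "rat_noael": ScenarioConfig(
        name="rat_noael", species="rat", dose_mg=0.25, n_doses=14,
        interval_h=24.0, t_end_h=14 * 24.0,
    ),
    "human_smoker": ScenarioConfig(
        name="human_smoker", species="human", dose_mg=43.4, t_end_h=48.0,
    ),
    "human_noael_single": ScenarioConfig(
        name="human_noael_single", species="human", dose_mg=70.0, t_end_h=48.0,
    ),
    "human_noael_repeated": ScenarioConfig(
        name="human_noael_repeated", species="human", dose_mg=70.0,
        n_doses=14, interval_h=24.0, t_end_h=14 * 24.0 + 24.0,
    ),
}


# ---------------------------------------------------------------------------
# PK dataset CSV I/O
# ---------------------------------------------------------------------------

PK_CSV_COLUMNS = ("time_h", "compound", "matrix", "value", "unit", "animal_id")


def write_pk_csv(dataset: PKDataset, path) -> None:
    dataset.data.to_csv(path, index=False, columns=list(PK_CSV_COLUMNS))


def read_pk_csv(path) -> PKDataset:
    """Read a PK dataset CSV, validating schema, units and times.

    Errors cite 1-based data line numbers (header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in PK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2
        if row["matrix"] not in UNITS:
            problems.append(f"line {line}: unknown matrix {row['matrix']!r}")
            continue
        if not np.isfinite(row["time_h"]) or row["time_h"] < 0:
            problems.append(f"line {line}: invalid time {row['time_h']!r}")
        expected = UNITS[row["matrix"]]
        if row["unit"] != expected:
            problems.append(
                f"line {line}: unit {row['unit']!r} invalid for {row['matrix']} "
                f"(expected {expected!r})"
            )
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return PKDataset(df[list(PK_CSV_COLUMNS)])
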