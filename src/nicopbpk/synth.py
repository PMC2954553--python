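"""Synthetic rat-study generator and named human exposure scenarios.

The generator emulates a repeated-oral-dose rat toxicokinetic study: blood
nicotine/cotinine concentrations sampled after the final of 14 daily doses,
and cumulative urinary amounts of both compounds, produced from the PBPK
model with multiplicative lognormal measurement noise (default CV 15%, the
reproducibility of the LC/MS assay the design emulates).  Every pipeline
stage is therefore testable without animal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pbpk
from .parameters import (
    CompoundParams,
    DoseRegimen,
    MICROGRAMS_PER_MILLIGRAM,
    Physiology,
)

BLOOD = "blood"
URINE = "urine_cumulative"
UNITS = {BLOOD: "ng/mL", URINE: "ug"}

DEFAULT_SAMPLE_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
DEFAULT_NOISE_CV = 0.15
DEFAULT_LLOQ = 0.5  # ng/mL
DEFAULT_N_ANIMALS = 5


@dataclass
class PKDataset:
    """Observed or synthetic PK records.

    ``data`` columns: time_h, compound, matrix (blood | urine_cumulative),
    value (ng/mL for blood, μg for urine; NaN when censored below the LLOQ),
    unit, animal_id (or "pooled").  ``provenance`` records how the dataset
    was produced (generator parameters, seed, noise CV) — empty for data read
    from files.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    REQUIRED_COLUMNS = ("time_h", "compound", "matrix", "value", "unit", "animal_id")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"PKDataset missing columns: {missing}")
        if (self.data["time_h"] < 0).any():
            raise ValueError("PKDataset contains negative times")
        bad_matrix = set(self.data["matrix"]) - {BLOOD, URINE}
        if bad_matrix:
            raise ValueError(f"unknown matrix labels: {sorted(bad_matrix)}")
        for (animal, compound), grp in self.data[self.data["matrix"] == URINE].groupby(
            ["animal_id", "compound"]
        ):
            vals = grp.sort_values("time_h")["value"].dropna().to_numpy()
            if np.any(np.diff(vals) < -1e-9 * max(1.0, vals.max(initial=0.0))):
                raise ValueError(
                    f"cumulative urine must be non-decreasing "
                    f"(animal {animal}, {compound})"
                )

    def subset(self, compound: str | None = None, matrix: str | None = None) -> pd.DataFrame:
        df = self.data
        if compound is not None:
            df = df[df["compound"] == compound]
        if matrix is not None:
            df = df[df["matrix"] == matrix]
        return df.copy()

    def pooled_mean(self) -> "PKDataset":
        """Average replicate animals at each (time, compound, matrix) point.

        Censored (NaN) observations are excluded from the mean, mirroring how
        pooled study means are reported.
        """
        df = (
            self.data.groupby(["time_h", "compound", "matrix", "unit"], as_index=False)[
                "value"
            ]
            .mean()
            .assign(animal_id="pooled")
        )
        return PKDataset(df[list(self.REQUIRED_COLUMNS)],
                         {**self.provenance, "pooled": True})


def _animal_rng(seed: int, animal_id: int) -> np.random.Generator:
    # sub-stream per (seed, animal): adding animals never reshuffles existing ones
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(animal_id))))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    # mean-one parameterization so noisy observations are unbiased
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def generate_rat_study(
    nic: CompoundParams,
    cot: CompoundParams,
    phys: Physiology,
    regimen: DoseRegimen,
    sample_times=DEFAULT_SAMPLE_TIMES,
    n_animals: int = DEFAULT_N_ANIMALS,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
    lloq: float = DEFAULT_LLOQ,
    formation_factor: float = 1.0,
) -> PKDataset:
    """Simulate a repeated-dose study and sample it like an assay would.

    Blood is sampled at ``sample_times`` hours after the final dose;
    cumulative urine is accumulated from the final dose onward (integral of
    CL_r·C_b carried by the simulator).  Multiplicative lognormal noise with
    CV ``noise_cv`` is applied independently per observation per animal —
    directly to blood concentrations, and to the nonnegative urine increments
    (then re-accumulated) so cumulative urine stays non-decreasing.  Blood
    values below ``lloq`` ng/mL are censored to NaN.  Deterministic given
    ``seed``.
    """
    if noise_cv < 0.0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    sample_times = np.asarray(sorted(sample_times), dtype=float)
    if sample_times[0] < 0.0:
        raise ValueError("sample times must be nonnegative")
    t_last = regimen.dose_times[-1]
    t_end = t_last + sample_times[-1]
    abs_times = t_last + sample_times
    result = pbpk.simulate(
        nic, cot, phys, regimen, t_end=t_end,
        t_eval=np.concatenate(([t_last], abs_times)),
        formation_factor=formation_factor,
    )

    true_blood = {
        c: result.concentration_at(c, abs_times) for c in (pbpk.NICOTINE, pbpk.COTININE)
    }
    cum_cols = {pbpk.NICOTINE: 0, pbpk.COTININE: 2}
    idx_last = int(np.argmin(np.abs(result.times - t_last)))
    idx_samples = [int(np.argmin(np.abs(result.times - t))) for t in abs_times]
    true_urine = {
        c: result.cumulative[idx_samples, cum_cols[c]]
        - result.cumulative[idx_last, cum_cols[c]]
        for c in (pbpk.NICOTINE, pbpk.COTININE)
    }

    rows = []
    for animal in range(1, n_animals + 1):
        rng = _animal_rng(seed, animal)
        for compound in (pbpk.NICOTINE, pbpk.COTININE):
            vals = true_blood[compound] * _lognormal_factors(rng, noise_cv, len(sample_times))
            vals = np.where(vals < lloq, np.nan, vals)
            rows.append(pd.DataFrame({
                "time_h": sample_times, "compound": compound, "matrix": BLOOD,
                "value": vals, "unit": UNITS[BLOOD], "animal_id": animal,
            }))
        for compound in (pbpk.NICOTINE, pbpk.COTININE):
            increments = np.diff(true_urine[compound], prepend=0.0)
            noisy = increments * _lognormal_factors(rng, noise_cv, len(increments))
            rows.append(pd.DataFrame({
                "time_h": sample_times, "compound": compound, "matrix": URINE,
                "value": np.cumsum(noisy), "unit": UNITS[URINE], "animal_id": animal,
            }))
    data = pd.concat(rows, ignore_index=True)
    provenance = {
        "generator": "generate_rat_study",
        "seed": int(seed),
        "noise_cv": float(noise_cv),
        "n_animals": int(n_animals),
        "lloq_ng_per_ml": float(lloq),
        "sample_times_h": [float(t) for t in sample_times],
        "regimen": regimen.model_dump(),
        "truth": {"nicotine": nic.model_dump(), "cotinine": cot.model_dump()},
        "physiology": phys.model_dump(),
        "formation_factor": float(formation_factor),
    }
    return PKDataset(data, provenance)


# ---------------------------------------------------------------------------
# Named human exposure scenarios.
# ---------------------------------------------------------------------------

CIGARETTES_PER_DAY = 31.0
MG_NICOTINE_PER_CIGARETTE = 1.4
SMOKER_DAILY_INTAKE_MG = CIGARETTES_PER_DAY * MG_NICOTINE_PER_CIGARETTE  # 43.4
NOAEL_DOSE_MG = 70.0  # 1 mg/kg × 70 kg


def smoker_scenario() -> dict[str, tuple[DoseRegimen, dict]]:
    """Named human dosing scenarios with reference-observation notes.

    ``human_smoker``: the mean daily nicotine intake of a smoker panel
    (31.0 cigarettes/day × 1.4 mg) given as one oral dose; notes carry the
    measured biomonitoring values (pooled plasma 1 h after smoking) the
    scenario is compared against.  ``human_noael_single`` and
    ``human_noael_repeated``: the 70 mg (1 mg/kg × 70 kg) dose, once and as
    14 daily administrations.
    """
    ka_human = 0.795
    smoker = DoseRegimen(
        dose_amount=SMOKER_DAILY_INTAKE_MG * MICROGRAMS_PER_MILLIGRAM, ka=ka_human
    )
    noael_single = DoseRegimen(
        dose_amount=NOAEL_DOSE_MG * MICROGRAMS_PER_MILLIGRAM, ka=ka_human
    )
    noael_repeated = noael_single.model_copy(update={"n_doses": 14, "interval": 24.0})
    return {
        "human_smoker": (
            smoker,
            {
                "dose_mg": SMOKER_DAILY_INTAKE_MG,
                "cigarettes_per_day": CIGARETTES_PER_DAY,
                "mg_nicotine_per_cigarette": MG_NICOTINE_PER_CIGARETTE,
                "observed_nicotine_1h_ng_per_ml": 15.6,
                "observed_cotinine_1h_ng_per_ml": 110.0,
                "note": "measured pooled smoker plasma, 1 h after smoking",
            },
        ),
        "human_noael_single": (
            noael_single,
            {"dose_mg": NOAEL_DOSE_MG, "note": "NOAEL dose, single administration"},
        ),
        "human_noael_repeated": (
            noael_repeated,
            {"dose_mg": NOAEL_DOSE_MG, "note": "NOAEL dose, 14 daily administrations"},
        ),
    }
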