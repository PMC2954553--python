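"""Validated, immutable parameter sets for the nicotine/cotinine PBPK model.

Unit convention (fixed for the whole package): mass in μg, volume in L, time
in h.  Concentration is therefore μg/L, which is numerically identical to
ng/mL, so simulated blood levels compare directly with assay readouts without
any conversion layer.  Doses entered in mg at an interface boundary (CLI,
scenario configs) are converted to μg exactly once, at that boundary.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

MICROGRAMS_PER_MILLIGRAM = 1000.0


class CompoundParams(BaseModel):
    """Per-compound, per-species PBPK constants.

    Attributes
    ----------
    name : compound label ("nicotine" or "cotinine").
    cl_h_int : hepatic intrinsic clearance, L/h (unbound-concentration basis).
    cl_r : renal clearance, L/h.
    kp_h : liver-to-plasma partition coefficient, dimensionless.
    fu_p : fraction unbound in plasma, dimensionless, in (0, 1].
    rb : blood-to-plasma concentration ratio, dimensionless.
    v1 : volume of the systemic-circulation (central) compartment, L.
    logp : octanol-water partition coefficient.  Stored for reference only;
        no computation in this package uses it (liver partitioning is taken
        from the fitted/literature ``kp_h`` directly).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    cl_h_int: float
    cl_r: float
    kp_h: float
    fu_p: float
    rb: float
    v1: float
    logp: Optional[float] = None

    @model_validator(mode="after")
    def _check_ranges(self) -> "CompoundParams":
        if not (0.0 < self.fu_p <= 1.0):
            raise ValueError(f"fu_p must be in (0, 1], got {self.fu_p}")
        for field in ("kp_h", "rb", "v1"):
            if getattr(self, field) <= 0.0:
                raise ValueError(f"{field} must be > 0, got {getattr(self, field)}")
        for field in ("cl_h_int", "cl_r"):
            if getattr(self, field) < 0.0:
                raise ValueError(f"{field} must be >= 0, got {getattr(self, field)}")
        return self


class Physiology(BaseModel):
    """Species-level constants: liver size, hepatic blood flow and the
    microsomal scaling coefficients used for in vitro → in vivo extrapolation.

    ``mg_microsomal_protein_per_g_liver`` for the rat defaults to 30 mg/g in
    the shipped fixture: that is the value consistent with the whole-body rat
    clearances used throughout (the often-quoted 40 mg/g over-predicts them by
    a third).  It is a plain field, so either convention can be used.
    """

    model_config = ConfigDict(frozen=True)

    species: str
    v_h: float  # hepatic volume, L
    q_h: float  # hepatic blood flow, L/h
    body_weight: float  # kg
    mg_microsomal_protein_per_g_liver: float
    g_liver_per_body: float  # g liver per reference body

    @model_validator(mode="after")
    def _check_positive(self) -> "Physiology":
        for field in (
            "v_h",
            "q_h",
            "body_weight",
            "mg_microsomal_protein_per_g_liver",
            "g_liver_per_body",
        ):
            if getattr(self, field) <= 0.0:
                raise ValueError(f"{field} must be > 0, got {getattr(self, field)}")
        return self


class DoseRegimen(BaseModel):
    """Oral bolus dosing schedule.

    ``dose_amount`` is in μg per administration.  Repeated doses are given
    every ``interval`` hours, ``n_doses`` times.  ``fa_fg`` is the fraction
    absorbed times intestinal availability (systemic hepatic first pass is a
    model output, not part of ``fa_fg``); ``ka`` the first-order absorption
    rate constant in 1/h.
    """

    model_config = ConfigDict(frozen=True)

    dose_amount: float  # μg
    ka: float  # 1/h
    fa_fg: float = 1.0
    interval: float = 24.0  # h
    n_doses: int = 1

    @model_validator(mode="after")
    def _check(self) -> "DoseRegimen":
        if self.dose_amount < 0.0:
            raise ValueError(f"dose_amount must be >= 0, got {self.dose_amount}")
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")
        if self.n_doses > 1 and self.interval <= 0.0:
            raise ValueError("interval must be > 0 when n_doses > 1")
        if not (0.0 < self.fa_fg <= 1.0):
            raise ValueError(f"fa_fg must be in (0, 1], got {self.fa_fg}")
        if self.ka <= 0.0:
            raise ValueError(f"ka must be > 0, got {self.ka}")
        return self

    @property
    def dose_times(self) -> list[float]:
        return [i * self.interval for i in range(self.n_doses)]


# ---------------------------------------------------------------------------
# Reference fixtures.  These are the literature parameter sets the package
# ships with: a rat model anchored to an in vivo repeated-oral-dose study
# (0.25 mg nicotine to a 0.25 kg rat, daily) and the human model obtained
# from it by IVIVE + parallelogram scaling (see ivive module).
# ---------------------------------------------------------------------------


def rat_physiology() -> Physiology:
    return Physiology(
        species="rat",
        v_h=0.00850,
        q_h=0.853,
        body_weight=0.25,
        mg_microsomal_protein_per_g_liver=30.0,
        g_liver_per_body=10.0,
    )


def human_physiology() -> Physiology:
    return Physiology(
        species="human",
        v_h=1.50,
        q_h=96.6,
        body_weight=70.0,
        mg_microsomal_protein_per_g_liver=40.0,
        g_liver_per_body=1500.0,
    )


def rat_nicotine_params() -> tuple[CompoundParams, Physiology, DoseRegimen]:
    """Rat nicotine parameter set: compound constants, rat physiology and the
    reference NOAEL regimen (0.25 mg = 250 μg orally, daily for 14 days)."""
    nicotine = CompoundParams(
        name="nicotine",
        cl_h_int=5.44,
        cl_r=0.0994,
        kp_h=0.797,
        fu_p=0.688,
        rb=1.00,
        v1=0.746,
        logp=0.930,
    )
    regimen = DoseRegimen(dose_amount=250.0, ka=1.07, fa_fg=1.00, interval=24.0, n_doses=14)
    return nicotine, rat_physiology(), regimen


def rat_cotinine_params() -> CompoundParams:
    return CompoundParams(
        name="cotinine",
        cl_h_int=0.208,
        cl_r=0.00421,
        kp_h=0.680,
        fu_p=0.743,
        rb=1.00,
        v1=0.451,
        logp=0.040,
    )


def human_params() -> tuple[CompoundParams, CompoundParams, Physiology, DoseRegimen]:
    """Human parameter set.

    Compound-specific clearances/volumes are human values; the partition
    coefficient, unbound fraction and blood/plasma ratio are shared with the
    rat set (species-independent physicochemical constants).  The reference
    regimen is the 70 mg (1 mg/kg × 70 kg) single oral dose.
    """
    nicotine = CompoundParams(
        name="nicotine",
        cl_h_int=755.0,
        cl_r=4.25,
        kp_h=0.797,
        fu_p=0.688,
        rb=1.00,
        v1=209.0,
        logp=0.930,
    )
    cotinine = CompoundParams(
        name="cotinine",
        cl_h_int=20.6,
        cl_r=0.180,
        kp_h=0.680,
        fu_p=0.743,
        rb=1.00,
        v1=127.0,
        logp=0.040,
    )
    regimen = DoseRegimen(dose_amount=70.0 * MICROGRAMS_PER_MILLIGRAM, ka=0.795, fa_fg=1.00)
    return nicotine, cotinine, human_physiology(), regimen


# ---------------------------------------------------------------------------
# Flat-config serialization.  Keys are the conventional symbol names; values
# are numbers in the package unit convention (μg / L / h).
# ---------------------------------------------------------------------------

_SECTIONS = {
    "compound": CompoundParams,
    "physiology": Physiology,
    "regimen": DoseRegimen,
}


def to_config(obj: BaseModel) -> dict:
    """Flat ``symbol -> number`` mapping for one parameter object."""
    return {k: v for k, v in obj.model_dump().items() if v is not None}


def save_params(path, *, compounds: dict[str, CompoundParams] | None = None,
                physiology: Physiology | None = None,
                regimen: DoseRegimen | None = None) -> None:
    doc: dict = {}
    if compounds:
        doc["compounds"] = {name: to_config(c) for name, c in compounds.items()}
    if physiology is not None:
        doc["physiology"] = to_config(physiology)
    if regimen is not None:
        doc["regimen"] = to_config(regimen)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_params(path) -> dict:
    """Load a parameter config written by :func:`save_params`.

    Returns a dict with keys among ``compounds`` (name -> CompoundParams),
    ``physiology`` and ``regimen``, each re-validated.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out: dict = {}
    if "compounds" in doc:
        out["compounds"] = {
            name: CompoundParams(**cfg) for name, cfg in doc["compounds"].items()
        }
    if "physiology" in doc:
        out["physiology"] = Physiology(**doc["physiology"])
    if "regimen" in doc:
        out["regimen"] = DoseRegimen(**doc["regimen"])
    return out
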