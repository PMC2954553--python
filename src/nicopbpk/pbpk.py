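"""Coupled nicotine → cotinine PBPK model and its integrator.

The model has three anatomical spaces per compound: gut (absorption depot,
nicotine only), liver (the metabolizing compartment, volume ``V_h``, perfused
at hepatic blood flow ``Q_h``) and the systemic circulation (volume ``V_1``).
All inter-compartment transfer is first order, so the system is linear and
time-invariant between dosing events; repeated oral doses are instantaneous
additions to the gut depot with integrator restarts at each event.

State vector (amounts in μg, concentrations in μg/L = ng/mL)::

    x_g      nicotine amount in gut
    c_h_nic  nicotine liver concentration
    c_b_nic  nicotine blood (central) concentration
    c_h_cot  cotinine liver concentration
    c_b_cot  cotinine blood (central) concentration

with governing equations (compound-specific parameters throughout)::

    dX_g/dt      = -ka·X_g
    V_h·dC_h/dt  =  Q_h·C_b - Q_h·C_h·R_b/K_p,h + ka·X_g
                    - CL_h,int·f_u,p·C_h/K_p,h                    (nicotine)
    V_1·dC_b/dt  = -Q_h·C_b + Q_h·C_h·R_b/K_p,h - CL_r·C_b

and for cotinine the same liver/central pair without absorption but with the
formation input ``CL_h,int,nic·f_u,p,nic·C_h,nic/K_p,h,nic`` (nicotine's
hepatic metabolism flux) entering the liver.  The metabolism term acts on the
unbound liver concentration, which makes the steady-state hepatic clearance
of the model exactly the well-stirred value Q_h·fu·CL_int/(Q_h + fu·CL_int).

Cotinine is described by two kinetic states (liver + central): its "third"
compartment, the formation input, is not an independent state because the
formation flux is fully determined by the nicotine subsystem.

Four cumulative elimination integrals (renal and hepatic, per compound) are
carried alongside the kinetic states so that mass balance and urinary
excretion are available without post-hoc quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .parameters import CompoundParams, DoseRegimen, Physiology

STATE_NAMES = ("x_g", "c_h_nic", "c_b_nic", "c_h_cot", "c_b_cot")
CUMULATIVE_NAMES = ("renal_nic", "hepatic_nic", "renal_cot", "hepatic_cot")

DEFAULT_GRID = 0.05  # h
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # μg/L scale

NICOTINE = "nicotine"
COTININE = "cotinine"


class SolverError(RuntimeError):
    pass


def _system_matrix(
    nic: CompoundParams,
    cot: CompoundParams,
    phys: Physiology,
    ka: float,
    formation_factor: float,
) -> np.ndarray:
    """Constant coefficient matrix of the full 9-state linear system
    (5 kinetic states + 4 cumulative elimination integrals)."""
    qh, vh = phys.q_h, phys.v_h
    met_n = nic.cl_h_int * nic.fu_p / nic.kp_h  # L/h acting on C_h,nic
    met_c = cot.cl_h_int * cot.fu_p / cot.kp_h
    ret_n = qh * nic.rb / nic.kp_h  # liver -> blood return, L/h on C_h
    ret_c = qh * cot.rb / cot.kp_h

    a = np.zeros((9, 9))
    # gut
    a[0, 0] = -ka
    # nicotine liver
    a[1, 0] = ka / vh
    a[1, 1] = -(ret_n + met_n) / vh
    a[1, 2] = qh / vh
    # nicotine central
    a[2, 1] = ret_n / nic.v1
    a[2, 2] = -(qh + nic.cl_r) / nic.v1
    # cotinine liver (formation from nicotine hepatic metabolism)
    a[3, 1] = formation_factor * met_n / vh
    a[3, 3] = -(ret_c + met_c) / vh
    a[3, 4] = qh / vh
    # cotinine central
    a[4, 3] = ret_c / cot.v1
    a[4, 4] = -(qh + cot.cl_r) / cot.v1
    # cumulative elimination fluxes (μg/h)
    a[5, 2] = nic.cl_r
    a[6, 1] = met_n
    a[7, 4] = cot.cl_r
    a[8, 3] = met_c
    return a


def rhs(
    state,
    nic: CompoundParams,
    cot: CompoundParams,
    phys: Physiology,
    regimen: DoseRegimen,
    formation_factor: float = 1.0,
) -> np.ndarray:
    """Time derivative of the five kinetic states.

    Raises ``ValueError`` naming the offending component if the state is not
    finite.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError(f"state must have 5 components {STATE_NAMES}, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(state))[0])]
        raise ValueError(f"non-finite state component: {bad}")
    a = _system_matrix(nic, cot, phys, regimen.ka, formation_factor)
    return a[:5, :5] @ state


@dataclass
class SimulationResult:
    """Trajectory of a PBPK simulation on a fixed output grid.

    ``states`` holds the five kinetic states (columns ordered as
    ``STATE_NAMES``), ``cumulative`` the four elimination integrals in μg
    (columns as ``CUMULATIVE_NAMES``).  Central concentrations are in
    μg/L ≡ ng/mL.
    """

    times: np.ndarray
    states: np.ndarray
    cumulative: np.ndarray
    dose_times: np.ndarray
    nic: CompoundParams
    cot: CompoundParams
    phys: Physiology
    regimen: DoseRegimen
    formation_factor: float = 1.0
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    _blood_cols: dict = field(
        default_factory=lambda: {NICOTINE: 2, COTININE: 4}, repr=False
    )
    _liver_cols: dict = field(
        default_factory=lambda: {NICOTINE: 1, COTININE: 3}, repr=False
    )

    def blood(self, compound: str) -> np.ndarray:
        """Central-compartment concentration trace, ng/mL."""
        return self.states[:, self._blood_col(compound)]

    def _blood_col(self, compound: str) -> int:
        try:
            return self._blood_cols[compound]
        except KeyError:
            raise KeyError(f"unknown compound {compound!r}; expected one of "
                           f"{sorted(self._blood_cols)}") from None

    def concentration_at(self, compound: str, t) -> float | np.ndarray:
        """Interpolated central concentration at time(s) ``t`` (h), ng/mL."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError(
                f"t outside simulated range [{self.times[0]}, {self.times[-1]}] h"
            )
        out = np.interp(t, self.times, self.blood(compound))
        return float(out) if out.ndim == 0 else out

    def cmax(self, compound: str) -> tuple[float, float]:
        """(Cmax ng/mL, tmax h) of the central concentration, refined by
        quadratic interpolation around the discrete grid maximum."""
        c = self.blood(compound)
        i = int(np.argmax(c))
        if c[i] <= 0.0:
            return 0.0, 0.0
        if 0 < i < len(c) - 1:
            t0, t1, t2 = self.times[i - 1 : i + 2]
            y0, y1, y2 = c[i - 1 : i + 2]
            denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
            if denom != 0.0:
                a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
                b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
                if a < 0.0:
                    tm = -b / (2 * a)
                    if t0 <= tm <= t2:
                        cm = a * tm**2 + b * tm + (
                            y1 - a * t1**2 - b * t1
                        )
                        return float(cm), float(tm)
        return float(c[i]), float(self.times[i])

    def auc(self, compound: str, t0: float = 0.0, t1: float | None = None) -> float:
        """Trapezoidal AUC of the central concentration over [t0, t1], μg·h/L."""
        if t1 is None:
            t1 = float(self.times[-1])
        if t1 <= t0:
            raise ValueError(f"t1 must exceed t0 (got t0={t0}, t1={t1})")
        if t0 < self.times[0] or t1 > self.times[-1]:
            raise ValueError("AUC window outside simulated range")
        c = self.blood(compound)
        inside = (self.times > t0) & (self.times < t1)
        ts = np.concatenate(([t0], self.times[inside], [t1]))
        cs = np.concatenate((
            [np.interp(t0, self.times, c)],
            c[inside],
            [np.interp(t1, self.times, c)],
        ))
        return float(np.trapezoid(cs, ts))

    # -- balance diagnostics ------------------------------------------------

    def total_dosed(self, up_to: float | None = None) -> float:
        """Absorbable dose (μg) administered up to time ``up_to``."""
        t = self.times[-1] if up_to is None else up_to
        n = int(np.sum(self.dose_times <= t + 1e-12))
        return n * self.regimen.dose_amount * self.regimen.fa_fg

    def mass_balance_error(self) -> float:
        """Relative nicotine mass-balance residual at the final time point:
        |dosed - (gut + liver + central + renal + hepatic)| / dosed."""
        dosed = self.total_dosed()
        if dosed == 0.0:
            return 0.0
        s, c = self.states[-1], self.cumulative[-1]
        held = s[0] + self.phys.v_h * s[1] + self.nic.v1 * s[2]
        return abs(dosed - (held + c[0] + c[1])) / dosed

    def metabolite_balance_error(self) -> float:
        """Relative cotinine mass-balance residual: cotinine formed
        (= formation_factor × nicotine hepatically cleared) vs cotinine
        held + eliminated."""
        formed = self.formation_factor * self.cumulative[-1, 1]
        if formed == 0.0:
            return 0.0
        s, c = self.states[-1], self.cumulative[-1]
        held = self.phys.v_h * s[3] + self.cot.v1 * s[4]
        return abs(formed - (held + c[2] + c[3])) / formed

    # -- export -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_h, compound, compartment, value, unit."""
        rows = []
        for compound in (NICOTINE, COTININE):
            for label, col, unit in (
                ("liver", self._liver_cols[compound], "ng/mL"),
                ("blood", self._blood_cols[compound], "ng/mL"),
            ):
                rows.append(pd.DataFrame({
                    "time_h": self.times,
                    "compound": compound,
                    "compartment": label,
                    "value": self.states[:, col],
                    "unit": unit,
                }))
        rows.append(pd.DataFrame({
            "time_h": self.times,
            "compound": NICOTINE,
            "compartment": "gut",
            "value": self.states[:, 0],
            "unit": "ug",
        }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _output_grid(t_end: float, grid: float, dose_times: np.ndarray) -> np.ndarray:
    n = int(round(t_end / grid))
    ts = np.linspace(0.0, n * grid, n + 1)
    if ts[-1] < t_end - 1e-12:
        ts = np.append(ts, t_end)
    ts = np.union1d(np.round(ts, 12), np.round(dose_times, 12))
    return ts[ts <= t_end + 1e-12]


def _segment_states(a, y0, t0, t1, eval_pts, method, rtol, atol, prop_cache):
    """States at ``eval_pts`` (subset of [t0, t1]) plus the state at t1."""
    if method == "expm":
        # the system is linear time-invariant within a segment, so matrix
        # exponential propagation is exact; propagators are cached per step
        pts = np.append(eval_pts, t1)
        ys = np.empty((len(pts), len(y0)))
        y, t = y0, t0
        for i, tp in enumerate(pts):
            dt = tp - t
            if dt > 0.0:
                key = round(dt, 12)
                if key not in prop_cache:
                    prop_cache[key] = expm(a * dt)
                y = prop_cache[key] @ y
                t = tp
            ys[i] = y
        return ys[:-1], ys[-1]
    sol = solve_ivp(
        lambda t, yy: a @ yy,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=np.append(eval_pts, t1),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"ODE integration failed on [{t0}, {t1}] h "
            f"(rtol={rtol}, atol={atol}): {sol.message}"
        )
    ys = sol.y.T
    return ys[:-1], ys[-1]


def simulate(
    nic: CompoundParams,
    cot: CompoundParams,
    phys: Physiology,
    regimen: DoseRegimen,
    t_end: float,
    grid: float = DEFAULT_GRID,
    t_eval: np.ndarray | None = None,
    formation_factor: float = 1.0,
    method: str = "lsoda",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SimulationResult:
    """Integrate the PBPK system over [0, t_end] hours.

    Each administration adds ``dose_amount·fa_fg`` μg to the gut depot
    instantaneously; integration restarts at every dose event, so the solver
    never steps across a discontinuity.  The default method is a
    stiff-capable integrator (LSODA) because the liver compartment is small
    against its clearances; ``method="expm"`` instead propagates the linear
    system exactly with cached matrix exponentials, which is both faster and
    exact for this model and is what the parameter-estimation loop uses.

    ``t_eval`` overrides the uniform output grid (dose times are always
    included as segment boundaries either way).
    """
    if method not in ("lsoda", "expm"):
        raise ValueError(f"method must be 'lsoda' or 'expm', got {method!r}")
    dose_times = np.array(regimen.dose_times, dtype=float)
    if t_end < dose_times[-1]:
        raise ValueError(
            f"t_end={t_end} h does not cover the last dose at {dose_times[-1]} h"
        )
    if t_eval is None:
        times = _output_grid(t_end, grid, dose_times)
    else:
        times = np.union1d(np.asarray(t_eval, dtype=float), dose_times)
        times = times[(times >= 0.0) & (times <= t_end + 1e-12)]
    a = _system_matrix(nic, cot, phys, regimen.ka, formation_factor)
    bolus = regimen.dose_amount * regimen.fa_fg

    # Integrate segment by segment between dose events; within a segment the
    # system is linear and autonomous.  The state reported AT a dose time is
    # the post-dose state (blood concentrations are continuous there anyway).
    boundaries = np.unique(np.append(dose_times, t_end))
    y = np.zeros(9)
    prop_cache: dict = {}
    collected_t: list[np.ndarray] = []
    collected_y: list[np.ndarray] = []
    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        if np.any(np.isclose(seg_start, dose_times, atol=1e-12)):
            y = y.copy()
            y[0] += bolus
        mask = (times >= seg_start - 1e-12) & (times < seg_end - 1e-12)
        seg_times = times[mask]
        ys, y = _segment_states(
            a, y, seg_start, seg_end, seg_times, method, rtol, atol, prop_cache
        )
        if len(seg_times):
            collected_t.append(seg_times)
            collected_y.append(ys)
    if times[-1] >= boundaries[-1] - 1e-12:  # t_end itself requested
        collected_t.append(times[-1:])
        collected_y.append(y[None, :])
    times = np.concatenate(collected_t)
    out = np.concatenate(collected_y, axis=0)
    # solver round-off can leave tiny negative values; clamp to zero
    out[np.abs(out) < atol] = np.maximum(out[np.abs(out) < atol], 0.0)
    return SimulationResult(
        times=times,
        states=out[:, :5],
        cumulative=out[:, 5:],
        dose_times=dose_times,
        nic=nic,
        cot=cot,
        phys=phys,
        regimen=regimen,
        formation_factor=formation_factor,
        rtol=rtol,
        atol=atol,
    )


# Module-level wrappers mirroring the SimulationResult methods.

def concentration_at(result: SimulationResult, compound: str, t) -> float:
    return result.concentration_at(compound, t)


def cmax(result: SimulationResult, compound: str) -> tuple[float, float]:
    return result.cmax(compound)


def auc(result: SimulationResult, compound: str, t0: float = 0.0,
        t1: float | None = None) -> float:
    return result.auc(compound, t0, t1)
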