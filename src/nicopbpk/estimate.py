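"""Two-stage PK parameter estimation.

Stage one is a classical one-compartment oral (Bateman) analysis of a blood
concentration-time profile, giving primary estimates of the absorption and
elimination rate constants and the apparent volume.  Stage two converts those
into physiologically meaningful starting values (CL_h,int via the inverse
well-stirred model, V_1) and refits the free PBPK parameters (k_a, CL_h,int,
V_1 per compound) to the data by weighted nonlinear least squares on the full
model, nicotine first and cotinine conditional on the nicotine fit.

Weighting is 1/y² with y the observed concentration (a proportional-error
model, matching an assay with a constant coefficient of variation; anchoring
the weights to the observations keeps the criterion a true least-squares
problem).  Parameters are log-transformed so the optimizer works in a
naturally positive, well-scaled space; a small multi-start (log-space
perturbations of the starting point) guards against local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import ivive, pbpk
from .parameters import CompoundParams, DoseRegimen, Physiology
from .synth import BLOOD, PKDataset

DEFAULT_MULTISTART_SEED = 20100901
LOG_BOUND = np.log(1e6)  # fitted parameters constrained to [1e-6, 1e6]
_KA_KEL_DEGENERATE = 1e-8


def bateman(t, dose: float, ka: float, kel: float, v_over_f: float) -> np.ndarray:
    """One-compartment oral concentration: first-order absorption (ka) and
    elimination (kel) of a dose into apparent volume V/F.

    The removable singularity at ka = kel is evaluated with its limit form
    (D/V)·ka·t·exp(-ka·t).
    """
    t = np.asarray(t, dtype=float)
    if abs(ka - kel) < _KA_KEL_DEGENERATE * max(ka, kel):
        return dose * ka * t * np.exp(-ka * t) / v_over_f
    return (
        dose
        * ka
        / (v_over_f * (ka - kel))
        * (np.exp(-kel * t) - np.exp(-ka * t))
    )


@dataclass(frozen=True)
class OneCompartmentFit:
    """Primary one-compartment estimates from an oral profile."""

    ka: float  # 1/h
    kel: float  # 1/h
    v_over_f: float  # apparent volume V/F, L
    auc_inf: float  # μg·h/L
    cl_tot_over_f: float  # apparent total clearance CL/F, L/h
    rss: float
    n: int


def _blood_profile(data, compound: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, PKDataset):
        df = data.subset(compound=compound, matrix=BLOOD)
    else:
        df = data[(data["compound"] == compound) & (data["matrix"] == BLOOD)]
    df = df.dropna(subset=["value"])
    df = (
        df.groupby("time_h", as_index=False)["value"].mean()
    )  # pooled mean over animals
    return df["time_h"].to_numpy(float), df["value"].to_numpy(float)


def fit_one_compartment(
    data, dose: float, compound: str = pbpk.NICOTINE
) -> OneCompartmentFit:
    """Least-squares Bateman fit of a blood profile (pooled over animals).

    Requires at least 4 time points with positive concentrations.  Because
    the Bateman curve is invariant under swapping (ka, kel) with a
    compensating volume ("flip-flop"), a warning is emitted when the swapped
    solution fits equally well; the returned orientation is the one found by
    the optimizer.
    """
    t, c = _blood_profile(data, compound)
    pos = c > 0
    if pos.sum() < 4:
        raise ValueError(
            f"need >= 4 positive concentrations to fit, got {int(pos.sum())}"
        )
    t, c = t[pos], c[pos]
    if np.ptp(c) == 0.0:
        raise ValueError("flat concentration profile is not identifiable")

    def residuals(logp):
        ka, kel, v = np.exp(logp)
        pred = bateman(t, dose, ka, kel, v)
        return (c - pred) / c

    # crude initials: terminal slope for kel, a faster ka, volume from peak
    tail = max(2, len(t) // 2)
    slope = np.polyfit(t[-tail:], np.log(np.maximum(c[-tail:], 1e-12)), 1)[0]
    kel0 = max(-slope, 1e-3)
    v0 = max(dose / (4.0 * c.max()), 1e-3)
    best = None
    for ka0 in (5.0 * kel0, 2.0 * kel0, 0.5 * kel0):
        sol = least_squares(
            residuals,
            np.log([ka0, kel0, v0]),
            bounds=(-LOG_BOUND, LOG_BOUND),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    ka, kel, v = np.exp(best.x)
    rss = float(2.0 * best.cost)
    swapped = np.sum(residuals(np.log([kel, ka, v * kel / ka])) ** 2)
    if abs(swapped - rss) <= 1e-6 * (1.0 + rss) and abs(ka - kel) > 1e-6 * ka:
        warnings.warn(
            "ka/kel flip-flop: the swapped solution "
            f"(ka={kel:.4g}, kel={ka:.4g}) fits equally well",
            stacklevel=2,
        )
    cl_over_f = kel * v
    return OneCompartmentFit(
        ka=float(ka),
        kel=float(kel),
        v_over_f=float(v),
        auc_inf=float(dose / cl_over_f),
        cl_tot_over_f=float(cl_over_f),
        rss=rss,
        n=len(t),
    )


def initial_pbpk_params(
    fit: OneCompartmentFit,
    cl_r: float,
    phys: Physiology,
    compound: CompoundParams,
) -> CompoundParams:
    """Convert one-compartment estimates into PBPK starting values.

    The one-compartment analysis yields apparent quantities CL_tot/F and V/F
    with F = 1 - E set by hepatic first pass, while E itself depends on CL_h
    — a circular definition.  Substituting CL_h = E·Q_h and
    CL_tot = (CL_tot/F)·(1 - E) gives the closed form

        E = (CL_tot/F - CL_r) / (Q_h + CL_tot/F)

    (the fixed point of the CL_h → E → F iteration, which is unstable to
    iterate directly for high-extraction compounds).  CL_h,int then follows
    from the inverse well-stirred model and V_1 = (V/F)·F.
    """
    x = fit.cl_tot_over_f
    e_h = (x - cl_r) / (phys.q_h + x)
    e_h = max(e_h, 0.0)
    cl_h = e_h * phys.q_h
    if cl_h >= phys.q_h:
        raise ValueError("implied hepatic clearance reaches hepatic blood flow")
    f_sys = 1.0 - e_h
    cl_h_int = ivive.invert_well_stirred(cl_h, phys.q_h, compound.fu_p, compound.rb)
    return compound.model_copy(
        update={"cl_h_int": cl_h_int, "cl_r": cl_r, "v1": fit.v_over_f * f_sys}
    )


_DEFAULT_FREE = {
    pbpk.NICOTINE: frozenset({"ka", "cl_h_int", "v1"}),
    pbpk.COTININE: frozenset({"cl_h_int", "v1"}),
}
_ALLOWED_FREE = {"ka", "cl_h_int", "v1"}


@dataclass
class PBPKFitResult:
    """Outcome of the full-model refit."""

    params: dict  # compound -> fitted CompoundParams
    ka: float  # fitted absorption rate constant, 1/h
    objective: float
    objective_start: float
    success: bool
    message: str = ""
    n_evaluations: int = 0
    start: dict = field(default_factory=dict)
    free: dict = field(default_factory=dict)


def _stage_residuals(
    obs_t, obs_c, compound, nic, cot, phys, regimen, t_last, formation_factor
):
    result = pbpk.simulate(
        nic, cot, phys, regimen,
        t_end=t_last + obs_t.max(),
        t_eval=t_last + obs_t,
        method="expm",
        formation_factor=formation_factor,
    )
    pred = result.concentration_at(compound, t_last + obs_t)
    # proportional-error weighting anchored to the observations: a fixed
    # weight makes this a true least-squares criterion (prediction-dependent
    # weights would let over-prediction saturate its own penalty)
    return (obs_c - np.asarray(pred)) / obs_c


def fit_pbpk(
    data,
    start: dict,
    phys: Physiology,
    regimen: DoseRegimen,
    free: dict | None = None,
    n_starts: int = 5,
    seed: int = DEFAULT_MULTISTART_SEED,
    formation_factor: float = 1.0,
    joint_refine: bool = False,
) -> PBPKFitResult:
    """Weighted nonlinear least-squares refit of the PBPK model.

    ``data`` holds blood profiles with times measured from the final dose of
    ``regimen``.  ``start`` maps compound name -> starting CompoundParams
    (cotinine optional); ``free`` maps compound name -> subset of
    {"ka", "cl_h_int", "v1"} ("ka" is meaningful for nicotine only).
    Nicotine parameters are fitted first; cotinine parameters are then fitted
    conditional on the nicotine estimates, since cotinine kinetics depend on
    nicotine but not conversely.  Each stage restarts the optimizer from
    ``n_starts`` log-space perturbations of the starting point (fixed
    ``seed``) and keeps the best solution.  On optimizer failure the
    best-so-far parameters are returned with ``success=False``.

    With ``joint_refine=True`` a final pass re-minimizes the combined
    nicotine + cotinine residual over all free parameters, starting from the
    sequential solution.  The metabolite's formation kinetics then feed
    information back into the parent's parameters, which matters when sparse
    or censored nicotine data leave (ka, V_1) weakly identified (the
    absorption/elimination "flip-flop" ridge).
    """
    free = dict(_DEFAULT_FREE) if free is None else {
        k: frozenset(v) for k, v in free.items()
    }
    for comp, names in free.items():
        extra = set(names) - _ALLOWED_FREE
        if extra:
            raise ValueError(f"unknown free parameters for {comp}: {sorted(extra)}")

    nic = start[pbpk.NICOTINE]
    cot = start.get(pbpk.COTININE)
    if cot is None:
        # cotinine placeholder: inert when no cotinine data is fitted
        cot = nic.model_copy(update={"name": pbpk.COTININE})
    t_last = regimen.dose_times[-1]
    rng = np.random.default_rng(seed)
    fitted = {pbpk.NICOTINE: nic, pbpk.COTININE: cot}
    ka_fit = regimen.ka
    n_eval = 0
    success = True
    message = "ok"

    def run_stage(compound, free_names, nic_p, cot_p, ka0):
        nonlocal n_eval
        obs_t, obs_c = _blood_profile(data, compound)
        keep = obs_c > 0
        obs_t, obs_c = obs_t[keep], obs_c[keep]
        if len(obs_t) == 0:
            raise ValueError(f"no usable {compound} blood observations")
        names = sorted(free_names)
        base = {"ka": ka0, "cl_h_int": getattr(nic_p if compound == pbpk.NICOTINE else cot_p, "cl_h_int"),
                "v1": getattr(nic_p if compound == pbpk.NICOTINE else cot_p, "v1")}

        def unpack(logx):
            vals = dict(base)
            vals.update({n: float(np.exp(v)) for n, v in zip(names, logx)})
            if compound == pbpk.NICOTINE:
                n_p = nic_p.model_copy(update={"cl_h_int": vals["cl_h_int"], "v1": vals["v1"]})
                return n_p, cot_p, vals["ka"]
            c_p = cot_p.model_copy(update={"cl_h_int": vals["cl_h_int"], "v1": vals["v1"]})
            return nic_p, c_p, ka0

        def residuals(logx):
            nonlocal n_eval
            n_eval += 1
            n_p, c_p, ka = unpack(logx)
            reg = regimen.model_copy(update={"ka": ka})
            return _stage_residuals(
                obs_t, obs_c, compound, n_p, c_p, phys, reg,
                t_last, formation_factor,
            )

        x0 = np.log([base[n] for n in names])
        start_obj = float(np.sum(residuals(x0) ** 2))
        if not names:
            return nic_p, cot_p, ka0, start_obj, start_obj, True, "no free parameters"
        best = None
        ok, msg = False, ""
        for i in range(max(1, n_starts)):
            xi = x0 if i == 0 else x0 + rng.uniform(np.log(0.5), np.log(1.5), len(x0))
            try:
                sol = least_squares(
                    residuals, xi, bounds=(-LOG_BOUND, LOG_BOUND), method="trf"
                )
            except Exception as exc:  # keep best-so-far on solver failure
                msg = str(exc)
                continue
            ok = ok or sol.success
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return nic_p, cot_p, ka0, start_obj, start_obj, False, msg or "all starts failed"
        final_obj = float(2.0 * best.cost)
        if final_obj > start_obj:  # monotone acceptance: never worse than start
            return nic_p, cot_p, ka0, start_obj, start_obj, ok, "kept start (no improvement)"
        n_p, c_p, ka = unpack(best.x)
        return n_p, c_p, ka, final_obj, start_obj, ok, "ok"

    objective = 0.0
    objective_start = 0.0
    nic_free = free.get(pbpk.NICOTINE, frozenset())
    nic_fit, _, ka_fit, obj, obj0, ok, msg = run_stage(
        pbpk.NICOTINE, nic_free, nic, cot, regimen.ka
    )
    fitted[pbpk.NICOTINE] = nic_fit
    objective += obj
    objective_start += obj0
    success &= ok
    if not ok:
        message = f"nicotine stage: {msg}"

    cot_free = free.get(pbpk.COTININE, frozenset())
    has_cot_data = len(_blood_profile(data, pbpk.COTININE)[0]) > 0
    if has_cot_data and (cot_free or pbpk.COTININE in start):
        _, cot_fit, _, obj, obj0, ok, msg = run_stage(
            pbpk.COTININE, cot_free, nic_fit, cot, ka_fit
        )
        fitted[pbpk.COTININE] = cot_fit
        objective += obj
        objective_start += obj0
        success &= ok
        if not ok:
            message = f"cotinine stage: {msg}"

    if joint_refine and has_cot_data and (nic_free or cot_free):
        profiles = {}
        for compound in (pbpk.NICOTINE, pbpk.COTININE):
            obs_t, obs_c = _blood_profile(data, compound)
            keep = obs_c > 0
            profiles[compound] = (obs_t[keep], obs_c[keep])
        free_list = [(pbpk.NICOTINE, n) for n in sorted(nic_free)] + [
            (pbpk.COTININE, n) for n in sorted(cot_free)
        ]

        def unpack_joint(logx):
            vals = {
                pbpk.NICOTINE: {"ka": ka_fit,
                                "cl_h_int": fitted[pbpk.NICOTINE].cl_h_int,
                                "v1": fitted[pbpk.NICOTINE].v1},
                pbpk.COTININE: {"cl_h_int": fitted[pbpk.COTININE].cl_h_int,
                                "v1": fitted[pbpk.COTININE].v1},
            }
            for (comp, name), v in zip(free_list, logx):
                vals[comp][name] = float(np.exp(v))
            n_p = fitted[pbpk.NICOTINE].model_copy(update={
                "cl_h_int": vals[pbpk.NICOTINE]["cl_h_int"],
                "v1": vals[pbpk.NICOTINE]["v1"],
            })
            c_p = fitted[pbpk.COTININE].model_copy(update={
                "cl_h_int": vals[pbpk.COTININE]["cl_h_int"],
                "v1": vals[pbpk.COTININE]["v1"],
            })
            return n_p, c_p, vals[pbpk.NICOTINE]["ka"]

        def joint_residuals(logx):
            nonlocal n_eval
            n_eval += 1
            n_p, c_p, ka = unpack_joint(logx)
            reg = regimen.model_copy(update={"ka": ka})
            parts = [
                _stage_residuals(profiles[c][0], profiles[c][1], c, n_p, c_p,
                                 phys, reg, t_last, formation_factor)
                for c in (pbpk.NICOTINE, pbpk.COTININE)
            ]
            return np.concatenate(parts)

        x0 = np.log([
            ka_fit if name == "ka" else getattr(fitted[comp], name)
            for comp, name in free_list
        ])
        joint_start = float(np.sum(joint_residuals(x0) ** 2))
        try:
            sol = least_squares(
                joint_residuals, x0, bounds=(-LOG_BOUND, LOG_BOUND), method="trf"
            )
            if 2.0 * sol.cost <= joint_start:
                nic_fit, cot_fit, ka_fit = unpack_joint(sol.x)
                fitted[pbpk.NICOTINE] = nic_fit
                fitted[pbpk.COTININE] = cot_fit
                objective = float(2.0 * sol.cost)
                success &= sol.success
        except Exception as exc:
            success = False
            message = f"joint refinement: {exc}"

    return PBPKFitResult(
        params=fitted,
        ka=float(ka_fit),
        objective=float(objective),
        objective_start=float(objective_start),
        success=bool(success),
        message=message,
        n_evaluations=n_eval,
        start={k: v for k, v in start.items()},
        free={k: set(v) for k, v in free.items()},
    )
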