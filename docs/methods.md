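# Methods

## Model structure and assumptions

The model is a deliberately minimal PBPK description: per compound, a
well-stirred liver (volume `V_h`, hepatic blood flow `Q_h`) and a central
systemic compartment (`V_1`), plus a first-order gut absorption depot for
nicotine.  Cotinine is produced in the liver at exactly the nicotine hepatic
metabolism rate and has no absorption depot of its own: its "third
compartment" is the formation input, which is fully determined by the
nicotine subsystem rather than being an independent state.  The whole system
is linear and time-invariant between dosing events, which has two useful
consequences exploited throughout: concentrations scale exactly with dose,
and a repeated-dose profile is the superposition of shifted single-dose
profiles.

Key kinetic assumptions:

* **Metabolism acts on the unbound liver concentration**: the elimination
  term is `CL_h,int·f_u,p·C_h/K_p,h`.  At steady state this makes the organ
  clearance exactly the well-stirred value
  `Q_h·(f_u,p/R_b)·CL_h,int/(Q_h + (f_u,p/R_b)·CL_h,int)`, which is the
  relationship the IVIVE chain and the reported total clearances (81.5 L/h
  human, 2.8 L/h/kg rat) rely on.  The alternative readings (no `f_u,p`, or
  `f_u,p` in the denominator) fail to reproduce those clearances and were
  rejected.
* **Mass-conversion factor for cotinine formation is 1.0** (no molecular
  weight correction, 162.2 → 176.2 g/mol not applied): the governing
  equations contain no MW term.  The factor is exposed as
  `formation_factor` for sensitivity analysis.
* **`R_b` appears only in the liver→blood return flux**, where the equations
  place it.  With the fixture value `R_b = 1.00` it is inert, but the symbol
  is kept explicit so blood/plasma distinctions survive if non-unit values
  are explored.
* **Oral absorption is complete** (`F_a·F_g = 1`): systemic availability is
  limited only by hepatic first pass, which the model produces mechanically
  (F = 1 − E ≈ 0.16 both in rat and human for nicotine).
* Not modeled: pulmonary uptake, enterohepatic recirculation, binding
  kinetics, P450 induction (repeated nicotine dosing alters P450 activities
  only marginally), between-subject variability.

## Parameters

Units are fixed package-wide (mass μg, volume L, time h; concentrations
μg/L ≡ ng/mL).  The shipped fixtures are the literature parameter sets the
model family was calibrated with:

| symbol | rat nicotine | rat cotinine | human nicotine | human cotinine | unit |
|---|---|---|---|---|---|
| CL_h,int | 5.44 | 0.208 | 755 | 20.6 | L/h |
| CL_r | 0.0994 | 0.00421 | 4.25 | 0.180 | L/h |
| K_p,h | 0.797 | 0.680 | (rat) | (rat) | – |
| f_u,p | 0.688 | 0.743 | (rat) | (rat) | – |
| R_b | 1.00 | 1.00 | (rat) | (rat) | – |
| V_1 | 0.746 | 0.451 | 209 | 127 | L |
| V_h | 0.00850 | | 1.50 | | L |
| Q_h | 0.853 | | 96.6 | | L/h |
| k_a | 1.07 | – | 0.795 | – | 1/h |

`logP` is stored for reference but never used in computation (liver
partitioning comes from the fitted/literature `K_p,h` directly).  Reference
regimens: rat 0.25 mg orally, daily × 14 (1 mg/kg NOAEL to a 0.25 kg rat);
human 70 mg single dose (1 mg/kg × 70 kg), plus a 43.4 mg "smoker daily
intake" scenario (31.0 cigarettes × 1.4 mg).

**Microsomal scaling coefficients.**  Human: 40 mg microsomal protein per g
liver × 1500 g liver per 70 kg body.  Rat: the fixture carries **30 mg/g**
(× 10 g liver per 0.25 kg rat) because only that value reproduces the
whole-body rat in vitro clearances (7.9 → 0.142, 9.6 → 0.173 L/h) that
anchor the parallelogram factor; the commonly quoted 40 mg/g over-predicts
them by a third.  The coefficient is a plain field, so either convention is
one assignment away.

**Renal clearances** are shipped as fixture values.  Re-deriving them from
the rounded urinary amounts and AUCs they were originally computed from
(5.32/56.5, 8.23/1970) gives 0.0942 and 0.00418 L/h — about 5% from the
fixture values, which evidently used unrounded intermediates.
`renal_clearance()` performs the re-derivation but its output is never
silently substituted for the fixtures.

## Numerical choices

* **Integration**: LSODA (stiff-capable — the liver compartment is small
  against its clearances: e.g. rat `V_h` = 0.0085 L against ~5 L/h effective
  elimination) with `rtol = 1e-8`, `atol = 1e-10` μg/L.  Doses are
  instantaneous additions to the gut depot with integrator restarts at every
  event, so no discontinuity is stepped across.  An exact alternative,
  `method="expm"`, propagates the linear system with cached matrix
  exponentials; the two agree to ~1e-8 of scale, and the estimation loop
  uses `expm` (~1 ms per 14-dose simulation).
* **Output grid** defaults to 0.05 h.  `Cmax` is refined by quadratic
  interpolation through the three grid points around the discrete maximum;
  AUC is trapezoidal with interpolated window endpoints.
* **Mass balance** is tracked by carrying four cumulative elimination
  integrals (renal/hepatic × parent/metabolite) as extra states; residuals
  are ~1e-15 relative, far inside the 0.1% the tests require.
* **Well-stirred inversion** `CL_int = Q_h·CL_h/((f_u,p/R_b)(Q_h − CL_h))`
  round-trips to 1e-12 at moderate extraction; as E → 1 the round-trip
  conditioning degrades like `f_u·CL_int/(R_b·Q_h)`, which the property
  tests account for explicitly.
* **Bateman degeneracy**: at `|k_a − k_el|` below 1e-8 (relative) the limit
  form `(D/V)·k_a·t·e^(−k_a·t)` is used.  This matters in practice: the rat
  nicotine profile has `k_el ≈ 1.066 ≈ k_a`.

## Parameter estimation workflow

1. **One-compartment analysis** of the pooled-mean blood profile gives
   primary `(k_a, k_el, V/F)`; apparent clearance `CL_tot/F = k_el·V/F`.
   The ka/kel "flip-flop" twin (swap with `V·k_el/k_a`) fits identically and
   is reported as a warning.
2. **Conversion to PBPK starting values.**  `CL_tot/F` and `V/F` involve the
   systemic availability `F = 1 − E`, while `E` itself depends on the
   hepatic clearance being estimated.  The circular definition has the
   closed-form solution `E = (CL_tot/F − CL_r)/(Q_h + CL_tot/F)` (the fixed
   point of the CL_h → E → F iteration; note the raw iteration is unstable
   for high-extraction compounds, with map slope −(CL_tot/F)/Q_h ≈ −5 for
   rat nicotine, so the closed form is used).  `CL_h,int` then follows from
   the inverse well-stirred model and `V_1 = (V/F)·F`.
3. **Full-model refit** of the free parameters (`k_a`, `CL_h,int`, `V_1` per
   compound) by nonlinear least squares: residuals `(y − ŷ)/y` (a
   proportional-error model matching a constant-CV assay; anchoring weights
   to the *observations* keeps the criterion a true least-squares problem —
   weighting by the current prediction lets over-prediction saturate its own
   penalty and was observed to bias the fit), log-parameterized with bounds
   [1e-6, 1e6], trust-region solver, multi-start (5 starts by default,
   log-space perturbations in [×0.5, ×1.5], fixed seed 20100901).  Nicotine
   is fitted first; cotinine `(CL_h,int, V_1)` conditional on it, since the
   dependency runs one way.
4. **Optional joint refinement** (`joint_refine=True`): a final pass over the
   combined nicotine + cotinine residual.  This matters when nicotine data
   alone leave `(k_a, V_1)` on the flip-flop ridge — with the default rat
   sampling design, LLOQ censoring leaves nicotine quantifiable only to
   ~4 h, and sequential fitting can land 30–50% off in `(k_a, V_1)` (while
   `CL_h,int` stays within a few percent); the cotinine formation kinetics
   resolve the ridge, bringing all parameters within ~10% at 15% noise.

## Synthetic-study generator

`generate_rat_study` emulates the reference rat design: 0.25 mg orally,
daily × 14; blood sampled at 0.25, 0.5, 1, 2, 4, 8, 12, 24 h after the final
dose (the published sampling times are graphical only, so these defaults are
a configurable stand-in); cumulative urine accumulated from the final dose
as the integral of `CL_r·C_b`.  Noise is multiplicative lognormal with
`σ = √ln(1+CV²)`, CV defaulting to 0.15 (the stated assay reproducibility),
mean-one parameterization so observations are unbiased.  Blood values below
the LLOQ (default 0.5 ng/mL) are censored to missing, as an LC/MS assay
would report them.  For urine, noise is applied to the nonnegative
increments and re-accumulated, so cumulative records stay monotone (noising
cumulative values directly could make them decrease).  Each animal draws
from a sub-stream keyed by `(seed, animal_id)`, so enlarging a study never
reshuffles existing animals.

What the generator does **not** emulate: between-animal parameter
variability (only residual error; the reference data are pooled means),
sparse/irregular sampling, assay drift, or model misspecification — passing
recovery tests therefore demonstrate estimator correctness under the model,
not robustness to real-data pathologies.

## Reproduction status and known limitations

The clearance chain is reproduced essentially exactly: 6.7 μL/min/mg scales
to 24.12 L/h (reported rounded to 24.0); × (5.44/0.173) gives 754.7 ≈ 755
L/h; well-stirred clearances 81.45 L/h (human) and 2.78 L/h/kg (rat) match
the reported 81.5 and 2.8.

The simulated human concentration endpoints are only partially reproducible,
for a structural reason worth stating plainly.  The reference values quoted
for these scenarios are: nicotine/cotinine = 17/150 ng/mL at 1 h after a
single 43.4 mg dose, and Cmax ≈ 20/180 ng/mL after a single 70 mg dose.
But the governing equations are dose-linear, so any parameterization must
satisfy `Cmax(70 mg) ≥ (70/43.4)·C(1 h; 43.4 mg)`; the quoted pairs violate
this for both compounds (17 × 1.613 = 27.4 > 20; 150 × 1.613 = 242 > 180).
No linear model can reproduce all four numbers, whatever its parameters.
This implementation, with the fixture parameters, gives 14.2/131.6 ng/mL at
1 h and Cmax 25.9/324.6 ng/mL — consistent with the linearity bound, within
~20% of the 1-h biomonitoring measurements (15.6/110 ng/mL), but not within
the quoted simulated values as a set.  Two observations from sensitivity
runs: the 1-h pair is matched almost exactly (16.9/157.6) if the *rat*
absorption constant (1.07 h⁻¹) is used in the human model, and the
steady-state cotinine level under *daily repeated* 43.4 mg dosing is
≈154 ng/mL ≈ 150; either may explain how the quoted values were produced,
but neither rescues the 70 mg Cmax pair, so the fixture `k_a = 0.795` and
single-dose scenario definitions are retained as specified.

Under 14-day repeated 70 mg dosing, "accumulation of approximately
20 ng/mL" is quoted without saying whether it means the steady pre-dose
trough or the gain over day 1.  This model gives ≈50 ng/mL for the former
and ≈4 ng/mL for the latter (the cotinine half-life of ≈6.6 h leaves only
8% carry-over per day), so the repeated-dose scenario report includes both
readings and asserts neither; the quoted figure sits between them and is
consistent with neither under this parameterization — unsurprising given
the Cmax discrepancy above.

Other limitations: the estimation workflow assumes the model that generated
the data (no model-misspecification diagnostics); `K_p,h` and `f_u,p` are
taken as species-independent constants; and the IVIVE chain treats the
microsomal values as point inputs with no uncertainty propagation.
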