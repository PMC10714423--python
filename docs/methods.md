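# Methods

`hemopkpd` implements a mechanism-based pharmacokinetic–pharmacodynamic
(PK-PD) model of chemotherapy-induced anemia and thrombocytopenia (CIAT) in
tumor-bearing rats: a single carboplatin dose suppresses a shared
hematopoietic stem/progenitor cell (HSPC) pool, while recombinant human
erythropoietin (rHuEPO) and the thrombopoietin-receptor agonist romiplostim
stimulate the erythroid and megakaryocytic lineages that compete for those
progenitors.  This note records the model equations as implemented, the
parameters and their defaults, the numerical choices, what the synthetic
data generator does and does not emulate, and the design decisions taken
where the published description left the algebra open.

## Pharmacokinetics

All three drugs have linear disposition; amounts are absolute (dose per kg
× body weight, default 0.180 kg), volumes in litres, time in hours.

* **Carboplatin** (i.v. bolus, day 4): three-compartment mammillary model
  with elimination `K_el` from the central compartment and two
  distribution pairs `K_CP1/K_PC1`, `K_CP2/K_PC2`.
  `C_CAR = A1/V_central` (µg/mL).
* **rHuEPO** (i.v. bolus, thrice weekly ×2 wk from day 8, days
  8/10/12/15/17/19): two-compartment model parameterized by clearance-type
  quantities — `K_CP = Q/V4`, `K_PC = Q/V5` hold exactly by construction.
  `C_EPO = A4/V4` (mIU/mL).  Endogenous EPO is neglected.
* **Romiplostim** (s.c., days 8 and 15): first-order absorption `ka` from a
  depot into a one-compartment system with apparent `CL/F` and `V/F`
  (bioavailability absorbed into the parameters).  `C_ROM = A7/V7` (ng/mL).

Because the system is linear, the central concentration of each drug is a
dose-superposed sum of exponentials obtained from the eigendecomposition of
its rate matrix.  This closed form is the forcing for the fast PD
integrator and is itself validated in the tests against
matrix-exponential (`scipy.linalg.expm`) oracles, superposition, dose
proportionality and mass balance.

**The packaged `nominal_pk.yaml` is a synthetic parameter set**, not an
estimate from the rat study (serum PK parameters of that study are not
available).  Values were chosen once to be physiologically plausible for a
180 g rat and to place the system in the regime the study describes:
carboplatin clearance is sized so that the effect-site inhibition
`kill·C_eff` peaks near 0.5 (deep but clamp-free myelosuppression, platelet
nadir ~40% below baseline around day 12), and romiplostim exposure gives
Cmax ≈ 10 ng/mL (inside the reported 0.25–25 ng/mL assay range, platelet
peak ≈ 2× baseline).  rHuEPO kinetics use typical rat values (central
volume ≈ plasma volume, terminal half-life of a few hours), so a 100 IU/kg
dose yields a peak of ≈ 2000 mIU/mL decaying through `SC50_EPO` = 66 mIU/mL
within half a day.  All recovery/acceptance quantities are PD-side and are
generated and re-fitted under the same PK, so none of them depends on
these choices being the study's true values.

## Pharmacodynamics

Latent state (default 26 components): HSPC; BFU-E; CFU-E; erythroid
precursor (normoblast) stage (a transit chain of configurable length,
default 1, mean residence `T_EP`); RET; mature RBC mass; MK1..MK10;
PLT1..PLT10; and the carboplatin effect-site concentration `C_eff` with
`dC_eff/dt = Ke0·(C_CAR − C_eff)`.

Named drug-effect factors (each behind its own function so any single
wiring choice is a one-line change):

* survival `S(t) = max(0, 1 − kill·C_eff)` — linear carboplatin inhibition,
  floored at zero because the linear form is unbounded; at the packaged
  parameter values the floor never engages (asserted in tests);
* EPO stimulus `1 + Smax_EPO·C_EPO/(SC50_EPO + C_EPO)` (Emax);
* romiplostim stimuli `1 + Smax_ROM1·C_ROM` and `1 + Smax_ROM2·C_ROM`
  (linear);
* platelet-deficit feedback `1 + Smax_PLT·max(ΔPLT, 0)` with
  `ΔPLT = PLT0 − PLT(t)` (see the stability discussion below).

HSPC balance:

    dHSPC/dt = Kin1·(1 + Smax_ROM1·C_ROM)·(1 + Smax_PLT1·ΔPLT⁺)·S
             − KE·(1 + Smax_EPO·C_EPO/(SC50_EPO + C_EPO))·S·HSPC
             − KM·(1 + Smax_ROM2·C_ROM)·(1 + Smax_PLT2·ΔPLT⁺)·S·HSPC

The erythroid branch amplifies by `2^MCFU` at BFU-E → CFU-E and `2^MNOR` at
CFU-E → precursor, then transits through RET (mean `T_RET`) and the mature
RBC pool (mean `T_RBC`).  The megakaryocyte branch is an n = 10 aging chain
with transition rate `10/T_MP`, shedding `CF = 4000` platelets per
megakaryocyte into an n = 10 platelet chain with rate `10/T_PLT`.
Carboplatin-stimulated MK apoptosis is an extra first-order loss
`kill·C_eff/T_MP` applied in every MK compartment — the dimensionless drug
effect scales the pool turnover rate `1/T_MP`, and the apoptotic flux is
not transferred downstream.  (Scaling instead by the per-compartment
transit rate `10/T_MP` multiplies the integrated apoptotic hazard tenfold
and empties the MK chain at any realistic exposure, which is incompatible
with the moderate observed nadirs; the pool-turnover scaling was adopted
for that reason.)

Observables are derived, never stored: `RBC = RET + MRBC` (hematology
analyzers count reticulocytes within RBC), `HGB = MCH·RBC/10` (the 10
converts pg/cell × 10¹² cells/L to g/dL; RET and mature RBC carry the same
MCH), `PLT = Σ PLT_i`.

### Secondary parameters and baselines

Given the observable baselines, the drug-free steady state fixes
everything upstream (`solve_baselines`):

    flux_RBC = RBC0/(T_RET + T_RBC)            RET0 = flux_RBC·T_RET
    HSPC0    = flux_RBC/(KE·2^(MCFU+MNOR))     MRBC0 = flux_RBC·T_RBC
    flux_MK  = PLT0/(T_PLT·CF)                 KM = flux_MK/HSPC0
    Kin1     = (KE + KM)·HSPC0                 PLT_i0 = PLT0/10

Substituting the returned baselines into the drug-free right-hand side
gives derivatives that vanish to numerical precision (asserted at 1e-10 in
relative terms).  `MCFU = 5` and `MNOR = 4` (32 CFU-E per BFU-E, 16
normoblasts per CFU-E — physiologic division counts) are fixed constants,
exposed in the config and excluded from estimation; they only set the
scale of the latent progenitor states (HSPC0 halves when MCFU increases by
one) and no reported quantity depends on them beyond this baseline
self-consistency.  `T_EP` is tied to `T_RET`; the BFU-E and CFU-E stages,
whose residence times are not separately reported, also use `T_EP`.

### Feedback stability (a deliberate design choice)

With a *two-sided* linear feedback `1 + Smax_PLT·ΔPLT` the drug-free
baseline is linearly unstable at the reported parameter estimates: the
loop gain of the platelet branch is `Smax_PLT2·PLT0 ≈ 2.8` through a
distributed delay of roughly `T_MP + T_PLT` ≈ 10 days, and the Jacobian at
baseline has a complex pair with real part +0.0032 /h (a growing 14-day
oscillation, amplitude doubling every ~9 days).  That is irreconcilable
with the damped course the model is meant to reproduce — platelet nadir
around day 15, a single rebound near day 22, and a slow return to baseline
within the 40-day window.  The implementation therefore makes the
thrombopoietin-like feedback **one-sided**: the deficit stimulates
(`ΔPLT > 0`), a surplus simply withdraws the stimulus rather than actively
suppressing hematopoiesis.  This leaves the baseline neutrally stable from
above, produces the damped nadir → rebound → return pattern on the
carboplatin arm, and preserves every qualitative contrast between arms.

## Time conventions and study design

One timeline: t = 0 is pharmacodynamic sampling day 0 (tumor inoculation);
carboplatin at day 4 (96 h); supportive therapy from day 8; day *d* maps
to 24·*d* hours.  Nine arms: tumor control, carboplatin control, rHuEPO
100/450/1350 IU/kg, romiplostim 30 µg/kg, and the three combinations (all
treated arms receive carboplatin).  Hematology sampling days:
0, 4, 8, 10, 12, 15, 17, 19, 22, 24, 26, 29, 31, 33, 36, 38, 40; n = 6
animals per arm.

## Synthetic data

`generate_dataset` simulates each arm at the design days and adds residual
noise per observable with `Y = Ŷ·(1 + ε₁) + ε₂`: combined
(σ₁ = 0.1657 proportional, σ₂ = 0.1103 additive) for platelets, additive
only for RBC (σ = 0.5616) and hemoglobin (σ = 1.177), all on the natural
observation scales.  Negative draws are floored at zero and flagged.
Subject identifiers are generated for realism but ignored by the
naive-pooled fitter.

What the generator does **not** emulate: inter-animal variability (each
animal differs from the arm mean only through residual noise — real rats
have correlated, animal-specific trajectories), dropout/death, sparse-PK
sampling, assay drift, or model misspecification.  Passing the recovery
suite therefore demonstrates that the estimation machinery is correct and
that the design identifies the parameters *when the model is true*; it
does not demonstrate robustness to biological between-animal variance or
structural misfit.

## Estimation

Naive pooling has no random effects, so the conditional mixed-effects
estimator used for such designs reduces exactly to pooled Gaussian maximum
likelihood; the objective is

    −2LL = Σ_ij [ log(2π·v_ij) + (y_ij − ŷ_ij)²/v_ij ],   v = σ₁²ŷ² + σ₂²

(+∞ on non-finite predictions, making failures optimizer-safe).  Because
`v` depends on ŷ for platelets, the exact optimum sits slightly below the
data in that channel — the familiar behavior of extended-least-squares
objectives; the two are identical up to additive constants.

Free parameters are log-transformed for positivity.  Fitting is two-stage:
a bounded trust-region-reflective least-squares pass on standardized
residuals (which ignores the log-variance term), then a Nelder–Mead polish
of the exact −2LL (default 300 iterations; a polish step is only accepted
if it does not increase the objective).  Standard errors come from the
central-difference Hessian of −2LL at the optimum (relative step 1e-4),
`cov = 2·H⁻¹`; on the log scale `100·SE(log θ)` is directly the RSE%, and
a singular Hessian yields "not available", never a fabricated number.
Presets: `core8` (kill, T_RBC, T_RET, T_PLT, T_MP, MCH, Smax_EPO,
SC50_EPO — the well-identified set used by the recovery experiments, ~10 s
per fit) and `full16` (all structural parameters).  Residual-error σ's can
be freed by name; the presets hold them fixed.

The recovery experiment (`run_recovery`) generates replicate datasets at
the packaged truth with seeds `seed + i`, perturbs the initial values by
U(0.8, 1.2) factors, fits, and reports per-replicate estimates; the
headline check is the median over 10 replicates.

Diagnostics: observed-vs-predicted and standardized-residual plots, the
empirical SD of standardized residuals (≈1 under a correct model), and a
Wald–Wolfowitz runs test on the time-ordered residual signs per observable
(detects structural trend; a negative control with the carboplatin effect
removed fails it decisively).

## Numerics

* **Coupled mode** (reference, default for `simulate`): one ODE system of
  7 PK + 26 PD states, integrated piecewise between dose events with
  LSODA (rtol 1e-8, atol 1e-10); boluses are exact state jumps at event
  times, never stiff impulse approximations.  A Radau cross-check agrees
  to better than 1e-5 relative.
* **Fast mode** (estimation path): closed-form PK concentrations forcing a
  fixed-step classical RK4 integration of the PD states in a numba
  kernel, step 0.25 h, segmented at dose times with per-segment active-dose
  counts so a dose never leaks into the preceding step.  Agrees with the
  coupled mode to ~1e-6 relative (tested at 1e-4) and is step-converged to
  <1e-6 at half the step.
* Output grids are extracted at exact grid membership, no interpolation;
  repeated runs are bit-identical.
* Trajectory phase metrics (`summarize`) identify the first nadir as the
  first local minimum below baseline, the rebound as the first local
  maximum after it, and the second nadir as the minimum thereafter —
  global extrema would misattribute the phases when the late recovery
  overshoots the first rebound.
* The megakaryocyte-to-platelet bookkeeping check integrates the
  CF-scaled outflow of a unit MK1 impulse with all drugs off until the
  chain is exhausted (40 mean lifespans); the exact value is CF = 4000.

## Problem sizes

The shipped experiments are desk-scale by design: hourly 40-day grids for
simulation checks, 9 arms × 17 days × 3 observables × 6 animals = 2754
observations per synthetic dataset, and 10-replicate core-8 recoveries
(≈ 2 minutes total on one CPU).

## Known limitations

* The progenitor amplification exponents and the BFU-E/CFU-E residence
  times are fixed assumptions, not estimates; only latent scales depend on
  them.
* Romiplostim disposition is linear — target-mediated clearance by the
  platelet mass is not modeled; neither are endogenous EPO/TPO kinetics.
* The one-sided feedback and the MK-apoptosis rate scaling are structural
  choices made where the source description was ambiguous (both are
  isolated behind named functions).
* No inter-individual variability: the fitter is naive-pooled ML and RSE%
  quantifies precision under pooling, not population variability.
* Granulopoiesis/neutropenia, tumor dynamics and VEGF are out of scope.
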