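# Methods

This note documents the models implemented in `tissuecage`, the choices made
where the design was genuinely open, and what the simulation-based tests do
and do not establish.

## Cage geometry

A tissue cage is a silicone cylinder (17 mm outer diameter, 1 mm wall, so a
15 mm lumen) sealed at both ends and perforated with `n_holes` fenestrations
cut by a biopsy punch (defaults: 24 holes, 4 mm punch). Drug exchange happens
only through the fenestrations, so the diffusible area is

    A = n_holes · π (d_punch / 2)²          [cm²]

independent of cage length, while the lumen volume is the full nominal
cylinder `V = π r_lumen² L` [mL]. The surface-area-to-volume ratio SA/V = A/V
therefore scales as 1/L for the five built lengths (3, 6, 10, 14, 18 cm),
spanning 0.5689 down to 0.0948 cm⁻¹. Punch holes are treated as flat circles
(tube-wall curvature ignored) and the putty-sealed ends are counted in the
volume; both conventions reproduce the published dimension table to four
decimals. The wall thickness is not stated in the source construction
protocol; 1 mm is adopted because it reproduces every published volume
exactly, and it is an overridable field of `CageSpec`.

Under Fick's law a well-stirred cage exchanging drug through area A has
first-order transfer rate constants proportional to SA/V
(`fick_rate(P, SA/V) = P · SA/V` with P an effective permeability in cm/h),
which is why cages of equal SA/V but different absolute size share kinetics.

## Pharmacokinetic model

Plasma disposition after the 4 mg/kg IV bolus is a linear two-compartment
model parameterised by central volume V (L/kg), clearance CL (L/h·kg) and
inter-compartment rates k12, k21 (h⁻¹), with elimination rate k10 = CL/V.
The central concentration is the biexponential

    C1(t) = A_f e^(−λ_f t) + A_s e^(−λ_s t),

where λ_f, λ_s are the roots of λ² − (k10+k12+k21)λ + k10·k21 = 0 and
A_f + A_s = dose/V. Each cage is a *forcing-function* compartment: its
concentration obeys

    dC3/dt = k13 C1(t) − k31 C3,   C3(0) = 0,

with no feedback on plasma (the drug mass entering a cage is negligible).
The closed-form solution is evaluated through the kernel
`t e^(−λt) φ((k31−λ)t)` with `φ(x) = (1−e^(−x))/x`, which is numerically
stable through the degenerate case k31 ≈ λ (φ(0)=1 recovers the `t e^(−λt)`
limit; the series switch point is |x| < 10⁻⁸, or 10⁻³ where first and second
derivatives are also needed). Closed forms agree with a stiff ODE integrator
to a relative error below 10⁻⁸ across a broad parameter grid including the
exactly degenerate rates.

### Covariates and variability

Covariates act log-linearly and uncentered on the rate constants:

    k = k_pop · exp(Σ β_i x_i),

with x the cage length in cm, and 0/1 flags for carrageenan-in-cage,
carrageenan-in-sheep (which acts on k12/k21, i.e. systemic kinetics change
when any cage in the animal is inflamed) and right-hand side. The reference
level is the left side with no carrageenan. The uncentered log-linear
convention is adopted because, at the reference estimates, exp(−0.147·15)
≈ 0.11 matches the observed ratio of 18 cm to 3 cm median efflux rates
(≈ 0.104), which neither an additive nor a centered convention does.

Between-subject variability is lognormal: V and CL share one per-sheep pair
of η's, and each physical cage carries its own (k13, k31) pair across both
periods; k12 and k21 carry no random effects because no variability was
reported for them. Per-cage (rather than per-sheep) placement of the cage
η's follows from each sheep contributing ten cages with visibly distinct
individual estimates. Residual error is proportional,
`y = f(1 + b ε), ε ~ N(0,1)`, with separate b for plasma and cage fluid.

### Reference parameter values

`reference_model()` carries the published population estimates used as the
default generating model: V = 0.0924 L/kg, CL = 0.00235 L/h·kg, k12 = 0.121,
k21 = 0.200, k13 = 0.124, k31 = 0.455 h⁻¹; covariates β_k12,carr-sheep =
0.00114, β_k21,carr-sheep = 0.336, per-cm β_k31 = −0.147, β_k13 = −0.0378,
carrageenan-in-cage β_k31 = −0.104, β_k13 = −0.184, right-side β_k31 =
−0.0701, β_k13 = −0.024; random-effect SDs ω_V = 0.188, ω_CL = 0.448,
ω_k31 = 0.522, ω_k13 = 0.482; error b_plasma = 0.136, b_cage = 0.468.

Note that ln2/λ_s at these values is ≈ 45.1 h; the 27.2 h terminal
half-life quoted alongside the same estimates cannot be derived from them
and was presumably computed from individual estimates or non-compartmental
analysis, so `terminal_half_life` is contracted to the closed form, not to
that number.

## Trial simulator

`simulate_trial` reproduces the cross-over design: 7 sheep, five cage
lengths duplicated left/right (10 cages per sheep), two periods, sampling at
−1, 0.5, 1, 2, 3, 4, 5, 6, 8, 12, 24, 36, 48 and 72 h, carrageenan injected
into all five cages of one randomised side during period 2. Pre-dose (−1 h)
samples carry concentration 0, are flagged `below_dose_time`, and are
excluded from every fit. Proportional-error draws that go negative are
truncated at zero (≈1.6% of cage records at the reference b_cage; the count
is logged); a check at 50 sheep showed fits with and without these zeros
differ by under 2%, so they are retained as ordinary records. Missingness is
uniform-at-random over cage records and off by default. Body weight is
absorbed into the per-kg units; individual weights are not simulated.

What the generator does *not* emulate: assay censoring and calibration
structure, enterohepatic recirculation (visible in the real profiles but
outside the model), enantiomer kinetics, protein-binding changes, and any
between-occasion variability. Passing recovery tests therefore demonstrate
that the estimator inverts the stated generating mechanism at the stated
sizes — not that the model captures every feature of real sheep data.

## Estimation

Fitting is sequential, mirroring the original analysis: (1) the plasma
model is estimated from plasma data alone; (2) each sheep's empirical-Bayes
(posterior-mode) V and CL are computed at the population estimates; (3) the
cage model {k13, k31, six covariate β's, ω_k13, ω_k31, b_cage} is estimated
with each sheep-period's fitted plasma curve as a fixed forcing function and
per-cage random effects. A joint refit is deliberately out of scope.

The marginal likelihood integrates the 2-dimensional random effects per
group by the Laplace approximation. Conditional modes are found by a damped
Newton iteration vectorised across all groups, using exact analytic
gradients and Hessians of the joint density (the cage prediction is linear
in e^η1, and the plasma derivatives reduce to closed-form sensitivities of
the disposition exponents in k10). The inner iteration stops at gradient
1e−9 or step 1e−9 — the step criterion makes repeated solves bitwise stable,
which keeps the outer finite-difference gradient clean. The outer optimiser
is L-BFGS-B on log-transformed positivity-bounded parameters (β's bounded by
±2 on the log scale), with the objective scaled per observation so the
identity initial Hessian gives well-sized first steps, warm-started from a
naive-pooled pre-fit (random effects pinned at zero). The original analysis
used stochastic-approximation EM; the model, not the optimiser, is what this
package reproduces, and the Laplace integrator is validated against adaptive
Gauss–Hermite quadrature (9 nodes per dimension, agreement well within 0.5
log-units).

Standard errors are Wald, from a central finite-difference Hessian of the
marginal negative log-likelihood at the optimum, delta-transformed to the
natural scale; CIs for log-parameters are exponentiated normal intervals and
covariate p-values are normal-reference Wald tests. Covariate β's whose
column does not vary in the supplied design are dropped with a logged
warning and reported as structural zeros. Convergence reporting follows the
optimiser; in the noise-free degenerate limit (b at its lower bound) the
optimiser may flag non-convergence while the estimates are exact — the
estimates, not the flag, carry the contract there.

## Peak summaries and contrasts

Observed Tmax/Cmax are read per cage series from the raw records, pre-dose
samples excluded, with ties broken to the *earliest* attaining time (the
source is silent; earliest is the common convention). Per-size summaries use
midpoint medians for even counts. Pairwise size contrasts come from a linear
mixed model `response ~ size factor + (1 | sheep)` fit by REML
(statsmodels MixedLM), reported as all ten pairwise marginal-mean
differences with normal-reference Wald CIs and unadjusted p-values (the
model behind the original contrast tables is unstated; a Holm option and a
fixed-effects fallback are provided but off by default).

## PGEM model

Prostaglandin-E-metabolite concentrations are modelled on the log10 scale as

    log10(PGEM) = β0 + γ_sheep + β1·t + β2[size] + β3[size]·t + ε,

with cage size a 5-level factor (3 cm reference), γ_sheep ~ N(0, sd_sheep²),
ε ~ N(0, sd_resid²), fit by REML. Carprofen concentration is excluded as a
predictor (collinear with time by design); time is hours from dosing,
uncentered. Explained variance is summarised by the Nakagawa R²:

    R²_marginal    = var(Xβ) / (var(Xβ) + sd_sheep² + sd_resid²)
    R²_conditional = (var(Xβ) + sd_sheep²) / (same denominator).

The variance components of the generating model were never reported; the
simulator derives them by inverting the R² definitions at the reported pair
(0.27, 0.42) given the fixed-effect variance of the realised design — the
only self-consistent choice (`solve_variance_components`). The simulated
assay subset samples all inflamed cage series at 6 of the trial's times
(0.5, 6, 12, 24, 48, 72 h) and includes non-inflamed records with
probability 0.11, reproducing the deliberate imbalance of roughly 280
records with ~74 from non-inflamed cages.

## Problem sizes and numerical settings

Simulation-based checks use: 50-sheep trials for recovery of CL, V and the
per-cm k13 covariate (6, 6 and 5 replicates in the test-suite; 20 and 30 in
the acceptance script), 100 replicates at the study's own 7-sheep size for
median-bias and CI-coverage checks, and 30 replicates for the PGEM model.
These sizes put the Monte-Carlo error of each replicate mean well inside the
recovery bands while keeping a full run in the minutes range on one CPU.
Outer optimiser: max 500 iterations, ftol 1e−11 (per-observation scale),
gradient FD step 1e−5; all overridable per fit call. Table display rounding
is 4 decimals for geometry; all computations keep full precision.

## Known limitations

- The Laplace approximation can bias variance-component estimates at very
  sparse designs; the 7-sheep bias checks cover V and CL, not the ω's.
- The sequential (plasma-then-cage) strategy conditions on empirical-Bayes
  plasma curves and ignores their uncertainty in the cage-stage standard
  errors, exactly as in the original two-step analysis.
- The reference model's typical values imply cage Cmax *increasing* with
  cage length (the k13/k31 ratio grows with length), so simulated
  observed-peak tables will not reproduce published observed Cmax orderings,
  which point the other way; the simulator is faithful to the stated model,
  and those observed tables are outside what this package claims to
  recompute.
- Wald inference throughout; no profile likelihood, bootstrap, or
  Kenward–Roger degrees-of-freedom corrections.
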