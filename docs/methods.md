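# Methods

This note documents the model equations, the numerical scheme, the choices
made where the underlying science leaves the design open, and what the
synthetic-data generator does and does not emulate.

## Compartment structure and mass balance

The mother and the child are each represented as one well-mixed lipid
compartment comprising all body lipids (blood lipids included). Working in
lipid-normalized concentration (ng/g lipid) makes maternal blood, cord
blood and breast milk commensurable and removes the need for organ-level
physiology. The state variables are chemical *amounts* `A_m`, `A_c` (ng);
concentration is `A / (1000 · V)` with `V` the lipid mass in kg, so any
change in lipid volume dilutes or concentrates the burden without extra
terms.

Postnatally:

    dA_m/dt = I − k_el·A_m − c(t)·A_m
    dA_c/dt = c(t)·A_m − k_el·A_c
    c(t)    = r_milk(t) · f_lip(t) / V_m(t)

where `I` is the constant maternal daily oral intake (ng/day, fully
absorbed, converted to ng/year), `k_el = ln 2 / t½`, `r_milk` the milk
volume intake (L/year) under the feeding schedule, `f_lip` the milk lipid
content (kg/L) and `V_m` the maternal lipid mass. The transfer term appears
with opposite signs in the two compartments; cumulative intake, elimination
and transfer are integrated alongside the state so that
`cum_intake = A_m + A_c + cum_eliminated` can be audited at every output
point (enforced to 1e−3 relative in the tests; in practice it holds to
machine precision).

**Prenatal phase.** The mother accumulates from her birth to delivery under
constant intake with first-order elimination and no lactation. This phase
has constant coefficients, so the exact solution
`A(t) = (I/k_el)(1 − e^(−k_el·t))` is used instead of stepping the ODE —
equivalent to, and cheaper and more accurate than, the integrator
(cohort-scale runs execute thousands of these simulations). During
gestation the fetus shares the maternal pool: fetal lipids (15%/14% of
fetal weight for males/females, fetal weight from a normalized reference
growth curve scaled to the individual birth weight) are counted in the pool
volume, and at delivery the pool splits in proportion to lipid mass. The
newborn therefore starts exactly at the mother's delivery concentration.
Maternal elimination is assumed unchanged during pregnancy, and the child
has no dietary (non-milk) POP intake after weaning; both are simplifying
assumptions flagged here because the source data cannot distinguish them.

**Maternal lifetime shape.** The pre-delivery weight trajectory ramps
linearly from 3.4 kg at birth to the prepregnancy weight at age 18. Because
the kinetics are linear in dose and the biomarker calibration rescales the
whole profile, this shape only fixes the *label* on the intake axis; every
concentration downstream of calibration is invariant to it.

## Physiologic sub-models

- **Milk intake.** Exclusive breastfeeding:
  `max(0, −0.0024·age + 0.0063) L/kg/h × child weight` (zero crossing at
  ~2.62 y). Partial feeding from 12 months: the absolute line
  `max(0, −0.0086·age + 0.0188) L/h`, applied to its natural zero crossing
  at ~2.19 y rather than cut at 24 months — extending to the zero avoids a
  discontinuous cliff and changes nothing for typical schedules. Partial
  feeding *before* 12 months is a configurable fraction (default 50%) of
  the exclusive volume at that age and weight.
- **Milk lipids.** `0.0034·ln(age) + 0.0414 kg/L`, clamped below to its
  value at 7 days (0.0280 kg/L) so the logarithm stays finite over the
  colostrum period. The clamp age is a pragmatic floor: colostrum is
  lipid-poor, and the first week contributes little transferred mass.
- **Maternal lipids.** Baseline lipid mass = body weight × an age-specific
  female lipid fraction from a packaged lookup table. Pregnancy adds
  `0.75 × (weight gain − lean gain)`, both ramping linearly from conception
  to their term values (total gain default 14.5 kg; lean gain — fetus,
  uterus, placenta, fluids — 5.8 kg at term). After delivery the weight
  excess over prepregnancy weight is treated as adipose tissue (75% lipid):
  the implicit anchor at delivery is the fat mass gained in pregnancy (lean
  tissue is assumed lost at birth, which also makes the lipid volume
  continuous across delivery), interpolated linearly through the postpartum
  offset records (default +2 kg at 0.5 y, 0 kg at 1 y) and constant after
  the last. A floor of 0.5 kg keeps the lipid pool positive under extreme
  postpartum loss.
- **Child lipids.** Weight (piecewise-linear through the timed records,
  constant beyond the last — supply a late weight record if the profile
  matters beyond it) × an age/sex lipid fraction lookup whose value at age
  0 equals the fetal fraction, making the newborn pool continuous with the
  prenatal one.
- **Reference tables.** The lipid-fraction and fetal-growth curves are
  packaged CSVs (`src/poptk/data/`). They are *synthetic* reference curves:
  assembled for this package with the shape of published body-composition
  and fetal-weight references, anchored at the constraints the model states
  (newborn fractions 15%/14%), and explicitly overridable
  (`lipid_table=`/`growth_table=` arguments) because the exact numeric
  curves behind the original analysis are not recoverable. Conclusions that
  depend on fine detail of these curves should supply measured ones.

## Numerical scheme

The postnatal coupled system is integrated with the classical 4th-order
Runge–Kutta method on a fixed ~1-day grid (configurable `step_days`). The
right-hand side is only piecewise smooth — feeding-phase boundaries, the
partial-feeding formula switch at 1 y, intake zero crossings, the milk-lipid
floor, weight-record and postpartum-offset kinks — so those breakpoints are
inserted into the grid and the transfer coefficient is precomputed on the
node/midpoint lattice; every step then integrates a smooth problem at full
order. Halving the step changes reported concentrations by far less than
0.1%. The system is linear and non-stiff; an explicit fixed-step scheme is
the simplest method that meets the accuracy contract.

Intake calibration exploits dose linearity: one unit-intake (1 ng/day)
simulation predicts the biomarker reading in the measured matrix (maternal
blood and cord blood are interchangeable delivery samples; breast milk
equals the maternal lipid concentration at the sampling time under the
instantaneous-equilibrium assumption), and the intake is the measured/
predicted ratio. The round trip is exact to floating point.

**Milk-basis factor.** Breast-milk lipids are nearly pure neutral
triacylglycerols, while the usual blood-lipid adjustment also counts
phospholipids that bind lipophilic compounds weakly; milk readings
therefore overread the blood-lipid basis by ~1.6 on average. A measurement
carries a `milk_basis_factor` (default 1.0 = no correction; set 1.6 to
divide the milk reading by the average artifact). The synthetic generator
emits milk biomarkers *with* the 1.6 artifact by default, so the
uncorrected milk pipeline reproduces the ~60% overestimation of child
levels and the corrected one cancels it — a mechanism check, not a claim
about any particular laboratory.

## Global sensitivity analysis (eFAST)

Variance-based indices are estimated with the extended Fourier Amplitude
Sensitivity Test: each input is driven along a periodic search curve
`x_j = low_j + (high_j − low_j)·(1/2 + arcsin(sin(ω_j s + φ_j))/π)`,
`s ∈ (−π, π]`, the focal input at a high frequency ω and the complement at
low frequencies. The first-order index is the spectral power at ω and its
harmonics up to the interference factor M (default 4) over the total power;
the total effect is one minus the complementary-band (≤ ω/2) share. Random
phases give Nr independent resampling curves whose indices are averaged;
everything is reproducible from the seed.

Two frequency-selection details matter in practice, and both are handled
here: (i) with the textbook saturated choice ω = (N−1)/(2M), the first
sidebands of every focal harmonic alias exactly onto other focal harmonics
(2Mω = N−1), inflating null-parameter indices by ~0.02–0.07 on the Ishigami
benchmark, so ω is backed off by a 2M guard band; (ii) complementary
frequencies are forced odd so no low-order harmonic of the complement
coincides with the (even) focal frequency. With N = 1025, Nr = 4 the
estimator matches the analytic Ishigami first-order indices to ~0.006.
When more parameters than available low frequencies force complements to
share a frequency, their cross-terms interfere in the per-curve variance;
this averages out over resampling curves but argues for the largest N the
budget allows (model default N = 129, Nr = 2, chosen as the smallest
configuration whose index *ordering* is stable across seeds; a run takes
tens of seconds on one core).

The model application varies the eleven inputs over their plausible ranges
(prepregnancy weight 51–114 kg, pregnancy gain 7.6–32 kg, postpartum change
−12–26 kg at 1 y, gestational age 22–42 wk, birth weight 0.34–4.9 kg, child
weights at 6 m/1 y/3 y, exclusive 0–12 mo and partial 0–45 mo breastfeeding,
partial milk fraction 0.1–0.9). Sampled child weights are sorted into a
monotone trajectory, and the partial duration is defined as time *after*
exclusive feeding so the pair is always consistent. The exposure scale is
anchored once — the mid-range reference dyad is calibrated to the fixed
cohort-median maternal-blood level — and each design row is simulated under
that intake scaled in proportion to its prepregnancy weight. Holding the
*intake* fixed (rather than recalibrating every row to the biomarker) keeps
the dilution effects of pregnancy and postpartum weight dynamics in the
output variance instead of absorbing them into the calibration, and scaling
intake with body size reflects that dietary intake tracks body weight;
together these choices yield the expected structure: breastfeeding duration
dominates the 6-month variance, pregnancy-gain influence fades with age,
postpartum-change influence grows, and prepregnancy weight and gestational
age matter little. Because the model is linear in dose, the biomarker level
itself is excluded from the varied set — it would dominate trivially and
uniformly.

## Cohort validation and the legacy metric

`validate_cohort` runs the full loop per dyad — calibrate from the
biomarker, simulate, evaluate at each child's *actual* sampling age — then
regresses ln(measured) on ln(simulated) within age windows (defaults:
6 mo = 5.5–11.7, 16 mo = 11.8–22.0, 45 mo = 33.0–69.1 months), reporting
R², slope, intercept and n per window. Natural logs are used (the base
cannot affect R²), the regression includes an intercept, non-detects are
excluded rather than substituted, rows missing essential fields
(breastfeeding durations, biomarker, sex) are excluded, and missing
non-essential values are imputed with the column mean (falling back to the
documented defaults: gain 14.5 kg, gestation 40 wk, partial fraction 0.5).

The legacy exposure metric — weeks of exclusive breastfeeding × milk level
— is degenerate under rescaling: doubling the level and halving the weeks
leaves it unchanged. The packaged misclassification fixture holds two dyads
with legacy products matched at ~4,700 weeks·ng/g (milk 639 ng/g for 7.4
weeks vs 193 ng/g for 24.4 weeks) whose simulated 3-month blood levels
differ by more than threefold. The fixture simulates from maternal-blood
measurements, as the cohort pipeline does, and assigns the two dyads
different milk/blood ratios (1.28 and 2.14, within the plausible biological
spread around the 1.6 average): with *all* other inputs identical, the
transfer term dilutes the ratio of the two profiles to ~2.2 by 3 months, so
the severalfold divergence requires the children to differ in more than the
legacy metric's two ingredients — which is itself the point the
demonstration makes.

## Synthetic-cohort generator

The generator emulates the *marginal* structure of the two study
populations. Demographics (maternal age, prepregnancy weight, gestational
age, birth weight, child weights) are normals matched to the printed
central value with σ = (p95 − p5)/(2·z₀.₉₅), truncated at the printed
percentiles. Breastfeeding durations are lognormal with the printed 5th/95th
percentiles (their strong right-skew rules out a normal), total duration
floored at the exclusive one and capped at the 45-month horizon; a
template-specific fraction of mothers ever breastfeeds (0.89 Inuit, 1.0
Slovak). Biomarker levels are lognormal with μ = ln(median) and
σ = ln(p95/median)/z₀.₉₅ from the printed medians — for Slovak
maternal-blood PCB-153, median 140 and p95 553 ng/g give σ = 0.835.

Each dyad carries one latent maternal burden: a target maternal-blood level
is drawn, the intake reproducing it is found by unit-dose calibration, and
the resulting true profile emits all three biomarker matrices consistently
(cord = maternal blood at delivery; milk = maternal level at the 1-month
sampling time × the 1.6 basis artifact) plus noise-free child levels at the
template's sampling ages. Measured child levels multiply the truth by
lognormal noise with log-scale σ_meas. The default σ_meas = 1.0 is a
*tuning, not an estimate*: it is the single dial that lumps assay error,
physiologic variation and model error, set once so that the 6-month
validation R² of the Slovak-template cohort falls in the 0.4–0.6 band
typical of PCB cohort validations (given this generator's log-level
variance of ~1.0, dominated by the biomarker lognormal). Cross-variable
correlations beyond the enforced consistency constraints are *not*
emulated (the source tables print marginals only), and no real-data model
error other than the single noise term exists here — so passing validation
on synthetic data demonstrates internal consistency of the
calibrate→simulate→regress loop and correct attenuation behavior, not
field accuracy on any real cohort.

## Known limitations

- Single compound per run; no metabolites, no non-dietary maternal routes,
  no child dietary intake after weaning.
- The lipid-fraction and fetal-growth tables are synthetic reference
  curves; absolute child-level predictions inherit their uncertainty
  (the biomarker calibration removes much of it, since only the *ratio* of
  lipid pools over time enters the calibrated profile).
- Constant-weight extrapolation beyond the last child weight record can
  turn growth dilution off; provide records covering the horizon.
- The 45-month horizon and 1-day step are defaults, not limits; both are
  arguments throughout.
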