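# Methods

This note documents the models, conventions and numerical choices behind
`gfrval`, in the order the pipeline applies them.

## Measured GFR from two plasma samples

The reference method assumes a single mono-exponential plasma
disappearance between the two late samples (~2 h and ~4 h
post-injection), i.e. a one-compartment description of the tracer after
early mixing. The chain is:

1. **Decay correction.** Counted activities are corrected over the
   sampling-to-counting interval with the Tc-99m half-life 6.02 h. The
   default direction (`as_printed`) multiplies by
   exp(−ln 2·Δt/6.02), i.e. it *shrinks* the value — appropriate when an
   early-counted reference standard is brought forward to the samples'
   counting time. The physically usual restoration of a late-counted
   sample to sampling time is the reciprocal and is available as
   `decay_direction="back_correct"`; with zero delays both are the
   identity. Both hooks exist because published protocols are often
   ambiguous about which quantity carries the delay.
2. **Slope-intercept clearance.** The two-point formula
   Cl′ = [D·ln(P₁/P₂)/(t₂−t₁)]·exp[(t₁·ln P₂ − t₂·ln P₁)/(t₂−t₁)]
   collapses to D·b/A on exact mono-exponential input; the test suite
   asserts this to 1e−9 relative error over a broad parameter sweep.
   D is a calibrated count rate (cpm/mL of a dilution standard), so Cl′
   is in mL/min only under that convention.
3. **Brøchner-Mortensen correction.** GFR = 0.990778·Cl′ − 0.001218·Cl′².
   The quadratic peaks at Cl′ ≈ 406.7 mL/min (maximum corrected value
   ≈ 201.5); inputs beyond the vertex are flagged, not rejected. The
   inverse mapping (used by the synthetic generator) takes the physical
   root below the vertex and is exact to 1e−9 over [0, 201.5).
4. **BSA standardization.** Haycock BSA from height (cm) and weight
   (kg); GFR is scaled by 1.73/BSA. Implausible anthropometry (height
   outside 100–220 cm, weight outside 25–200 kg) warns but computes.

Non-physiological records (P₁ ≤ P₂, clearance beyond the vertex) produce
flagged results with mGFR set to 0 rather than exceptions, so cohort
runs never abort mid-pipeline; flagged records surface in the
per-patient table.

## Creatinine equations

Equations are data: sex-stratified two-branch power laws
`coef·(Scr/denom)^exp·base^age` with the ≤-branch inclusive at the knot.
Two details deserve attention:

* **Male CKD-EPI denominator.** Transcriptions of the Asian modified
  CKD-EPI equation sometimes print (Scr/0.7) in the male rows although
  the male knot is 0.9 mg/dL, which would make the male curve
  discontinuous at its own knot — contrary to the construction of the
  CKD-EPI family. The default is the published 0.9; `male_denominator=0.7`
  reproduces the printed variant, and every report records which was
  used.
* **Ensemble regression knots.** The regression component of the
  ensemble model is *not* continuous at its knots as published (female
  coefficients 92 vs 79 at 1.2 mg/dL; male 98·0.996^age vs
  105·0.993^age at 1.0). The discontinuities are reproduced faithfully
  and characterized by tests, not repaired; as a consequence the male
  curve is non-monotone across its knot below age ≈ 23, and a band of
  GFR values at each knot has no creatinine preimage (the inversion
  raises for values in the gap). Monotonicity therefore holds globally
  for CKD-EPI and within each branch for the ensemble regression.

Age enters as a real number; no rounding rule is applied.

## Ensemble components

The ensemble eGFR is the mean of ANN, SVM and regression outputs; all
three are mandatory. The original ANN/SVM weights are not
redistributable, so the default run uses synthetic-trained stand-ins —
an MLP (16×8, lbfgs) and an RBF-kernel SVR on (log Scr, age, sex),
fitted to the true GFR of one seeded synthetic cohort (n = 2000) and
predicting on the log scale so outputs stay positive. They are faithful
to the ensemble's architecture, not to the original fitted weights;
conclusions about the *original* ensemble's accuracy cannot be drawn
from them, which is exactly why the component interface accepts external
coefficient files (`load_component`). Training is deterministic under
`standin_seed` and recorded in the run manifest.

## Exclusion screens and attrition

Rules apply in a fixed order — missing data, age < 18, dialysis,
interfering drugs, edema/cardiac insufficiency, outliers — with
append-only flags carrying the rule text. A record failing several rules
is counted once, under its first matching rule, making attrition tables
unique; the accounting identity n_screened = n_enrolled + Σ counts is
property-tested.

The outlier screen is |externally studentized residual| > 3 in the OLS
fit of eGFR on mGFR, run by default on both models' pairs (union).
Source descriptions of such screens rarely state the rule; ours is
config-visible (threshold, which model) and recorded in the report
metadata, with no claim that it reproduces any particular study's
exclusions. Below 10 pairs the screen is skipped with a warning.

## Comparison statistics

* Quantiles use linear interpolation (the common statistical-package
  default); declared in report metadata.
* Bias is eGFR − mGFR (positive = overestimation). Bland–Altman
  differences default to mGFR − eGFR, the orientation agreement plots
  conventionally use; widths and all CIs are invariant to the choice.
* P30's ±30 % boundary is inclusive, implemented with a 1e−12 relative
  slack so exact-boundary constructions are not lost to floating point.
* Bootstrap CIs are percentile 2.5/97.5 over B = 2000 patient-level
  resamples (the pair is resampled, never its components
  independently). Coverage of the bias CI is Monte-Carlo-checked at
  92–98 % over 500 cohorts of n = 150 (B scaled to 500 there to keep
  the suite fast).
* Wilcoxon signed-rank on per-patient error differences drops zero
  differences, uses the exact distribution for ≤ 25 untied non-zero
  values and the tie-corrected normal approximation above.
* McNemar on within-30 % indicators is exact-binomial when the
  discordant margin is < 25, continuity-corrected chi-square otherwise.
* **Precision comparison.** The natural percentile scheme — resample
  patients jointly, double the smaller tail of IQR_A* − IQR_B* — turns
  out measurably conservative for IQR statistics at cohort-scale n
  (empirical type-I ≈ 0.02 at α = 0.05, n = 150; percentile intervals
  for sample-quantile statistics over-cover at this n). The default is
  therefore a paired within-patient label-swap resampling test: under
  the null that the two models' errors are exchangeable within patient,
  randomly swapping them draws the exact null distribution of the IQR
  difference, and p = (1 + #{|Δ*| ≥ |Δ̂|})/(B + 1). Measured type-I is
  0.047–0.058 under both heavy-tailed multiplicative and additive
  normal error nulls. The percentile scheme remains available as
  `method="percentile"`; the report records which was used.
* All p-values are two-sided; no multiplicity adjustment.
* Statistics whose preconditions fail (e.g. n < 4 for precision) become
  null report cells with recorded reasons, never crashes.

## Synthetic cohort

The generator emulates a hospital CKD cohort referred for radiotracer
GFR measurement. Defaults (all config-visible, units in the dataclass):

| quantity | default | note |
|---|---|---|
| male fraction | 0.462 | |
| age | N(56.5, 15.1²), ≥ 18 | truncation lifts the mean to ≈ 57 |
| height / weight | N(165.3, 7.8²) / N(68.7, 13.5²) cm/kg | weight > 30 |
| true GFR | log-normal(3.9496, 0.9416²) | see below |
| creatinine noise | log-normal(−0.135, 0.26²) | see below |
| sample times | 120/240 min ± 10 jitter | exercises time dependence |
| distribution volume | 200 mL/kg body weight | one-compartment V |
| plasma noise CV | 0 | exact round-trip by default |

The true-GFR prior is fitted to the target quartiles 25.3/47.7/80.5
*after* truncation at the Brøchner-Mortensen invertible ceiling
(≈ 201.5, de-standardized per patient by BSA; out-of-range draws are
resampled and counted): a plain fit to the printed quartiles would
undershoot the simulated median by ≈ 2 units once truncated. Creatinine
is generated by inverting the CKD-EPI relation at the patient's age/sex
and multiplying log-normal noise; the noise SD (0.26) is the single
correlation knob, calibrated once so the eGFR–mGFR Spearman correlation
is ≈ 0.94, and the location (−0.135) calibrates the creatinine marginal
to a median of ≈ 1.30 mg/dL (noiseless inversion of this GFR prior
would put it near 1.52). A consequence worth knowing: the simulated
CKD-EPI marginal runs ≈ 15 % above measured GFR at the median, so the
simulated equations carry a positive median bias of ≈ 4–5 mL/min/1.73 m²
— the generator reproduces the *marginal structure* of such cohorts,
not any particular study's joint (eGFR, mGFR) distribution, and
simulated comparison results characterize the machinery, not the
equations' real-world accuracy.

Random streams are split per quantity from one seed
(`SeedSequence.spawn`), so adding a sampled column never perturbs
earlier draws; cohorts are byte-identical under a fixed seed. The
exclusion-scenario mode engineers disjoint record sets tripping each
screen (blanked creatinine, pediatric ages, indicator flags, creatinine
displaced ×6 or ÷6 for outliers) for attrition fixtures.

The null-pair generator used to calibrate the between-model tests draws
both models' values as mGFR times independent log-normal factors from
one distribution (σ = 0.3, putting per-model P30 near 0.7), so all three
between-model nulls hold by construction while eGFR stays positive.

## Problem sizes and runtime

The default test suite runs in well under a minute: Monte-Carlo checks
use 500 cohorts × B = 500 for CI coverage and 1000 null cohorts ×
B = 500 for test calibration; the acceptance script runs the full study
at n = 158 with B = 2000 plus a 10⁴-patient fidelity check in a few
seconds. These sizes were chosen so the calibration checks have
binomial Monte-Carlo error well inside their acceptance bands.

## Known limitations

* The plasma model is strictly mono-exponential; two-compartment
  kinetics, early-sample protocols and camera-based methods are out of
  scope, as are >2-sample fits.
* The stand-in ANN/SVM components are surrogates; dropping in the
  original coefficient files is supported but untested against the
  originals.
* The synthetic cohort has no etiology-specific GFR structure (labels
  are sampled at realistic frequencies but carry no effect), no
  longitudinal component, and no measurement-protocol failure modes
  beyond plasma noise and non-decreasing sample pairs.
* Dose-residue checks (syringe/injection-site counts) are represented
  only as validation flags, never as numerical corrections to D.
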