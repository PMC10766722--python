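# Methods

This note documents the statistical model implemented by `allerquant`, the
choices made where the procedure was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Signal model and calibration

The analytical signal is the light/heavy (L/H) peak-area ratio of each marker
peptide against its isotopically labelled internal standard (heavy spiked at a
fixed 25 fmol/µL). Calibration is **unweighted ordinary least squares** of
ratio on spiked concentration. No weighting is applied: heteroscedasticity
across the two-decade range is handled instead by restricting the fit used for
detection limits to the low concentration range (≤ 5 fmol/µL by default),
where the noise is closest to homoscedastic. Replicate ratios enter as
individual observations rather than level means — this preserves degrees of
freedom for the intercept SD that drives the limits. The blank (0 fmol/µL) is
a calibration point whenever its ratio is measurable. R² is reported to three
decimals in reports; internal values keep full precision.

The interpolation-uncertainty formula uses the standard denominator
Σ(xᵢ − x̄)² (Sxx). One widely circulated rendering of this formula contains a
typographical variant of that sum; the standard form is implemented.

### Matrix-effect test

Residual variances of the matrix-matched and buffer curves are first screened
with a one-tail Fisher–Snedecor F-test (larger/smaller variance, α = 0.01,
(n₁−2, n₂−2) df). Only if not significantly different are they pooled,
weighted by degrees of freedom, for the slope t-test:

    t = |b₁ − b₂| / sqrt(s²_pooled (1/Sxx₁ + 1/Sxx₂)),  df = n₁ + n₂ − 4.

When the variances are not poolable the t-branch is reported *not applicable*;
no Welch-style fallback is applied silently, because the pooled test is the
documented protocol. The df convention for the pooled slope comparison is the
standard n₁+n₂−4; other conventions exist but are not printed in validation
protocols, so the standard one is used and stated here.

### Detection limits

LOD = 3·SD/b, LOQ = 10·SD/b (so LOQ/LOD ≡ 10/3 exactly for the same SD
estimate), with three SD estimators: SD of the intercept (default, the
reporting basis), residual SD of the regression (systematically the most
conservative), and the signal SD over ≥ 5 replicates at the lowest detected
point. Comparisons of signals with LOD/LOQ are inclusive (≥). Negative
interpolated concentrations are floored at zero and flagged — blanks scatter
around zero and a negative concentration is "not detected", not a value.

## Reporting unit and conversion factors

Peptide content converts to total allergenic food protein as

    x₀_TAFP [µg/g] = x₀_peptide [fmol/µL] · (cMM/cCF) · 10⁻⁵ · 1.33

where 10⁻⁵ folds the 1:10 matrix-to-solvent extraction ratio with SI-prefix
conversion and 1.33 is the digestion dilution factor. cMM and cCF are
*centered* estimates: midpoint of the min–max range over protein
isoforms/variants (cMM) or over independent discovery replicates (cCF), with
standard uncertainty = half-range/√3 (rectangular distribution). The midpoint
rather than the plain mean is the formula-level definition tied to the
half-range uncertainty; the arithmetic mean is also carried in
`CenteredEstimate.mean` for transparency. A single-basis centered estimate
gets u = 0 and a warning — it conveys no variability information.

Replicate CFs sum the intensities of **all accessions carrying the marker
peptide** (each gated on ≥ 1 unique peptide) before dividing by the total
intensity of all identified proteins. Replicates with no marker accession
passing the gate are excluded with a warning rather than counted as CF = 0.
Molar masses are supplied as explicit lists in the panel configuration; no
live database lookup is performed.

### Default panel values

The shipped default panel carries the experimentally established conversion
factors for milk caseinate (0.374 ± 0.009), milk whey (0.193 ± 0.002), egg
white (0.468 ± 0.003) and peanut (0.695 ± 0.006). For egg yolk, soybean,
hazelnut and almond no published experimental CF is available to this package;
the defaults (0.30, 0.30, 0.50, 0.65) are **synthetic placeholders** at
literature-plausible magnitudes, as are the molar masses other than milk's.
Users validating a real method must supply their own panel. The packaged
per-gram method limits (`data/method_limits.csv`) are shipped verbatim as
inputs for the compliance computation and are not recomputed.

## Uncertainty budget

Five contributors, combined in quadrature on the relative scale and scaled by
x₀ (first-order propagation), then expanded with k = 2 (~95% confidence):

| term | meaning | form |
|------|---------|------|
| u_PR | method precision | SD of repeated determinations / √3 |
| u_SS | stock concentration | manufacturer's relative precision (default 30%) / √3 |
| u_RL | regression | (S_y/x/b)·√(1/p + 1/n + (ȳ₀−ȳ)²/(b²·Sxx)) |
| u_MM | molar mass | half-range/√3 over isoforms |
| u_CF | conversion factor | half-range/√3 over replicates |

u_SS enters as a pure relative term: the stock concentration itself cancels in
the ratio formation, so only its relative precision propagates. u_PR is
computed on the peptide-concentration scale (fmol/µL), pooling all replicate
determinations that passed the ANOVA poolability gate — the conversion to TAFP
units is linear, so the relative budget is identical on either scale. Budgets
are refused for x₀ ≤ 0 (below LOQ there is nothing to attach an uncertainty
to). The rectangular (/√3) treatment of precision and stock terms is a
deliberately conservative Type-B-style assumption. Reports render
"value ± U (k=2)" with U at two significant figures.

A Monte-Carlo propagation oracle (rectangular draws for PR/SS/MM/CF, Gaussian
for RL, 10⁶ samples) agrees with the first-order combination to within 2%
relative at realistic budget magnitudes; exact agreement is not expected
because the combination is first-order in the relative terms.

## Precision and variance components

Variance decomposition is **method of moments via expected mean squares**, not
REML: the validation designs are balanced, the estimators are closed-form and
reproducible without an optimizer, and negative component estimates are
truncated to zero before weights are formed (standard practice). Repeatability
(one day, b bio × t tech): σ²_IA = MS_within, σ²_SP = (MS_between − MS_within)/t.
Intermediate precision (d days crossed with a analysts, n samples nested per
cell, technical replicates averaged first): MS_day estimates σ²_SP + a·n·σ²_DA,
MS_analyst estimates σ²_SP + d·n·σ²_A, residual estimates σ²_SP. Single-analyst
designs report the analyst component "nt" (not tested). Unbalanced layouts are
truncated to the largest balanced subset with a warning. The exact three-factor
layout conventions differ between laboratories; the nested/crossed convention
implemented here is documented, not asserted as universal.

Note on interpreting per-seed weights: with few biological replicates the
between-sample mean square has very few degrees of freedom, so per-dataset
weight ratios are skewed even though the variance components themselves are
unbiased. Parameter-recovery tests therefore average components across
simulations before forming weights.

Stability over days is a family of two-sample t-tests of day 0 against each
later day at α = 0.05 per comparison; recovery is 100 × (spiked-before
content)/(spiked-after content) on the quantitative marker, both quantified
against the matrix-matched curve.

## Decision rules

Detection requires ≥ 2 transitions of ≥ 2 peptides of the allergen at or above
the marker-specific LOD; whether the quantitative marker's own transitions
count toward the two-peptide requirement is ambiguous in common protocol
wording — here **any** two configured peptides qualify, including the QTM.
Allergens configured with a single peptide degrade the rule and require an
explicit override. Quantification requires the QTM at or above its LOQ;
averaging ȳ₀ across replicate groups (days/analysts) is gated on the one-way
ANOVA poolability check and can only be forced explicitly (the result is then
flagged). The egg-white compliance exception — reference doses refer to
egg-white protein, of which ovalbumin is taken as 54% — is a per-entry
`compliance_cf` applied only when converting method limits for compliance,
never in sample quantification.

## Compliance reporting

Per-portion limits are per-gram limits × portion (25 g default for a chocolate
bar), in mg, rendered to one significant figure. The per-portion basis
defaults to the **LOD**: the published per-portion column is numerically
consistent with the per-gram detection limits × 25 g even though it is
labelled as an LOQ; the output here is called "per-portion limit" with the
basis explicit, and LOQ can be selected instead. Reference-dose schemes with
no issued value ("nd") produce no verdict.

## Synthetic-data generator

The generator emulates the validation study's designs: 10-point calibration
(0, 0.5, 1, 1.5, 2, 3, 5, 10, 25, 50 fmol/µL; heavy at 25 fmol/µL; 3 technical
replicates), incurred samples at 2/4/10/40 µg_TAFP/g with biological ×
technical × day × analyst structure, six-replicate discovery intensity tables,
and spiked-before/after recovery pairs.

Structural choices:

- **Noise on ratios, not areas.** Heavy areas fluctuate around a constant and
  light areas are derived from the noisy ratio, so internal-standard
  normalisation is built into the data rather than merely assumed.
- **Mixed noise model.** Biological/day/analyst effects are multiplicative
  log-normal (ratio × exp(ε_SP + ε_DA + ε_A)); instrumental noise is additive
  Gaussian with an absolute floor (ratio + ε_IA). This reproduces the
  qualitative pattern of real validation data — sample preparation dominates
  the variance at high content, the instrument near the lowest detected point.
  No distributional form is published for the real noise; this model is a
  documented stand-in, and passing parameter-recovery tests shows the
  *estimators* are sound under it, not that real data follow it.
- **Calibration noise** has SD √((rel·µ)² + abs²) with defaults rel = 5%,
  abs = 0.002 ratio units; ratios are clipped at zero (areas cannot be
  negative), which censors blank-level noise — analyses that rely on exact
  Gaussian theory at the blank should use a positive baseline.
- **Matrix attenuation.** The generating slope is the matrix-matched slope;
  buffer (standard) curves divide it by the attenuation factor (default 0.85,
  i.e. the matrix suppresses response), so matrix-effect detection can be
  exercised with a known separation. Setting the factor to 1 produces
  statistically identical curves for type-I-error studies.
- **Generating slopes** default to the published sensitivities of the eight
  quantitative markers (0.0212–0.0597 ratio/(fmol/µL)); qualitative markers
  respond at 0.8× their paired QTM. These published values are *realism
  anchors* for defaults and packaged inputs only — the study's measured
  slopes, limits, CVs and recoveries cannot be recomputed here because the raw
  instrument data are not distributed.
- **Seeding.** One global seed fans out to per-dataset substreams keyed by a
  stable CRC-32 hash of the dataset label: datasets are individually
  reproducible and mutually independent.

What the generator does **not** emulate: chromatographic interferences,
retention-time drift, digestion kinetics, matrix-dependent recovery per
peptide, inter-laboratory effects, and natural variability of ingredient
protein profiles (the CF uncertainty covers only analytical variability).

## Problem sizes used in the tests

Monte-Carlo test sizes were chosen for stable statistics: 200 random instances
for the OLS oracle, 20 budgets × 10⁶ draws for the propagation oracle, 2000
seeds for type-I-error calibration (binomial SE ≈ 0.5 points at α = 5%),
400–500 seeds for parameter recovery. The end-to-end noiseless identity is
exact to ~1e-14 relative and asserted at 1e-9.

## Known limitations

- Unweighted OLS under-uses the low range when fitted over two decades; the
  low-range restriction mitigates but does not remove this.
- The EMS decomposition assumes balanced designs; unbalanced data are
  truncated, not modelled (no REML).
- First-order uncertainty combination; no second-order or Bayesian treatment.
- The detection rule treats transitions as independent evidence; correlated
  interferences across transitions are not modelled.
- Default panel cMM/cCF values for four of the eight entries are synthetic
  placeholders (see above) — shipped for pipeline completeness, not as
  reference values.
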