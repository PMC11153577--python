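# Methods

This note records the models, assumptions and numerical choices behind
each stage, in the order data flow through the pipeline.

## Respirometry

**Signal model.** The optode reports % air saturation at `sampling_hz`
(default 1 Hz; instrument rates are not standardized, so this is
configurable). A two-point calibration (0% via sodium sulfite, 100% via
vigorous aeration) maps raw signal linearly to saturation; readings
outside the anchors are extrapolated, not clipped, so noise around the
anchors stays unbiased, and negative values are flagged.

**Cycle schedule.** 15-min flush + 5-min sealed measurement per 20-min
cycle. Windows are contiguous runs of the `measure` phase label; a
20-h occupancy gives 60 windows, 21 h gives 63. The first `trim_s`
seconds of each window (default 30 s) are discarded as a mixing
transient before the OLS slope fit — the trim length is a judgment
call; it removes the flush-to-seal transition without costing
meaningful degrees of freedom at 1 Hz.

**Units and conversion.** Slopes in %sat s⁻¹ are converted to
mg O2 L⁻¹ h⁻¹ through the García–Gordon (Benson–Krause refit) oxygen
solubility at the trial temperature and salinity (mL/L coefficient set
× 1.42905 mg/mL, which avoids needing a density equation; the µmol/kg
coefficient set with a nominal density agrees to 0.02%). Barometric
pressure is taken as 1 atm (not recorded). Declining saturation gives
negative slopes; consumption is reported positive.

**Background correction.** Microbial respiration is measured for 1 h
before and after occupancy; the background slope is interpolated
linearly in time across the session. With a single background segment
the model is constant (warning); with none it is zero (warning). The
MO2 formula subtracts the full-chamber background term from the
effective-volume fish term, i.e. both are treated as concentration
rates — the standard correction, and the reading under which a
fish-free chamber yields MO2 ≈ 0.

**SMR.** Lowest 10% of the per-fish MO2 values by the ceil rule (6 of
60), sample SD (n−1), single-pass removal of values > 2 SD *below* the
decile mean (spuriously low slopes: leaks, flush carryover), mean of
the survivors. The filter is deliberately one-shot — no re-iteration —
so the estimate is a deterministic function of the order statistics.
An r² gate on window fits is available but off by default.

## Carbonate chemistry

Input pair is (pH_TS, TA): with [H⁺] fixed by the pH, every
non-carbonate alkalinity term is known, so carbonate alkalinity and DIC
follow in closed form — no iteration. Speciation then gives CO2*,
pCO2 = [CO2*]/K0 (partial pressure; the fugacity correction, ~0.3%
here, is omitted), and Ω = [Ca²⁺][CO3²⁻]/Ksp.

Constants: K0 Weiss 1974; K1/K2 Lueker et al. 2000 (the Mehrbach refit
formulated directly on the total scale, the scale the pH data are on);
KB Dickson 1990 with Uppström boron; KW Millero 1995 converted from the
seawater scale; KS Dickson 1990, KF Dickson & Riley 1979 for the scale
conversions; Ksp Mucci 1983; Ca²⁺ proportional to salinity. Nutrient
alkalinity is zero (phosphate/silicate unmeasured) and pressure is
surface. The original workstation's constants set is unknown, so
agreement with the published ambient pCO2 is expected at the
constants-set level (±5–10%); the solver computes 392 µatm against the
printed 404.

Validation is three-way: (i) TA reconstructed from the solved
speciation closes to < 0.01 µmol kg⁻¹; (ii) an independently coded
route (root-finding DIC on a hand-written alkalinity expression, and
recomputing pH from (DIC, TA) by Brent bisection) agrees to < 0.5% in
pCO2 over pH 7.4–8.2, TA 2000–2400, T 5–20, S 20–35; (iii) pCO2 is
strictly decreasing and Ω strictly increasing in pH.

A caution on averaging: pCO2 and Ω are convex in pH, so the solver
output at *mean* inputs is not the mean of per-sample outputs. For the
acidified treatments (pH SD 0.30) the difference is large — at the mean
inputs Ω_aragonite is ≈ 0.97 while the per-sample expectation is ≈ 1.2
(supersaturated). Treatment-level statements should therefore be made
on per-sample solutions, which is how the pipeline's chem stage
operates; tests of the "all treatments supersaturated" property use the
per-sample expectation for the acidified groups.

The Table-4-style comparison statistics operate on summary statistics
alone: the variance-ratio F (larger variance in the numerator,
two-sided p) and the pooled-variance two-sample t (df = n1+n2−2).

## Assays

Kinetic wells are fit by OLS over the first 3 min (configurable), with
an r² ≥ 0.98 linearity flag; the blank rate is subtracted and the sign
folded by assay direction (GST accumulates product at 340 nm; GR
consumes DTNB at 405 nm). Specific activity is
rate/(ε·path) × (reaction/sample volume) ÷ protein. The microplate
optical path depends on fill volume and is **not** standardized —
default 1.0 cm, and all activities scale inversely with it. Reaction
and sample volumes default to 200/20 µL. Protein is Lowry with linear
BSA-curve inversion; glutathione is standard-curve inversion ×
dilution (80 for total GSH, 1 for GSSG after vinylpyridine
derivatization), %GSSG = GSSG/GSH × 100. GSH is reported as assayed;
an optional mode expresses it as tGSH − 2·GSSG in GSH equivalents.
Tissue normalization assumes the 1 g + 4 mL (w/v) homogenization, a
factor-5 tissue-to-homogenate dilution.

## Cohort statistics

**Split rule.** For one treatment's values: median, SEM = SD(n−1)/√n of
*all* values (the rule runs before any grouping exists, so subgroup
SEMs are undefined); two distinct groups are declared when the nearest
observation above and the nearest below the median each lie ≥ 1 SEM
from it; A = below median, B = above. The stricter reading (two
observations per side) additionally requires two points on each side
and is available behind a flag. With odd n a data point sits exactly at
the median, distance zero — there is then no clean gap at the median
and no unambiguous assignment for that fish, so the rule reports no
split (logged). Consequence: after odd-numbered mortality a treatment
cannot split; the even-sized treatments are where the rule is
informative. The rule is exactly affine-equivariant. Calibration at
n = 16: halves separated by six within-mode SDs are detected in ≥ 95%
of replicates; unimodal normal data false-split in ~3%.

**Treatment tests.** Shapiro–Wilk (per group) and Levene gates at
α = 0.05; transform ladder sqrt → log → log10(x+1), first pass wins;
ANOVA with Tukey–Kramer unequal-n HSD (or Fisher LSD) on success,
otherwise Kruskal–Wallis with Bonferroni-adjusted Dunn comparisons.
Tank effects are checked with a nested ANOVA
(value ~ treatment + tank(treatment), tanks recoded within treatment so
the nested term carries k·(m−1) df), flagged at p < 0.05.

**Ecotype association.** Heightened (B) and reduced (A) classes pooled
across the split treatments, cross-tabulated against ecotype, tested
with the Yates-corrected χ² (correction clamped at |O−E|, df = 1). Fish
with unknown ecotype are excluded; the test requires ecotype known for
≥ 80% of split fish. At n ≈ 31 the correction makes the test
conservative: null rejection runs below the nominal 5%.

## Synthetic-data generator

Defaults are the experimental design: 5 treatments × 4 tanks × 5 fish;
biometrics N(159.4 g, 72.6) and N(24.3 cm, 3.5); per-treatment death
probabilities {0, 0.2, 0.1, 0.1, 0.1} (the observed deaths out of 20);
water presets equal to the per-treatment measured means/SDs. SMR is
baseline 60 mg O2 kg⁻¹ h⁻¹ (a representative juvenile-cod value near
13 °C) plus small treatment shifts (−4 freshening … +6 multi-stressor,
mirroring the observed ordering without forcing treatment-level
significance) plus, in the freshening and multi-stressor treatments, a
±15 bimodal offset tied to ecotype at 90% concordance (offshore →
heightened), plus N(0, 4) individual variation. Optode noise defaults
to 0.1 %sat per sample, typical of modern optode systems. Background
respiration defaults to a constant −0.2 %sat h⁻¹, optionally drifting
linearly to exercise the interpolation. Flush phases relax
exponentially to 100% with a 60-s time constant (cosmetic — only sealed
windows are analyzed). Growth over the exposure is generated directly
as endpoint multipliers per treatment and response class (reduced-SMR
fish grow more, as observed), not via a bioenergetic model. Circadian
MO2 variation is not modeled by default; an activity-spike mixture is
available for stress-testing the lowest-decile estimator.

What passing tests on this generator do *not* show: robustness to
autocorrelated optode drift, temperature transients inside sessions,
non-Gaussian biometrics, or tank-level pseudo-replication beyond the
modeled structure — real traces violate iid-noise assumptions in ways
the generator deliberately keeps simple. Ecotype class counts are
binomial draws, so whether a particular bimodal cohort actually splits
at the median depends on the realized balance, exactly as in a real
collection of wild-caught fish.

## Problem sizes in the test suite

The suite runs the full 20-h, 1-Hz respirometry forward model for the
100-fish recovery check, 500-replicate simulations for the split-rule
power/size and association-null checks, and 200 replicates for the
nested-ANOVA type-I check; the bundled demo shortens sessions to 4 h at
0.2 Hz, which leaves per-window slope fits overdetermined while keeping
the run interactive.

## Known limitations

- The carbonate solver targets the (pH, TA) input pair only; no
  titration processing, no (DIC, pCO2) input modes beyond the round-trip
  pH solver used in validation.
- Eq-level ambiguity in the MO2 background term is resolved as rate
  subtraction (see above); alternative readings (e.g. Δt as a divisor
  applied once) would change nothing at fixed window length.
- The split rule is a deterministic gap heuristic, not a mixture test;
  its null behavior is controlled empirically, not analytically.
- Assay volumetrics (path length, reaction volumes) default to common
  microplate practice and must be set to the actual protocol values for
  absolute activities to be comparable across laboratories.
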