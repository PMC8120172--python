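# Methods

## Calling model

A subject's plasma result is derived from three qPCR replicates, each
reporting Ct values for the ACTB control and the two methylation targets.
The inequalities are read strictly: validity fails only when the aggregated
ACTB Ct is *greater than* 35.0 (Ct exactly 35.0 is valid), and a replicate
detects a marker only when its Ct is *strictly below* the marker threshold
(45.0 cycles for mSEPT9, 50.0 for mSDC2). Because the mSDC2 threshold
coincides with the 50-cycle run ceiling, an mSDC2 Ct recorded exactly at 50
and an undetected well are equivalent by construction.

How ACTB should be aggregated across the three replicates is not uniquely
determined by the assay description, so it is a policy knob on
`CallingThresholds`:

* `mean` (default) — mean Ct of the amplified replicates; all-undetected
  is invalid;
* `max` — the worst amplified replicate must pass;
* `per_replicate` — every replicate must amplify at or below threshold.

Marker positivity is a k-of-n count rule (1-of-3 for mSEPT9, 2-of-3 for
mSDC2; both k and the thresholds are configurable, so the 1/3-vs-2/3
trade-off can be swept as a configuration). The combined test is the
logical OR of the marker calls. Plasma methylation level is the mean
replicate Ct after substituting 50 for undetected wells; the same
set-to-ceiling substitution is applied to an undetected leukocyte target
before forming ΔCt = Ct(target) − Ct(ACTB). A leukocyte reaction whose
ACTB fails is flagged uninformative rather than assigned a level. Invalid
plasma samples carry no positivity or level fields and are excluded from
every downstream denominator.

## Diagnostic evaluation

Sensitivity and specificity are binomial proportions over valid cases and
controls. Interval method: Wilson score by default (well-behaved at the
small control n of 38), Clopper-Pearson selectable. Percentages are rounded
to one decimal, half away from zero, at the reporting layer only.

ROC curves use plasma mean Ct as the score with the lower-is-disease
orientation. The AUC is the tie-corrected rank statistic — equal to the
trapezoidal area under the empirical curve and to Mann-Whitney
U/(n₁n₂), a duality the test suite checks on random instances. The AUC
confidence interval uses DeLong's structural-component variance; a seeded
bootstrap is available as an alternative. The combined-test score is the
*minimum* of the two mean Cts, i.e. the strongest single-marker
methylation evidence, chosen to mirror the OR structure of the calling
rule; an average-Ct variant is selectable. AUC comparisons between the
combined score and single markers should therefore be read as descriptive.

Group comparisons follow the study design's toolkit: Mann-Whitney U for
methylation levels (exact enumeration when n₁·n₂ ≤ 400 and the pooled
sample is tie-free, otherwise the tie-corrected normal approximation
without continuity correction), Pearson chi-square for rates across more
than two groups, and the pooled-variance t-test (Welch selectable) for
two-group means. No multiple-testing correction is applied; all p-values
are raw, matching how such validation studies are conventionally reported.

The stratified sensitivity table uses the conventional strata: gender, age
decades (<40, 40-49, …, ≥80), T stage (Tis-T4), N stage (N0-N2), tumor
site, size ≤4 vs >4 cm, and differentiation, each with an explicit N/A
stratum. N/A rows are displayed but excluded from the per-stratifier
chi-square by default (inclusion is a flag), since published tables print
heterogeneity p-values alongside N/A rows without stating their treatment.
When a marker's negative (or positive) margin is zero across strata the
observed table equals its expectation exactly, so the statistic is 0 and
p = 1 rather than an error.

`pool_strata` reconstructs an overall percentage from published
per-stratum (n, percent) rows by recovering each stratum's positive count
as the nearest integer to n·percent/100. The consistency bound is
deliberately lenient (half a count plus tolerance): published one-decimal
percentages are occasionally off by a unit in the last digit, and the
device's purpose is to recover the underlying integers, not to certify the
rounding.

## Synthetic cohort generator

The generator emulates the case-control structure the analysis assumes; it
is a statistical emulation, not a mechanistic cfDNA model.

* **Composition.** Defaults: 91 CRC (stages 0/I/II/III/IV/unknown =
  4/9/31/29/4/14), 49 adenoma, 27 hyperplastic polyp, 8 other
  gastrointestinal tumors, 38 controls. Demographics are truncated normals
  with group-specific (for CRC, stage-specific) means, SDs and min-max
  clipping; CRC tumor descriptors (T/N stage, site, size category,
  differentiation) follow fixed marginal compositions scaled to the group
  size and assigned independently across stratifiers.
* **Plasma signal.** Each replicate detects a marker independently with a
  group-specific probability p; detected replicates draw Ct from a normal
  truncated to (20, threshold). The default p values are calibrated once,
  by bisection of the binomial k-of-n link P(Bin(3, p) ≥ k), to published
  sample-level positivity rates: CRC 75.8% (mSEPT9) / 60.4% (mSDC2),
  controls 5.3% / 13.2%, and per-marker splits for adenoma, hyperplastic
  polyp and other tumors chosen so the independent OR matches the
  published combined rates (24.5%, 22.2%, 25.0%). Default detected-Ct
  means are 38/40 cycles (mSEPT9/mSDC2) in CRC and 42/45 elsewhere, with
  per-stage shifts (+3 at stage 0 down to −2.5 at stage IV) so later-stage
  plasma shows lower mean Ct, qualitatively matching the stage trend such
  assays report. Replicates are conditionally independent given the
  subject; an optional per-group shedder fraction provides a
  positive/negative mixture in which non-shedders can never be detected.
  Under independence the combined sensitivity in CRC lands near 90%,
  slightly above the published 85.7% — real markers are positively
  correlated through tumor DNA shedding, and the shedder mixture is the
  hook for modeling that.
* **Leukocyte background.** ΔCt per marker is drawn from one normal per
  marker — mSEPT9 N(12, 1.5), mSDC2 N(5, 1.5), reflecting the much higher
  leukocyte mSDC2 background — *identically in every group*. The
  generator's null is that leukocyte methylation carries no disease
  signal; the acceptance suite verifies that CRC-vs-control Mann-Whitney
  p-values on leukocyte ΔCt are KS-uniform across 500 seeded cohorts.
* **ACTB.** Plasma ACTB is a truncated normal with mean 28 (SD 1.5) on
  (20, 35); leukocyte ACTB mean 22 (SD 1), since genomic DNA input is
  orders of magnitude larger. `invalid_sample_prob` (default 0: enrollment
  already excludes insufficient-DNA samples) makes a whole plasma sample's
  ACTB undetected.
* **Randomness.** One integer seed feeds a `SeedSequence` that spawns
  three child streams (demographics, plasma, leukocyte), so a given
  config + seed yields byte-identical cohort CSVs independent of call
  order.

What passing tests on simulated cohorts do *not* show: the generator has
no replicate correlation (no published concordance data exists to fit
one), no batch or extraction effects, no bisulfite-conversion error, and
Ct distributions are convenient truncated normals rather than fits to raw
fluorescence data. Results on real cohorts can differ accordingly;
the fixture-based worked examples, whose integer counts force the printed
percentages, are the part that transfers exactly.

## Problem sizes and numerical choices

The acceptance and property suites run at deliberately chosen sizes:
parameter recovery at 2,000 cases per rule against a 99% binomial band;
null-fidelity at the study's own 91-vs-38 contrast over 500 seeded
replications; AUC properties on 200 random instances. Bisection for the
binomial inverse runs to interval width 1e-15 (round-trip accurate to
1e-9, with exact endpoints short-circuited to avoid floating-point
saturation of the binomial tail near p = 1). Report JSON serializes floats
rounded to 6 decimals with sorted keys so end-to-end runs are
byte-reproducible.

## Known limitations

* The combined-test ROC score construction (minimum mean Ct) is a design
  choice; published combined AUCs built some unstated composite, so
  combined-AUC values are not directly comparable beyond direction.
* DeLong intervals are large-sample; at 38 controls they can overcover
  near AUC 1 (the bootstrap option is the cross-check).
* Exact published AUCs and p-values are not reproducible without the raw
  Ct data, which is not deposited; the package reproduces the printed
  count-based percentages exactly and the distributional findings
  qualitatively.
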