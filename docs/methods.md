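# Methods

This package analyzes longitudinal DNA-methylation data from small,
intensively sampled cohorts: a handful of subjects, each profiled at a
handful of sampling days, alongside per-subject phenotype time series.
Its design target is the six-subjects × six-timepoints setting of a
long-confinement study, where per-individual dynamics matter at least as
much as population averages. The sections below document the models,
parameter choices, numerical conventions, and what the synthetic cohorts
do and do not establish.

## Data model

A **beta value** β ∈ [0,1] is the methylation fraction at one CpG probe in
one sample. The central container pairs a probes × samples beta matrix
with a sample design table (subject, sampling day, technical-replicate
flag). Probe metadata follows the 450k-manifest conventions: probe type
(cg/ch/rs), chromosome, 0–3 gene symbols with one gene-model feature group
each (TSS200, TSS1500, 5'UTR, 1stExon, Body, 3'UTR; intergenic probes are
IGR and carry no genes), a CpG-island relation (Island/Shore/Shelf/
OpenSea), SNP and multi-alignment flags, and the fraction of samples with
bead-count failure. The package consumes already-normalized matrices;
raw-intensity processing, normalization, and batch correction are out of
scope.

## Probe filtering

Four removal rules, applied in a fixed order with each probe counted at
the first rule it matches: bead-count failure in ≥5% of samples
(implemented as `beadfail_frac ≥ 0.05`; whether the boundary is strict is
a convention, and the inclusive reading is used), non-cg probe type,
SNP-overlapping probes, and multi-mapping probes. X/Y probes are kept — 
appropriate for a single-sex cohort. Filtering is idempotent and reports
per-rule counts.

## Variability metrics

Technical noise is summarized by **error(β)** = |β₁ − β₂| between one pair
of replicate hybridizations, reported as type-7 (linear-interpolation)
quantiles plus the fraction of probes under a threshold (default 0.008).
Biological drift is summarized per probe per subject by **sd_personal(β)**
(sample SD, n−1 divisor, across that subject's sampling days) and
**range_personal(β)** (max − min). Summary fractions use thresholds 0.012
(sd) and 0.016 (range). A probe with a missing value anywhere in a
subject's series is excluded from that subject's metrics; probes with any
missing values must be dropped before the downstream testing stages (six
observations per subject leave no room for imputation).

## Longitudinal tests

Both tests operate on a complete subjects × timepoints grid.

**Repeated-measures ANOVA.** One within-subject factor (time), subject as
a blocking factor: F = MS_time / MS_error on (t−1, (n−1)(t−1)) df, no
sphericity correction by default (Greenhouse–Geisser available). A grid
with numerically zero error sum of squares cannot support an F ratio and
returns p = 1, logged — this includes the perfectly-consistent-time-effect
boundary case, which is treated conservatively rather than as p = 0.

**Rank-based ANOVA-type statistic (ATS).** All N = n·t observations are
mid-ranked jointly (ties take the average of the spanned ranks); each
subject's rank profile is scaled to Yᵢ = Rᵢ/N; with p̂ the mean profile
(the relative treatment effects), T = I − J/t, and V̂ the sample covariance
of the Yᵢ (n−1 divisor):

    Q = n · p̂ᵀT p̂ / tr(TV̂),   f̂ = tr(TV̂)² / tr(TV̂TV̂),
    p = P(F(f̂, ∞) > Q) = P(χ²_f̂ > f̂·Q).

If tr(TV̂) is numerically zero (all subjects' rank profiles identical and
flat), p = 1. The statistic is invariant to strictly monotone transforms
of the data, exactly.

*Known limitation.* The Box-type χ² approximation with estimated f̂ is an
asymptotic device. At n = 6 its α = 0.05 tail is well calibrated (empirical
type-I error 0.04–0.06 in the suite's null simulations) but the p-value
distribution under H0 is visibly non-uniform in the mid-range
(Kolmogorov–Smirnov D ≈ 0.12 against U(0,1) at n = t = 6, shrinking to
≈ 0.03 by n = 40), and mid-range p-values can differ from a within-subject
permutation reference by more than 0.1. Decisions made at α = 0.05, and
BH-FDR built on small p-values, are trustworthy; the raw mid-range
p-values should not be over-interpreted at this sample size. A
finite-denominator-df variant F(f̂, f̂₀) was evaluated and does not improve
mid-range calibration here.

**Multiple testing.** Benjamini–Hochberg step-up (via statsmodels), the
field default where only "FDR" is specified.

## DMP calling

A probe is a differentially methylated probe (DMP) when
(i) sd_personal(β) > 0.02 in **every** subject (the stringency filter is
applied first), (ii) RM-ANOVA q < 0.05, and (iii) ATS q < 0.05, with each
test's BH-FDR computed within the sd-filtered tested set — matching the
filter-then-test sequence. The conjunction of a parametric and a
rank-based test protects the call set against both outliers and
distributional artifacts at n = 6.

## Location and gene-set enrichment

For a probe set against a universe: observed category count, expected
count = |set| × category frequency in the universe, log2(obs/exp) (with a
+0.5 pseudo-count on both terms only when observed = 0), and one-sided
hypergeometric tail p-values in each direction (both tails include the
observed point mass, so p_enrich + p_deplete ≥ 1). CGI-relation enrichment
is strictly per-probe (north/south Shore/Shelf variants are collapsed; the
mapping is configurable). Gene-feature enrichment counts (probe, feature)
pairs because a multi-gene probe legitimately occupies several feature
groups; the hypergeometric is then over pairs, a documented approximation.
The same machinery applies to user-supplied GMT gene sets (with BH
correction across sets) in place of external annotation-database queries,
which are out of scope.

## The PeSa screen

PeSa (personalized epigenetic–phenotype synchronization analysis) asks,
per subject, whether a probe's beta trajectory tracks a phenotype
trajectory. For time courses A = (a₁…aᵢ) and B = (b₁…bᵢ) over the shared
sampling days:

1. p_corr from Pearson correlation(A, B);
2. slope series A* = (a₂−a₁, …, aᵢ−aᵢ₋₁), B* likewise;
3. p_slope from Pearson correlation(A*, B*);
4. synchronized ⇔ p_corr < α **and** p_slope < α (α = 0.05).

Pearson p-values are two-sided from t = ρ√((i−2)/(1−ρ²)) on i−2 df; |ρ|=1
gives p = 0. A constant vector has no defined correlation and yields
p = 1 — deliberately conservative: an exactly linear probe trajectory has
a constant slope series and therefore cannot pass on the strength of a
0/0 slope correlation. Synchronization is sign-agnostic (anti-phase
coupling passes; the direction is reported via ρ). No multiple-testing
correction is applied inside the screen — the operating characteristic is
instead documented by the null property that the dual-criterion pass rate
for an independent phenotype lies between α² and α (the two criteria are
positively correlated; ≈1–4% empirically at six timepoints).

Candidates are restricted per subject to probes whose biological variation
exceeds the technical yardstick, sd_personal(β) > 0.01. Methylation and
phenotype series are aligned by exact sampling-day intersection (phenotype
tables may carry more days than the methylome; only shared days are used,
and ≥4 are required so the slope correlation has ≥3 points).

Cross-subject aggregation maps passing probes to gene symbols (IGR probes
contribute nothing), collects the distinct subjects per gene, and sorts by
that consistency count, flagging genes found in every scanned subject.
Probe ranking for downstream enrichment is by |ρ_corr| descending (ties:
p_corr, then probe id), with a signed option.

## Phenotype handling

**TMD.** Total Mood Disturbance from the six POMS subscales:
TMD = TA + DD + AH + FI + CB − VA, on raw subscale scores with no
normative offset (an additive constant would change no test or
correlation).

**Indicator screen.** Each indicator's complete subject × day grid gets
both longitudinal tests; an indicator is significantly changed when both
raw p-values are < 0.05 (conjunctive rule; a disjunctive switch exists).
No FDR across indicators, matching the few-dozen-indicators setting.

## Synthetic cohorts

The generator emulates the study conditions end to end and records ground
truth for every planted effect.

* **Design**: 6 subjects × 6 methylation days spanning a ~520-day mission
  (default days −7, 60, 168, 250, 340, 418), one technical replicate pair;
  phenotypes optionally sampled at extra interleaved days (the indicator
  screen uses 10).
* **Baselines**: two-component beta mixture (defaults Beta(1.5, 8) and
  Beta(8, 1.5), equal weight), reproducing the bimodal beta-value
  distribution of methylation arrays.
* **Noise**: biological noise N(0, σ_bio²) per observation on the beta
  scale, default σ_bio = 0.015 — chosen so the null sd_personal
  distribution straddles the 0.012 reporting threshold the way the study
  describes (most probes' biological variation exceeds the technical
  yardstick). All values truncate to [0.001, 0.999]. Working on the beta
  scale keeps the error(β) and sd_personal quantiles directly
  controllable; the cost is mild truncation distortion near 0 and 1.
* **Technical noise**: σ_tech is the per-hybridization SD; the replicate
  column adds N(0, 2σ_tech²) so error(β) ~ |N(0, 2σ_tech²)|. The default
  calibrates the expected fraction of error(β) below 0.008 to 0.78,
  representing a study in which *more than* 75% of probes sit under that
  bound; σ = 0.008/(√2·Φ⁻¹(0.89)) ≈ 0.0046. An exact-quantile calibration
  (P75 = 0.008) is available.
* **Glucose**: a 3-stage stepwise rise — stage means 4.5, 5.2, 6.0 mmol/L
  with SDs 0.34, 0.37, 0.37 — drawn independently per subject per day;
  stage boundaries default to days 168 and 300 and are configurable, since
  the narrative fixes the plateau days but not a formula.
* **TMD**: per-subject baseline plus a Gaussian bump peaking late-mission
  (day 390, width 80) plus noise — a smooth stand-in for third-quarter
  mood disturbance.
* **Planted DMPs**: a mid-mission step of size `effect_dmp` (default 0.05)
  shared by all subjects. A step rather than a linear ramp is the
  package's own choice: the study's phenotypes move in stages, and a step
  of size e yields per-subject sd ≈ 0.548·e — detectable above the 0.02
  stringency cutoff at the default effect size, where a ramp of the same
  amplitude (sd ≈ 0.374·e) would sit below it and make the planted class
  invisible to its own caller.
* **Planted synchronized probes**: beta adds `effect_sync` × zᵢ(t), where
  zᵢ(t) is subject i's standardized target-phenotype trajectory at the
  methylation days, with a per-probe ±1 coupling sign (both directions
  occur; the screen is sign-agnostic). Planted fractions default to 1%
  DMP + 1% synchronized, split evenly over the phenotypes present. The
  magnitudes are chosen for testability — the study itself reports no
  simulation — with recovery checks run at effect/σ_bio = 10 and null
  checks at effect 0.
* Planted classes are assigned only among clean cg probes, so the filter
  stage never silently destroys planted signal; flagged probes are always
  null, and the truth table covers every probe exactly once. Category
  counts in the manifest follow configured proportions by deterministic
  largest-remainder rounding.

Everything is reproducible bit-identically from (config, seed): all
randomness flows from `numpy.random.default_rng` seeded by the config
seed plus fixed per-component salts.

**What the synthetic cohorts do not show.** No array chemistry, dye bias,
batch structure, cell-composition heterogeneity, probe-probe correlation,
or genomic autocorrelation of methylation; noise is homoscedastic on the
beta scale, whereas real beta-value variance shrinks near 0 and 1; planted
effects are uniform in location, so enrichment runs on synthetic data
demonstrate the bookkeeping, not biology. Passing recovery tests therefore
establishes the pipeline's correctness and calibration under its stated
model, not performance on real arrays.

## Problem sizes and numerical conventions

The analysis scripts and the reproduction script use 20,000-probe cohorts
(with 10,000 for null-calibration runs and 5,000 for high-SNR recovery
runs) — ample for stable fractions (SE of a 1% rate at 10k probes is
0.1%) while keeping any run in the seconds-to-minutes range. Quantiles are
type-7 throughout. Degenerate statistics (zero error SS, zero rank
covariance trace, constant correlation inputs) uniformly resolve to p = 1
and are logged. Tie-breaks in orderings are lexicographic on ids so all
outputs are deterministic. TSV floats are written at full repr precision
and read back with round-trip parsing, making write→read bit-exact.
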