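# Methods

This note records the models, conventions and design choices behind
`ladspectra`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and shape

The package is a library first: the importable API and the `examples/`
scripts are the primary interface, with a thin `ladspectra` CLI for users
who prefer running the pipeline stage by stage from a shell. All CLI
subcommands are wrappers over the same functions the tests exercise.

## Synthetic cohort model

The generator emulates the statistical signature of a two-class SELDI-TOF
serum study at desk scale; it is not an instrument model (no flight-time
physics, detector saturation or baseline drift, and no profile-mode
spectra — records are centroided peak lists).

* **Peak geography.** `background_peak_count` peak positions are drawn
  uniformly over `mz_range` once per cohort and shared by all patients,
  kept ≥ 4 Da from planted masses (separate 2-Da bins) and ≥ 12 Da from
  the internal standard (so the standard dominates its detection window).
  Each background peak gets a cohort-level median intensity from a
  log-normal (median 5, log-sd 1 by default), spanning the two-plus decades
  typical of serum profiles.
* **Patient variation.** A patient's latent intensity at each peak is the
  cohort median times an independent log-normal factor with log-scale
  standard deviation `noise_sd` (mean-corrected so the expected factor is
  1). Multiplicative patient noise is the natural choice for positive,
  right-skewed intensities; the distributional family is a modeling choice,
  not something the motivating data dictate. `noise_sd = 0` makes latent
  spectra deterministic, which is what makes the planted-effect recovery
  invariant exact.
* **Planted class structure.** Seven masses (by default at the m/z
  locations of a published discriminative panel — locations only; the
  intensities are synthetic) carry an additive intensity shift
  (`effect`, default 6 raw units on the scale where the standard averages
  ~29) in their enriched class. Five of seven are enriched in the slow
  class, echoing the observation that most discriminative peaks are higher
  in slow progressors. Additive-on-the-natural-scale effects keep
  class-mean differences exactly equal to the configured effect in the
  noise-free limit.
* **Internal standard.** Intensity drawn once per patient from a normal
  (28.96 ± 2.02 by default) truncated at zero; between-run noise applies to
  it like to any peak, so the *detected* per-run standard varies somewhat
  more than 2.02.
* **Replicates.** Both runs of a patient share the latent spectrum; each
  adds independent Gaussian noise with per-patient variance solved in
  closed form from the target between-run Pearson correlation `r`:
  across a patient's peaks, cor(run1, run2) = Var(latent)/(Var(latent)+τ²),
  so τ² = Var(latent)·(1−r)/r. Clipping intensities at zero censors the
  noise and biases the realized correlation slightly upward (about +0.03
  at the default r = 0.82); the calibration tests budget ±0.05 for this.
  `r = 0` would require infinite noise, so the accepted range is (0, 1].

Two presets freeze the study conditions used throughout the tests and the
acceptance script: `cv_scale_config` keeps the full 57/59 cohort but
restricts emission to [500, 902] Da (201 bins at 2 Da, ~60 background
peaks, standard relocated to 752.3 Da) so that full-pipeline
cross-validation runs in seconds; `planted_recovery_config` additionally
raises the planted effect to 8 raw units and lowers the noise
(`noise_sd = 0.15`, `r = 0.95`) — the strong-effect, low-noise regime in
which the 80%/80% degree-1 screen is expected to recover the planted panel.
At the default moderate-noise conditions the screen is deliberately
stringent and may retain nothing; the training pipeline then falls back to
all features with cutpoints (see below).

What passing tests on these cohorts do *not* show: real serum spectra have
correlated neighboring bins, baseline artifacts, batch effects and
peak-position jitter, none of which the generator emulates. Recovery of a
planted panel here validates the machinery, not the biology.

## Preprocessing

* **Binning.** Bin centers on the grid `low, low+width, …, high`
  (inclusive), each bin covering `[center − width/2, center + width/2)`;
  the feature count is `floor((high−low)/width)+1`, which reproduces the
  standard 5,751 features for [500, 12000] at 2 Da. The interval rule is
  stated explicitly because published feature counts alone do not pin it
  down. Multiple peaks in a bin are summed (preserving total ion intensity
  in range); peaks must arrive sorted — unsorted input raises instead of
  being reordered, to catch upstream corruption.
* **Normalization.** The standard is detected as the maximum-intensity bin
  within ±10 Da (configurable) of the nominal standard mass; every value is
  divided by that intensity. The detected mass feeds a QC check against
  the 0.06% relative-error tolerance conventional for SELDI mass accuracy.
* **Replicate aggregation.** Arithmetic mean of the normalized replicate
  vectors, with the between-run Pearson correlation computed *before*
  averaging and reported per patient in the QC block.

## Discretization

Essential cutpoints are midpoints between adjacent distinct sorted values
whose label sets are not both the same singleton; values observed in both
classes generate cutpoints on both sides. This is the standard
construction that preserves all pairwise class separability: any
opposite-class pair differing on a feature has a class change somewhere
between their values, hence a cutpoint between them. Only the `>= c`
direction is materialized (`< c` is its complement). Ties with a cutpoint
cannot occur on training data (cutpoints are midpoints of distinct
values); for new data the boundary rule `value >= c → 1` is fixed for
determinism. No per-feature cutpoint cap is applied — downstream
support-set selection prunes.

## Support-set selection

The universe is the set of (positive, negative) patient pairs, held as
integer bitmasks (57×59 = 3,363 bits per column is cheap). The production
solver is greedy set cover — pick the column distinguishing the most
uncovered pairs, ties to the lowest column index — followed by an
irredundancy prune in reverse selection order. An exhaustive solver
(subset enumeration in order of increasing size, guarded to ≤ 25 columns)
provides the minimum-cardinality oracle for tests; whether published
"smallest" support sets were exact or heuristic is generally unstated, so
both modes are exposed.

## Patterns

Prevalence and homogeneity are kept as exact integer counts alongside the
float ratios, so threshold comparisons never suffer rounding drift.
Enumeration is exhaustive over the literal space (default) — the
brute-force oracle equivalence in the tests depends on this — with an
opt-in dominance prune (drop a pattern whose cover is contained in a kept
same-sign pattern's cover with no better statistics) used by the pipeline's
candidate-generation stage, where only the selected model matters.

Thresholds are configuration. The degree-1 feature screen defaults to
80%/80% (prevalence/homogeneity), the convention for "high-quality"
single-feature patterns. The degree-2 candidate stage defaults to
homogeneity ≥ 0.75 and prevalence ≥ 0.3: final two-feature patterns in
this methodology typically cover only ~55–60% of their class while staying
~80% homogeneous, so the candidate stage must admit lower prevalence than
the screen. The screen's vectorized implementation (sorted-value searches
per cutpoint) is tested for exact agreement with the definitional route
through degree-1 enumeration.

## Model assembly and the discriminant

Candidates of each sign are assembled by greedy cover of the own-class
patients, tie chain: coverage gain, then homogeneity, then prevalence,
then lexicographic literal order; a reverse-order prune removes redundant
patterns; every training patient must end up covered by an own-sign
pattern (coverage completeness), and an uncoverable patient is a named
error. Two refinements, both package design choices:

* **Coverage completion.** Degree-≤2 candidates above fixed thresholds do
  not guarantee that every patient is coverable. Before model assembly the
  pipeline adds, for each uncovered own-class patient, the best-statistics
  literal combination (within the support literal space) that covers them.
  A covering combination always exists — the literal matching the
  patient's own side of any support column — so assembly is always
  feasible on splits containing both classes.
* **Cover multiplicity.** A plain minimum cover collapses to one pattern
  per sign on strongly separable data, making the discriminant three-valued
  (δ ∈ {−1, 0, 1}) with a wide unclassified band for out-of-sample
  patients. The pipeline therefore requests redundant coverage (each
  patient covered by up to 3 own-sign patterns where the pool allows,
  preferring patterns that introduce a new feature set), which yields the
  graded, multi-pattern discriminant this methodology is known for.
  `select_model(..., multiplicity=1)` remains the plain minimum cover.

δ is computed in exact rational arithmetic (`fractions.Fraction`); δ = 0
is surfaced as "unclassified", never silently coerced to a class. For
accuracy-type metrics the default policy counts unclassified patients as
misclassified (an "exclude" policy is available, and unclassified counts
are always reported separately) — published treatments rarely state this
choice, so it is explicit here.

Risk groups sort patients by (risk score, patient id) — the id breaks ties
so quantile boundaries are a total order — and split them into g contiguous
groups, remainder to the highest groups (116 patients in quintiles:
23/23/23/23/24). AUC is the Mann–Whitney probability with ties counted ½;
the CI defaults to the Hanley–McNeil normal approximation (labeled in the
output), with a seeded patient-resampling bootstrap as an alternative,
since reports of AUC CIs often omit the method.

## Cross-validation

Folds are stratified by default (fold sizes differ by ≤ 1 overall *and*
within each class; per-class remainders are dealt to the folds with the
smallest running totals so both laws hold at once). Every training-stage
quantity — cutpoints, the degree-1 screen, the support set, patterns, the
model — is refit on the training split alone; a leakage test spies on the
fitting call to verify no test patient ever reaches it. When the screen
retains nothing on a training split (routine under label permutation), the
fallback to all features keeps the split trainable, so null-model accuracy
is measurable instead of degenerating into wall-to-wall failures. Splits
that still fail (e.g. a class absent) are recorded as failed tests with the
error message and excluded from aggregate means, never silently dropped.

Aggregates report the mean and *two* dispersions per metric — the standard
deviation over all k·repeats fold evaluations and over the repeat means —
because a "± x" after a cross-validated percentage is ambiguous between
the two scales (and an SD of ~0.1 percentage points across 100 folds of
~12 patients is only arithmetically plausible on the repeat-mean scale).

## Numerical and serialization choices

* Canonical JSON for all artifacts: fixed key order, floats at 10
  significant digits, integral floats rendered `x.0`, NaN as `null`;
  serialize → parse → serialize is byte-identical, which the model
  round-trip test asserts at the byte level.
* CSV dialect: comma-separated, UTF-8, mandatory header, `.` decimal
  separator; negative intensities are parse errors naming the row and
  column.
* One master seed fans out to per-stage seeds via
  `SeedSequence([master, stage_index])` reduced to 31 bits, so stages are
  independently rerunnable and a rerun with the same config reproduces
  identical artifact checksums (asserted in the pipeline tests).
* All greedy tie-breaks (support columns, patterns, model assembly) are
  fixed and documented above for cross-platform determinism.

## Problem sizes

The test suite and acceptance script run the full 57/59 cohort at 201 bins
for cross-validation (100 full-pipeline refits in a few seconds) and at the
full 5,751 bins for shape/QC checks; solver oracles run on hundreds of
random instances of ≤ 12 patients × ≤ 25 binary columns (support sets) and
≤ 12 patients × ≤ 5 features (pattern enumeration), sizes at which
exhaustive enumeration is itself fast enough to trust as ground truth.

## Known limitations

* The generator's independence across peaks and patients understates the
  correlation structure of real spectra; prevalence/homogeneity thresholds
  that behave well here may behave differently on real cohorts.
* Degree > 2 pattern enumeration is supported but unoptimized.
* The exhaustive support-set solver is an oracle, not a production path;
  no ILP solver is used.
* Survival/hazard analyses and baseline-characteristics statistics that
  often accompany risk-score studies are out of scope; the risk-group and
  ROC machinery accepts any numeric score column, so external comparators
  (e.g. proteinuria) can reuse it generically.
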