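# Methods

`rvbtools` packages the quantitative analyses used to study how promoter-bound
factors (Rvb1/Rvb2-type AAA+ ATPases) couple transcription, cytoplasmic mRNA
localization, and translation during glucose starvation in budding yeast. Each
module implements one assay's analysis; a seeded synthetic-data module
generates statistically faithful inputs so the whole pipeline is testable
without any deposited sequencing or proteomics data.

## Kinetic model of mRNA induction and decay

Induced mRNA abundance X(t) follows

    dX/dt = β − αX,

with transcription rate β (abundance·min⁻¹) and first-order degradation
constant α (min⁻¹), both assumed constant over the induction course. The
closed form is

    X(t) = X0 + (β/α − X0)(1 − e^{−αt}),

with steady state Xss = β/α, relaxation half-time ln(2)/α, and the α → 0
limit X0 + βt handled explicitly. `simulate_decay` is the β = 0 special case
(transcription shut off chemically, e.g. with 1,10-phenanthroline), giving
X(t) = X0·e^{−αt} and mRNA half-life T½ = ln(2)/α.

**Fitting.** All fits run on log2-transformed values because qPCR-derived
abundances carry multiplicative error; in log space the noise is
homoscedastic and a lognormal measurement model becomes Gaussian.
`fit_decay` is ordinary least squares of log2(value) on time pooling
replicates; half-life = −1/slope, with a +∞ sentinel when the slope is
non-negative. `fit_induction` works on fold induction F(t) = X(t)/X0 with X0
normalized to 1, fitting F(t) = 1 + (Fss − 1)(1 − e^{−αt}) by bounded
nonlinear least squares (α ∈ (10⁻⁵, 10], Fss ∈ [1, 10⁶]). β is **not**
returned: from fold data it is identifiable only as α·Fss·X0, and X0 is
normalized away. Starts are a deterministic grid of α0 = ln2/{5, 25, 60} min
so results carry no seed dependence; a flat course (Fss → 1) leaves α
unidentifiable and is reported with `converged=False` rather than raised.
Confidence intervals come from the delta-method covariance at the optimum.

`compare_decay` fits the joint model log2(value) ~ time × condition; the
interaction coefficient is the slope difference (log2·min⁻¹) and its t-test
is the formal contrast of decay rates between conditions.

## Transcription-shift vs decay-shift classifier

On a log fold-induction plot, raising β at constant α multiplies the curve by
a constant in the regime X0 ≪ β/α — an equal-distance vertical shift —
whereas changing α alters the relaxation time, so the offset between treated
and control grows (or shrinks) over the course. `classify_mechanism` makes
this operational:

1. compute d(t) = log2 F_treated(t) − log2 F_control(t) on the shared grid for
   t ≥ `t_min` (default 5 min; t = 0 is excluded because both folds are 1
   there by construction, and the early course is where the finite-X0
   deviation from a pure shift concentrates);
2. regress d on t (OLS) and t-test the slope at `trend_alpha` (default 0.05);
3. call `decay_shift` if the trend is significant; otherwise
   `transcription_shift` if |mean d| ≥ `min_effect_log2` (default 0.25 log2,
   a ~19% fold floor below which the offset is not biologically
   interpretable); otherwise `indistinguishable`.

When grids differ the treated course is interpolated linearly in
(t, log2 F), consistent with the log-scale model. The constant-shift
diagnostic is exact only as X0/Xss → 0; with a finite basal level a β-change
produces a small residual trend, which is why the classifier tests the trend
rather than requiring an exactly constant offset.

**Operating characteristics.** The classifier's advertised performance
(≥ 95% correct over β-scalings ×2/×4/×8 and α-scalings ÷2/÷4 at 5% lognormal
CV, 4 replicates, 200 seeds) is evaluated at study conditions chosen to
mirror the biology: α = ln2/25 min⁻¹ (the measured reporter half-life), the
experiment's sampling grid {0, 5, 10, 15, 30, 45} min, and a basal abundance
of 0.5% of steady state (steady-state fold 200), i.e. the strongly repressed
stress-induced regime the shift diagnostic assumes. Note a structural
ceiling: with a 5% trend test, β-shift cases are mislabelled at the nominal
type-I rate even with perfect data, so pooled correctness near 95% is the
best the prescribed decision rule can achieve at these noise levels.

## qPCR: ΔΔCt and the RIP cascade

Ct is inversely log2-linear in template abundance with amplification
efficiency fixed at 2 (perfect doubling); efficiency calibration is out of
scope. Replicates are averaged on the Ct scale before differencing, and
standard errors propagate replicate variances on the log2 scale (one cycle =
one log2 unit). Fold = 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference per
sample (reference ACT1 by convention) and ΔΔCt contrasting test vs
calibrator. No automatic outlier rejection: flagged wells are removed via an
explicit exclusion list only.

RIP enrichment is a three-stage cascade: (1) reference-gene normalization
within each (strain, fraction); (2) IP-over-input contrast within each
strain, with an optional `input_fraction` dilution correction (a constant
log2 offset); (3) division by the untagged wild-type strain's IP/input ratio,
which cancels both non-specific bead recovery and the dilution constant. If
wild-type records are absent the function returns the two-stage ratio with an
explicit `wt_normalized=False` flag — never silently.

`induction_series` turns per-timepoint ΔΔCt folds over a pre-stress baseline
into a `TimeCourse` (replicate spread preserved), feeding the kinetics
module directly.

## ChIP coverage enrichment

Inputs are fixed-bin coverage tracks (bedGraph) and BED-convention
annotations (0-based, half-open); alignment, deduplication and peak calling
are upstream, external steps. Signal definitions:

* **RPKM** over an interval: reads × 10⁹ / (length·library size); windows
  beyond a chromosome end are clipped with a warning and the clipped length
  used. Partial bin overlaps count fractionally.
* **Normalized density** = (RPKM_ChIP + pc)/(RPKM_input + pc). The
  pseudocount (default 0.5) lives on the RPKM scale so the ratio is exactly
  library-depth invariant and stays finite over empty input windows.
* **Metagene**: per gene, a −500 bp→TSS flank in 10-bp bins, the body
  mean-pooled to 100 bins, and a TES→+500 bp flank; minus-strand genes are
  flipped so the axis always runs promoter→terminator. The plotted quantity
  is target normalized density over control normalized density per bin.
  Genes shorter than one bp per body bin are excluded with a warning.
* **Promoter enrichment**: raw read counts in the strand-aware
  [TSS−500, TSS) window (constant length, so no length normalization), the
  control scaled to the target's depth, log2 of the pseudocounted ratio. An
  `rpkm` mode is available since published cumulative plots do not always
  state the count convention.
* **Class contrast**: Welch two-sample t on per-gene log2 ratios between
  gene classes, plus empirical CDF coordinates for cumulative plots. Class
  labels (e.g. >3-fold-induced, Hsf1-target) are user-supplied via a class
  table, not recomputed from expression data.

## Reporter expression and ribosome occupancy

Protein synthesis rate from nLuc plates: each sample is OD₆₆₀-normalized and
the cycloheximide-treated paired well (translation stopped ~5 min earlier) is
subtracted, isolating enzyme made within the window. Negative rates are
reported with a QC flag, never clamped. Translatability — the
translational-efficiency proxy — is log2(protein fold) − log2(mRNA fold),
both relative to the same control; the sign convention (protein minus mRNA)
is the only one under which "protein down while mRNA up" yields reduced
translatability, and is fixed here deliberately because legend phrasing of
the form "subtracting A from B" is ambiguous in the source assays.

Ribosome occupancy per gene is ribo-seq RPM over RNA-seq RPM in
[AUG+120, ORF end): the first 120 nt are excluded because initiation-region
footprints accumulate there regardless of elongation flux. ORFs ≤ 120 nt have
no defined region and raise. (Published descriptions of the initiation window
sometimes contain an obvious sign typo, e.g. "216 bp to 120 bp in relation
to the AUG"; only the downstream-region definition is implemented.) Per-base
occupancy is footprint counts over the gene's mean per-base mRNA density.
Foci scoring compares replicate per-field fractions by t-test (the source
convention), with a two-proportion z-test as an alternative mode.

## CoTrIP screen

Per protein, log2 fold change of pseudocounted group mean spectral counts
(default pc = 0.5) and a Welch t-test on raw counts (a `log` mode tests
log2-counts instead); unequal group sizes (2 vs 3) are the design norm. The
candidate list is everything at p < 0.05 ranked by fold descending, protein
id ascending — deterministic by construction. No multiple-testing correction
is applied, matching the screen's use of raw p-values as a ranking; this is a
caveat, not an endorsement: the list is a screen, not an inference. The
optional background filter divides by a user-supplied contaminant table
(e.g. a CRAPome-style summary); proteins missing from the background are kept
but flagged.

## Synthetic data

Generators share one `GeneratorConfig`; the global seed expands into fixed
per-generator substreams so adding a generator never changes another's
output, and every generator's `noise_cv = 0` mode emits its exact
expectation, which the round-trip test suite composes with the consuming
analysis to recover configured truths exactly.

Defaults mirror the study conditions: sampling grid {0, 5, 10, 15, 30, 45}
min, 4 replicates, 5% multiplicative CV (median-one lognormal, so log-scale
fits are unbiased), Ct baseline 30 cycles at unit abundance, coverage depth
10⁶ reads over a 2×300 kb genome of 60 non-overlapping genes in 10-bp bins
(classes I/II/other at 30/30/40%), and negative-binomial spectral counts
(variance μ + 0.1μ²).

**What the generators do not emulate** — and hence what passing tests do not
establish about real data: qPCR efficiency ≠ 2 and probe chemistry;
position-dependent ChIP fragment-size and mappability structure (background
is homogeneous Poisson; real input tracks are not flat); cross-replicate
batch effects and plate-position effects; ribo-seq P-site offsets and codon
pauses; protein-inference ambiguity in spectral counts. One known small bias
is retained deliberately: promoter enrichment on the target track adds reads
to the target library, so depth scaling shrinks the recovered class mean
log2 ratio slightly (≈ 0.06 log2 at 4-fold enrichment over 18 promoters at
default depth); round-trip tolerances account for it.

## Numerical choices

* Closed-form trajectories are validated against an independent fixed-step
  RK4 integrator over a 75-point (α, β, X0) grid, max |error| < 10⁻⁶.
* The induction fit's multi-start grid, bounds, and flat-course convergence
  rule are described above; ties between starts resolve to the lowest SSE.
* Degenerate statistics return sentinels, not exceptions: +∞ half-life for
  non-decaying series, NaN occupancy at zero mRNA reads, p = 1 for
  zero-variance-equal-means contrasts and NaN+flag for zero-variance-unequal
  ones.
* Text output uses 6 significant digits so regenerated files are
  byte-stable.

## Scope and limitations

The package consumes processed inputs (coverage, counts, Ct, plate tables);
it does not align reads, call peaks, search spectra, or segment images.
Bayesian inference and time-varying α(t)/β(t) are out of scope, as is
estimating absolute β from fold data. Problem sizes in the test suite (200
Monte-Carlo seeds for classifier and recovery studies, 10⁶-read synthetic
tracks) are the package's chosen defaults for characterizing its estimators;
they are small enough to run anywhere yet large enough that the Monte-Carlo
error on the reported rates is about one percentage point.
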