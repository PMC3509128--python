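# Methods

This note documents the statistical models, estimators, and numerical
choices inside `mirpanel`, the defaults they ship with, and what the
synthetic-data experiments do and do not demonstrate.

## Preprocessing

**Detection calls.** For each feature on each array, the spot
intensities of its probes (quadruplicate by default) are compared with
the pooled spot intensities of non-specific background probes in the
same GC bin by a one-sided Wilcoxon rank-sum test (alternative:
target > background); the feature is "present" when p < α (default
0.05). The vendor's detection algorithm is unpublished; the rank-sum
against GC-matched background spots is the standard
detection-above-background idiom and is the contract we guarantee. The
null distribution of the U statistic is computed exactly by
dynamic-programming convolution (cached per group-size pair) whenever
the pooled values are tie-free; with ties the midrank normal
approximation with tie-corrected variance and continuity correction is
used. Exactness matters here because the per-call level drives the
all-absent filter downstream: with 4 spots against a 76-spot pool the
achievable levels are dense enough that the realized false-positive
rate sits within a point or two of α.

**Background correction.** The normal + exponential convolution model:
observed x = s + b with signal s ~ Exp(α) and background b ~ N(μ, σ²).
The returned value is the posterior mean
E[s | x] = a + σ·φ(a/σ)/Φ(a/σ), a = x − μ − σ²α, which is strictly
positive and strictly increasing in x. Parameters are estimated per
array from the intensity distribution: a first kernel-density pass
locates a provisional mode; the density is re-estimated on the sub-mode
values only (so Silverman's bandwidth is not inflated by the signal
tail); σ comes from the left half-width at half maximum of that
density (HWHM/√(2 ln 2)); α is the reciprocal mean exceedance above
the mode. Because the mode of the convolution sits above μ by a
predictable offset — at the mode φ(t)/Φ(t) = ασ with
t = (mode − μ)/σ — the location estimate is de-biased by inverting that
relation. In the generator's signal regime this estimator's corrected
values have lower mean absolute error against the true signal than
oracle-mean subtraction clipped at zero; in very high signal-to-noise
regimes the HWHM σ estimate is inflated by the signal flank and the
correction is merely comparable to naive subtraction. Order
preservation and positivity hold in all regimes.

**Quantile normalization.** Every array's sorted values are replaced by
the across-array mean of order statistics; tied input values receive
the mean of the reference values their ranks span. The operation is
idempotent and leaves all columns with identical value multisets.

**Summarization.** Tukey median polish of each feature's log₂
spot × array matrix, with the array summary = overall effect + column
effect. Sweeps alternate row and column medians; iteration stops when
the sum of absolute residuals changes by less than a relative
tolerance of 0.01 per sweep or after 10 sweeps (conventional defaults
for this summarization). A single-spot feature degenerates to its own
values. Summaries are translation-equivariant.

**Replicates.** For samples hybridized more than once, the retained
array maximizes the mean Pearson correlation with the other replicates
(ties break to the lowest index). "Best replicate" is underdetermined
in the source material; maximal mean inter-replicate correlation is
this package's operationalization, and the QC report retains all
pairwise correlations so other rules can be audited. The QC report
also records per-array 75th/95th percentiles of summarized log₂
signal. A rolling-window Pearson correlation (width 99, reported at
the mid-window abscissa) is provided for replicate-quality inspection
as a function of signal level; it shows the generic phenomenon that
inter-replicate agreement degrades at low signal.

## Expressed-feature filtering

Stage one removes features with absent calls in every sample. Stage
two computes each array's inter-quartile range (linear-interpolation
quantiles) over the *linear-scale* normalized signals and removes
features that never reach `multiplier × mean IQR` (default 4×). The
linear scale is a deliberate decision: the magnitudes this rule is
calibrated to (mean IQRs of tens of signal units, thresholds near 70)
are impossible on the log₂ scale, where 75th percentiles are ~3.6.
The boundary is inclusive (≥ threshold counts as present), because
absence is phrased as strictly "< 4×". The FilterReport enforces the
bookkeeping identity n_input − removed_detection − removed_IQR =
retained on every run. The quantile convention (linear interpolation)
is exposed as an option since alternative conventions shift small-n
IQRs.

## Concordance

Per shared feature (exact name match after whitespace trimming),
Pearson r across the shared-sample intersection, on each dataset's
values as delivered — no rescaling, since Pearson r is invariant to
per-feature affine recalibration anyway. Zero-variance features are
excluded with a count rather than assigned r = 0. Summaries: mean and
SD of r, fraction above a cutoff (default 0.75, strict inequality),
and a cumulative distribution over [−1, 1] with bin width 0.025. The
resampling control permutes one dataset's sample labels uniformly,
destroying correspondence while preserving both marginals. RT-PCR
cross-validation regresses quantification cycles on log₂ signal
(least squares) and reports Pearson r with the two-tailed t-based p
(df = n − 2); agreement appears as negative slopes because lower Cq
means more template.

## Differential expression

Moderated t as described in the README, with hyperparameters (d₀, s₀²)
estimated by moment matching on z = log s²_g: E[z] and Var[z] under the
hierarchical model involve digamma/trigamma of d_g/2 and d₀/2;
trigamma is inverted by Newton iteration. When the observed dispersion
of z does not exceed trigamma(d_g/2), d₀ = ∞ and all features share
s₀² (t is then referred to the normal). d₀ = 0 is the no-shrinkage
limit and reproduces the classical pooled two-sample t exactly. One
hyperparameter fit is shared per matrix (pooled within-group variances
across all tissue groups, df = Σ(n_g − 1) over groups with ≥ 2
samples), rather than per contrast, matching the cited method's usual
practice of a single prior per dataset. The whole chain — prior
estimation, shrinkage, p-values — agrees with Bioconductor limma to
~1e-9 on shared inputs (tested).

One-vs-rest contrasts skip tissues with fewer than 2 samples on either
side, with a warning. Mutation contrasts refuse to run below a
minimum mutant count (default 10; the eligibility rule "more than 10"
is relaxed to "at least 10" and documented here). Heatmap export takes
the k = 8 features with lowest raw p per group (ties broken by feature
id; raw rather than adjusted p is the default since the source
convention is unstated, and it is configurable), z-scaled along rows
with the n−1 standard deviation.

Clustering uses average linkage on uncentered-Pearson distance
1 − Σxy/√(Σx²Σy²) ∈ [0, 2]; leaf order is optimized by the
Bar-Joseph dynamic program (scipy's `optimal_leaf_ordering`), with the
plain dendrogram order behind a flag. Trees are exported as Newick.

## Phenotype screens

Phenotype values are positive; the screen correlates log₂ expression
with log₂ phenotype and flags |r| > cutoff with p < 0.05 (two-tailed
t, df = n − 2). Records carry both r and p so either convention — the
0.5 primary cutoff or the 0.4 reporting cutoff, with or without the p
condition — is reproducible. Before the screen, a Gaussian KDE
(512-point grid spanning the data ± 3 bandwidths; Silverman's rule by
default, since the referenced density tool's settings are otherwise
unrecorded) checks for bimodality; modes are strict local maxima with
prominence ≥ 5 % of the global maximum — a threshold chosen to make a
visual judgement testable. Mode count is non-increasing in bandwidth.
The robustness operation re-runs the screen with one named tissue
excluded and reports features that pass only in the full panel: the
signature of a correlation driven by one extreme group rather than a
panel-wide trend.

## Target correlations

The map is three duplicate-free relations (family→miRNA, family→gene,
gene→probe); expansion produces one pair per (expressed member miRNA,
retained probe of a targeted gene), with duplicates collapsed — a
miRNA reached through two families targeting the same gene counts
once, while a gene measured by several probes contributes one pair per
probe. mRNA probes are pre-filtered to log₂ sample range ≥ 1
(inclusive). BH is applied jointly across all pairs as one family.
r = 0 counts as positive in the sign summary (probability ~0 on
continuous data; documented for completeness). The permutation null
shuffles only the mRNA matrix's sample labels; the summary records
per-permutation significant counts (mean, SD) and one two-sided
rank-sum p per permutation comparing observed and permuted r values.
Expected false discoveries among k significant calls at level q is
reported as q·k.

## Synthetic panel generator

The generator emulates the study's data structure: 60 samples across
nine tissue groups (6/6/7/6/9/9/7/2/8), 847 miRNA probes spotted in
quadruplicate, 95 background probes in five GC bins, 72 hybridizations
in nine batches of eight across three days, and four samples assayed
in quadruplicate. All counts are configurable.

Spot model: intensity = true linear signal + N(GC-bin mean, σ_bg),
clipped at 0.5 — the convolution RMA inverts. The bin means rise from
40 to 100 linear units across bins (σ_bg = 15), giving detection calls
real GC structure to match against. A feature's true signal is shared
by its quadruplicate spots; per-sample effects (tissue shifts,
mutation shifts, phenotype coupling, batch offsets, N(0, 0.5) log₂
noise) act multiplicatively on the linear scale. Batch offsets are
N(0, 0.25) log₂ per batch.

Per-feature abundances are log-uniform over the platform dynamic range
(log₂ ∈ [1, 11] by default), with 35 % of features expressed and the
rest background-only. Log-uniform rather than linear-exponential
amplitudes is a deliberate design choice: quantile normalization is
rank-based, and a planted log₂ shift is only representable after
normalization if the panel presents a dense signal continuum for the
shifted feature to move through. Exponential amplitudes concentrate
every expressed feature within about one octave; shifted features then
saturate at the same top ranks on every array and the shift is erased
by normalization — a property of rank normalization, not of the assay.
Features carrying planted effects are drawn from a mid-continuum
stratum (log₂ ∈ [7, 8.5]) so they sit clearly above the presence
threshold with rank headroom on both sides; a 20-seed Monte-Carlo test
confirms a planted +2 log₂ tissue shift is recovered without material
bias after full preprocessing.

Phenotypes: each phenotype has a per-sample standard-normal latent u;
planted features receive β·u in log₂ expression with
β = σ_tot·ρ/√(1 − ρ²) (σ_tot = √(noise² + batch²)), so their
correlation with the log₂ phenotype is ρ by construction; the
phenotype itself is 2^(3 + u). Effect-size magnitudes for tissue DE
are not reported by the emulated study; the defaults (+2 log₂ shifts,
ρ = 0.7, pair r = −0.6) are calibrated only to make recovery tests
meaningful, not to mimic any real panel. An optional extreme-group
flag (off by default) adds a −4 log₂ offset to one tissue's phenotype,
reproducing the hazard where screen hits are driven entirely by one
sensitive group: such hits vanish when that group is excluded.

Companion datasets for concordance keep a feature subset, apply a
per-feature affine distortion (slope 0.5–2, offset N(0, 2)) and add
independent noise; a calibration helper solves for the noise SD that
yields a target mean per-feature r under identity distortion (slope
distortion changes per-feature SNR, so calibrated targets assume it
off). Target mRNA matrices plant each pair as
ρ·z(miRNA) + √(1 − ρ²)·noise mapped to a log₂-like scale, plus
independent null probes.

What the generator does **not** emulate: scanner optics and spatial
artifacts, cross-hybridization, probe-sequence effects beyond the GC
bin, heavy-tailed or correlated biological variation, missingness, and
cross-platform nonlinearity beyond the affine-plus-noise model.
Passing recovery tests therefore demonstrates the pipeline's
statistical machinery is correct and calibrated under its own model
assumptions — not that any particular biological conclusion transfers
to real panels.

## Problem sizes and numerical details

Simulation-based tests use the full 60-sample, 847-probe panel where
power at study conditions is the question (tissue-DE sensitivity,
artifact reproduction, determinism) and smaller 8-sample panels (40 to
300 probes) for structural properties; oracle-equivalence suites use
100 random small instances each. Null-calibration checks use
m = 2000 features for the moderated-t uniformity test, 5000
independent pairs for the mass-correlation null, and m = 5000
variances for hyperparameter recovery. Random number generation is
numpy's PCG64 with explicit seeds everywhere; the full pipeline's
manifest records config, output digests, and per-stage seeds, and two
runs with the same seeds are byte-identical modulo timings. Quantile
ties are resolved by run-averaging; trigamma inversion stops at a
relative step of 1e-10; exact rank-sum tables are cached per (n, m)
and bounded at n·m ≤ 20 000 before falling back to the normal
approximation.

## Known limitations

* The HWHM-based σ estimator over-estimates background spread in
  high-SNR regimes (documented above); a maximum-likelihood fit would
  be sharper but departs from the mode/HWHM/tail estimator family this
  implementation documents.
* The IQR presence threshold interacts with panel composition: with
  few assayed features (tens rather than hundreds) the quartiles land
  in the expressed continuum and the 4× rule becomes aggressive.
* The moderated-t contrasts assume equal within-group variance; the
  shared hyperparameter fit borrows strength across tissues and is
  slightly anticonservative when group variances differ systematically.
* Mutation contrasts inherit the panel's tissue–mutation confounding;
  the package reports, but does not adjust for, tissue composition
  (multi-factor designs are out of scope).
* Concordance assumes shared sample names; name harmonization across
  datasets is a config input, not built in.
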