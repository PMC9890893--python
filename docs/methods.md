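# Methods

This note documents the models and estimators implemented in `trem2quant`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Field-potential analysis (`ephys`)

**Quantities.** Evoked fEPSPs are reduced to a signed initial slope
(mV/ms; negative for the usual downward deflection — all ratios, I/O
points and LTP normalization use the magnitude), a fiber-volley amplitude
(mV, peak-to-baseline), I/O curves of |slope| versus fiber-volley
amplitude with an ordinary least-squares line, paired-pulse ratios
|slope₂|/|slope₁| on the 20–400 ms (step 20) schedule, and a minute-binned
LTP profile expressed as percent of the baseline mean.

**Slope definition.** The slope is the least-squares line over the first
1 ms of the descending domain — the segment running from the local maximum
that precedes the fEPSP trough down to the trough. A regression, rather
than a two-point difference, is used because it is far less sensitive to
grid noise; on noise-free traces the two coincide for a linear segment.

**Descending-domain detection.** The raw local maximum is fragile under
sensor noise, so landmarks are found on smoothed copies of the trace:

* value smoothing: Savitzky–Golay, window 0.3 ms, order 2 (`smooth_ms`);
* the trough is the smoothed minimum inside the search window (default:
  from the end of the fiber-volley window to the end of the trace);
* the steepest descent is the minimum of a wider Savitzky–Golay first
  derivative (window 0.5 ms, `deriv_smooth_ms`) before the trough;
* the domain start is the last sample before the steepest point at which
  the decline first reaches `onset_frac` (default 0.6) of the steepest
  rate.

The fractional-rate crossing biases the start slightly *into* the descent
(a fraction of the smoothing width), which is deliberate: starting
marginally late keeps the 1 ms regression window on the descending limb,
whereas starting early mixes in pre-onset baseline and biases the slope
toward zero. The regression itself always runs on the raw samples. The
first 1 ms after the stimulus is blanked as artifact (`blank_ms`,
configurable; stimulus-artifact handling is not prescribed by any standard,
so the window is a parameter).

Errors: a flat trace (no descent deeper than 4× a robust pre-stimulus
noise scale) raises a no-response error; a descending segment shorter than
1 ms raises an error carrying the segment length.

**Minute binning.** Sweeps at 20 s intervals give 3 sweeps/minute; sweeps
with session time *t* relative to the tetanus marker fall in minute
⌈*t*⌉ for *t* > 0 and ⌊*t*⌋ for *t* < 0. The per-minute mean |slope| is
divided by the mean over baseline minutes, so baseline minutes average to
100% exactly. The "last-5-minute" summary averages the last five post-TBS
minutes present. The theta-burst stimulus itself is an event marker only.

**Test-stimulus selection.** Among I/O sweeps, the smallest stimulus level
whose fEPSP amplitude (trough depth below the pre-stimulus baseline) falls
within 50–60% of the maximum; when no level lands in the band, the level
closest to the 55% midpoint is returned flagged. Band membership uses a
relative tolerance of 1e−9 so exact-boundary amplitudes are inside.

## Clearance kinetics (`clearance`)

Post-inhibitor interstitial-fluid Aβ follows first-order elimination, so
log₁₀(concentration) falls linearly in time. The fit is ordinary least
squares of log₁₀(conc) on *t* over fractions with *t* > 0; the fraction
collected during the dosing hour is excluded (the drug is administered at
its start), a boundary configurable via `t0`. Per-animal fits are computed
and then compared across groups (normalizing each half-life to the
reference-group mean), rather than pooling animals before fitting.

Constants: by default *Ke* = −ln(10)·*a* and *T*₁/₂ = ln(2)/*Ke*; with
`paper_constants=True` the rounded 2.3 and 0.693 familiar from
pharmacokinetics methods are used verbatim, for exact agreement with hand
arithmetic at that precision. Both identity chains (*T*₁/₂ =
log₁₀2/(−*a*) = ln 2/*Ke*) hold to 1e−12 relative on every fit and are
asserted in the tests. A non-decaying series (*a* ≥ 0) returns a fit with
the half-life marked undefined (NaN) and flagged; nonpositive post-dose
concentrations are an error naming the offending fraction.

## Image quantification (`histoquant`)

Conventions: 0-based pixel indices, origin top-left; all reported geometry
in physical µm; objects are 8-connected components of above-threshold
pixels; the "diameter" of an irregular object is its equivalent circular
diameter 2√(area/π); distances are Euclidean between centroids.

* **Area fraction** — percent of ROI pixels strictly above the threshold.
  The "unified intensity threshold" per stain is a configuration value
  applied to every image of a batch; `pooled_otsu_threshold` offers an
  Otsu-on-pooled-histogram default when no value is given.
* **Plaque particle analysis** — components with equivalent diameter
  strictly greater than 8 µm (default) are retained; density is count per
  mm² of ROI.
* **Microglial somata** — particle analysis with a soma-scale diameter
  gate (4–30 µm default); the soma threshold is chosen above the process
  intensity so only cell bodies survive.
* **Skeleton morphometry** — per component, a medial-axis skeleton;
  junctions are 8-connected clusters of skeleton pixels with ≥ 3 skeleton
  neighbors; branches are the connected segments left after junction
  removal; total length is the minimum-spanning-tree weight of the
  skeleton pixel graph with straight steps = 1 px and diagonal steps =
  √2 px (the MST prevents corner diagonals from being double counted).
  These weights are the field-standard choice but carry the classical
  digital-length staircase bias: a straight segment at an arbitrary angle
  is overestimated by up to cos 22.5° + (√2−1) sin 22.5° − 1 ≈ 8.2%.
  Tests bound lengths by this analytic limit rather than pretending the
  estimator is angle-unbiased.
* **Plaque neighborhoods** — per plaque, microglia whose *soma centroid*
  lies within 30 µm of the plaque centroid (an automated surrogate for
  manual counting), plus the plaque-microglia colocalized area inside the
  disk divided by that count (NaN and flagged when zero).
* **Colocalization** — area above both thresholds; the fraction is
  intersection over union of the single-channel masks. With no thresholds
  supplied, a Costes-style bisection lowers both thresholds along a common
  intensity fraction until the below-threshold pixels decorrelate. The
  named interactive tool's exact algorithm is not published; the bisection
  is the documented automated stand-in, and fixed-threshold mode is exact.

## Targeted-proteomics and small assays (`assayquant`)

Inputs begin where chromatographic peak areas end (no spectral
processing). The absolute amount of a peptide is
(native area / SIL-IS area) × spike, spike defaulting to 5 fmol. Soluble
and full-length totals, the global s/fl ratio and per-allele ratios (for
heterozygotes carrying all four peptides) follow by arithmetic; ratios are
NaN and flagged when the full-length denominator is zero. Normalization
"to the reference group" divides by the reference arithmetic mean (the
choice of mean over median is a documented convention). qPCR relative
expression uses 2^−ΔCt; the C/N Ct ratio is per-sample Ct(C-term)/Ct(N-term)
normalized to the reference-group mean — truncated transcripts raise it
above 1. Units behind per-mg normalizations (total protein vs wet weight)
are left to configuration; neither is asserted.

## Post-count RNA-seq (`transcript`)

* **Sample QC** drops samples below a gene-count percentage floor
  (default 50%) or outside a strandness band (default 0.70–1.0; a score
  near 0.5 marks an ambiguous library), each with a reason string.
* **Gene filter**: keep a gene iff ≥ 4 samples have ≥ 10 counts
  (boundary read as ≥ 10; both knobs configurable).
* **TMM**: doubly-trimmed (30% on M, 5% on A), precision-weighted mean of
  gene-wise log ratios against the sample whose upper-quartile count
  fraction is closest to the mean; factors are rescaled to geometric mean
  1 (held to 1e−12). Verified in tests against both a naive in-test
  re-derivation and the reference Bioconductor implementation (2%).
* **Differential expression** is a gene-wise negative-binomial Wald test:
  group abundances λ̂ = Σy/ΣL on TMM-effective library sizes; per-gene
  moment dispersions shrunk toward a 20-bin running-median mean-dispersion
  trend with prior weight 10; the log-abundance contrast referred to a
  t distribution with residual + prior degrees of freedom; log₂FC from
  normalized group means with a library-scaled prior count of 0.5. This is
  a deliberately simple, documented stand-in for quasi-likelihood GLM
  machinery — validated by null calibration (uniform p-values, FDR-level
  discoveries on null data) and planted-effect recovery, never by claiming
  identity with any published package.
* **Classification**: up if FDR < 0.05 and log₂FC > 0.25; down if
  FDR < 0.05 and log₂FC < −0.25; otherwise ns (strict inequalities;
  |log₂FC| > 0.25 corresponds to |FC| > 2^0.25 ≈ 1.19, i.e. the rounded
  1.2 of figure legends). BH adjustment is the standard step-up rule.
* **Clustering**: rows on standardized Euclidean distances (each feature
  scaled by its ddof-1 standard deviation; zero-variance features map to
  zeros with a warning), average linkage, scipy's deterministic
  index-based tie-breaking.
* **Residualization** for network analysis: per-gene least-squares
  residuals of log-CPM against an intercept plus sex, strandness and
  exonic-rate covariates; collinear designs are an error naming the
  columns.

### Co-expression modules

Signed-hybrid adjacency a_ij = cor(i,j)^β for positive correlations
(zero otherwise), β = 12; topological-overlap dissimilarity; average
linkage. Instead of the dynamic hybrid tree cut, a static height cut is
chosen to maximize weighted Newman modularity subject to the minimum
module size (40), a documented simplification. Candidate modules are then
eigengene-purified: members whose module membership falls below 0.3 are
released (two passes).

Because hierarchical clustering *selects* the densest clumps, random data
also yields candidate clusters; a naive random-gene-set null is therefore
too lenient. Candidates must instead clear a selection-aware permutation
screen: the identical pipeline is run on data whose gene profiles are
independently sample-permuted (n = 10 networks), the densest purified
cluster of each permuted run is recorded (retained at half the minimum
size, since purified noise clusters rarely reach full size), and an
observed module survives only if its intramodule density exceeds that null
by 5 standard deviations. This makes pure-noise matrices return no modules
while leaving genuinely co-expressed modules untouched (their densities
sit an order of magnitude above the null).

Surviving modules whose eigengenes correlate above 0.6 (merge cut 0.4) are
merged. The eigengene is the first principal component of the per-gene
standardized member profiles (unit norm, one value per sample), with its
sign fixed so the mean member membership is positive; membership is the
Pearson correlation of a gene's profile with the eigengene, with t-based
p-values; hubs are the top 10 members by membership p-value. Module–trait
analysis correlates eigengenes with a coded trait (reference genotype 0,
variant 1) and, for binary traits, adds a rank-sum comparison of
eigengenes between the groups.

### Module preservation

For each reference module, two statistics are evaluated in the test data:
density (mean intramodule signed-hybrid adjacency) and connectivity
(Pearson correlation between reference and test intramodule connectivity
over the member genes). Each is standardized against ≥ 50 random gene
sets of the same size drawn from the shared gene universe, and Zsummary is
the mean of the two Z scores — a two-statistic simplification of the
published multi-statistic composite, retaining the conventional
thresholds (> 2 moderate, > 10 strong preservation). Being a calibrated Z,
it has the usual ~2.5% null tail above 2; null-behavior tests therefore
require Zsummary < 2 in ≥ 90% of seeds rather than in all of them.

## Group statistics (`groupstats`)

The decision rule is reproducible from the design alone: groups larger
than 7 use rank-based tests (Kruskal–Wallis with *uncorrected* Dunn
pairwise z-tests for ≥ 3 groups — pairwise p-values deliberately not
multiplicity-adjusted, with a Bonferroni option off by default — or
two-sided Wilcoxon rank-sum for 2 groups); groups of at most 7 use the
unpaired t test when a two-sided variance F-test finds p ≥ 0.05 (the
"similar variances" threshold is not standardized anywhere; 0.05 is the
configurable default) and Welch's t test otherwise; paired designs use
the Wilcoxon matched-pairs signed-rank test. Rank tests use average ranks
with tie-corrected variances and exact small-sample nulls where scipy
provides them. The ANCOVA slope comparison is the F-test of the group × x
interaction in the two-line linear model, with an exact-fit guard at
1e−12 of the response scale.

## Synthetic data (`synthdata`)

All generators draw from a single `numpy.random.default_rng(seed)`;
identical seed and parameters reproduce outputs byte for byte.

* **fEPSP sweeps** — baseline + 0.2 ms biphasic artifact at the stimulus
  + Gaussian fiber volley (σ 0.35 ms, 2 ms post-stimulus) + synaptic
  deflection + optional white sensor noise, on a 0.05 ms grid (sampling
  rate is not a claim about any acquisition system; it is configurable).
  The synaptic component descends **linearly at exactly the planted
  slope** for 1.6 ms before rounding into the trough (half-cosine, 1 ms)
  and recovering exponentially (τ 3 ms). The linear segment is longer than
  the 1 ms measurement window on purpose: the planted slope then *is* the
  steepest-1 ms regression slope of the noise-free trace, so zero-noise
  recovery is exact to the grid and needs no calibration constant. A
  difference-of-exponentials shape was considered and rejected because its
  continuously steepening onset makes the "first 1 ms" slope acutely
  sensitive to onset-detection jitter, coupling generator truth to the
  estimator's landmarks.
* **LTP sessions** — 20 baseline + 60 post-TBS minutes at 3 sweeps/minute
  by default; post-TBS slopes are baseline × potentiation factor, with
  optional multiplicative Gaussian sweep-to-sweep variability.
* **Dialysate series** — 10 baseline + 4 post-dose hourly fractions
  (14 total); post-dose concentration baseline × exp(−Ke·t); noise is
  multiplicative log-normal with the stated CV and mean 1, so
  concentrations stay positive for the semi-log fit and the log-domain
  slope is unbiased.
* **Scenes** — anti-aliased disks (plaques, somata; edge coverage ramps
  over one pixel, so thresholding at half the object intensity recovers
  the planted area to pixel quantization) and capsule-profile branches,
  with ground truth recorded in µm: counts, diameters, per-cell branch/
  junction/length (junctions counted as endpoints shared by ≥ 3 planted
  branches), pairwise plaque–soma distances, and overlap flags. Optional
  Gaussian noise on top of a constant background.
* **PRM runs** — native area = amount × response factor, SIL-IS area =
  spike × response factor, each with independent mean-1 log-normal noise.
* **Counts** — negative-binomial with log-normal relative abundances,
  gene-wise dispersions log-normal around 0.05 (σ_log 0.3), planted log₂
  fold changes on DE genes, and a planted module whose members load on a
  single latent factor f = effect × (group − mean) + N(0, 0.5), shifting
  log₂ means by loading × f × 0.4. The single-latent-factor construction
  is the simplest structure producing a co-expression module correlated
  with genotype; 0.4 yields intra-module correlations near 0.5, typical of
  a strongly co-regulated immune module.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: electrode drift and line noise, slice-to-slice
response heterogeneity, microdialysis probe-recovery and flow artifacts,
optical PSF blur/vignetting/uneven illumination, touching or overlapping
cells beyond the overlap flags, chromatographic interference or matrix
effects, batch effects and GC/length biases in counts, and any raw-signal
processing upstream of the package's inputs (spectra, reads, microscope
optics). Parameter-recovery results demonstrate estimator correctness
under the stated noise models, not robustness to these artifacts.

## Problem sizes and runtimes

Tests and the cohort demo use deliberately modest sizes chosen so the full
suite exercises every stage in well under a minute of the heaviest module:
count matrices of 300–2000 genes × 10–20 samples, scenes of 200–300 µm at
0.5–1 µm/px, 100–200 Monte-Carlo seeds for recovery studies, 2000 null
replicates for test-calibration runs, and ≥ 50–100 permutations for
preservation statistics. These sizes are statements about what suffices to
verify the estimators, not about the scale the code can handle; all
operations are vectorized and scale to realistic inputs.

## Known limitations

* The DE test is a moment/Wald approximation; very small groups (n = 2)
  or extremely low counts push it conservative rather than anticonservative.
* The static modularity tree cut can split one module across heights that
  the dynamic hybrid algorithm would join; the eigengene merge step
  recovers most such splits.
* Skeleton lengths inherit the 0–8.2% digital staircase bias discussed
  above.
* The Costes-style threshold search assumes a roughly monotone
  intensity relationship between channels; fixed thresholds should be
  preferred whenever a batch-wide unified threshold exists.
* Microglia counting near plaques uses soma centroids; cells whose soma
  lies just outside 30 µm but whose processes contact the plaque are not
  counted, unlike a human rater.
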