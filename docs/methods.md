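# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions a maintainer would need.

## Synthetic data: the study conditions

All generators draw from `numpy.random.default_rng(seed)`; a fixed seed
gives bit-identical outputs across runs and platforms.

**Expression.** Cells come in three classes (excitatory, inhibitory,
glia) × two genotypes (WT, cKO), 170 cells per combination by default
(~10³ cells total).  Counts are negative binomial with variance
μ + μ²/θ (θ = 2 by default) — the standard overdispersed model for UMI
counts; the paper-scale alternative of ~11k genes is represented at
desk scale by 2,000 genes whose lengths are log-uniform on
[1 kb, 2.5 Mb] so that long-gene bins stay populated.  Class identity
is encoded by one canonical marker gene per class (Neurod6, Gad1, Aqp4:
mean 5 in the home class, 0.1 elsewhere) plus a 100-gene program
elevated 3-fold per class.  The knockout effect multiplies the mean of
every gene in excitatory-cKO cells by `2^(−β·max(0, log10 L − log10 L0))`
with β = 0.5 per decade and L0 = 100 kb by default, i.e. a 1 Mb gene
loses 0.5 log2 units; a designated *Top1* gene additionally loses 2 log2
units (4-fold) in that class only.  The applied per-gene log2FC is
returned as the truth table.  Not emulated: droplet chemistry, ambient
RNA, doublets, batch effects — so passing tests demonstrate correctness
of the analysis logic under the assumed count model, not robustness to
those artifacts.

**CNV bin counts.** A synthetic genome of 19 autosomes (2.5 Gb, 500 kb
bins ⇒ ~5,000 bins) by default; test and acceptance runs use a compact
5-chromosome, 500 × 1 Mb-bin genome so circular binary segmentation
stays affordable at 50 cells × 20 seeds.  Per cell and bin the expected
count is `depth · copy/2 · lognormal(0, σ_amp)` (σ_amp = 0.15, depth
100 reads/bin), Poisson-sampled; the lognormal bias is drawn
independently per (cell, bin), modelling whole-genome-amplification
noise without spatial correlation.  Implanted events are ≥1 bin,
copy ∈ {1, 3}, carried per cell with a configurable fraction; a preset
reproduces the study's carrier design exactly (24 of 123 WT, 60 of 169
cKO cells carrying one event each).

**smFISH sections.** Cells on a grid in three layers (L2–4, L5, L6),
80% excitatory (Neurod6 counts ~ Poisson(15), others Poisson(1)).
Ptprd singles per gated cell ~ Poisson(8); clusters of k ∈ {2..5}
transcripts occur at rate `density·cluster_fraction/3` and have area
k·a₀ (a₀ = 4 px²) while singles have area a₀ ± 0.3.  In cKO sections
the Ptprd density in L5/L6 is halved.  Truth per cell is
singles + Σk.

**Foci images.** Nuclei are disks (radius 10 px) in a label mask; each
carries `Bernoulli(rate)·(1 + Poisson(0.7))` foci rendered as Gaussian
blobs (σ = 1.5 px, amplitude 180 over background 10), separated by
> 2σ; optional Poisson shot noise.

**Survival.** Per-group Weibull; the preset uses shape 8 (tight failure
times appropriate for a lethal developmental phenotype) with scales
solved so medians are 18 and 23 days; group sizes default to 11 and 10.

## Expression pipeline

*Normalization*: each cell is scaled to the median library size then
log1p-transformed ("median centered and log normalized" read as
per-cell median-library scaling; gene-wise median-centering would
break non-negativity and the zero pattern — the alternative reading can
be composed manually from the returned layers).

*PC selection*: observed eigenvalues are compared rank-by-rank against
the 95th percentile of eigenvalues from matrices with independently
permuted columns (1,000 permutations by default, 100 in tests); the
retained count is the longest prefix of ranks beating their threshold.
A percentile was chosen over the permutation maximum because the
criterion "greater than permuted data" is otherwise ill-defined; the
quantile is a parameter.

*Clustering*: Louvain (resolution 1.0, seeded) on a symmetrized
Euclidean kNN graph in PC space, with k chosen from a grid by maximal
mean silhouette (smallest k on ties).

*Markers*: one-sided presence–absence binomial enrichment:
p = P(X ≥ d_in), X ~ Binomial(n_in, max(f_out, 1/n_out)); the 1/n_out
floor avoids p = 0 degeneracies for genes absent outside the cluster.
Flagged when p < 0.05 and mean log2FC (normalized expression,
pseudocount 1) > 1.

*Differential expression*: a deliberately simple NB Wald test — group
means per genotype, pooled method-of-moments dispersion
α = (s² − μ)/μ² (clipped to [1e-8, 100]), delta-method variance
(1/μ + α)/n of the log-mean, two-sided normal p, BH adjustment across
tested genes.  It is an approximation standing in for a full
shrinkage-based NB framework (out of scope); null simulations in the
test suite show its raw type-I error at ~0.04 at nominal 0.05 under
the generator's conditions, and BH keeps the realized FDR under 0.10.

*Length-bin curve*: stable sort by annotated length, consecutive bins
of 200 genes (last bin smaller), arithmetic mean log2FC and mean length
per bin.  `long_gene_summary` reports mean length of significantly
downregulated genes (adj p < 0.05, log2FC < 0) vs all tested genes.

## CNV pipeline

*Normalization* fixes every cell's autosome-wide mean at copy 2; this
slightly compresses absolute copy states when events occupy a
non-negligible genome fraction (a 4% genome-wide event pulls a 3-copy
region to ~2.94), which is immaterial for thresholding but explains
small systematic offsets in segment means.  An optional cohort-median
per-bin correction removes recurrent amplification bias.

*CBS*: per chromosome, the arc (i, j] maximizing
`|mean_in − mean_out| / (σ̂·sqrt(1/k + 1/(n−k)))` is tested by permuting
bin order within the segment; the split is accepted when
`(1 + #{perm max ≥ observed}) / (1 + n_perm) < α` (α = 0.001,
n_perm = 1000, matching the study's segmentation settings; undo.SD = 0
disables merge-back).  Permutations stop early once the p-value can no
longer fall below α — decisions are identical to the full computation.
Minimum width 5 bins is enforced for the arc, its circular complement
and any nonempty linear flank, so all resulting segments obey it.  Ties
in the arg-max (an arc and its complement score identically) break to
the smallest (i, j).  Abutting same-type threshold crossings are merged
into one call.

*Mixture thresholds*: a K ≤ 3 component 1-D Gaussian mixture (EM,
k-means init, 10 restarts, tol 1e-8, ≤500 iterations) over segment
means replicated by bin count (length weighting — long segments should
dominate the neutral component).  The neutral component is the one with
mean nearest 2; deletion/duplication cut-points are the
density-intersection roots between the neutral and flanking components.
A flank counts as genuine only when its mean is ≥0.5 copies from the
neutral mean (i.e. nearer the adjacent integer state); otherwise the
fallback is pooled-neutral mean ∓ 2.5 pooled-neutral SD, where the pool
merges all components inside the 0.5 window — EM sometimes splits the
neutral mass into two narrow components, and using a single narrowed SD
would place the fallback inside the neutral spread.  With no genuine
flank on one side (e.g. a cohort containing only deletions) the
fallback threshold on that side is intentionally conservative but can
still flag strong outlier segments; fixed thresholds (e.g. the study's
1.22/2.82) can always be supplied directly to `call_cnvs`.

*Per-cell QC*: each cell is scored against a "clean" reference model —
bins Gaussian around the integer-rounded copy state of their segment
with the cohort-median residual variance —

    score = 1 + ln(v_cell / v_ref) − SS_int / (n·v_ref),

a per-bin BIC difference that is ≈0 for well-behaved integer-copy cells
and strongly negative for excess amplification noise or off-integer
segment means; cells with score > −1.5 are kept.  The exact score used
in the original quality control is not public; this is the package's
own construction with the same interface and cutoff convention, and its
absolute scale should not be compared against other implementations.

*Filters*: a hotspot is a maximal union of overlapping call footprints
(pooled over cells and call types) overlapped by ≥6 calls; calls lying
entirely inside a hotspot are removed, then calls shorter than 5 Mb.
Both filters are idempotent.

*Coordinates*: 0-based half-open bp internally and in BED output; the
call writer can emit 1-based inclusive starts behind a flag.  Only
autosomes are modelled — sex chromosomes would need a ploidy convention
the pipeline deliberately avoids.

## smFISH quantification

Objects are connected components (8-connectivity) above an intensity
threshold, optionally split by distance-transform watershed.  A spot is
a single transcript when its area ≤ 1.5 × the section's median spot
area; the per-cell transcript estimate is

    transcripts = singles + cluster_area / mean_single_area,

i.e. clusters contribute their area in single-spot equivalents.  The
printed form of this formula ("number of clusters divided by the
average area of singles") is dimensionally inconsistent; the area-based
reading is the standard smFISH convention and the literal one is kept
behind a `literal=True` flag for comparison.  Gating is inclusive
(≥5 Neurod6 transcripts).  Sections with no single spots have an
undefined cluster term and are excluded with a NaN.  Spot assignment is
nearest-cell within a radius, ties to the smallest cell id.  All units
are pixels.

## Foci counting

`find_maxima` reproduces prominence semantics: flood regions grow from
the top down and merge at saddles; a region's peak is reported iff
peak − saddle > tolerance (the global maximum is always reported;
constant images yield none).  Flood regions and plateaus use
8-connectivity; a plateau contributes one point at its first pixel in
row-major order; edge pixels are eligible; tolerance is in intensity
units of the input.  Counts per nucleus divide the summed binary point
map (255 per point) inside the mask by 255.  Percent-positive summaries
aggregate per animal before testing (n = animals), matching how such
quantifications are reported.

## Statistics layer

Summary-statistic t-tests recover SD = SEM·√n; the pooled variant
reproduces the published foci comparison (p = 0.008) and is the
default, since Welch on those summaries gives a different value.
Fisher's exact test is two-sided by summing hypergeometric
probabilities ≤ the observed table's.  FDR: classic BH and the
two-stage Benjamini–Krieger–Yekutieli variant.  Kaplan–Meier medians
use the smallest time with Ŝ ≤ 0.5.  Dunnett's many-to-one comparison
is computed by seeded Monte Carlo from the joint null of the correlated
t statistics (correlation √(n_i n_j / ((n_i+n0)(n_j+n0))), shared χ²
denominator); n_mc and the seed are recorded in each result, and the
test suite cross-checks against an independent implementation.

## Problem sizes and numerical conventions

The acceptance computations use: a 1,020-cell × 2,000-gene expression
run; 50 cells × 500 bins × 20 seeds (tests) or 8 seeds (script) for
end-to-end CNV recovery, with 15 implanted ≥10 Mb loci at 4% carrier
fraction each — rare enough that true events stay below the 6-call
hotspot rule, as in the real design where genuine events are not
recurrent across neurons; 150 subjects per survival arm (the median
difference of the 18/23-day preset is then estimated to ±0.2 days);
three smFISH sections of 90 cells.  The exhaustive prominence
equivalence runs over every 3×3 image with values in {0,1,2} plus
seeded random 4×4 and 8×8 batches, and Fisher's test is enumerated for
all 2×2 tables with total count ≤ 30.

Degenerate inputs are errors, not silent results: empty QC output,
zero-total cells, zero-subject survival groups, thresholds outside an
image's range, non-binary point maps.  Known limitations: the DE test
lacks dispersion shrinkage and will be anti-conservative for very small
groups; CBS recursion with the renormalized baseline can call strong
neutral-region fluctuations when one event sign is absent (see the
mixture fallback note); the generators' noise models are intentionally
simple, so test results bound correctness of the algorithms, not their
behavior on raw instrument data.
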