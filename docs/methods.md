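# Methods

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open (BED convention). The
`chrN-start-end` id strings used in candidate reports are 1-based
inclusive display coordinates; `parse_region_id`/`Region.id` are the only
bridge (`start_internal = start_display − 1`), so the off-by-one cannot
drift. An id whose two integers satisfy `start ≥ end` is rejected as
degenerate — a consequence is that a 1-bp region formats to an id that
will not re-parse; such regions do not occur in practice.

Overlap means ≥ 1 shared base; there is no minimum-fraction option.
`intersect` returns the overlap fragments of the two merged base sets
(bookended fragments fused), which is also the default semantics of
`consensus_peaks`; an alternative mode returning full first-replicate
peaks that touch the second replicate is available
(`consensus_peaks(..., mode="rep1")`) but is not the default, because
fragment semantics is the common default of genome-arithmetic tools and
is symmetric in the replicates' base sets.

`shuffle_match` draws length-matched negatives by rejection sampling: a
chromosome is chosen with probability proportional to its length, a start
uniformly over the admissible range, and the draw is rejected while it
overlaps an exclusion region, up to `max_attempts = 1000` per template
(then a `PlacementError` names the offending length). Placements may land
on any chromosome and may overlap each other — only the exclusion set is
avoided — mirroring the behaviour of a plain genome shuffle with an
exclusion file. Determinism comes entirely from the caller-supplied
generator; tests verify the exact conservation of the length multiset,
zero exclusion overlaps across 100 seeds, and uniformity of placements
over the enumerated admissible space (chi-square p > 0.01).

### Nearest-TSS annotation

The distance of a region to a gene is signed and strand-aware: 0 when the
region contains the TSS, otherwise measured from the TSS to the nearest
region boundary, negative when the region lies upstream of the TSS on the
gene's strand. The nearest gene minimises |distance|; ties break on
smaller |distance| then lexicographic symbol — determinism is preferred
over matching any particular annotation tool's unspecified tie-break.
Location categories: `Promoter` when the region overlaps the TSS ± 1000 bp
window (a promoter-window region that does not contain the TSS keeps its
nonzero distance); else `exon i of n` / `intron i of n` when exon
structure is available and the region midpoint falls in the gene body,
numbered 5′→3′ on the gene's strand; else `Distal Intergenic`. UTR calls
would require annotated UTR sub-features and are never emitted without
them. The anchor (nearest edge rather than region start or midpoint) is a
recorded choice; annotation tools differ here and no option is exposed in
v1.

## Feature matrix

Binary columns: region overlaps ≥ 1 peak of the track. Coverage columns:
base-pair-weighted sums, Σ value × overlapped-bases over the track's
intervals — chosen over a per-interval value sum because it is invariant
to re-segmentation of the same piecewise signal. Rows are positives then
negatives; columns are the peak block then the coverage block, in library
order.

## The penalised logistic ensemble

The solver minimises mean negative log-likelihood + λ‖β‖₁ with the
intercept unpenalised, on columns standardised to zero mean/unit variance
(population variance) over the data being fitted; binary columns are
standardised too, and zero-variance columns are inert. Coefficients are
reported on the original scale. The algorithm is IRLS around cyclic
coordinate descent with soft-thresholding (weights floored at 1e-5),
warm-started along the path; convergence is declared at relative objective
change ≤ 1e-8 (inner sweeps stop at max weighted squared coordinate change
< 1e-10), with a 1e5-sweep safety cap. The hot loop is compiled with
numba. λ_max is computed from the null model and inflated by a relative
1e-10 so the all-zero solution is strictly optimal at the grid top
regardless of floating-point summation order; the grid is 100 geometric
points down to λ_max · 1e-4. KKT subgradient conditions at the solution
are tested directly, as is exact agreement of the λ = 0 fit with a
general-purpose optimizer.

Cross-validation uses stratified K = 10 folds (per-fold standardisation,
grid fixed from the full training portion) and picks the λ minimising mean
held-out binomial deviance — the minimum-deviance rule rather than the
one-standard-error rule, since the target is the *best* regularisation
parameter rather than the sparsest acceptable model. Whether the original
workflow stratified its folds and split is not documented anywhere we
could rely on; stratification is used because it only reduces variance
for a balanced design. Along each path, once the fit explains 99.9 % of
the null deviance the remaining smaller penalties reuse the current
solution: on separable data the unpenalised tail diverges without
changing predictions, and the early exit mirrors what path-fitting
packages do.

Training (`train_once`): negatives are shuffled fresh (avoiding positives
∪ blacklist), the 80/20 split is stratified by label, CV and the final
fit see only the training portion, accuracy is the fraction of test
regions whose strictly-thresholded score equals the label. The ensemble
(`ensemble_predict`) runs R = 10 such rounds on independent substreams
spawned from one seed; the score is the exact arithmetic mean over
repeats and the enhancer call is `mean > τ` with τ = 0.5 — strictly, so a
score of exactly 0.5 is not called.

## Discovery stage

A differential region is trusted when the primary caller's region
overlaps ≥ 1 region of the confirming caller with the same direction;
coordinates are kept from the primary caller. "Differentially expressed
by both methods" means significant in both tables *and* concordant log2FC
sign — the sign condition prevents merging contradictory calls. Marker
intersection is by exact nearest-gene symbol (whitespace-stripped,
case-sensitive, no alias resolution). A candidate whose gene has no
expression row is reported as "not expressed". Multiple regions mapping
to the same gene are all retained. Reports sort by score descending
(ties: coordinates) once scores are attached, by coordinates before;
percentages round to the nearest integer.

## Synthetic data

Generators are pure functions of `SimulationConfig`; each derives its own
substream by hashing (seed, generator name), so outputs are byte-stable
and adding a generator never perturbs the others. Defaults are the
benchmark conditions: a 2 × 25 Mb genome, 500 planted non-overlapping
enhancers of 500–2000 bp, 20 informative tracks covering each enhancer
with probability 0.9 (peak centred on the enhancer, ±200 bp jitter), 20
noise tracks at the 0.05 background rate, background peaks in
enhancer-free 1 kb windows at 0.05/window, and coverage tracks of
Gamma(4, ¼) 200-bp bins (mean 1) scaled five-fold over enhancers — so an
enhancer's track-overlap probability is exactly the track's foreground
rate, which the binomial-CI tests rely on. Differential tables plant
confirmed/flipped/orphan classes (60/20/20 by default) on a fixed grid;
gene annotations anchor one gene 2–20 kb from each enhancer, place fillers
uniformly, and record the true nearest gene by brute-force scan over the
realised TSS layout. The DEG model gives markers log2FC ~ N(3, 1), all
significant; non-markers N(0, 1) with 10 % significance.

What the simulation does *not* emulate: sequence content and motifs,
fragment-size structure, replicate structure, peak-caller artefacts,
correlated tracks, and chromosome-scale heterogeneity. Passing the
parameter-recovery benchmark therefore demonstrates that the estimator
recovers planted signal under its own assumptions — not performance on
real chromatin data.

## Benchmark and problem sizes

The parameter-recovery benchmark trains on 500 planted enhancers and
scores 500 held-out enhancers plus 500 held-out matched negatives; with
the default signal (p_fg 0.9 vs 0.05, five-fold coverage gain) the
10-repeat ensemble reaches AUROC ≈ 1.0, mean test accuracy ≈ 1.0, and
selects no noise tracks at λ*. The test suite exercises the same machinery
at smaller sizes (tens to hundreds of regions, 5–10 tracks, 30–50-point
grids) chosen so each property is still informative: e.g. the null
(all-noise) accuracy check uses 695 positives so the 20 % test split has
278 regions, giving a tight binomial band around 0.5.

## Known limitations

* One assembly at a time; no liftover, no strand-aware interval algebra
  beyond TSS distance signs.
* The solver targets dense, modest-width design matrices (p up to a few
  hundred); there is no sparse-matrix path.
* Probability calibration of the ensemble score is not attempted; the 0.5
  threshold is a convention, not an optimised operating point.
* `consensus_degs` ignores effect sizes beyond the sign; no shrinkage or
  meta-analysis across the two methods.
* The packaged candidate tables are transcriptions of published summary
  tables and carry their rounding.
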