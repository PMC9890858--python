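# Methods

This note records the models, conventions and design choices behind
`rootarch`, in the order data flows through the pipeline.

## Image model and binarization

Scans are grayscale images of washed root systems on a black
background, so roots are bright on dark and a single global threshold
separates the network.  `binarize` defaults to Otsu's threshold with a
fixed-threshold override for difficult scans.  Connected components
(8-connectivity everywhere — components, perimeter and sweep runs use
one convention so skeleton and boundary bookkeeping cannot diverge)
smaller than a speckle floor are removed; the floor defaults to 50 px
at 300 dpi and scales with the square of the resolution.  Binarization
is idempotent on its own output, and raising a fixed threshold never
adds foreground.

Physical scale is explicit: masks carry pixels-per-cm, read from dpi
metadata or supplied by the caller, and every trait is reported in
cm-based units.

## Trait extraction

The skeleton is a topology-preserving thinning
(`skimage.morphology.skeletonize`); the local root radius at each
skeleton pixel is the Euclidean distance transform of the mask — the
medial-axis radius.  With `s` the pixel size in cm:

* NeA = foreground count × s²; NeP = count of foreground pixels with a
  background 8-neighbour × s (image border counts as background);
  NeL = skeleton pixel count × s; ARW = mean of 2·radius over skeleton
  pixels × s; NeSA = Σ 2π·radius s²; NeV = Σ π·radius² s³.
* NeD and NeW are inclusive pixel extents ((last − first + 1) × s).
* NeCA is the pixel count of the filled convex hull × s² — a pixel
  count like the other area traits, which also makes the rectangle
  fixture exact.  Note the half-pixel boundary layer makes hull areas
  of *small* shapes read a few percent high; oracles in the tests use
  shapes large enough that this digitization stays below 2%.
* MaEA/MiEA are the full axis lengths (4·√eigenvalue of the pixel
  coordinate covariance) of the second-central-moments ellipse — the
  standard image-moments convention, stable on ramified shapes, rather
  than the minimum enclosing ellipse.  Single-pixel networks get
  MiEA = 0 with a degeneracy flag instead of an exception.
* The line sweep counts, per image row between the network's uppermost
  and lowermost pixel, maximal runs of consecutive skeleton pixels, so
  a thick root crosses a row once (a mask-based sweep is available via
  `sweep_source="mask"`).  Restricting to the network's own vertical
  extent keeps the median count from being diluted by empty rows.
  MaNR is the nearest-rank 84th percentile (the ⌈0.84·n⌉-th smallest
  count — reproducible without interpolation ambiguity; linear
  interpolation is selectable), MeNR the median, NeB their ratio.
* NeLD is the fraction of all network pixels (not skeleton pixels) at
  depth ≥ top + depth/3, i.e. in the lower two-thirds of the network's
  own extent, not of the image.
* Ratios are exact: NeS = NeA/NeCA, SRL = NeL/NeV, EAR = MiEA/MaEA,
  NeWDR = NeW/NeD, SRR = SDW/RDW (shoot over root).  Zero denominators
  yield NaN plus a flag so batch runs continue.

### Skeleton length conventions

The default NeL counts skeleton pixels × pixel size, mirroring the
convention of the original extraction tool.  Pixel counting measures a
digital curve in the chessboard metric and therefore underestimates
oblique centerlines by up to 29% at 45°.  For comparisons against
continuous ground truth the package provides
`length_method="corrected"`: each straight (4-neighbour) skeleton link
is weighted 0.948 and each diagonal link 1.340 — the calibrated
chain-code length estimator, unbiased over line orientations (raw
1/√2-weighting would overestimate oblique lines by up to ~8%).  Its
residual orientation-dependent error is within about ±5%, worst at
exactly 0° and 45°.  The synthetic-recovery validation uses the
corrected estimator, since there the target is the true centerline
length; trait tables default to the pixel convention.

## Synthetic root networks

The growth model is a recursive straight-segment random walk: 0.1 cm
segments whose heading (radians from vertical-down) is perturbed per
step by Gaussian noise scaled by a tortuosity parameter and relaxed at
a tropic pull rate (default 0.6/cm) toward a target course — primaries
toward their fanned initial heading, laterals toward vertical
(gravitropism).  The pull matters: without it the random walk lets
roots wander and cross at shallow angles; overlapping roots rasterize
into fused masks whose shared skeleton under-measures total length by
up to ~12%, which is a property of the scene, not an extraction error.
With the pull, centerline recovery on whole root systems is within 5%
per image (mean ≈ 1–3%).

Laterals spawn along each primary as a Poisson process
(`lateral_rate_per_cm`), leave at ±60° ± noise from the parent's local
heading, and draw their length from a normal distribution (clamped
positive).  All roots trace back to a single crown point at the top
edge.  Growth stops at the rhizotron bounds; ground truth (total
centerline length, lateral count, maximum depth, radius) is summed
over the segments actually generated, so truncation keeps truth exact.

The three default archetypes span the small/medium/large gradient
(2/3/4 primaries, 6/10/14 cm depth, 1.2/2.0/2.8 laterals per cm,
1.0/1.5/2.0 cm lateral length); root radius is 0.018 cm (a fine-root
of ~0.36 mm width) and the rhizotron window is 24 × 22 cm.  Images
default to 0.02 cm/px (50 px/cm) rather than scanner resolution —
extraction behaves identically and tests stay fast; the tests and the
acceptance script run 10-genotype batches (40 images) at this scale.

Rasterization marks a pixel foreground when its center lies within the
root radius of the continuous centerline (exact point-to-segment
distances), and always marks the digitized centerline so sub-pixel
roots stay connected.  An earlier distance-transform variant quantized
stroke widths to odd pixel counts, a ±1 px bias visible in the
stadium-area check; the exact form is unbiased at generic alignments.

Per-plant dry weights derive from the true root volume at a dry tissue
density of 0.034 g/cm³ with lognormal noise, and shoots at 2.5× root
weight — magnitudes matching the reference experiment.

## Synthetic trait tables

Statistical validation bypasses images.  For each trait,

value = μ + shift·1[LP] + σ·(g + ge + gr + ger),

with independent normal components at the configured variances — the
additive decomposition assumed by the heritability formula.  In
single-latent mode (used for recovery tests) the four variances come
straight from the config.  In full-table mode each of the 22 traits
uses the published means, LP shifts, standard deviations and
heritabilities of the reference experiment; the heritability fixes the
variance split via σge = σgr = σger = c with total unit variance.

The genotype effect carries the planted rooting-type structure:

g_i,t = √σg · ( sep · λ_t · offset_i + 0.45 λ_t S_i + √(1 − (0.45 λ_t)²) e_i,t ),

where offset ∈ {−1, 0, +1} by planted type (proportions 25.5 / 46 /
28.5% small/medium/large), S is a shared within-type size factor, e is
trait-idiosyncratic, and λ_t is the trait's size loading.  Var(g) = σg
exactly for any loading when the separation is zero, and adjacent type
centroids sit `type_separation` (default 3) × λ_t within-type standard
deviations apart in each trait.  Loadings follow the reported
correlation structure: the ten strongly intercorrelated size/extent/
count traits load 0.95, dry weights 0.90, MaEA/NeD 0.85, and the
traits that run against system size load negatively (ARW −0.50,
NeB −0.40, NeLD −0.55, NeS −0.60, SRL −0.55).  Splitting within-type
variation between one shared factor and independent per-trait parts is
what lets a 3-s.d. planted separation be recoverable (the idiosyncratic
parts average out across traits) while the between-type and shared
components still put >50% of variance on Dim1.

What the generator does **not** emulate: real scans' illumination
gradients, touching/overlapping plants, root hairs (absent from the
trait definitions by design), genotype-specific G×E response shapes,
or the environmental instability that made nearly half the real
genotypes change rooting type between treatments — simulated types are
stable across HP/LP by construction, so transition percentages from
synthetic data characterize the machinery, not the biology.  Passing
tests therefore demonstrate correctness of the computations, not
field-scale effect sizes.

## ANOVA, variance components, heritability

The design is fully crossed and balanced with one plant per G×E×R
cell.  Because the second replication was grown months after the
first, replication is treated like a "year" effect and no within-cell
error term exists; the three-way interaction is the bottom stratum,
and E, G and G×E are tested against MS(G×E×R).  This is the only
defensible error term for this design; on real data the choice of
error stratum may shift significance patterns relative to other
analyses of the same design.  Under a zero-effect model these F-tests
are exactly calibrated (verified by KS uniformity of p-values over
1000 simulated tables).

Sums of squares use the closed-form balanced decomposition from
marginal means (cross-checked against a saturated OLS ANOVA).
Variance components solve the expected-mean-square equations

E[MS_GER] = σ²ger, E[MS_GE] = σ²ger + nR σ²ge,
E[MS_GR] = σ²ger + nE σ²gr,
E[MS_G] = σ²ger + nR σ²ge + nE σ²gr + nE·nR σ²g,

with negative solutions truncated to zero and flagged.  Heritability
uses the fixed divisors 2/2/4 of the two-environment two-replication
design (`heritability_general` accepts other designs).  Because no
residual variance is subtracted, these h² values are comparative
within a study, not absolute genetic parameters; truncation also
biases estimates slightly upward near h² = 0.  No multiple-testing
correction is applied across traits — stars are per-trait, as in the
reference analysis.

Correlations are Pearson r between z-score standardized genotype means
(mean over replications), HP and LP trait columns jointly, with stars
at 0.05/0.01/0.001 and NA for constant columns.

## Classification

Within each environment, genotype trait means are z-scored
(constant columns dropped with a warning), decomposed by PCA (Dim1
oriented so NeL loads non-negatively; variance percentages over all
components sum to 100), and clustered by hierarchical agglomeration on
Euclidean distances.  Two open choices were measured rather than
assumed:

* **Clustering basis.** The tree is built on the genotype scores of
  the first two principal components by default (`cluster_on="pca"`),
  matching the PCA-based classification procedure the reference
  workflow follows; clustering the full z-matrix is available
  (`cluster_on="traits"`).  Euclidean distances are rotation
  invariant, so full-z clustering equals clustering on *all* PC
  scores; truncating to the leading components denoises.  On planted
  three-type populations, full-z clustering misses the ARI ≥ 0.8 bar
  in roughly 1 in 12 runs; two-component clustering did not miss in 24
  measured runs.
* **Linkage.** Ward by default — it recovers size-gradient groups most
  reliably on the same benchmark; complete (the classical default of
  the cited clustering routine), average and single are selectable.

The k = 3 clusters are ranked by mean z-score over the size-category
traits NeA, NeL, NeP, NeSA, NeV — ARW is excluded because mean root
width anti-correlates with the rest of the size block — and labelled
small/medium/large; ties break by mean NeL, then cluster id.
Transitions compare each genotype's HP and LP labels: a 3×3
row-normalized percentage matrix plus the same/one-step/two-step
partition of all genotypes.  Dendrograms serialize to Newick with
branch lengths from merge heights and children in canonical order
(sorted by smallest leaf name), so the serialization is invariant to
input row order on tie-free data; `plot_tanglegram` renders the
side-by-side view with connecting lines.

## Determinism and numerical conventions

Every stochastic step takes an explicit seed; the pipeline derives
per-plant seeds from the run seed, and two runs with the same config
produce byte-identical CSV/JSON outputs (verified by SHA-256 digests
recorded in the run report).  Cluster ids are renumbered in order of
first appearance; percentile ranks use nearest-rank; degenerate inputs
(single-pixel networks, zero denominators, constant columns) produce
flagged missing values rather than exceptions so batch runs continue.

## Problem sizes used in validation

Analytic fixtures are ≤400×400 px.  Image-recovery checks use 40
root systems (10 genotypes × 2 treatments × 2 replications) at 50
px/cm; heritability recovery uses 100 simulations per truth at 200
genotypes; null calibration uses 1000 tables at 50 genotypes;
classification recovery uses the full 200-genotype design.  The whole
test suite runs in about a minute on one CPU.

## Known limitations

* Pixel-count NeL (the default) is a chessboard-metric length; use the
  corrected estimator when absolute lengths matter.
* The medial-axis radius quantizes at coarse resolutions (a 0.36 mm
  root is ~1 px at 50 px/cm), so ARW/NeSA/NeV from low-resolution
  synthetic images are conventions, not calibrated absolutes.
* Heavily overlapping root systems fuse in 2D masks; all mask-based
  tools share this limit, and the trait values then describe the
  visible network, not the underlying plant.
* REML estimation for unbalanced designs is out of scope; the balanced
  method-of-moments estimator errors out on incomplete designs rather
  than silently dropping cells.
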