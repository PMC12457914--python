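# Methods

This note records the models, conventions and parameter choices behind
`hullscape`, and what the synthetic-data tests do and do not establish
about real plate photographs.

## Imaging

**White balance.** The plate background is assumed near-white and to cover
a substantial part of the frame. Pixels with luminance ≥ 140 (of 255) are
background candidates; if they are under 5 % of the image the plate is
rejected as having no usable white reference. The white estimate is the
mean RGB of the brightest quartile of the candidates, and each channel is
scaled by `mean(white)/white_c` (a diagonal von-Kries map), so the
background maps to a neutral grey of unchanged luminance. This is a
deliberately simple neutralizing map: downstream analysis only needs
colours to be comparable across plates, not colorimetrically exact.

**Segmentation.** Foreground is luminance below a local mean (block size
51 px, odd, configurable) minus an offset C = 5. The local-mean window
must exceed the typical nut diameter fraction at which nut interiors
disappear; interior holes are filled morphologically. Connected components
use 8-connectivity so thin diagonal structures (the nut tip) stay attached
to the body. Components touching the border (plate rim, clipped nuts) are
discarded, as are components below 0.05 % of the image area. Nuts are
labelled 1..N by centroid row, ties by column — matching the convention of
reading a plate top-to-bottom. Contours are Douglas-Peucker simplified at
0.5 % of perimeter; the pixel ensemble itself comes from the label mask,
so every retained pixel belongs to exactly one nut.

## Tip geometry

PCA of the (x, y) ensemble gives the centre (coordinate mean) and axes
(covariance eigenvectors). Semi-axis lengths are reported as 2·√eigenvalue
— an internal convention; only the axis direction matters downstream. In
the rotated frame the min-x and max-x pixels are the two extremes; the tip
is the one farther from the centre. Exact ties (ideal discs) resolve to
the larger rotated |x|, then the smaller original y, and are logged.
Distance ranks are assigned by stable sort, so equal distances keep
row-major pixel order — this makes the k% region partitions deterministic.
Tip detection is rotation/translation-invariant to within a pixel, which
the test suite checks by rigidly transforming ensembles.

## Colour palette

Pooled reference-nut pixels are subsampled to 2000 per nut (hierarchical
clustering is O(n²) in memory; 10 nuts × 2000 px is comfortably tractable
while leaving centroid estimates tight), then clustered with Euclidean
distance and Ward-D2 linkage and cut at 9 clusters. The minimum-luminance
cluster is the black background/edge cluster (code 0); the remaining 8 are
re-indexed 1..8 by *descending* centroid luminance. The luminance ordering
is this package's convention to make colour codes stable across runs — the
original study's codes came from its tree layout, and no fixed mapping
between the two code sets exists without that tree.

Pixel classification is nearest-*centroid* by default, with ties to the
lower id. A nearest-member mode (distance to the stored member sample) is
available behind a flag, since a cluster is in principle the collection of
its member colours; over large member sets that mode is quadratic, and on
well-separated palettes the two agree.

## Features and categorization

Background-classified pixels are removed *before* regions are carved, so
all 7 regions are fractions of hull pixels. The closest-k set is ranks
1..⌈k n/100⌉ and the farthest-k set the top ⌈k n/100⌉ ranks. With the
ceiling on both sides, closest-k ∪ farthest-(100−k) always covers the
ensemble, and the two sets are exactly disjoint whenever k·n/100 is an
integer (at fractional boundaries they share one rank). Feature columns
are fixed and versioned in the file header: regions in the order full,
tip-closest-30/50/70, tip-farthest-30/50/70, colours 1..8 within each.

The variability filter keeps features with sample SD ≥ 0.01 (ddof = 1);
constant columns typically flag the absence of a colour at that time
point. Binarization is at the per-feature median by default (fixed cutoffs
are accepted per feature); values exactly on the cutoff go to category 0 —
the "smaller or larger" rule leaves the equality case open, and this
choice is documented and configurable. Order-2 variables are the joint
cells {00, 01, 10, 11} of two binarized features; empty cells are skipped.

## CEDA ensemble screening

Entropies are natural-log Shannon entropies of a row's conditional
(blank, filled) distribution; this reproduces every printed reference
entropy, while base-2 does not. Two printed values carry last-digit slips:
(1, 44) is printed 0.10656 where the value is 0.1065660 (truncation), and
(19, 26) is printed 0.68098 where the value is 0.6809991. The package
computes the exact values. Odds are blank/filled counts, +∞ when the
filled count is zero.

Both ensembles resample each column as a multinomial with the observed
column total: the alternative uses the within-column row proportions
(keeping the observed association, including structural zeros), the null
uses the marginal row proportions (independence). M defaults to 1000
tables per ensemble. The overlap of a row statistic's two distributions is
computed on a shared 50-bin equal-width grid over the joint finite range;
+∞ odds occupy a dedicated overflow bin shared by both samples, and a
joint point mass counts as full overlap. Degenerate simulated rows (zero
row sum, possible under the null at tiny margins) contribute statistic 0.
The overlap is symmetric, lies in [0, 1] and is invariant under a common
affine map of both samples (property-tested).

The default statistic is odds — its ensemble distributions are more
bell-shaped and stable than entropy's, whose logarithm compresses the
upper range — with entropy retained for comparison. τ is a required,
logged parameter defaulting to 0.1; the reference analyses themselves used
0.1–0.3 depending on the time point, so no single value is canonical.
Because M and the binning behind the published overlap areas are unstated,
overlap targets are treated as Monte-Carlo estimates: single-run values at
M = 1000 have SD ≈ 0.005, so reported estimates average 10 replicate
streams. No multiple-testing correction is applied across the 1540 pairs;
the per-category overlap threshold is the only control, by design.

## Landscapes

The binary major-category × nut matrix is clustered on both axes with
plain Euclidean distance and Ward-D2 (scipy's `ward` on raw observations
follows the squared-distance ward.D2 update). All tie-breaks are by id, so
heatmaps, Newick exports and K-NN profiles are deterministic. K = 10
nearest-neighbour profiles are computed by exhaustive distance scan (n is
at most a few hundred). Branch blank rates at any dendrogram cut satisfy
the conservation identity — the size-weighted overall rate equals the
global blank fraction — which the tests assert for several cuts.

## Growth-stage determination

The admission test is the operational core: candidate z admits query x iff
d(x, z) ≤ r_K(z), z's own K-th-NN radius. OddsG is the maximum of
|N[z] ∩ CandiG|/K over admitting candidates, 0 if none admit. The
admission gate is required: a bare argmax over candidates is always
positive for a nonempty candidate set and could never flag outliers.
|N[z]| is fixed at K (the neighbourhood is defined by the same Euclidean
metric as the candidate search). Stage patterns are matched with tolerance
tol = 0.2: entries ≤ tol read as 0, ≥ 1−tol as 1, anything between as the
δ of a between-stage pattern; δ itself is qualitative, so tol is a free,
configurable parameter. Blank-prevalence annotation uses the nearest
*admitting* neighbour's branch rate; queries admitted by no candidate are
reported as outliers and excluded from the mean, never silently dropped.

## Synthetic data

The generator renders elliptical nuts with a blunt protruding tip wedge
(minimum half-width ~1.6 px so the wedge rasterizes as a connected
protrusion) on a near-white canvas, colours each nut by sampling
tip-region and body mixtures over the palette's major colours (tip region
= nearest 30 % of the nut's pixels to the apex) with Gaussian RGB noise
(SD 6), and records a manifest of true centres, apices, axes and kernel
status. Blank nuts get extra tip weight on the red major colour,
emulating the red-tip association that motivates the analysis. Plates
default to 30 nuts on a 1500×2000 canvas and a 10 % blank fraction
(the CT1/CT2 study design had 9–10 blanks of 90; harvest had 21).

Planted feature tables draw each nut's high/low bin from
status-conditional probabilities and the value uniformly within the bin
half, plus clipped Gaussian jitter (SD 0.05); non-planted features are
independent uniform noise. The strong-association check plants
bin-conditional blank odds of 10:1 vs 1:10 at n = 90 (which entails ~45
blanks); under that condition detection at τ = 0.1 is 20/20 seeds with a
0 % noise false-positive rate in the packaged runs. Block landscapes place
two prototype groups on disjoint category halves with independent bit
noise.

What the synthetic data does *not* emulate: real hull texture and gloss,
shadows and uneven illumination, touching or overlapping nuts, camera
noise correlated across channels, and GDD-driven continuous colour
dynamics (each time point is a separate parameter set). Passing tests
therefore establish the correctness of the algorithms under controlled
conditions, not field robustness of segmentation or white balance.

## Problem sizes and determinism

Tests run on plates of 12–30 nuts, palettes subsampled to a few hundred
pixels per nut, and ensembles of M = 1000; the acceptance script uses the
packaged reference tables directly with 10 replicate streams per overlap.
Every stochastic component takes an explicit seed and is bit-reproducible
at a fixed seed; derived seeds are drawn from `numpy.random.default_rng`
integer streams below 2³¹.
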