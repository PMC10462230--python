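# Methods

## Problem and model

The package predicts neoadjuvant-chemotherapy response (pathological
complete response, pCR, vs residual disease, RD) for triple-negative
breast cancer from H&E-stained biopsy images in two supervised steps.

**Step 1 — tile-level histology classification.** Pathologist-drawn
polygon contours label 16 tissue classes (stroma, tumor, three TIL
compartments, PGCC, vessels, necrosis, microvessel, benign tumor, in situ
carcinoma, hemorrhage, adipocytes, apocrine and mucinous change, normal
tissue) plus background. Each region's bounding box is swept by a
non-overlapping 224×224 window on the global stride-224 grid; a tile is
retained when the polygon (holes subtracted) covers at least 90% of its
area, inclusive at equality. Tiles claimed by two regions of different
classes are an error rather than silently resolved. Tiles are
stain-normalized and deconvolved to the hematoxylin optical-density
channel, from which 80 texture features are computed. A classifier trained
under stratified 8-fold cross-validation (train on 7 folds, test on 1)
emits a per-tile probability profile over the 16 tissue classes; argmax
labels are assembled by grid position into a histology classification map.

**Step 2 — patient-level response prediction.** On each patient's map,
8-connected components of same-class cells form tile clusters; cluster
centroids (mean of member tile centers, in pixels) are graph nodes. For
every unordered pair of tissue classes a simple undirected random
geometric graph joins nodes within a Euclidean radius. Twenty features per
pair graph — texture averages, local node configuration, global
connectivity — give 120 × 20 = 2400 columns per patient. Inside every
leave-one-out fold, ReliefF ranks the columns, the top 8 are kept,
features are z-scored and a classifier outputs (p_pCR, p_RD); the larger
probability is the call. pCR is the positive class for all reported
metrics (accuracy, sensitivity, specificity, precision, F1, ROC/AUC).

## Color model

Staining follows the Beer–Lambert law in base-10 optical density,
`OD = -log10(I/255)`, `OD = C·M`, with `M` the Ruifrok–Johnston H&E stain
matrix (rows normalized to unit length; the third row is the cross product
residual). The hematoxylin channel is the least-squares concentration of
the first stain, clipped to `[0, 2]` OD and divided by 2, so white maps to
0 and saturated nuclear staining to 1. Stain normalization is the Macenko
procedure: SVD of the tissue-pixel OD cloud (pixels with any OD > β = 0.15),
stain vectors at the 1st/99th percentile angles in the dominant plane
(hematoxylin = the vector with the larger red-OD component), concentration
rescaling to the reference's 99th percentiles, reconstruction through the
reference basis, and 8-bit clamping. Tiles without tissue pixels are
returned unchanged with a flag. Normalization is idempotent to within one
intensity level on average.

## Texture feature registry (80 features)

The exact published feature list is not available, so the registry is a
reconstruction honoring the six families and the 80-feature total; it is
an ordered, named registry so an alternate budget can be swapped without
touching extraction code.

| family | features | count |
|---|---|---|
| GLCM | contrast/correlation/energy/homogeneity/entropy averaged over 4 offsets, plus the first four per offset | 5 + 16 |
| Gabor | mean and variance of response magnitude, 3 frequencies (0.1, 0.2, 0.4 cyc/px) × 4 orientations | 24 |
| LBP | normalized histogram of uniform rotation-invariant codes, P=8, R=1 | 10 |
| Tamura | coarseness, contrast, directionality | 3 |
| lower-order histogram | mean, variance, skewness, kurtosis, energy, entropy of intensity + 10 percentiles | 6 + 10 |
| higher-order histogram | the same six statistics of gradient magnitude | 6 |

Numerical conventions: GLCMs are symmetric, normalized, at distance 1 over
L = 32 gray levels; energy is the angular second moment (Σp²) so a
constant image scores 1; correlation of a constant image is defined 0.
Gabor responses are computed after mean removal so a constant image scores
0. The LBP kernel is in-package (vectorized): circle offsets are rounded
to 8 decimals so axis-aligned samples hit grid points exactly, samples are
bilinearly interpolated (floor/ceil corners, columns-then-rows grouping),
compared `>=` against the center on the 8-bit quantized image, and border
pixels with incomplete neighborhoods are excluded. Tamura coarseness is
the mean best window size 2^k (k ≤ 5) by neighborhood-average differences;
contrast is σ/α₄^¼ (0 for flat images); directionality is the sum of
squared bin masses of the 16-bin gradient-orientation histogram (≈1/16 for
isotropic texture, →1 for stripes, 0 when no gradient exceeds 1e-4).
Histogram energy/entropy use 32 bins on [0, 1]; skewness/kurtosis of a
constant sample are defined 0.

Feature filtering (fit on training data only) drops columns that are
identically zero, contain NA, or exactly duplicate an earlier column
(first in registry order wins). An exact-duplicate notion of "repetitive"
is the default; a |r| > 0.999 correlation mode would be a looser variant
but is deliberately not the default because it is not order-stable.

## Classifiers

Four models are shared by both steps: 1-nearest-neighbor; linear SVM
(C = 1, balanced class weights); RBF SVM (C = 10, γ = "scale", balanced
class weights, probabilities via Platt-calibrated decision values with
pairwise coupling); and a RUSBoost ensemble — SAMME AdaBoost over depth-8
decision trees where each round draws a class-balanced subset (every class
undersampled to the minority count, sampled by the boosting weights).
Rounds worse than chance are discarded; per-round class counts are logged
on the fitted model. Features are z-scored with training statistics only.
Training rows are put in a canonical (lexicographic) order before fitting
so that predictions are invariant to patient ordering — libsvm's internal
Platt calibration is otherwise sensitive to row order.

The stratified k-fold plan assigns each shuffled class round-robin to
folds with a rotating offset: per-class fold counts differ by at most one,
and classes thinner than k are still spread across folds (with a warning)
rather than rejected. Background participates as a 17th training class
when present; reported probability profiles renormalize over the 16 tissue
classes.

## Graph features (20 per class pair)

Texture averages (6, over nodes of degree ≥ 1 so the average reflects
interacting regions): GLCM contrast, correlation, energy, homogeneity,
LBP-histogram entropy, intensity mean — each first averaged over a
cluster's member tiles. Local node configuration (7): node count, edge
count, mean degree, degree variance, average clustering coefficient,
cross-class edge fraction, and algebraic connectivity (second-smallest
Laplacian eigenvalue) of the largest component. Global connectivity (7):
number of components, largest-component fraction, and — on the
Euclidean-weighted minimum spanning forest of the radius graph — total
length, mean edge length, edge-length variance, diameter in hops, plus the
mean nearest-neighbor centroid distance. The MST is Euclidean-weighted
(an unweighted MST is degenerate); the pair graph itself stays unweighted
for the degree-based features.

Degenerate defaults: an empty graph maps to all zeros; a single-node graph
maps to zeros except node count = 1 (by this convention its component
count reads 0). The edge radius defaults to 3 tile widths (672 px) and is
exposed as a parameter; features are translation-invariant, and MST
lengths scale linearly under uniform spatial scaling when the radius is
scaled identically.

## ReliefF and selection

Classic multi-class ReliefF with m = n (every instance), k = 10 neighbors
(clamped to class size − 1 with a warning), Manhattan differences on
range-normalized ([0, 1]) columns; miss contributions are weighted by the
class prior relative to the complement of the instance's class. Weights
lie in [−1, 1]; constant columns score exactly 0; ranking ties break by
column order. Selection granularity is the individual (pair, feature)
column — the most informative reading — and a per-pair ranking follows by
aggregation. Selection runs inside each LOO fold by default (leakage-free);
a global-selection flag reproduces the leaky alternative for comparison.

ROC curves sweep the unique predicted probabilities plus endpoints; AUC is
the trapezoid rule (cross-checked against scikit-learn in the tests).
Attention maps highlight the grid cells of every cluster that contributes
a node to a selected pair's graph, blended 50% with the highlight color
over the class-colored map render.

## Synthetic data: what it emulates, and what it does not

`make_tile` synthesizes 224×224 tiles by generating a scalar texture field
(stripes, checkerboard, filtered-noise "blobs", fine noise, or mixtures;
one distinguishable recipe per class) and mapping it to hematoxylin/eosin
concentrations through the forward Beer–Lambert model, so deconvolution
recovers the planted concentrations. `make_slide` renders axis-aligned
rectangular labeled regions onto a white canvas (default 2048×2048) and
derives the retained-tile grid analytically with 1-D overlap arithmetic,
independent of the geometry library used by the pipeline. `make_cohort`
generates map-level patients: a 32×32 label grid per patient (large enough
to host clusters of all 16 classes with meaningful spatial statistics; a
pixel-rendered canvas of that size would be 7168², which the features
under test never consume), with per-cell texture summaries drawn as class
means plus N(0, 0.02) noise.

The planted outcome signal is spatial: for the informative pairs
(tumor–tumorTIL enriched in pCR, microvessel–PGCC enriched in RD), a
partner cluster is placed near its anchor with probability
0.5 + effect·(p − 0.5) where p is 0.9 for the enriched outcome and 0.1
otherwise; inter-cluster distances follow shifted Gamma laws
(close: 0.8 + Γ(2, 0.35) tiles, far: 5 + Γ(2, 1.0)), chosen so "close"
falls inside the 3-tile edge radius and "far" outside it. All other
classes are placed identically in distribution across outcomes. Defaults
are the study conditions: 51 pCR / 34 RD, effect = 1, three anchor pairs
per informative pair, 1–3-cell clusters.

What passing tests therefore show: the pipeline recovers a genuine spatial
co-arrangement signal end-to-end (maps → clusters → graphs → ReliefF →
LOO) and its components match independent oracles. What they do not show:
performance on real slides — synthetic textures are far cleaner than
histology (no staining artifacts, no intra-class heterogeneity, no
annotation noise), regions are rectangles, and the planted effect is
stronger and purer than any biological association. The headline
cross-cohort accuracies reported for the original patient material cannot
be reproduced here because those slides are not public; the acceptance
script instead verifies the metric arithmetic from the published confusion
counts and measures the pipeline on the synthetic conditions above.

## Problem sizes and numerical choices

The test suite and acceptance script run at sizes chosen to keep a full
desk-scale run in minutes: 12 tiles per class (204 tiles) for the
tile-level CV fixture; 85-patient cohorts on 32×32 grids for patient-level
runs; 100 replicates at n = 40 patients × 200 columns for ReliefF recovery;
oracle equivalence on 8×8 images (GLCM/LBP), ≤ 7 nodes (exhaustive MST
enumeration) and 20×20 grids (flood fill). Every random draw is seeded;
generators are byte-reproducible from (spec, seed).

Known limitations: the 80-feature budget and the 20-feature graph roster
are reconstructions (documented above) rather than the original
supplementary lists; stain-normalization parameters (α = 1/99 percentiles,
β = 0.15) are the standard Macenko defaults; SVM hyperparameters were not
published and use the documented defaults; overlapping annotations of
different classes are rejected rather than resolved by precedence; and the
pipeline reads plain rasters (PNG/TIFF via imageio), not proprietary
scanner formats.
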