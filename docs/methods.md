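# Methods

`phasetrack` implements a complete analysis chain for classifying cell
phenotypes from time-lapse quantitative phase imaging (QPI):
reconstruction of off-axis holograms into dry-mass-calibrated phase
images, single-cell segmentation and tracking, per-frame feature
extraction, time-lapse feature engineering, filter feature selection,
and a 19-classifier cross-validated benchmark comparing three
representations of a cell's observation window. A built-in synthetic
generator provides ground-truthed data for every stage, so the whole
chain is testable without any external dataset.

## Phase reconstruction and dry-mass calibration

An off-axis hologram encodes the object phase φ(x, y) on a spatial
carrier: I = A_o² + A_r² + 2·A_o·A_r·cos(2π f·x + φ). Reconstruction
takes the 2-D FFT, extracts the +1 sideband with a circular window
centred on the carrier frequency (default radius 0.6 |f|; a hard window
for determinism, with optional raised-cosine apodization), demodulates
the carrier exactly (including fractional-bin components, by a complex
exponential in the image domain), and returns the argument of the
inverse transform — the wrapped phase in (−π, π]. Unwrapping uses the
standard 2-D algorithm from scikit-image; the unwrapped surface differs
from the wrapped input by exact multiples of 2π. Residual aberrations
are modelled as a polynomial compensation surface (default degree 2)
least-squares fitted on background pixels (a supplied mask, or pixels
below the Otsu threshold) and subtracted.

Phase converts to dry-mass surface density through the protein
refraction increment γ:

    ρ(x, y) = λ φ(x, y) / (2π γ)        [pg/µm²]

with λ in µm and 1 ml/g = 1 µm³/pg. Defaults: λ = 0.65 µm (the red
interference filter of the reference instrument) and γ = 0.20 ml/g, the
midpoint of the 0.18–0.21 ml/g range reported for unconjugated
proteins; both are configurable. At λ = 0.65, γ = 0.18, one radian of
phase corresponds to 0.5747 pg/µm².

Round-trip fidelity (synthesize → reconstruct → unwrap → compensate,
interior RMSE < 0.02 rad) holds for smooth phases whose gradients stay
inside the sideband bandwidth. The synthetic cells below are steep
enough (up to ~10 rad peaks over ~10 px) that the optional
hologram-and-reconstruct pipeline stage degrades their edges slightly;
it is provided for completeness, while the benchmark stages consume the
rendered phase directly.

## Synthetic time-lapse generator

The generator emulates the observable contrast between two phenotypes
in an epithelial–mesenchymal transition (EMT) experiment, observed as
30-frame windows at 5-minute intervals (the defaults; 95 + 85 cells per
run). Each cell is an elliptical profile — a centre-peaked dome
(1 − u²)², a plateau with a cosine rolloff, or a blend (the
`profile_flatness` parameter) — normalised so the integrated dry-mass
density equals the cell's total dry mass exactly on the render grid,
converted to radians through the inverse of the calibration above, plus
Gaussian phase noise (sd 0.02 rad).

Dynamics: each cell draws a start and an end morphology (footprint
area, aspect ratio, mass-profile flatness, total mass) from class
distributions and moves between them along a smoothstep ramp with a
per-cell random onset and duration. On top of the ramp, every
morphological parameter fluctuates frame to frame as a stationary AR(1)
process (relative sd 0.10, lag-1 correlation 0.2) — the morphodynamic
jitter real cells show; without it, temporal statistics such as
approximate entropy would see nothing but sensor noise, and adjacent
time points would be degenerate duplicates. Motion is a persistent
random walk (per-class step scale and persistence), confined to a
per-cell territory on a jittered grid so masks never overlap by
construction; infeasible density raises a crowding error.

Presets (the two classes differ only through these parameter sets):

- **paper-like** — epithelial cells stay rounded, compact,
  centre-peaked and sessile; mesenchymal cells elongate (aspect
  1.3 → 2.7), grow (155 → 240 µm²), flatten their mass profile and
  migrate with high persistence. Mesenchymal transition onsets are
  drawn from (−0.5, 0.7) window units with durations (1.0, 1.5), so a
  fixed 30-frame window cut from a long recording catches cells across
  the whole transition spectrum — some fully transitioned, some barely
  started — as happens in an asynchronously responding population.
- **temporal-only** — both classes draw their *final* morphology from
  identical distributions; one class sits at it throughout, the other
  ramps up to it and completes within the window. Single-frame
  marginals at the window end are matched by construction; only the
  dynamics separate the classes.
- **static-only** — constant morphologies that differ between classes,
  with identical motility and ramp parameters: a negative control in
  which temporal features can add nothing.
- **null** — identical parameters for both classes.

The generator does not emulate cell division or death, touching-cell
deformation, optical shot noise structure, or biophysically calibrated
EMT kinetics. Passing benchmarks on it therefore demonstrates that the
pipeline extracts and exploits the *kind* of signal described — not
performance on real microscope data.

## Segmentation, tracking, and ROI filtering

Foreground is thresholded on the raw compensated phase (default
0.1 rad; the threshold contour is sharp because it sits ~5 noise sigmas
above background, and smoothing first would dilate shallow footprint
tails). Markers are connected h-maxima plateaus (h = 0.3 rad) of the
σ = 2 px Gaussian-smoothed phase, and marker-controlled watershed on the
inverted smoothed phase splits touching cells. Regions under 20 px are
dropped. ROI filtering removes regions touching any image border and
regions whose solidity falls below 0.8 (a proxy for unresolved
overlaps); it is idempotent.

Linking is greedy mutual-nearest-centroid matching per consecutive
frame pair with a 20 px displacement gate; non-mutual matches (two
cells claiming one region) are rejected, unmatched regions open new
tracks, and equal distances break towards the lower label. Centroids
are unweighted binary-mask centroids, 0-based (row, col) pixel centres.
Only gap-free tracks spanning the full window (default 30 frames)
survive, trimmed to the first 30.

## Per-frame features and the multivariate series

Each (cell, frame) yields d = 16 scalar features: nine shape features —
footprint area, perimeter, convex area, convex perimeter, solidity,
roundness 4πA/P², indentation P/P_convex, eccentricity (from
normalised second central moments), extent — plus seven statistics of
the phase values inside the footprint: total, mean, median, variance,
standard deviation (population), skewness, and kurtosis (non-excess).
The centroid is carried separately and feeds only the motion features.
The perimeter estimator is the chain-code approximation from
scikit-image, which bounds roundness near (not exactly at) 1 for a
digital disk; "roundness" and "indentation" are deliberately isolated
behind named functions because their field definitions vary. A
zero-variance (or numerically near-constant) pixel population reports
skewness = kurtosis = 0 by convention so series stay complete.

A complete track becomes an n × d multivariate series (n = 30). All
transforms below act on its univariate columns.

## Time-lapse features

Per univariate series (L = 52 values):

- **statistics (7)** — mean, median, population sd, min, max, skewness,
  kurtosis;
- **FFT (5)** — magnitudes of the five lowest nonzero-frequency DFT
  coefficients of the mean-removed series. Fixed positions, not the
  largest magnitudes: largest-magnitude selection would misalign
  feature meaning across cells;
- **DWT (32)** — orthonormal Haar coefficients at level 2
  (approximation then details, coarsest first), with series zero-padded
  30 → 32 (preserves Parseval energy);
- **trend (2)** — OLS slope (per minute) and intercept against time;
- **approximate entropy (1)** — ApEn(m = 2, r = 0.2·sd), self-matches
  included (the Pincus convention); 0 for constant series;
- **SAX (5)** — the series is z-normalised, PAA-reduced to 5 segments
  (fractional-overlap weighting when the length is not divisible) and
  discretised by Gaussian equiprobable breakpoints into a 4-letter
  alphabet; symbols are emitted as integers 0–3 (ties at a breakpoint
  round up; constant series map to the middle symbol).

The d partial vectors are concatenated (d·L = 832), followed by p = 3
PCA scores of the flattened series and the four motion features —
accumulated path length, net (Euclidean) displacement, velocity
(accumulated / elapsed time), and directionality (net / accumulated,
defined as 1 for a stationary cell) — for 839 features total. The
value-based alternative concatenates the raw series columns (480
features). Feature vectors are min–max scaled to [0, 1] with statistics
from training cells only; test values are clipped and zero-range
features map to 0.

## Feature selection

Features are ranked by Welch two-sample t-test p-values (ties break by
feature order; features constant in both classes get p = 1). The
empirical CDF of the p-values summarises how much of the vector carries
signal. The retained count k is chosen by scanning k = 2…25: for each
k, the top-k features feed a five-classifier panel (tree, LDA, linear
SVM, 1-NN, small bagged-tree ensemble) under a shared stratified 5-fold
split, and the argmin of the mean error wins, ties towards smaller k.
Defaults mirror the benchmark configuration: k = 10 for the static and
feature-based representations, k = 12 for value-based.

Two protocols are provided. In **nested** mode (the default)
normalisation, ranking and the PCA block are refitted on each training
fold, so test labels never touch selection — honest generalization
estimates. In **paper** mode they are fitted once globally before
cross-validation, reproducing the common global protocol.

## Classification benchmark

The panel holds exactly 19 configurations: decision trees with at most
100/20/4 splits (`max_leaf_nodes` 101/21/5); linear and quadratic
discriminant analysis (QDA with a 10⁻³ covariance ridge — selected
features can be constant within a class, e.g. saturated SAX symbols,
and an unregularised class covariance would be singular); SVMs with
linear, quadratic, cubic and Gaussian kernels (kernel scale
√n_features); five KNN variants — fine (k=1, Euclidean), medium (k=10),
cosine (k=10), cubic-distance (k=10, Minkowski p=3), and k=10 weighted
by inverse squared Euclidean distance; four 30-learner ensembles —
bagged trees, boosted trees (AdaBoost), random-subspace LDA and
random-subspace 1-NN (subspace dimension ⌈√n_features⌉); and a
feed-forward neural network with one hidden layer of 10 logistic units
(L-BFGS, ≤ 500 iterations, seeded initialisation).

All approaches and classifiers share one seeded stratified 5-fold
partition, so per-classifier metrics are paired. Accuracy, precision,
recall and F-score come from each fold's 2×2 confusion matrix
(mesenchymal positive; empty denominators report 0) and are averaged
unweighted over folds. Approaches are compared by the two-sided
Wilcoxon signed-rank test over the 19 paired per-classifier metrics,
zero differences dropped; a pair with no nonzero differences reports
p = 1 with a note. The static approach classifies the per-frame
features of a single snapshot, by default the window's **middle**
frame: the protocol being emulated drew static images at arbitrary
transition stages, and using the window end would flatter static
classification whenever the population is still transitioning.

## Problem sizes and numerical choices

The acceptance checks run at desk scale by design: segmentation and
tracking recovery uses 40 cells × 30 frames; selection recovery uses
120 × 25 matrices over 20 seeds; the temporal-only headline comparison
uses 200 cells; the paper-like ordering is replicated over 10 seeds at
115 cells (and the benchmark report in the acceptance script at the
default 180). Benchmark-scale runs featurize from the generator's
ground-truth masks — segmentation fidelity is established by its own
recovery check, and decoupling the two keeps the classification
property attributable to the representations rather than to
segmentation quality.

Everything is deterministic under a single seed: the generator consumes
a `numpy` `Generator`, CV splits and classifiers take derived seeds,
and reports serialise floats by `repr`, so a rerun with the same
configuration is byte-identical.

Known limitations: the ApEn implementation is O(n²) per series (fine at
n = 30); SAX symbols enter classifiers as plain integers (no string
kernel); boosting flavour (AdaBoost) and ensemble sizes are fixed
choices where the emulated protocol left them unstated; and none of the
benchmarks here say anything about instrument-specific artifacts of
real holographic microscopes.
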