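# Methods

This note documents the models and procedures implemented in `hyperclass`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical conventions that a
user re-implementing or auditing the pipeline needs to know.

## Data model and flat-field correction

A hyperspectral acquisition is a band-major cube `(band, row, column)` with
an explicit wavelength grid (strictly increasing, 350–900 nm).  Raw stacks
are 16-bit unsigned counts (the emulated camera is 12-bit, values clipped
to 4095); corrected stacks are 32-bit reals.  Flat-field correction is the
per-pixel, per-band ratio `FFC = (O − D) / (F − D)`.  Pixels where
`F − D ≤ 0` in any band cannot be corrected; they are zeroed and flagged in
an `invalid` mask rather than raising, because isolated dead or noisy
sensor elements should not abort a session.  The mask propagates: invalid
pixels are excluded from cluster-model fitting and are re-labelled as
ignore (255) for classifier training and for all metrics.  Saturated
pixels receive no special treatment beyond this mask.

Band selection is exact wavelength matching with no interpolation — the
instrument acquires on a fixed grid (63 bands, 420–730 nm at 5-nm pitch)
and the analysis subset is 25 bands, 450–690 nm at 10-nm pitch.

## Spectral clustering and the cluster image

Per-pixel 25-band spectra are clustered by k-means: k-means++ seeding,
Euclidean distance over the 25 corrected values, and a **fixed 30 Lloyd
updates with no early exit** (a converged model is updated idempotently).
The cluster count is configurable; `k = 32` is the evaluation default.
Two non-standard details are part of the contract and are asserted by
tests:

- an empty cluster arising during an update is re-seeded with the point
  farthest from its assigned centroid (each point can re-seed at most one
  cluster per iteration), keeping `k` fixed;
- nearest-centroid ties resolve to the lowest cluster index.

Distances use a float32 fast path with precomputed row norms; centroid
updates accumulate in float64.  The within-cluster sum of squares recorded
at each assignment step is non-increasing (a property test).  Fitting
pools all pixels of the training images with a seeded uniform subsample
cap (10⁶ spectra) to bound memory on large image sets.

The **cluster image** maps each pixel to its cluster's *display value*:
the rank of the cluster by centroid mean intensity across the 25 bands
(rank 0 = darkest), scaled linearly to 0–255.  The mapping from "cluster
average intensity" to pixel value is not uniquely determined by the
procedure being reproduced; rank-then-scale was chosen because it is
deterministic, invariant to cluster index permutation, and keeps the
single-channel image ordinal in brightness while carrying the spectral
category.  Features are computed on this display channel, not on the
nominal cluster ids.

## Morphological features

Per scale, eight planes: raw intensity, Hessian components `Hxx, Hyy,
Hxy`, Hessian eigenvalues `λ₁ ≥ λ₂`, local standard deviation, and the
circular standard deviation of gradient orientations.  Three scales
(original, half, quarter; area-average downscale, nearest-neighbour
upsample back to full resolution) give `8 × 3 = 24` features.  The
four-family feature set and the 24-plane total are fixed by the procedure
being reproduced; its per-scale decomposition is not stated, and this
decomposition was chosen because it contains all four named families,
reaches 24 exactly, and retains the spectral-category signal through the
raw intensity plane.  The Laplacian (`Hxx + Hyy`) is available as an
operation and a configurable plane name but is linearly redundant given
the Hessian components, so it is not in the default list.

Derivatives are Gaussian-derivative filters with `σ = kernel/4` and filter
radius `kernel//2` (the named 7-px kernel).  At this small support a bare
truncated Gaussian derivative leaks low-order polynomial terms, so the tap
weights are moment-normalized (`Σw = 0`, `Σm·w` or `Σm²·w` fixed to the
derivative order), making the operators exact on polynomials up to their
order; tests pin this against central finite differences.  Borders use
reflect padding everywhere.

The circular standard deviation is `√(−2 ln R̄)` of gradient orientations
over the kernel window, with the doubled-angle convention for axial data
and gradient-magnitude weighting; `R̄` is clamped to `[10⁻⁶, 1]` (cap
≈ 5.257) and windows with zero total gradient magnitude yield 0.
Orientation (rather than some other angular quantity) is the conventional
choice for this statistic in texture analysis and is the reading adopted
here.

## Random forest with feature-difference splits

Each internal node holds one of two rule types: `fᵢ ≤ t` or
`fᵢ − fⱼ ≤ t` (left child on ≤).  The difference family realizes oblique
boundaries along `fᵢ − fⱼ = t`; a property test shows a depth-3 forest
with difference rules solving `sign(fᵢ − fⱼ)` labels that an axis-aligned
forest of equal budget cannot.  Training per node draws **exactly 400**
candidate rules ("around 400" in the source procedure; an exact count
keeps runs reproducible): type uniform over the allowed set, feature
indices uniform (distinct pair for differences), threshold uniform over
the node-local range of the rule's expression (no threshold scheme is
prescribed by the source; the node-local range is the natural
scale-free choice).  Candidates are scored by entropy reduction in bits
(parent entropy minus size-weighted child entropies); growth stops at the
depth limit (default 50), on pure or degenerate nodes, or when no
candidate achieves positive gain with both children non-empty
(`min_samples_leaf = 1` by default, exposed).  Leaves store the class
frequencies of the samples that reached them; prediction averages leaf
probabilities over the trees (default 100) and takes the argmax, ties to
the lowest class code.

Each tree trains on its own seeded bootstrap sample: with replacement,
stratified by class to preserve the pooled class shares, capped at
`per_tree_sample` pixels (default 100,000 — full-size image sets reach
~10⁸ pixels, so an explicit cap is unavoidable; the source procedure says
only "randomly sampled training data").  Ignore-labelled (255) and
invalid-FFC pixels never enter training or metrics.  The node split search
is JIT-compiled (numba) and scans the transposed feature matrix directly;
the public `propose_candidates` / `best_split` operations implement the
same semantics in plain numpy and serve as the cross-check.

Models serialize to JSON (nested node records); identical seeds and inputs
give byte-identical files.

## Evaluation

Per class: `PRE = TP/(TP+FP)`, `REC = TP/(TP+FN)` (0 when the denominator
is 0), `F_β = (1+β²)·PRE·REC/(β²·PRE+REC)` at β = 0.5 and 1, with
`F_β = 0` when both PRE and REC are 0.  Object-wise, a ground-truth object
is classified by the plurality of predicted labels over its pixels (ties
to the lowest code).  Predictions are not segmented into objects, so
object-wise precision for class c divides correctly recalled class-c
objects by all ground-truth objects with plurality label c — the one
consistent denominator available when objects exist only on the truth
side.  The external region has no objects and is excluded from object-wise
metrics and from the three-class averages.

Leave-one-out cross-validation re-fits *both* models per fold — the
cluster model and the forest see only the training images; the held-out
image is clustered with the fold's model, featurized and classified.
Aggregates are per-fold means ± s.d. (not pixel-pooled).  Per-fold seeds
derive from the pipeline seed through `SeedSequence`, so the whole report
is byte-reproducible.

## Synthetic scenes

The generator emulates the structure the classifier exploits in real
differentiated-NSC images:

- elliptical cell bodies with a **two-zone spectral structure**: a bright
  center spectrum (`N_high`, `G_high`) and a darker rim (`N_low`, `G_low`)
  of configurable width (3 px default);
- thin widened random-walk **processes** leaving each body, one combined
  class regardless of parent cell type;
- a flat external background near transmittance 1.0;
- a smooth low-order polynomial **illumination field** (default 10%
  peak-to-peak, within the 3.5–14.1% non-uniformity range observed on the
  emulated instrument), a dark offset (200 counts), a flat level
  (2400 counts, keeping the brightest signature within the 12-bit range)
  and additive Gaussian sensor noise clipped at zero (default s.d. 44
  counts = 2% of the dynamic range);
- optional ignore-label blobs to exercise masking paths.

The default signature bank satisfies the qualitative orderings reported
for the real classes: neuronal bodies contain both the brightest and the
darkest spectra; the external spectrum sits between them; the glial center
spectrum rises toward long wavelengths relative to the process spectrum.
The flat reference is built as `F = dark + illumination × (flat − dark)`,
i.e. the dark offset is an additive camera offset on top of the optical
signal, so flat-field correction cancels the illumination field exactly —
with zero noise and flat illumination the corrected spectra equal the
signature bank up to count rounding (an asserted identity).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: organelle-level texture beyond the two-zone
body, optical blur and chromatic aberration (class boundaries are
pixel-sharp), spectral mixing at edges, wavelength-dependent illumination
patterns, cell-to-cell spectral variability, and annotation noise.  The
synthetic classes are far better separated than real NSC classes, so
pipeline metrics on these scenes are ceilings that exercise correctness
and wiring, not instrument-level difficulty; the noise parameter provides
a monotone difficulty knob (a property test checks that accuracy falls as
noise rises).

## Optics QC

Hopkins two-point resolution: `R = A(σ)·λ/NA_obj` with
`σ = NA_ill/NA_obj`.  The factor table plateaus at `A = 0.82` for
`σ ≤ 0.2` — the regime of the emulated instrument (`σ = 0.14`), where the
value is pinned by the three published resolutions (0.820/1.002/1.184 µm
at 450/550/650 nm with NA 0.45) — and falls to the incoherent Rayleigh
value 0.61 by `σ = 2`; intermediate knots (0.77 at 0.5, 0.69 at 1.0, 0.63
at 1.5) are an approximate monotone reading of the Hopkins–Barham curve
and should not be treated as reference values.  Temporal fluctuation is
the per-pixel maximum deviation from the temporal mean as a percent of the
global mean at that wavelength; spatial non-uniformity is the smoothed
(5×5 median) peak-to-peak range over the mean — the underlying statistic
is not defined by the source, and this is one consistent reading.

## Problem sizes and numerical conventions

The shipped evaluation study runs leave-one-out over **6 scenes of
256 × 256 px** with `k = 32`, 50 trees, depth 25, 400 candidates and
50,000 bootstrap pixels per tree — a desk-scale configuration of the same
pipeline (the full-size design is 19 images of 2048² px with 100 trees and
depth 50); tests use still smaller scenes.  Ties break low everywhere
(cluster index, class code, first-proposed split).  Entropy uses log₂.
Counts round half-to-even via `np.rint` and clip to the 12-bit range.
All reported runs are reproducible from a single integer seed.

## Known limitations

- Object-wise precision uses ground-truth objects (see above); a
  predicted-segmentation variant would need an instance segmenter, which
  is out of scope.
- The forest offers no feature importance, out-of-bag error or pruning.
- The k-means has no automatic `k` selection and no alternative
  clusterers.
- Absolute count scales in the generator are free parameters, not
  calibrated to any instrument (the emulated camera reports arbitrary
  units).
- Hardware control (camera, tunable filter, exposure calibration) is out
  of scope; stacks are consumed from multi-page TIFF + JSON sidecars.
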