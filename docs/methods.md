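# Methods

`cellchannel` re-creates, end to end and on fully synthetic data, a
label-free single-cell classification workflow for two hematopoietic
progenitor populations (an LMPP-like, marker-negative type and a proB-like,
marker-positive type): microscopy emulation, cell segmentation, per-cell
cropping, fluorescence-marker gating, balanced trimming, CNN / SVM
classification, and dish-level cross-validated ROC/AUC evaluation.  This
note documents the model choices, the defaults, and what the synthetic
experiments can and cannot show.

## Synthetic microscopy model

Each *experiment* is a set of culture dishes; each dish contributes several
*fields* (multi-channel 2D images).  Four channel roles are rendered:

- **ph** — the segmentation channel: phase-contrast-like contrast with a
  dark cell body and a bright 2-px halo just outside the cell boundary.
- **dic**, **bf** — two auxiliary transmitted-light channels that share the
  cell's texture pattern with different gains and body offsets.
- **marker** — fluorescence of a surface-marker stain.  Per-cell total
  emission is log-normal; the log-means of the two types are separated by
  `marker_separation` (log units) with common log-sd `marker_sd`.  Emission
  is spread over the cell with a smooth radial profile, multiplied by a
  smooth illumination surface (`background_amplitude`), and scaled by a
  per-dish gain (sd 6%) drawn once per dish — the batch effect that makes
  dish-level cross-validation meaningful.

Cells are smoothed ellipses with eccentricity jitter (axis ratio U(0.75, 1)),
pixel areas N(`size_means[type]`, `size_sd`), random orientation.  Internal
texture is band-passed Gaussian noise (sigma 1.5 px) normalised to unit
standard deviation inside the cell and scaled by a base amplitude times
`1 + texture_effect` for the proB-like type.  The two types therefore differ
*only* through `size_means`, `texture_effect` and `marker_separation`; with
all three neutral the types are exchangeable in every classifier-visible
channel, which is the basis of the null-calibration tests.

Placement is rejection sampling with a 3-px clearance between bounding
circles; a configurable fraction of cells is placed as touching pairs whose
boundaries overlap by ~6 px along the line of centers.  Cells that cannot be
placed after 200 retries are counted as placement failures (an error is
raised only if fewer than half the requested cells fit).  Focal offsets are
emulated as isotropic Gaussian blur of 2 px per micron of defocus; time
points re-draw only the sensor noise (Gaussian, sd `noise_sd`).  Pixels are
16-bit unsigned with fixed gain.  All randomness derives from one seed via
`SeedSequence` spawning per dish and field, so experiments are bit
reproducible.

What the generator does **not** emulate: real DIC shear or phase-ring
optics, cell motion, division, photobleaching, debris, or out-of-band cell
sizes.  Passing tests therefore demonstrate that the *pipeline* recovers
what the generative model encodes — not that the classifiers would reach any
particular accuracy on real micrographs.

## Segmentation

The phase-contrast plane is thresholded with Otsu's method (256-bin
histogram over the min–max range; threshold at the bin center maximising
between-class variance, first maximum on ties).  Cell bodies are dark, so
the default polarity takes pixels at or below the threshold as foreground;
a `bright` polarity flag covers the opposite convention.  The mask is closed
with a radius-3 disc (the smallest element that bridges halo-induced 1–2 px
gaps), border-touching components are removed, holes are filled.  Touching
cells are split by watershed on the negated Euclidean distance transform
smoothed with a Gaussian of sigma 4 px — enough to suppress spurious EDT
peaks for cell radii of ~25–50 px implied by the area band — seeded at local
maxima with a 10-px minimum separation (one marker per plateau, first pixel
in scan order; any component left without a marker is re-seeded at its
maximum), 8-connectivity throughout.  Finally regions with area ≤ 2000 px or
≥ 8000 px are removed (both bounds exclusive; at 162.5 nm/px these are
52.81 and 211.2 µm²) and survivors are relabelled consecutively.

## Cropping and flat-fielding

The marker channel is divided, on the full field and before cropping, by a
Gaussian blur of itself with sigma 200 px.  The blur uses reflect boundaries
(avoiding a dark vignette at field edges) and is evaluated in Fourier space
on a mirror-padded field (relative error < 1e-4 against the direct separable
filter, several-fold faster at this sigma).  The divisor is floored at 1e-6
of the image mean; hitting the floor raises an error naming the pixel.

Each region yields 150×150 crops per channel plane, centered on the region
centroid rounded to the nearest pixel (robust to watershed boundary noise),
with the centroid at crop index (75, 75).  Windows are half-open, row-major,
0-based.  Cells whose window would leave the field are skipped and logged —
border clearing already removed edge-touching cells; this removes near-edge
ones without introducing padding artifacts.  Intensity crops are raw
(neighbouring cells visible; masking happens later with a fixed circle, not
the segmentation mask, so the segmentation channel cannot leak shape
information into other channels).  The contour crop contains only the
generating region's own pixels; `area_px` is the full-field pixel count of
the region.

## Marker gating

For cell *i*, `l_i` is the flattened-marker sum over pixels strictly closer
than 30 px to the crop center, and `F_i = ln(l_i / max_j l_j)` with the max
taken over the whole experiment (all dishes pooled — this yields the single
"unused" interval the gating reports; a per-dish max would produce one per
dish).  A two-component Gaussian mixture is fitted to the raw F values by EM
(k-means initialisation with fixed seed, 500 iterations cap, 1e-6
log-likelihood tolerance; raw values rather than histogram counts, which the
binned description approximates).  A cell is labelled by the component whose
posterior is ≥ 0.8 (the boundary is inclusive; only cells below 0.8 in both
components become "unused"); the high-mean component is the marker-positive
proB-like class.  The reported unused interval is located on a dense grid
(8001 points) spanning the observed F range.

## Pre-classifier transforms

Crops are masked with a circle of radius 50 px from the crop center (strict
inequality, consistent with the 30-px gating radius), each channel is scaled
so its inside-mask mean is 1 (the binary contour channel included — uniform
treatment keeps multi-channel inputs comparable; cells with non-positive
inside-mask mean are excluded), and per-dish class counts are trimmed by
uniform random choice without replacement to C* = min over (dish, type).
The trim seed is separate from the network-init seed so init-variation
experiments hold the data fixed, and trimming happens once per experiment so
every channel configuration trains and tests on identical cell sets.

## Classifiers

**CNN.**  Four 5×5 convolution layers of widths (16, 16, 32, 32), doubled to
(32, 32, 64, 64) when the input has ≥ 2 channels; ReLU after every hidden
layer; a 3×3 stride-2 max-pool after each convolution; dropout 0.1 in every
gap between layers (after each pool and after the 2000-node layer — the most
common reading of "all gaps"; not on the input); a 2000-node ReLU dense
layer; a 2-node softmax output.  Convolutions use "same" padding and pools
are valid, giving 150 → 74 → 36 → 17 → 8 and a flatten size computed
programmatically (asserted at build time).  The loss is binary cross-entropy
with the softmax probability of the proB-like node as ŷ — the only reading
consistent with a 2-node softmax.  Training: Adam (α = 1e-4, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8; an `eta = 1.0` multiplier is recorded in the config
and treated as an identity), batch 32, a stratified 10% validation split
with its own seed, early stopping after 5 consecutive epochs without a
validation-loss decrease with restoration of the best-seen state, and a
30-epoch cap.

The engine is written in NumPy with numba kernels for the convolution
passes and pooling: direct 5×5 convolution keeps the taps in registers and
streams each input row once, which on a single CPU core is several times
faster than im2col+GEMM (whose patch matrix multiplies memory traffic by
the kernel area).  Gradients are verified against scipy correlation
oracles, an einsum patch oracle, and directional finite differences.
Training is deterministic given the init and data seeds.

**SVM.**  An RBF-kernel SVM (kernel coefficient γ = 1) on the cell size
alone.  Areas are z-scored with training-fold statistics first: γ = 1 on raw
pixel counts of order 10³ would make all kernel entries effectively zero, so
the unit coefficient is only meaningful on an order-1 feature.  The
continuous decision value feeds the ROC.

## Evaluation

Validation *n* tests dish *n* and trains on the other dishes.  The AUC is
the Mann–Whitney pair statistic computed from midranks (ties get half
credit); positive class proB-like, scored by its softmax probability (CNN)
or the SVM decision value.  Unit and acceptance tests cross-check it against
exhaustive O(n²) pair counting.  A permutation utility re-draws test-set
labels within each validation to build the null distribution of the mean
AUC, and a sign-flip paired-permutation comparison is provided for
configuration contrasts; no particular significance test is hard-coded.
The grid runner evaluates channel combinations, contour-only and size-SVM
baselines, focal offsets (training and testing at the same offset), training
set sizes (nested random subsamples per seed, fixed held-out test set,
asserted by cell-id audit) and init seeds, always on the same balanced cell
set, and reports per-configuration mean AUC with between-dish and
between-seed standard deviations.

## Problem sizes in the shipped tests

The test suite and the acceptance script run the pipeline at reduced scale,
chosen once as the smallest sizes at which each phenomenon is comfortably
expressed: 1024² fields with ~35 cells each; 3 dishes × 3 fields (~300
balanced cells) for the null-calibration and strong-effect runs with an
8-epoch cap; 3 dishes × 9 fields (~540-cell training pool) for the
training-size sweep (sizes 30/80/200/450, six init seeds, 4-epoch cap);
1280² fields for segmentation recovery.  The strong-effect condition uses
size means (3200, 5200) px with texture effect 2.0.  Defaults in
`SyntheticConfig` remain at full study scale (2048² fields, ~300 cells per
field).

## Known limitations

- Synthetic optics are schematic; absolute AUC values on this data say
  nothing about real micrographs beyond the pipeline's correctness.
- The watershed seeds on the smoothed EDT (the unsmoothed variant is a
  configuration away); heavily overlapping cells (> ~30% area) are outside
  the generator's regime and untested.
- The GMM gate assumes exactly two marker populations; >2-component
  mixtures and per-dish gating are out of scope.
- Time planes share a frozen scene (no motion), so time-stacking can only
  demonstrate noise averaging, not temporal information.
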