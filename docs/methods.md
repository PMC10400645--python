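# Methods

`spintrack` measures the planar rotation of an optically trapped ellipsoidal
cell (the motivating case is a human sperm head held in optical tweezers)
from grayscale video.  The measurement chain is: region-of-interest (ROI)
extraction → binary segmentation of the cell head → ellipse fit → orientation
phase α per frame → phase unwrapping → forward-difference angular speed Ω →
summary and group-comparison statistics.  A synthetic-video generator with
exact ground truth makes every stage testable without microscopy data.

## Coordinate and angle conventions

Images use the raster convention: origin at the top-left, rows increasing
downward.  The orientation α of the fitted major axis is measured
counterclockwise from the +x (column) axis in the mathematical sense applied
to (col, −row), and lives in [0, 180) because an ellipse axis has no head or
tail.  Angles are stored in degrees throughout; radians appear only inside
the speed formula.

## Synthetic-video generator (`synthcell`)

The generator emulates what the pipeline actually consumes: a bright
elliptical head over a structured, noisy background.

* **Geometry.** Head length 4.5 µm and width 3.0 µm by default (training
  data samples length from 4–5 µm and width from 2.5–3.5 µm, the accepted
  morphological range for a human sperm head), at 0.1 µm/px.  The camera
  scale of the motivating instrument is not public; 0.1 µm/px puts a 4.5 µm
  head at 45 px, matching the apparent head size in published trap imagery,
  and is configurable.
* **Motion.** The true orientation advances deterministically by
  ω·360/fps degrees per frame (fps defaults to 163, the recording rate of
  the motivating camera); the center optionally performs a Gaussian random
  walk (`center_jitter_px`).  Truth masks are rasterized by a
  center-of-pixel inclusion test against the implicit ellipse equation, so
  ground truth is exact and oracle-checkable; the noise model never touches
  it.
* **Background.** A Gaussian point-spread surrogate (σ = 1 px) blurs the
  ellipse; the background carries 10 smooth bright blobs (amplitude up to
  0.55, i.e. overlapping the cell's intensity range) emulating out-of-focus
  debris under a high-NA oil objective, plus additive Gaussian noise
  (SD 0.05).  The blob brightness is deliberately comparable to the cell's:
  complex high-NA backgrounds are precisely the regime in which
  intensity-only segmentation breaks down and learned segmentation is
  worth its cost, and a background separable by a single threshold would
  not represent that regime.  The parameters are a visual surrogate chosen
  once — real high-NA backgrounds are not quantitatively characterized
  here, so passing tests demonstrate correct *mechanics*, not performance
  on clinical imagery.  Real data also differ in ways the
  generator does not model: no flagellum, no out-of-plane rolling, no
  intensity flicker, no diffraction rings.
* **Determinism.** Every random draw is keyed on `(seed, purpose, frame)`
  via independent `SeedSequence` streams, so identical parameters give
  bit-identical output and `render_frame(params, t)` is independent of
  rendering order.

## Learned segmentation (`segmentation`, `nn`)

The segmenter is a nested encoder–decoder (U-Net++ topology): a grid of
convolution blocks X[i,j] for i+j ≤ depth−1 in which node X[i,j] receives
all same-level predecessors X[i,0..j−1] concatenated with the upsampled
X[i+1,j−1].  Depth is 4 by default; channel widths are
`base_channels·2^i`.  The two-channel softmax head mirrors the two-class
structure of the loss.  The network, its backpropagation, and the Adam
optimiser are implemented directly on NumPy arrays (`spintrack.nn`) and are
gradient-checked against finite differences in the test suite.

**Hybrid loss.** Training minimises

    L(Y,P) = −(1/N) Σ_c Σ_n [ y_nc log p_nc + 2·(2 y_nc p_nc)/(y_nc² + p_nc²) ]

a per-pixel cross-entropy plus a per-pixel soft-Dice reward, with N the
pixel count of the batch.  The minimum is −2, attained exactly at P = Y.
The log is clamped at log(eps) and the Dice fraction defined as 0 when its
denominator is below eps (eps = 1e−7).  The Dice term here is *per pixel*
(denominator y² + p² pixelwise); the classical image-aggregated soft Dice
is available via `dice_mode="aggregated"` (normalised so a perfect
prediction is also −2).  The per-pixel form is the default because it is
the printed form of the criterion this package implements; for one-hot
targets it reduces to −log p_true − 4p_true/(1+p_true²) per pixel.

**Training defaults.** Adam at lr 5e−3, batch 8, 20 epochs, depth 4,
base_channels 4, with label-consistent augmentation (random 90° rotations
and flips — orientation-rich but safe for binary masks).  These sizes were
chosen so a full 125-image training run completes in under four minutes on
one CPU core; at that budget the held-out IoU on the default (complex)
background is ≈ 0.92, and wider variants buy little on this task for
substantially more compute.  Validation is a single 80/20 split
by default, returning the best-validation-epoch weights; k-fold
cross-validation (`cv_folds ≥ 2`) reports per-fold held-out IoU and
retrains on all data with the median best epoch.  Deep supervision of the
nested decoder exists behind a flag but is off by default.

**Binarization and post-processing.** Masks are `p_cell ≥ threshold`
(default 0.5, inclusive), then reduced to the largest 8-connected
component; a component below `min_area_px` flags the frame invalid rather
than producing a garbage fit.  Both operations are idempotent.

**Classical baselines.** Two-cluster intensity k-means (deterministic
min/max initialisation, the brighter cluster is the cell), a Chan–Vese
level set initialised from a centered box (fixed iteration budget;
non-convergence returns the last iterate), and plain Otsu thresholding.
They stand in for the classical comparators of segmentation-model
comparison tables; exact parity with any particular ImageJ plugin is out
of scope.

## Orientation extraction (`orientation`)

The ROI is a square crop (default 150 px) that is either fixed at the trap
center or tracks the previous frame's mask centroid (one-frame lag, with
fall-back to the last known center when a frame yields no mask).  The
ellipse is fitted to the *outer boundary contour* of the mask by direct
least-squares conic fitting; when the conic degenerates, an image-moments
fit is used instead.  Frames whose mask is empty, too small, or whose fit
is too circular (a/b < 1.1, configurable — the orientation of a near-circle
is noise) are marked missing rather than guessed.

**Unwrapping.** Because α is defined modulo 180°, consecutive differences
are mapped to the minimal-magnitude representative Δ ∈ (−90°, 90°] via
Δ = 90 − ((90 − d) mod 180); ties at ±90° resolve to +90.  The cumulative
sum anchored at the first valid frame is the unwrapped phase.  Two
consequences are documented and asserted: every increment is bounded by
90°, so the maximum recoverable rotation rate is fps/4 revolutions per
second; and missing frames are never interpolated — pairs spanning a gap
are recorded and excluded from speed estimation, since interpolation would
manufacture rotation.

## Kinematics and statistics (`kinematics`)

The angular speed is the forward difference

    Ω(k) = |α(k+1) − α(k)| / (2π) · fps     [revolutions per second]

equivalently |Δdeg|/360·fps.  No smoothing is applied to α before
differencing.  Ω is reported in rev/s everywhere because "rotation rate" is
otherwise ambiguous.  Summaries report mean, median, linear-interpolation
quartiles, sample SD (ddof = 1), and n.  Group comparison is a two-sided
two-sample t-test — Welch by default, since equal variances between cells
or conditions is not defensible; the pooled variant is available.  Speeds
from the frames of one cell are treated as samples within a group, which
matches the box-plot reading of per-frame speeds but is pseudo-replication
in the strict sense (frames of one cell are autocorrelated); p-values
between *conditions* should therefore be read per-cell, not per-population.

## Metrics (`metrics`)

IoU = |S∩T|/|S∪T| and Dice = 2|S∩T|/(|S|+|T|) by integer pixel counting.
Two empty masks score 1 by convention (documented; the benchmark never
produces this case).  The benchmark harness scores each method per frame,
records wall-clock time (informational only), converts means to percent
with one decimal in the rendered table, and scores a method failure on a
frame as 0 with a warning rather than crashing.

## Problem sizes used in the acceptance experiments

The headline numbers of the motivating study were computed on a private
clinical dataset and cannot be reproduced; the acceptance experiments
instead verify properties on synthetic data at desk scale: training on 125
images of 120×120 px (the published training-set size), evaluation clips of
163 frames (1 s at 163 fps), a 30-frame benchmark set for the
method-ordering comparison, and 1000 repetitions for the type-I calibration
of the t-test (rejection rate estimated to ±~0.7 percentage points).

## Known limitations

* Planar rotation only; out-of-plane (3-D) orientation is not recovered.
* One target per ROI; no multi-cell tracking.
* Rotation faster than fps/4 rev/s aliases and cannot be recovered.
* The NumPy network is CPU-sized; it is not intended for large-scale or
  GPU training, and no pretrained weights are shipped.
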