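# Methods

This note records the models, parameter choices and numerical decisions
behind `dropcascade`, and what the synthetic benchmark does and does not
establish about real microscopy data.

## Segmentation cascade

Each stage is a binary encoder–decoder U-Net: `n_encoders` resolution
levels with two 3×3 same-padded conv + ReLU blocks per level, filters
doubling per level, 2×2 max pooling on the way down, nearest-neighbor
upsampling with skip concatenation on the way up, and a 1×1 convolution
with sigmoid output.  No normalization layers are used — at desk scale the
nets are shallow enough that He-initialised plain convolutions train
stably, and omitting them keeps training bit-reproducible.  Input spatial
size must be divisible by 2^(n_encoders−1).

Training minimizes per-pixel mean binary cross-entropy with Adam
(β₁=0.9, β₂=0.999, ε=1e−8).  The loss trace can be reported as per-pixel
means or as summed totals (`TrainConfig.loss_mode`); the two differ only by
the pixel count, but summed totals are what large-image training logs
typically show, so both are available and comparisons must use one mode
consistently.  The data are split 80:20 into disjoint, exhaustive train and
validation sets by a seeded shuffle, and the best-on-validation weights are
restored at the end.  Augmentation (horizontal/vertical flips, 90°
rotations for square tiles, ±10% multiplicative brightness jitter) is
applied on the fly to training samples only.

Two hyperparameter tiers exist.  `FULL_SCALE_PRESETS` mirrors a full-scale
configuration (5–6 encoders, 32–64 base filters, thousands of epochs,
learning rates ~4–7×10⁻⁴) appropriate for GPU training on real labeled
frames.  The package defaults (`UNetSpec()`: 2 encoders, 8 base filters,
60 epochs, lr 2×10⁻³) are desk-scale: they train all three stages on 48
synthetic 64×64 tiles in ~2–3 minutes on one CPU and reach droplet IoU
≈ 0.97 and per-droplet content classification accuracy ≥ 0.95 on held-out
synthetic scenes.  The desk-scale tier is the one exercised by the test
suite.

The stage-1 probability map is binarized (see below) before the overlay,
rather than overlaying the soft map: the overlay's purpose is to remove
background contrast entirely, and a soft mask would leak attenuated
background into stages 2–3.

Stacking precedence is crystal > droplet > background.  A pixel claimed by
both crystal masks goes to vaterite when its stage-2 probability is at
least the stage-3 probability; without probabilities the tie-break is
vaterite (the more commonly observed metastable polymorph).  Crystal pixels
outside the droplet mask are rendered anyway and flagged with a warning —
dropping them silently would hide stage-1 under-segmentation.

## Tiling

Frames are cut into at most a 3×3 grid (≤2 cuts per axis); tiles partition
the frame exactly, with no overlap and no blending at reconstruction, so
merged figures are exactly what the per-tile models produced.  Seam
artifacts are mitigated only by the cut limit.  Images are resized
bilinearly, masks with nearest-neighbor so labels stay binary; resizing is
skipped entirely (bit-exact) when source and target sizes match.  Default
tile target is 512×512 for real frames; the tests use 64×64.

## Binarization and counting

Probability maps are binarized by two-cluster K-Means on pixel intensity
(k-means++, fixed seed, default 0 for bit-stable masks).  In one dimension
the two-means assignment reduces to thresholding at the midpoint of the
two centers, which is how it is applied after fitting.  Maps whose cluster
centers are separated by less than 0.1 are treated as all-background: a
near-constant map has no foreground cluster, and splitting it would
manufacture objects out of noise.  For maps larger than 200k pixels the
centers are fitted on a seeded 200k subsample.

Counting is connected-component labeling (default 8-connectivity) with a
minimum-area filter: 50 px for droplets (a genuine droplet at the default
scale covers ~400 px), 1 px for crystals (which may legitimately be a
single pixel).  Cluster centers alone cannot yield object counts, which is
why components are counted rather than K-Means centers.

## Droplet delimitation and content assignment

Droplet regions are delimited by the minimum enclosing circle of each
component, computed by Welzl's algorithm over the component's convex hull
(exact, and fast because only hull vertices matter).  Crystal components
are assigned by centroid: a centroid inside a circle inflated by
`margin_px` (default 2 px) flags that droplet; inside several circles, the
nearest center wins; inside none, the crystal is logged as an orphan and
ignored for classification.  The centroid-in-inflated-circle rule, rather
than exact point-in-contour, is robust for 1–3 px crystals at mask
resolution.  Border-truncated droplets are counted but flagged.  ACC counts
are derived, never segmented: `n_acc = n_droplets − |droplets with any
crystal|`, so the conservation identity holds by construction frame by
frame.

## Kinetics

The ACC series is pooled over locations: counts are summed per timestep,
the timestamp is the mean of per-location acquisition times, and the
(min, max) span records the sequential-acquisition time discrepancy.
Fitting y = A·e^(−kt) + C uses unweighted trust-region least squares with
k ≥ 0, initialised at C₀ = min(y), A₀ = max(y) − C₀ and k₀ from a
log-linear regression of y − 0.99·C₀ on t, refined to 1e−10 tolerances.
Residuals are scaled by max|y| so count-form and ratio-form fits converge
identically.  A fit with negligible amplitude or a zero rate is flagged
`no_decay`.  On noiseless model-generated points the fitter recovers the
generating coefficients to machine precision (the tests assert 1e−6
relative).

Half-life: exact t½ = ln(A/(0.5 − C))/k when the ratio-form plateau C is
below 0.5; otherwise unreachable under the fitted model, and the latest
empirical observation with ACC fraction > 0.5 supplies a lower bound.

Parameter uncertainty, when requested, comes from a nonparametric
bootstrap over locations (default 200 resamples, seeded) — an additive
feature of this package; the point estimates themselves are plain
unweighted fits.

## Synthetic generator

The generator emulates the study conditions rather than photorealism.
Defaults: a 3 mm × 1.5 mm field of view rendered at ~7 µm/px (214×428 px)
with 50 non-overlapping droplets of radius 12 ± 8% px (≈170 µm diameter),
crystals ≤3 px, 17 timesteps over 360 min, 12–16 locations imaged
sequentially (0.75 min offset per location).  Droplets are bright disks
with a 2 px darker rim on a background of smooth illumination gradient
plus low-frequency high-contrast blobs (amplitude set by
`background_contrast`, default 0.5) and additive Gaussian intensity noise
(default σ=4 on the 0–255 scale).  Placement uses rejection sampling with
a 2 px clearance so rendered disks are never pixel-adjacent (components
stay separable at 8-connectivity); failure after bounded attempts raises
an explicit error.

Kinetics follow a two-population first-order model: a labile fraction
(default 0.1) transforms with exponentially distributed waiting times at
rate `k_true` (default 0.027 min⁻¹); the rest never transform, so the ACC
fraction decays as (1 − f) + f·e^(−kt) with a plateau of 0.9 — the same
exponential-plateau form the fitter assumes, with amplitude and plateau
matching the fitted ratio model this package is benchmarked against.  The
transformed polymorph is Bernoulli(p_vaterite = 0.5); the experimental
record does not quantify the polymorph split, and the analysis is
insensitive to it.

Vaterite is rendered as a small round warm-toned blob, calcite as a
sharp-edged cooler square — encoding the premise that the polymorphs are
visually distinguishable (spherical vs rhombohedral habit).  **Limitation:**
at ≤3 px, shape alone would not separate the two; the generator's color
cue does real discriminative work that, on experimental images, is played
by subtler texture and contrast differences.  Passing the learned
segmentation tests therefore shows the cascade machinery (training,
overlay, per-stage specialization, counting, classification) works end to
end, not that these tiny nets would reach the same accuracy on real
frames.  The generator also omits touching droplets, droplet shrinkage (not
observed experimentally), defocus, and oil-phase artifacts; watershed
splitting of touching droplets is out of scope.

## Problem sizes used by the tests

Learned-segmentation checks train on 48 tiles of 64×64 px from 12 scenes
(6 droplets each) and evaluate 4 held-out scenes — the smallest
configuration at which the cascade's accuracy properties are stable across
seeds.  Rate-recovery checks use 30 seeded count-level simulations of 660
droplets × 16 timesteps (no rendering), where the median fitted k falls
within a few percent of the generating 0.027 min⁻¹; the acceptance
threshold of 25% reflects binomial counting noise at a 10% labile
fraction, not fitter accuracy.
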