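# Methods

## Problem

A multispectral camera measures the near-infrared (NIR) reflectance needed
for vegetation indices such as NDVI, but standard RGB cameras are cheaper
and sharper. `plotvi` implements a model-based alternative: learn, from
paired multispectral/RGB observations of field plots, a convolutional
regression that maps a plot's RGB image directly to the plot's mean
vegetation index. The package contains the complete loop — a synthetic
multispectral field-trial simulator that supplies ground truth, the index
computations, plot extraction, the network and its training procedure, the
ablation baselines that isolate spectral / spatial / temporal information,
and the evaluation machinery.

## Vegetation indices

Five indices of the normalized-difference family are implemented per pixel
on reflectance bands (blue, green, red, red-edge, NIR):

- NDVI = (NIR − Red) / (NIR + Red)
- GNDVI = (NIR − Green) / (NIR + Green)
- RENDVI = (NIR − RedEdge) / (NIR + RedEdge)
- SAVI = (1 + L)(NIR − Red) / (NIR + Red + L)
- EVI = G(NIR − Red) / (NIR + c₁Red − c₂Blue + L)

SAVI's soil factor defaults to L = 0.5; EVI uses the conventional constants
G = 2.5, c₁ = 6, c₂ = 7.5, L = 1. These constants are the literature's
standard choices and are exposed in `VIParams`.

The plot-level regression target is the **mean of the per-pixel index map**
(mean pooling), not the index of mean reflectance; the two differ on mixed
pixels, and the mean-pooled form is fixed normatively throughout. Pixels
with an exactly zero denominator are masked out of the mean rather than
mapped to 0, so bare-soil degeneracies cannot bias plot means. No
vegetation/background segmentation precedes averaging: the soil contribution
is part of the learned signal.

## Synthetic field trial

The simulator emulates a row-plot breeding trial surveyed from the air:
3 bays × 576 single-row plots × 7 growth stages by default (12096
observations), rendered as 5-band reflectance rasters with an affine
geotransform and a rectangular plot grid. Each plot pixel is drawn
i.i.d. Bernoulli(cover) vegetation over soil; a per-stage fraction of
vegetation pixels is senescent; Gaussian sensor noise (sd 0.01 reflectance)
is added and values clipped to [0, 1]. The cover curve rises through the
season (0.10 → 0.85) and the senescence curve takes over late
(0 → 0.85). A 16-bit digital-number encoding with a rendered calibration
panel, and its inversion through the panel, model the radiometric chain.

Four forms of per-plot heterogeneity make the plot index a non-trivial
regression target within a stage, standing in for germplasm, soil and
illumination variation between entries:

- cover jitter: per-plot cover ~ stage value + N(0, 0.12), clipped;
- senescence jitter: per-plot fraction ~ stage value + N(0, 0.10), clipped;
- soil brightness gain: per-plot multiplicative factor ~ U(0.85, 1.15) on
  the soil spectrum (dry vs moist soil);
- canopy brightness gain: per-plot multiplicative factor on the vegetation
  and senescent spectra (sun angle, canopy structure, genotype); unity by
  default, widened in the spatial-ablation study. Because every ratio
  index is invariant to a per-pixel gain, both gains perturb the RGB
  appearance without perturbing the target.

Default spectra (blue, green, red, red-edge, NIR): soil
(0.10, 0.15, 0.20, 0.25, 0.30), healthy vegetation
(0.04, 0.08, 0.05, 0.30, 0.50), senescent vegetation
(0.15, 0.20, 0.25, 0.28, 0.30) — a qualitative high-NIR/low-red healthy
canopy against brighter soil. A second preset (`ablation_config`) places
the three materials at one luminance on a single green↔red line in RGB
space, for studies of what spatially resolved colour alone contributes
(see below).

What the simulator does **not** model: radiative-transfer canopy optics,
within-plot spatial correlation of the canopy (pixels are independent),
photogrammetric stitching artifacts, illumination gradients, wind blur, and
atmospheric effects. Consequently, passing results here show that the
estimator recovers the mapping the simulator embodies under realistic noise
and layout; they do not certify accuracy on real orthomosaics.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawn keys, so every scene, fold and training
run is independently reproducible, and identical configurations reproduce
reports byte for byte.

## Plot sampling

Plot rectangles live in world coordinates and are mapped through the exact
affine inverse of the scene's geotransform. Rasterization uses 0-based,
half-open pixel ranges `[floor(min), floor(max))`, so adjacent rectangles
tile without double-counting boundary pixels. All five bands are cropped at
native resolution; the target index is computed on that native crop; the
RGB crop (red, green, blue bands) is then standardized to height 15 × width
208 — "208 × 15" is width × height, matching the long-thin geometry of a
4 m row at ~2 cm ground sampling distance. Downscaling uses exact
area-weighted averaging (radiometry-preserving; channel means are invariant
for integer ratios), upscaling bilinear interpolation. Plots that fall
outside the raster are skipped and reported, not fatal. Raw digital numbers
are calibrated to reflectance via the panel (`reflectance = DN ×
panel_reflectance / panel_DN`); network inputs are calibrated reflectance on
a fixed [0, 1] scale — deliberately *not* per-image contrast stretched,
which would destroy the absolute-brightness cue.

## The network

Architecture (same-padded 5×5 convolutions, non-overlapping 2×2 max
pooling, floor division on odd sizes):

    (15, 208, C) → conv 20 maps → pool → (7, 104, 20)
                 → conv 50 maps → pool → (3, 52, 50)
                 → flatten 7800 → fc 500 → ReLU → dropout 0.5 → fc 1

Same-padding is forced: with valid convolutions the 15-pixel height would
collapse to zero before the second pooling stage. The hidden width (500)
and dropout rate (0.5) are AlexNet-lineage defaults, exposed in `NetConfig`.
C is 3 for RGB and 1 for the grayscale ablation, everything else identical.

Training is plain SGD with momentum 0.9 and weight decay 5e-4 on the
Euclidean loss `(1/2N) Σ (pred − target)²`, mini-batches of 72 drawn by
per-epoch shuffling, and the inverse-decay schedule
`lr(t) = 0.01 (1 + 0.9 t)^−0.75` in the iteration count. Images are flipped
left-right with probability 1/2 when augmentation is on (row plots are
left-right symmetric; the target is unchanged). Dropout is active only in
training; prediction is a deterministic forward pass.

Numerical choices that matter:

- **Input centering.** The per-channel mean of the training images is
  stored with the model and subtracted before every forward pass. Without
  it, the common DC component of reflectance images dominates the loss
  curvature and the 0.01/momentum-0.9 recipe diverges or collapses to a
  near-constant predictor; with it, standard-width initialization trains
  stably. This mirrors the mean-image subtraction that is conventional in
  this family of networks.
- **Initialization.** He-normal for convolutions, Glorot-uniform for the
  dense layers, from the run seed, with a configurable global width
  multiplier (`init_scale`, default 1).
- **Decay index.** The inverse-decay schedule is indexed by *epoch*, not
  by mini-batch step. With a decay constant of 0.9 per step the learning
  rate falls three orders of magnitude within two epochs and the network
  provably stays in a near-linear regime (we measured train error equal to
  test error and insensitive to doubling the epochs — i.e. pure underfit
  with a dead step size). Per-epoch decay is the only indexing under which
  this recipe — all constants kept — actually trains; `lr_at` itself is a
  pure function of the decay index either way.
- Training aborts with a diagnostic naming the iteration if the loss goes
  non-finite; gradients are checked against numeric differentiation in the
  test suite.

The implementation is a small, self-contained numpy stack (im2col
convolutions as single GEMMs, explicit backward passes); it is exact
backpropagation, fully deterministic given the seed, and fast enough to
train the full model on one CPU core in minutes.

## Baselines

- **DNN-GRAY** (spectral ablation): inputs collapsed to luminance with the
  ITU-R BT.601 weights 0.299/0.587/0.114 (an equal-weight variant is
  available); identical architecture and hyperparameters otherwise.
- **LR-RGB** (spatial ablation): each image reduced to its per-channel
  means; ordinary least squares with intercept predicts the index from the
  three means.
- **DNN-T** (temporal ablation): leave-one-stage-out splits; for each stage
  the network trains on all other stages and is tested on the withheld one.

A structural note on the spatial ablation: with three linearly independent
material spectra, the plot-mean index is *exactly affine* in the plot-mean
RGB (both are linear in the mixture weights — even a per-plot soil gain is
absorbed, because soil fraction × soil gain enters as a single variable
the target does not depend on), so on such scenes a mean-pixel linear
model is optimal and the spatial ablation shows nothing. The
equal-luminance collinear preset removes that degeneracy by construction:
all three material colours lie on one line in RGB space, so the plot's
mean colour collapses to a single scalar that cannot identify the three
fractions, and the grayscale view is constant up to noise. The pure pixel
colours remain three distinct points on that line, so a model with spatial
resolution can classify pixels and count each material. On these scenes
spatial-chromatic structure is, provably, the only carrier of the index
signal — which is the simulator's sharpened version of the real-world
observation that both colour and spatial arrangement matter.

## Evaluation

Validation is leave-one-bay-out: one fold per bay, trained on the other two
spatially distinct bays (8064 training / 4032 test samples at full layout),
with held-out predictions pooled across folds. Accuracy is summarized by:

- per-sample percentage error `(VI_obs − VI_est)/VI_obs × 100`
  (overestimates negative; samples with VI_obs = 0 are excluded from the
  moments and counted);
- per-stage mean ± sd, within-stage Pearson r, and box statistics
  (type-7 linear-interpolation quartiles; whiskers at the most extreme
  points within 1.5 IQR of the quartile; values beyond flagged outliers);
- a pooled straight-line fit of estimated on observed index by iteratively
  reweighted least squares with bisquare weights (tuning constant 4.685,
  MAD-based scale, convergence at parameter change < 1e-8 or 50
  iterations). When the residual scale is zero all weights are one and the
  fit coincides with OLS. R², RMSE and Pearson r are reported for the
  robust line on all points (not an OLS refit), so figures and tables are
  self-consistent. Within-stage correlations pool the folds rather than
  averaging per-fold values.

## Reference studies and problem sizes

`plotvi.studies` fixes three desk-scale protocols used by the acceptance
script and the test suite, all on one CPU core:

- **Bookkeeping**: the full 3 × 576 × 7 layout (counts only, no rendering)
  reproduces 12096 observations, 8064/4032 bay-fold sizes, 10368/1728
  temporal-split sizes and 72 ground-reference plots (24 per bay in two
  lines of 12).
- **Held-out-bay recovery**: 3 bays × 64 plots × 7 stages, default spectra,
  noise 0.01, 30 epochs, first bay fold. The expectation is a strong
  held-out fit (R² ≥ 0.9, RMSE ≤ 0.05 on the robust line) — a scaled-down
  analogue of the full survey's headline fit, not a reproduction of its
  printed values, which would require the original imagery.
- **Chromatic ablation**: 3 bays × 32 plots × 7 stages on the
  equal-luminance collinear preset, 25 epochs. Both reduced models must
  trail the RGB network: the grayscale model by at least 1.5× RMSE (its
  input is nearly constant) and the mean-pixel linear model strictly (its
  input cannot identify the mixture fractions).
- **Temporal ablation**: 3 bays × 32 plots × 7 stages, default spectra
  with an abrupt terminal senescence step (0.30 → 0.90) and a terminal
  collapse of the senescent material's NIR (0.30 → 0.24), 25 epochs. In a
  pure fixed-spectra mixture, a temporally blind model extrapolates
  proportions *correctly* (the plot index is linear in the fractions), so
  the blindness would be benign; the NIR collapse is what real late
  senescence adds — the index falls while the colour barely moves. Models
  that saw the terminal date learn the new colour-to-index relationship
  from the heavily senesced plots unique to it; the network trained
  without that date carries the old relationship forward and
  overestimates, with the largest mean signed error of the four models.

## Known limitations

- The simulator's independence assumptions (i.i.d. pixels, independent
  per-stage jitters) understate the spatial and temporal correlation of
  real canopies; held-out-bay generalization here is therefore easier than
  across a real field.
- The grayscale ablation's magnitude depends on how metameric the chosen
  spectra are in luminance; the default spectra give brightness real
  predictive power, the hue-dominant preset removes it by construction.
- Eq.-style percentage errors blow up as the observed index approaches
  zero; terminal-stage mean errors are accordingly large and heavy-tailed.
- The numpy network targets this architecture specifically (stride-1
  same-padded convolutions, 2×2 pooling); it is not a general-purpose
  training framework.
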