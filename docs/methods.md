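# Methods

## Problem and model

`cropseg` performs crop-type mapping — pixel-level classification of a
single-date, 4-band (red, green, blue, near-infrared) 10 m satellite scene
into crop classes (here: other, rice, maize, soybean) — cast as 2-D semantic
segmentation. The network is a two-branch encoder–decoder:

**Master branch.** A five-level U-Net. Level 1 is a double convolution block
(two rounds of 3×3 convolution, batch normalisation, activation) taking the
4-band input to 64 channels at full resolution; each of levels 2–5 max-pools
2×2 and doubles the channels with another double-conv block, ending at 1024
channels at 1/16 resolution. The activation is PReLU (per-channel learnable
negative slope, initialised at 0.25) by default, ReLU for the baseline.
Efficient channel attention (ECA) is applied to the encoder outputs of
levels 1–4 before they are used as skip connections: global average pooling
compresses each feature map to a per-channel scalar, a bias-free 1-D
convolution of size 3 mixes neighbouring channels, a sigmoid yields
per-channel weights in (0,1), and the input map is rescaled channel-wise
(shape unchanged; the operation is an elementwise contraction). The decoder
runs four stages, each bilinearly upsampling the running feature ×2,
concatenating the attended skip at that resolution and applying a double
conv with output channels 512, 256, 128, 64; a final 1×1 convolution maps
the 64-channel map to class logits. Input sides must be divisible by 16.

**Point-constraint branch.** After the softmax of the master logits,
per-pixel difficulty is the top-1 minus top-2 probability margin (computed on
probabilities, so it is invariant to logit scale). The k valid pixels with
the smallest margins are selected per image — k = 8096 on a 256×256 patch
(≈12.35% of pixels), and the same fraction, `round(0.1235·H·W)`, for other
sizes; ties break by ascending flat index so selection is deterministic, and
masked pixels are never selected. Feature vectors for the selected pixels
are bilinearly sampled from the level-2 encoder map (after ECA by default; a
toggle samples before ECA) upsampled to input resolution, concatenated with
the master softmax scores at those pixels, and passed through a shared MLP
(hidden widths 256, 256). At prediction time the MLP argmax overrides the
master argmax at exactly the selected pixels.

**Losses.** The master branch minimises α·L_ce + β·L_dice with defaults
α = 0, β = 1 (Dice only — the best-performing ratio of the prescribed
nine-combination weight sweep, exposed as `LOSS_RATIO_SWEEP`). Cross-entropy
is the mean of −log p(truth) over non-ignored pixels. Dice is per-class soft
Dice with ε = 1e−6 smoothing, macro-averaged over the classes with any
support in truth or prediction (averaging over all C classes would let the
smoothing award absent classes a vacuous perfect score). The point branch
uses plain cross-entropy over its selected, non-ignored points; branch
losses are summed with point-branch weight 1 (no combination weight is
prescribed, so equal weighting is the neutral choice). Pixels carrying the
ignore value (255) contribute to no loss and no metric.

## Dataset protocol

A labelled scene is an image raster, a class raster and a validity mask;
rectangular regions without trustworthy labels are masked out (labels set to
the ignore value). The scene is cut into 256×256 tiles (configurable) with
stride equal to the tile size, so the splits share no pixels; partial edge
tiles are dropped rather than padded, because padding would inject synthetic
class pixels (a 5505×4280 scene yields 21×16 = 336 tiles). Tiles whose
masked fraction exceeds 15% are discarded — the cut is strict, a tile at
exactly 15% is kept. The retained tiles are split 8:1:1 at random with
n_val = n_test = ⌊n/10⌋ and the remainder in train; this floor convention is
the one that turns 177 retained patches into 143/17/17. "10-fold
cross-validation" is repeated random subsampling: ten independent seeded
8:1:1 re-splits of all retained patches, not ten disjoint folds. Per fold
the model is re-initialised from a fold-specific seed; fold metrics come
from the fold's pooled test confusion matrix and are averaged (mean ± sd)
across folds. Class indices 0–3 map to (other, rice, maize, soybean);
reflectance is passed through unnormalised by default, with optional
per-band z-scoring using training-split statistics only.

## Training

Adam, learning rate 0.0003, up to 150 epochs, batch size 16, early stopping
after 20 epochs without improvement of validation overall accuracy, with
best-epoch weight restoration (the protocol does not say whether last or
best weights are used; restoring the best is the conservative choice).
Weight initialisation is Kaiming fan-in normal for convolutions and linear
layers, unit/zero for batch-norm, 0.25 for PReLU slopes; no pretraining, no
augmentation, no schedule, no weight decay. Everything is seeded (weight
init and shuffling use separate streams), so identical runs are bit-identical.
A non-finite loss aborts with a diagnostic. The network, layers and
reverse-mode automatic differentiation are implemented in numpy inside the
package (float32 compute; convolutions by im2col + BLAS; bilinear resize as
separable interpolation-matrix products whose backward is the exact
transpose); every operation's vector–Jacobian product is verified against
central finite differences in the test suite.

## Metrics

Confusion-matrix based, ignore-aware: OA (diagonal fraction), AA (mean
per-class recall; classes with no true pixels are dropped) and mIoU (mean
per-class intersection-over-union; classes absent from both truth and
prediction are dropped), all reported in percent. Accumulation is additive
across patches, so patchwise evaluation equals stitched-scene evaluation.

## Synthetic scenes

The study's labelled imagery is private insurance data, so the generator
emulates its statistical structure: Voronoi cells of uniformly seeded points
form irregular parcels (including long, narrow ones — the shapes the point
branch targets); each parcel draws a class from configurable probabilities
whose defaults are the study area's pixel shares (0.6416/0.1989/0.1203/0.0393
for other/rice/maize/soybean, normalised from the published pixel counts);
pixels within `gap_width` (default 2 px) of a parcel boundary become
background, emulating roads and field margins; band values are per-class
mean reflectances modulated by a random quadratic illumination surface
(peak amplitude 0.08) plus i.i.d. Gaussian noise (SD 0.05); random
rectangles are masked. The default band means are fixed so pairwise class
separation is ≈2–3 noise SDs — separable but overlapping, mimicking
inter-class spectral similarity. Not modelled: within-parcel texture, mixed
boundary pixels, atmospheric effects, temporal dynamics. Tests passing on
these scenes therefore demonstrate that the pipeline and optimisation are
correct and that the architecture can learn parcel classes from 4-band
spectra with spatial context; they say nothing about accuracy on real
imagery, and the published accuracies on the private dataset are documented
targets of the architecture, not reproducible assertions.

## Scaled study sizes

CPU-friendly problem sizes are used throughout the tests and the acceptance
script, chosen as the package's standard desk-scale configuration: a
512×512 default scene tiled into 64×64 patches (≈56 retained), a width-16
model (encoder channels 16…256) trained ≤30 epochs for the held-out
learning check, and a width-32 model trained 30 epochs at batch 2 with
CE+Dice and learning rate 0.001 on 8 patches for the memorisation (overfit)
sanity check. At 64×64 the point branch selects round(0.1235·4096) = 506
points per patch. With a batched forward pass, k is additionally clamped to
the smallest per-image valid-pixel count in the batch; since retained
patches are ≥85% valid and the selection fraction is ≈12%, the clamp never
binds in practice.

## Known limitations

* The printed decoder description ("reduced to 1/4") cannot hold exactly
  with channel-doubling to 1024 and channel-preserving bilinear upsampling;
  the implemented decoder (512, 256, 128, 64) preserves the stated
  64-channel final map and symmetric shape.
* Whether top-k selection is per image or per batch is ambiguous; per image
  is implemented (consistent with the ~12%-of-each-patch statement).
* The point-branch MLP depth/width is not specified; (256, 256) is used.
* CPU-only numpy training: practical for the desk-scale configurations
  above, not for 256×256 patches at width 64 over 150 epochs.
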