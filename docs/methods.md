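# Methods

## Problem setting

The package segments the thyroid gland (a radiotherapy organ at risk) on
2-D CT slices. The gland is small — a few percent of a slice — and sits among
vessels and soft tissues of nearly identical attenuation, so the task stresses
shape/context modeling rather than intensity thresholding, and the training
objective must survive extreme class imbalance.

## Architecture

MSFA-U-Net keeps the U-Net encoder–decoder skeleton but replaces the encoder's
per-level double convolution with an HRNet-style multi-resolution stage:

* `num_levels` branches (default 4; the desk-scale experiments use 3), branch
  *i* at resolution `full / 2^i` with `base_channels · 2^i` channels
  (defaults 32/64/128/256). Stage *k* spawns branch *k* from branch *k−1* via
  a 3×3 stride-2 convolution, runs one attention residual block per active
  branch, then fuses: each branch receives the elementwise sum of every other
  branch mapped to its resolution (chained 3×3 stride-2 convolutions going
  down, chained 3×3 stride-2 transposed convolutions going up, identity at
  the same scale).
* The attention residual block is
  `cSE(ReLU(BN(conv3×3(ReLU(BN(conv3×3(x))))))) + BN(conv1×1(x))`.
  The cSE gate pools each channel to a scalar (GAP), halves the channel count
  with a dense layer + ReLU, restores it with a second dense layer, and
  applies a sigmoid; the feature map is rescaled channelwise. The projection
  shortcut (1×1 conv + BN) also handles channel changes.
* The decoder is U-Net-like: transposed convolution up one level,
  concatenation with that level's (post-fusion) encoder feature, dropout
  (rate 0.2) after each skip concatenation, then an attention residual block
  in place of U-Net's two convolutions. A 1×1 convolution + sigmoid yields
  the foreground probability; the 0.5 binarization threshold is applied
  downstream, never inside the model.

Design choices made where the design was genuinely open:

* **Branch widths / stage count.** One fusion round after each stage's
  blocks, encoder stage count equal to `num_levels`, and U-Net-like channel
  doubling. These are the minimal consistent reading of the architecture
  sketch; HRNet proper repeats fusion several times per stage.
* **Fusion aggregation** is elementwise sum (the HRNet convention);
  concatenation is reserved for decoder skip connections.
* **Transitions are bare (transposed) convolutions** without BN/ReLU. This
  keeps cross-scale fusion linear in the branch features (zero features and
  zero biases fuse to zero) and costs nothing measurable on phantoms.
* **Skip features are post-fusion** encoder features (the fused maps carry
  strictly more context; the alternative is a one-line change).
* **Activation** is ReLU throughout the conv paths; BN order conv→BN→ReLU;
  BN ε=1e-5, momentum 0.1.
* **Initialization**: He-uniform for all convolutions and dense layers,
  zero biases, BN γ=1/β=0, all drawn from one seeded generator per model.

## Numerical core

No deep-learning framework is used: `msfaseg.nn` is a small reverse-mode
autodiff engine over float32 numpy arrays implementing exactly the operator
set the model needs (conv2d via cached im2col with a fast 1×1 path,
transposed conv as the conv adjoint, batch norm with running statistics,
dense, ReLU, clipped sigmoid, GAP, channel gating, concatenation, dropout,
soft Dice loss). Correctness is established in the test suite: forward
convolution against `scipy.signal.correlate2d`, the transposed convolution
against the adjoint identity ⟨conv(y), x⟩ = ⟨convᵀ(x), y⟩, and every
operator's gradient against central finite differences. Sigmoid outputs are
clipped to [1e-6, 1−1e-6] so open-interval contracts and loss ratios remain
well defined in float32.

## Loss and metrics

Training minimizes the soft Dice loss
`DL = 1 − (2 Σp·t + ε)/(Σt + Σp + ε)` (mean over the batch) with ε = 1.0,
the V-Net smoothing convention; the soft reading over probabilities is
required for differentiability. As ε → 0 on binary predictions the loss
equals 1 − DSC (asserted in tests).

Evaluation uses hard masks: DSC = 2TP/(2TP+FP+FN), JSC = TP/(TP+FP+FN),
PPV = TP/(TP+FP), SE = TP/(TP+FN), and the exact symmetric Hausdorff
distance (maximum, not 95th percentile) between foreground point sets, in
pixels unless a physical spacing is supplied. Degenerate cases: two empty
masks give DSC = JSC = 1 and HD = 0; an undefined ratio (empty prediction
for PPV, empty reference for SE) is NaN and excluded from aggregates; HD
against exactly one empty mask is +inf and excluded from the mean with the
finite count reported separately. Metrics are computed per slice and
aggregated as mean ± std, with box-plot statistics (median, quartiles,
1.5·IQR whiskers, outliers) recomputable from the per-case CSV.

## Training protocol

Batch 2, Adam (β₁=0.9, β₂=0.999; the optimizer is exposed in config), initial
learning rate 2·10⁻⁴ with staircase exponential decay — multiplied by 0.96
after every 300 optimizer steps ("step" = iteration, not epoch). No early
stopping; the checkpoint with the best validation DSC is kept. Augmentation
is applied on the fly per batch: rotation ±15°, horizontal flip p=0.5, zoom
0.9–1.1, shear ±8°, the same geometric transform applied to image (bilinear)
and mask (nearest neighbor, re-binarized at 0.5). The full-scale defaults
are 120 epochs at 512×512; the canned experiments scale down (below).

## Preprocessing

Stored pixels → HU via the DICOM rescale (HU = raw·slope + intercept), then
window/level to [0, 1]. The window is level 60 HU / width 400 HU — a
soft-tissue neck window that keeps thyroid tissue (~60–100 HU) inside its
linear range; no specific window is canonical for this task, so both values
are exposed in `WindowSpec`. Contrast is then enhanced with CLAHE
(clip limit 0.01, 8×8 tile grid) — the contrast-limited variant is chosen
because unlimited adaptive equalization amplifies noise.

## Phantom generator

Each phantom is a pure function of (config, index): per-index randomness
comes from `default_rng(seed + index)`. Geometry: two ellipse lobes
(semi-width 6–10 % of the image side, height 1.5–2× width, centers jittered
about the slice middle) joined by a thin isthmus band — thyroid topology,
not anatomy. Intensities: gland 60–100 HU with a smooth sinusoidal texture,
neck background 40 HU, vessels (default 8 discs, radius 1–3.5 % of the side)
drawn from the *same* 60–100 HU range and rejection-sampled to never touch
the gland, so gland-vs-vessel discrimination is purely a shape problem and
the labels stay exact. Additive Gaussian noise (default σ = 10 HU,
soft-tissue CT noise scale) is applied after the mask is fixed. With noise
and vessels disabled, thresholding at the background value reconstructs the
mask exactly — the generator's self-consistency oracle.

What the phantoms do **not** model: 3-D continuity between slices, beam
hardening and streak artifacts, anatomical variability of real necks,
partial-volume boundary blur, or annotation noise. Passing the phantom study
therefore demonstrates that the architecture, losses, metrics and pipeline
are implemented correctly and can learn shape-from-context at desk scale —
it is not evidence of clinical-grade accuracy.

## Desk-scale experiment sizes

The canned experiments (`msfaseg.experiments`) run on 64×64 phantoms with a
3-level, 8-base-channel model: the end-to-end study uses 80 phantoms split
6:1:1 by case into 60/10/10 and trains 25 epochs (validation DSC plateaus by
then); the capacity check memorizes 4 noise-free phantoms for 300 steps at a
constant 3·10⁻³ learning rate (a higher rate than the full protocol,
appropriate for 4-sample memorization). The optimizer family, batch size and
decay schedule are unchanged from the full protocol.

## Known limitations

* 2-D only; per-slice segmentation with no volumetric aggregation.
* The pure-numpy engine is single-threaded-friendly but far slower than a
  GPU framework; the 512×512, 4-level default configuration is practical
  only for inference or short runs on CPU.
* Exact Hausdorff (not HD95) is sensitive to single outlier pixels; both
  masks must be nonempty for a finite value.
* Batch normalization with batch size 2 gives noisy statistics; running
  statistics make inference deterministic regardless.
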