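# Methods

## Model

HDS-Net is a U-shaped binary segmentation network. Input is an RGB image in
[0, 1], output a single logit map of the same spatial size; `sigmoid` turns
logits into lesion probabilities and a threshold (default 0.5) into a mask.

**Encoder.** A residual CNN trunk in the ResNet-bottleneck style, entirely
group-normalized: a 7×7/2 stem, then four stages of 1×1→3×3→1×1 bottleneck
blocks with block counts (3, 4, 6, 3). The trunk runs at *output stride 16*:
stages 1–3 downsample (strides 4, 8, 16), stage 4 keeps stride 16, the
standard layout for segmentation backbones — it keeps high-resolution
computation (and hence FLOPs) bounded while concentrating parameters in the
deep stages. Skip features are taken at strides 2 (stem), 4 (stage 1) and
8 (stage 2); the stage-4 output is the bottleneck. Each block's last
group-norm scale is zero-initialized, so every block starts as (a projection
of) the identity; convolution weights use He fan-out initialization.

**Group normalization** everywhere (32 groups, reduced to the largest divisor
of the channel count when needed): no batch statistics, so per-image outputs
are independent of batch composition, batch size 1 works, and train/eval
normalization is identical.

**DSA bottleneck.** A 1×1 convolution, flatten to (C, S) tokens, element-wise
external attention, unflatten, 1×1 convolution. The memory units K and V are
free parameters of shape (C, S) (one value per channel *and* token —
per-channel rather than channel-shared, since they must "maintain the same
shape" as the flattened map), initialized N(0, 0.02²), with element-wise
learnable scalings (initialized at 1) standing in for their linear maps; all
computation stays element-wise — no matrix products. Order of operations:
scores → softmax over the token axis → Bernoulli mask → multiply by V. The
masking is applied *after* normalization, which is what makes the keep-ratio
p a literal fraction of retained attention mass. (An alternative reading
wraps the softmax around the whole product; the procedural description is
unambiguous and was followed.) There is no residual path inside the block, so
p = 0 zeroes its output — degenerate but valid.

**Mask semantics.** Training draws a fresh i.i.d. Bernoulli(p) mask per
forward pass, independently per batch element, channel and token; p = 1 and
p = 0 short-circuit to exact all-ones/all-zeros. Evaluation substitutes the
expectation (every entry = p), dropout-style, making inference deterministic;
at p = 1 train and eval paths coincide exactly.

**Decoder.** Three stages of 2×2/2 transpose convolution, concatenation of
the matching skip, then two 3×3 conv + GN + ReLU units; finally a 2×2/2
transpose convolution to full resolution and a 1×1 projection to one channel
(no extra nonlinearity before the sigmoid). The head bias is initialized at
−1.4 ≈ logit(0.2), the typical lesion area fraction, so early training is not
dominated by the background class.

## Width calibration

The reference architecture is specified only as "similar to ResNet50" plus a
compute budget (24.36 M parameters, 8.67 G MACs at 224×224). The default
widths — stem 48, stages (192, 384, 768, 1536) (= 0.75 × the ResNet50
widths), decoder (320, 64, 48), head 24 — were chosen once by an analytic
parameter/MAC enumeration of the architecture over a width grid and then
frozen; they land at 24.444 M (+0.35 %) and 8.679 G (+0.10 %). FLOPs are
counted in the MAC convention of common profilers: convolution and transpose
convolution multiply–accumulates plus the element-wise attention products;
normalizations and activations are not counted. `width_scale` multiplies
every width (rounded to a multiple of 4, minimum 4) for CPU-scale work; it
changes capacity, not structure.

## Loss and metrics

`L = L_Dice + L_BCE` on sigmoid probabilities. The Dice term uses soft
probabilities with smoothing constant 1 (differentiability; no constant is
prescribed), computed over the whole batch; BCE is evaluated in the stable
logit form. Gradients are analytic; a finite-difference test checks them.

Metrics come from pixel-wise confusion counts (foreground = lesion):
IoU = TP/(TP+FP+FN), Sen = TP/(TP+FN), Spe = TN/(TN+FP),
Dice = 2TP/(FP+2TP+FN), so Dice = 2·IoU/(1+IoU) identically. Convention for
degenerate images: if prediction and truth are both empty, Dice = IoU =
Sen = 1; if exactly one is empty, Dice = IoU = 0; Spe = 1 when no negatives
exist. Test-set metrics are computed per image and then averaged (the
challenge convention), not pooled over pixels — whether the reference numbers
are pooled or averaged is unstated.

## Training protocol

SGD with lr 0.01 (constant — only an *initial* rate is specified, and no
schedule), momentum 0.9, weight decay 1e-4, batch 24, 300 epochs, input
224×224, no augmentation (none is specified; the loader has a hook but ships
empty). The 8:2 train/test split is a pure function of the sorted id set,
ratio and seed with |train| = floor(0.8·N); the published per-dataset counts
do not all satisfy exact 8:2 of their totals, so the rule is fixed and
documented rather than fitted to them. Best checkpoint is selected by
test-split Dice (no separate validation protocol is named). All randomness —
weight init, shuffling, mask draws — flows from explicit seeds; runs are
bit-reproducible on one CPU.

Everything runs in float32 on the CPU; there is no GPU path. Desk-scale runs
use `width_scale` ≤ 0.25 and 48–64 px inputs; the test suite trains a
quarter-width network on eight 64×64 synthetic images for 200 steps (about a
minute single-threaded), and the acceptance script uses the same sizes.

## Synthetic data

The generator emulates the stated challenges of dermoscopic segmentation:
irregular lesion shape (star-convex contours — periodic cubic interpolation
of 8–16 noisy control radii), ambiguous boundaries (Gaussian blur of the
compositing alpha, σ = 1.5 px), size variation (area fraction uniform in
0.05–0.40, enforced by redrawing with rescaled radii), pigmentation contrast
(dark-brown lesion on light skin with per-sample color jitter, per-pixel
texture, low-frequency illumination gradient), and hair clutter (0–8 dark
quadratic-Bézier strokes drawn after compositing so they occlude the lesion).
The mask is the exact un-blurred polygon support. Defaults were chosen once
as a realistic middle ground and are not tuned.

Not modeled: gel bubbles, rulers, vignetting, multi-lesion images, real ISIC
intensity statistics, lesion types with low skin contrast. Passing tests on
these images shows the architecture, gradients, and training loop work and
that the network can fit lesion structure; it does *not* predict benchmark
scores on real dermoscopy, which require the external datasets and GPU-scale
training.

## Numerical choices and degenerate inputs

- Softmax over tokens is computed with max-subtraction; BCE clamps
  probabilities to [1e-7, 1 − 1e-7].
- Non-finite values entering the attention raise immediately rather than
  propagating; a non-finite loss aborts training with diagnostics.
- Input sizes must be divisible by 16; the DSA block rejects inputs whose
  stride-16 resolution does not match its memory-unit token count (the
  memory units tie a trained model to its configured input size — `predict`
  therefore resizes arbitrary images to the model's input size and resizes
  the probability map back before thresholding).
- Mask PNGs are binarized at > 127 (ISIC masks are 0/255); images are resized
  bilinearly, masks nearest-neighbor.
- Duplicate dataset ids are an error; unpaired images/masks go to an
  exclusion report instead of being silently dropped.

## Known limitations

- Pure-NumPy training is single-device and orders of magnitude slower than a
  GPU framework; the package is built for inspection, testing and desk-scale
  experiments, not for reproducing full benchmark training.
- The exact stage/width layout of the reference encoder is unknown; only its
  compute budget is matched. Different layouts with the same budget could
  behave differently at full scale.
- The eval-time expectation mask is a modeling choice (the alternative —
  sampling at inference — would make reported test metrics stochastic).
- Memory units are resolution-specific; transferring a checkpoint across
  input sizes is not supported.
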