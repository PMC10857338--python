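# Methods

This note records the model, the procedures and the design choices the
package makes where the design was genuinely open, together with what
the synthetic-data experiments do and do not demonstrate.

## Architecture

The detector is a fully convolutional single-stage network in the
YOLOv8 family, reduced to about one million parameters. Backbone:
`Conv(3→16,s2) → Conv(→32,s2) → C2f(32) → Conv(→64,s2) → C2f(64) →
Conv(→80,s2) → C2f(80)×2 → Conv(→96,s2) → C2f(96) → SPPF(96, k=5)`.
The neck is a closed-loop aggregation: two nearest-neighbor ×2
upsampling + concatenation + C2f steps down to stride 8, then two
stride-2 Conv + concatenation + C2f steps back up, yielding features of
64/80/96 channels at strides 8/16/32. Each Detect block has three
decoupled branches (box, class, depth), each two Conv blocks
(hidden widths 24/66/24) followed by a plain 1×1 convolution. Every
convolution except those three per-task output layers is followed by
batch normalization (ε=1e-3, momentum 0.03) and SiLU.

**Width calibration.** The exact per-stage widths are a free design
choice; we fixed the schedule above by requiring simultaneously
(a) 1.06 M trainable parameters and 4.24 MB fp32 storage at nc=80,
(b) 1.04 M and 4.18 MB at nc=1, and (c) 64 channels at the stride-8
detect level. The printed counts are the only hard constraints; many
schedules satisfy them and this one also keeps the compute profile
balanced across stages.

**Box representation.** Each side distance is a categorical
distribution over `reg_max = 4` bins (stride units 0..3) decoded as the
softmax expectation. The derived quantity
`ModelConfig.max_box_extent(level) = 2·(reg_max−1)·stride[level]`
documents the largest decodable box side per level (48/96/192 px); the
box-width identity width = (l+r)·stride fixes the factor 2·(reg_max−1)
rather than 2·reg_max−1.

**Class head prior.** The final class conv bias starts at −4.595
(prior probability ≈ 0.01) so the background-dominated BCE is balanced
from the first steps.

## Loss and assignment

The objective is the λ-weighted, N_pos-normalized sum of CIoU box loss,
BCE classification, distribution focal loss and a depth MSE, plus
decoupled weight decay φ‖θ‖² realized inside the optimizer
(φ = 5e-4). Unprinted weights default to the one-stage-detector
convention λ_box=7.5, λ_cls=0.5, λ_dfl=1.5, and λ_depth=1.0; all are
configurable. In the CIoU term, α = v/(1−IoU+v) with ε=1e-7 in the
denominator, applied literally (no overlap gating) and fully
differentiable — the finite-difference gradient checks cover the whole
term including α. Images without foreground contribute the
(unnormalized) classification term only.

Task-aligned assignment uses top-k = 10 candidates per object among
cells whose center falls inside the object box, ranked by
`score^0.5 · IoU^6`; a cell claimed by several objects goes to the one
with highest IoU (ties to the lowest index). Foreground classification
targets are alignment-normalized soft scores (each object's best cell
receives its best IoU). Two deliberate deviations from the bare rule:
an object whose box contains no cell center (or that loses all its
candidates) falls back to the nearest *background* cell, so tiny
objects always receive a gradient without disturbing cells owned by
other objects; and DFL targets are clamped into [0, reg_max−1−1e-6].

The DFL term follows the canonical two-bin cross-entropy definition
(proximity-weighted log-probabilities of the bracketing integer bins,
averaged over the four sides).

## Training

Adam with the AMSGrad max-corrected second moment (β = 0.9/0.999,
ε = 1e-8) and decoupled decay; learning rate linear from 1e-4 to 1e-3
over three warmup epochs, then cosine back to 1e-4, interpolated per
step. Gradients are clipped at global norm 10 for small-batch
stability. Mosaic/mixup can be switched off after configured epochs;
mixup weights are Beta(32,32); color jitter (±0.4
brightness/contrast/saturation, ±0.015 hue) and horizontal flip run at
p=0.5 when enabled. Validation losses for model selection are computed
with augmentation off; the checkpoint kept is the lowest-validation-loss
epoch (training loss when no validation split exists).

**Batch-norm recalibration.** The running-statistics momentum (0.03) is
tuned for long schedules; on the short runs this package targets, the
stored statistics lag the trained activations so badly that
inference-mode outputs are unusable. After training (and before each
validation pass) the running mean/var of every BN layer is therefore
recomputed as the exact average of batch statistics over one
unaugmented pass of the training set. This is a deterministic
post-processing step, not extra optimization.

## Depth labels

A depth map is dimensionless with no fixed range; larger = closer. Each
object's label is 0.5·(mean + max) of the depth values whose pixel
centers fall inside its (clipped) box — the midpoint biases the label
toward the near surface rather than the background the box also covers.
Raw backend values are used without per-image normalization (the depth
MSE is then in backend units²); membership is by pixel-center inclusion
and backends with a different native resolution are resampled
bilinearly to the image frame. An empty box/raster intersection is an
error, a failing backend skips that image and the run continues.

## Synthetic orchard generator

The generator emulates the orchard-benchmark regime: up to 120
quasi-circular bright fruits per image (default range 1–120, radii
8–22 px at 320²) packed without overlap on a textured green-brown
background, with a planar-gradient depth map (z = 1 + 0.02·y: the lower
image region, nearest the camera in an orchard shot, is closest) whose
per-box statistics are known in closed form. Labels are produced by the
package's own representative-depth operator, so ground truth is
internally consistent. Nearer fruits are rendered brighter, emulating
illumination falloff and giving the depth head an appearance cue in
addition to image-position context.

What passing on this fixture shows: the full pipeline — assignment,
four-term loss, optimization, decode, metrics — can drive the network
to memorize a small scene set to near-perfect detection and depth
fidelity, and every primitive agrees with brute-force references. What
it does not show: generalization to real orchard imagery, robustness to
occlusion, lighting and scale variation, or real monocular-depth label
noise; those require the external datasets and a real depth backend,
both outside this package's test scope.

**Integration-run sizes.** The overfit check trains 300 epochs on 8
images (2–6 fruits each) at 320×320 with batch 4 and asserts
training-set mAP50 ≥ 0.95 and depth MSE ≤ 1% of the label variance;
the quantization check compares fp32 and int8 on those 8 plus 12 fresh
images from the same distribution.

## Quantization

Post-training static quantization: each conv + BN pair is folded
(W′ = W·γ/σ, shift = β − μγ/σ), the folded weight is quantized
per-tensor to signed 8-bit (symmetric, scale = max|W′|/127), and
activation ranges recorded during a calibration pass become
quantize–dequantize round trips on the pre-activation maps
(asymmetric, zero-point in int8 range). SiLU and the three final
per-task convolutions stay float32. The folded shift is stored back in
the BN tensors (γ=1, σ²=1−ε, μ=0, β=shift), so the module tree and
every tensor name/shape are preserved exactly while the arithmetic is
the folded convolution. Serialized int8 archives store one byte per
quantized weight plus per-tensor scales; the measured size ratio is
≈ 0.25–0.32 of fp32.

## Filter ablation

Blocks are addressed by their graph names (conv1..conv7, c2f1..c2f8,
sppf, detect1..3). Within every conv layer of a block, ⌈p·F⌉ filters
are selected as the most mutually similar group — unit-normalized
weight vectors, pairwise Euclidean distances, greedily grown from the
closest pair by minimal average distance — and zeroed. Similarity is
defined within a layer (filters of different layers are not
commensurable); the block-level proportion applies to each of its
layers. Zeroing covers the conv weights, the conv bias and the
channel's BN affine and running mean, which makes the ablated channel's
output exactly zero on any input (BN of a zero map would otherwise leak
its β). A fully ablated class head emits identically constant (zero)
logits, i.e. confidence 0.5 everywhere; detections vanish for
thresholds above 0.5.

## Evaluation

COCO-protocol metrics: greedy confidence-ordered matching per image and
class, 101-point interpolated AP, macro-averaged mAP50 and mAP50–95
(IoU 0.50:0.05:0.95). Reported precision/recall are read at the argmax
of the macro F1–confidence curve (grid step 0.005). Depth MSE is
computed over matched true positives at IoU 0.5 only (unmatched
detections have no defined ground-truth depth) and reported as
undefined, not zero, when there are no pairs. Default operating
points: confidence 0.10 / NMS IoU 0.60 for the 80-class profile,
0.20–0.27 / 0.80 for fruit profiles; NMS is class-wise.

## Numerical choices and limitations

All network math is float32 (the autodiff engine preserves float64 for
high-precision loss checks); ε-guards: 1e-7 in IoU/CIoU/BCE clamps,
1e-3 in BN. NMS and matching tie-breaks are deterministic (confidence,
then lower index). Runs are reproducible given the config seeds;
convolution uses im2col + BLAS, so exact bitwise equality across BLAS
builds is not guaranteed, only within-build determinism. Known
limitations: single-node CPU training only, no EMA of weights, no
metric (physical-unit) depth calibration, and the int8 path simulates
quantized arithmetic in float rather than executing integer kernels.
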