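# Methods

## Problem and model

Fundus image quality is judged no-reference (no pristine counterpart
exists) along three human-visual-system dimensions — uneven illumination
or color (I/C), blur, and low contrast (LC) — plus an overall verdict.
Each item is a binary classification (1 = good) handled by its own scalar
head; a convenience wrapper can train all four, but nothing is shared
between items at the loss level.  The prediction is
`q̂ = g(f(X;θ) · att(f(X;θ);γ); δ)` with binary cross-entropy on
`sigmoid(q̂)`; probabilities are binarized at a strict `> 0.5` (a score of
exactly 0.5 maps to 0 — the tie rule is documented rather than load-bearing).

## Canonicalization

Inputs are cropped so the content (mean-channel brightness > 0.02 on the
[0,1] scale) fits a centered square, zero-padding when the content box is
non-square and touches the frame — padding never cuts content, and the
operation is idempotent.  The square is resized to 512×512 (any side
divisible by 32 is accepted; the /32 feature grid downstream requires it)
with bilinear, antialiased resampling.  The eye-area mask is the largest
connected component of an Otsu brightness threshold unioned with a
dilated Sobel edge map, hole-filled, then eroded by the dilation radius so
the boundary stays tight; on an analytic disk fixture the mask's IoU with
truth exceeds 0.98.  Gaussian corruption for robustness experiments adds
i.i.d. noise (default mean 0, variance 0.05) on the [0,1] intensity scale
and clips to [0,1]; [0,1] is the only scale on which a 0.05 variance is a
meaningful perturbation, and clipping (rather than rescaling) preserves
the interpretation of untouched pixels.  At mid-gray the clipped sample
variance measures ≈ 0.048.

## SIR extractor

Stage activations come from a 50-layer bottleneck residual backbone
(stages at /4, /8, /16, /32; channel counts 256/512/1024/2048).  Scale i
(1..3) is rescaled to O_i = 16/32/64 channels by a 1×1 conv–BN–ReLU unit,
split into non-overlapping chunks of the stage-4 spatial size, and the
chunks are concatenated channel-wise.  Two conventions are fixed as part
of the format contract, since any consistent choice yields the same model
class:

- chunk count k_i is the **total** number of chunks (64/16/4; grid side
  √k_i = 8/4/2) — the only reading consistent with the stacked channel
  sizes 16·64, 32·16, 64·4;
- chunks are ordered row-major (row index outer, column inner), and the
  final concatenation runs in scale order 1, 2, 3, 4.

The rearrangement is a pure permutation (bijection on elements), verified
bit-exactly against an explicit-loop reference and by reassembly.  Each
stacked map and the stage-4 map are projected to 128 channels (1×1
conv–BN–ReLU) and concatenated: `[512, H/32, W/32]`.

Backbone weights are He-initialized from a seed.  No pretrained
checkpoint is bundled; CPU-scale experiments use the `reduced` preset
(stem 8, stage widths 4/8/16/32, one block per stage, O = (4,8,16),
32-channel projections) which preserves every shape contract at ~1/256 of
the compute.  Batch-norm uses batch statistics in training and running
averages in eval mode; all determinism tests run in eval mode.

## Attention and aggregation

- *Spatial attention*: three 3×3 conv–BN–ReLU blocks (128→64→32 channels)
  followed by a 1×1 conv and sigmoid — a single-channel map in [0,1]
  broadcast across channels.  Chosen for bounded weights and modest
  receptive-field growth; depth/widths are configuration, not contract.
- *Self-attention*: a non-local block with 1×1 query/key projections to
  C/8 channels, a C-channel value projection, softmax over key positions
  scaled by 1/√d, an output projection, and a residual add.  It is
  permutation-equivariant over spatial positions (no positional
  encoding); with the value/output projections pinned to identity,
  residual off and attention forced uniform it reduces to the spatial
  mean — the closed form used to test it.
- *Aggregation*: global average pooling then a two-layer head
  (512→128→1, ReLU between).  The eye-mask variant gates the stage-4
  feature with the mask area-averaged to the feature grid and binarized
  at 0.5.

The loss is computed in the numerically stable logit form
(`max(z,0) − z·q + log(1+e^−|z|)`), equivalent to BCE∘sigmoid; the sigmoid
is materialized only at inference.

## Training protocol

Adam with weight decay 5e-4, minibatch 8, 20 epochs; learning rate 1e-3
for newly added layers and 1e-4 for backbone parameters (the 1:10 ratio),
with no schedule and no early stopping — the epoch with the highest test
accuracy is selected.  Splits are seeded and stratified: an 80/20 holdout
(per-class train counts within one sample of the target) or 5-fold
cross-validation with disjoint, exhaustive test folds.  The original
protocol's two fixed random rounds with shipped index files are replaced
by seeded splits; importing explicit index lists is supported by passing
indices directly.  AUC uses trapezoidal integration over all score
thresholds, which equals the Mann–Whitney average-rank statistic; with a
single class present AUC is undefined and the error object carries the
still-defined accuracy.  Reproducibility of training is asserted on the
loss trajectory to 1e-4 rather than bit equality.

## Saliency maps

For attention variants the learned map itself is shown (for
self-attention, the per-position attention received, averaged over
queries); for the attention-free baselines, gradient-weighted activation
mapping on the stage-4 feature (channel weights = spatially pooled logit
gradients, rectified weighted sum).  Maps are bilinearly upsampled to the
image, min–max normalized per image (an all-constant map becomes uniform
0.5 by convention), restricted to the eye area, and blended with the
image at alpha 0.4 using the jet colormap.

## Synthetic data

The generator emulates color-fundus geometry: a bright circular retina
(radius 0.47·side) with radial vignetting and low-frequency mottle, an
offset optic disc, and a vessel tree drawn as seeded biased random walks
from the disc.  Defects map to labels through fixed thresholds chosen so
the classes are visually and statistically separable: an illumination
ramp or hotspot of strength ≥ 0.3 flips I/C to poor; Gaussian blur with
σ ≥ 2 px flips Blur (blur at σ = 4 drops the Laplacian-response variance
by far more than half); keeping ≤ 0.5 of the intensity spread flips LC
(RMS contrast inside the eye mask scales by the keep factor); Overall is
the conjunction.  Labels are a pure function of the defect specification
— noise never flips them.  Dataset sampling draws each item's good/poor
state independently (default good-prevalence 0.6, near the pooled CFP
annotation fractions) and then samples defect magnitudes away from the
thresholds (poor blur σ ∈ [2.5, 5], poor contrast keep ∈ [0.25, 0.45],
poor illumination strength ∈ [0.45, 0.9]).

What the generator does **not** emulate: disease lesions, ultrawide-field
optics, camera vendor color profiles, or annotator disagreement.  Passing
tests on synthetic data therefore demonstrate that the architecture,
training loop and metrics behave as specified and that the model can
learn genuinely separable quality defects at desk scale — not that the
published real-data accuracies transfer.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full-width extractor
forward-only at 512×512 (random weights) to measure architecture
contracts, and train only the reduced preset — 200 images at 128 px, 5
epochs — for the learning benchmark; these sizes are the package's chosen
desk-scale defaults.  All arithmetic is float32; gradient tests compare
against float64 loop oracles or use tolerances consistent with float32
accumulation (~1%).  Adam uses the classic L2-coupled weight decay.  The
checkpoint is a single `.npz` with a JSON metadata entry (schema tag
`retiqa-checkpoint-v1`).

## Known limitations

- No pretrained backbone weights, so full-width training from scratch on
  real data would need far more epochs than the published protocol; the
  reduced preset is the practical CPU path.
- The package assesses quality; it does not enhance poor images.
- Multi-class grading, variant ensembling and UWF-specific geometry are
  out of scope.
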