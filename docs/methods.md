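# Methods

This note documents the model, the pipeline conventions, the synthetic
phantoms, and the design decisions taken where the architecture left genuine
freedom.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Network

One **fire module** maps an n-channel feature map through a ReLU-activated
1×1 squeeze convolution (s₁ channels) into parallel ReLU-activated 1×1 (e₁)
and 3×3 (e₃) expand convolutions; the branches are concatenated, 1×1 branch
first, giving e₁+e₃ output channels.  All convolutions are stride 1 with
shape-preserving zero padding and one bias per output channel; there is no
batch normalization.  The closed-form parameter count of a module is
n·s₁ + s₁ + s₁·e₁ + e₁ + 9·s₁·e₃ + e₃, and the package asserts this equals
the allocated array sizes for every configuration it builds.

The full network has 4 resolution levels (128→64→32→16→8 for 128×128
patches) plus a bottleneck, two fire modules per level:

- **Encoder level l**: two chained fire modules, then 2×2/stride-2 max
  pooling that records the argmax offset of each window (tie: first maximum
  in row-major window order).  The level output eₗ concatenates the pooled
  fire output with the input patch pooled to the same resolution (the left
  leg).
- **Decoder level l**: index-based unpooling places each value at its
  recorded position (zeros elsewhere), doubling resolution; the
  combined-connection concatenates the encoder stream at that resolution
  (e₍ₗ₋₁₎, or the raw patch at full resolution), then two fire modules.
- **Right leg**: seeded with the ×2 nearest-neighbour-upsampled bottleneck
  output, then at each level concatenates the decoder output and — when
  long skips are enabled — the left-leg side input at that resolution,
  upsampling ×2 between levels.  The leg is parameter-free.
- **Classifier**: the top decoder output and the right leg are concatenated
  and mapped by a 1×1 convolution + softmax to 4 channels in the fixed
  order (0 background, 1 CSF, 2 GM, 3 WM).

Two structural facts are *forced* by index-based unpooling and are easy to
miss: the stream entering each unpooling must carry exactly the channel
count its indices were recorded with, so (a) the bottleneck expand width
must equal the deepest encoder expand width, and (b) the decoder level
producing resolution R must use the expand width of the encoder level
*above* the one whose indices it consumes (the top decoder level reuses
level 1's widths).  `SMSegNetConfig.layout()` validates this closure and
names the offending layer on violation.

Ablation flags: `long_skips_enabled` removes only the side-input terms of
the right leg (encoder/decoder shapes are untouched; classifier fan-in
drops by one channel per level); `combined_connections_enabled` removes the
decoder skip concatenations (unpooling indices are kept — they are the
upsampling mechanism, not an optional extra).

### Channel plan

Per-level widths are solved, not chosen: `solve_channel_plan` enumerates
plans with expand widths doubling from a base (e₁ = e₃, both modules of a
level sharing widths, decoder mirrored as above) and solves the per-level
squeeze widths — the parameter total is exactly linear in them — for an
exact total of 835,776 trainable parameters.  Among exact solutions it
deterministically prefers minimal L1 deviation from the SqueezeNet-style
ratio s₁ = e/2, then smaller base width.  The winner (base 20: expand
20/40/80/160, squeeze 18/21/37/81, bottleneck squeeze 81) is frozen in
`resources/reference_plan.yaml`; a test asserts the solver reproduces the
frozen plan.  The plan is not unique — the budget equation has many integer
solutions — which is why the tie-break rule is part of the solver contract.

### Initialization, loss, optimization

Weights are He fan-in normal (std √(2/fan-in)), biases zero, drawn from a
seeded generator in build order, so builds are bit-reproducible per seed.
The loss is mean per-pixel cross-entropy between the softmax output and the
one-hot truth, summed over the 4 classes and averaged over pixels and
batch; the probability-space form floors log arguments at 1e-12, while the
training path uses the fused log-softmax, which needs no floor.  The
optimizer is SGD with classical momentum (v ← μv − η∇; θ ← θ + v), defaults
η = 0.001, μ = 0.99, validation split 0.2, 10 epochs.  Early stopping
monitors validation loss (train loss when the split is empty), stops after
`patience` (default 3) epochs without improvement and restores the best
weights.  The validation set is the last 20% of the seeded shuffle of the
patch list.

The network, including reverse-mode autodiff for every operation, is
implemented in NumPy (float32; float64 is preserved when fed in, which the
finite-difference gradient tests use).  Analytic gradients agree with
central differences to < 1e-4 relative error once parameters are perturbed
off exact ReLU kinks — with zero-initialized biases downstream of zeroed
squeeze outputs, pre-activations can sit exactly at 0, where the valid
subgradient (0) differs from a two-sided difference quotient.

## Pipeline conventions

- Coordinates are 0-based row-major; the slice axis is the third array
  axis; "axial" slices along it.  Plane changes are pure axis permutations
  (axial (H,W,S) → coronal (W,S,H) → back), bijective on voxels.
- `pad_to_square` (default 256) splits padding evenly per axis, extra pixel
  to the bottom/right; a 208×176 slice pads as 24/24 top/bottom and 40/40
  left/right.  Oversized slices are an error; nothing is ever resampled.
- `extract_slices` keeps `count` (48) indices at step `spacing` (3),
  window centred: start = ⌊(S − (3·47+1))/2⌋, so a 176-slice volume yields
  indices 17, 20, …, 158.  The start is exposed for other placements.
- `divide_patches` tiles in row-major order (TL, TR, BL, BR for quadrants);
  overlapping mode slides at the given stride and requires
  (side − patch) divisible by stride, giving ((side−patch)/stride + 1)²
  windows — 289 on a 256 canvas at stride 8.  Overlap fusion averages
  softmax probabilities per pixel over covering windows before the argmax.
- Intensities are min–max normalized to [0,1] per volume before patching.
- Pad/crop and divide/reassemble are exact inverses (property-tested).

## Metrics

DSC = 2|s∩s′|/(|s|+|s′|), JI = |s∩s′|/|s∪s′| (so JI = DSC/(2−DSC) holds
identically), and the Hausdorff distance is the larger directed maximum of
Euclidean nearest-point distances between foreground voxel centres (no
surface extraction), computed with KD-trees and reported in pixel units; a
`spacing` argument scales to millimetres.  A class absent from both maps is
reported missing (NaN), never 0; present in exactly one map gives
DSC = JI = 0 with HD missing.  Reports keep full precision and offer a
2-decimal rounded view; at that rounding a DSC of 0.97 pairs with a JI of
0.94 (97/103).

## Phantoms

`make_phantom` stacks per-slice nested, axis-aligned ellipses (semi-axes
0.42/0.34/0.21 of the volume's height and width for CSF/GM/WM), scaled by a
profile that shrinks towards the first and last slices to mimic
non-informative edge slices, and jittered per slice (±5% by default, one
draw shared by the three ellipses so nesting cannot break).  Intensities
are class means 0.05/0.25/0.55/0.80 plus Gaussian noise (σ = 0.05 default),
optionally times a per-slice second-order polynomial bias surface
(amplitude 0 by default), clipped to [0,1].  Default dims 176×208×176
exercise the 256-canvas padding arithmetic verbatim.  Subject i of a
dataset uses seed base+i; everything is bit-reproducible from the seed.

What the phantoms deliberately lack: anatomy (gyri/sulci, partial volume,
tissue texture), MR physics, inter-subject intensity variation.  Passing
tests on phantoms therefore demonstrate that the code paths are correct and
that the network can learn a segmentation end to end — they say nothing
about accuracy on real MRI.

## Desk-scale problem sizes

The test suite trains only small configurations: the overfitting check uses
8 phantom patches of 64×64, a narrowed 3-level plan (expand 8/16/32,
squeeze 4/8/16, 34,212 parameters), and the published optimizer settings
for up to 500 epochs (batch 4, patience 30, seed 0) — about two minutes on
one CPU — and requires a training-set mean foreground DSC ≥ 0.90.  The
reference 835,776-parameter model is built and run forward in tests, but
never trained there; full-scale training on real MRI datasets is out of
scope for this package's validation.

## Known limitations

- 2D only: volumes are segmented slice-wise; no 3D convolutions.
- Ablated variants get whatever total the channel arithmetic gives:
  toggling long skips changes the classifier fan-in by exactly one channel
  per level (4 parameters each with 4 classes), so only the combined
  configuration's total is pinned to the 835,776 budget.
- Overlapping-mode inference is dense (289 windows per 256 canvas); no
  window subsetting is implemented.
- NumPy training is single-threaded per matmul batch and meant for
  desk-scale experiments, not full-dataset training.
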