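# smsegnet

Automatic tissue segmentation of T1-weighted brain MRI — cerebrospinal fluid
(CSF), gray matter (GM) and white matter (WM) against background — with a
lightweight *squeeze M-shaped* encoder–decoder network, for researchers who
need volumetric tissue maps without a GPU-scale parameter budget.

## The model

The network is an M-shaped fully convolutional encoder–decoder built from
SqueezeNet-style **fire modules**: a 1×1 *squeeze* convolution reduces *n*
input channels to *s₁*, feeding parallel 1×1 and 3×3 *expand* convolutions
whose outputs are concatenated (*e₁ + e₃* channels), every stage
ReLU-activated.  Replacing plain 3×3 convolutions with squeeze/expand pairs
cuts the weight count roughly ninefold per layer, which is what keeps the
whole model under 10⁶ parameters.

Around the fire modules the M-shape adds:

- a **left leg** of multi-scale side inputs — the input patch repeatedly
  2×2 max-pooled and concatenated into each encoder level;
- **combined-connections** from each encoder level to its decoder level:
  the max-pooling argmax indices (used by parameter-free unpooling to put
  features back at their original coordinates) *and* a skip concatenation of
  the encoder features at the matching resolution;
- a **right leg** of deep supervision — every decoder output, upsampled to
  full resolution and concatenated, optionally with **long skip
  connections** from the left leg, feeding the final 1×1 softmax classifier
  over (background, CSF, GM, WM).

Training minimizes mean per-pixel cross-entropy
L(y, ŷ) = −Σᵢ yᵢ log ŷᵢ with SGD (learning rate 0.001, momentum 0.99,
validation split 0.2, early stopping).

Volumes are never resampled: each slice is zero-padded to a 256×256 canvas
(e.g. 208×176 slices get 24/24 rows and 40/40 columns of zeros), 48 slices
per volume are retained at an interval of 3, and each padded slice is
divided into four uniform non-overlapping 128×128 patches (or a stride-8
overlapping grid whose softmax outputs are averaged before the argmax).
Per-class Dice (DSC), Jaccard (JI = DSC/(2−DSC)) and Hausdorff distance
evaluate predictions against ground truth.

The per-level channel widths of the reference network are not hand-picked:
`smsegnet.plan.solve_channel_plan` derives them by constrained enumeration
(widths doubling per level, e₁ = e₃, decoder mirroring the encoder) so that
the total is exactly **835,776** trainable parameters; the solved plan is
frozen in `src/smsegnet/resources/reference_plan.yaml`.

The network itself is implemented in NumPy (convolutions, index-recording
pooling/unpooling, reverse-mode autodiff, SGD), so the package has no
deep-learning framework dependency and runs anywhere SciPy does.

## Worked example

Overfit a small network on 8 slices of a synthetic brain phantom — the
package generates its own seed-deterministic phantoms (nested WM ⊂ GM ⊂ CSF
ellipses with Gaussian noise), so no data download is needed:

```python
import numpy as np
import smsegnet as sm

vol, lab = sm.make_phantom(sm.PhantomSpec(dims=(56, 56, 26), seed=7))
data = sm.normalize_intensity(vol.data)
idx = sm.extract_slices(26, spacing=3, count=8)
X = np.stack([sm.pad_to_square(data[:, :, k], 64)[0] for k in idx])
Y = np.stack([sm.pad_to_square(lab.data[:, :, k], 64)[0] for k in idx]).astype(np.int16)

cfg = sm.SMSegNetConfig(plan=sm.ChannelPlan((8, 16, 32), (4, 8, 16), 32, 16),
                        input_size=(64, 64, 1))
clf = sm.SMSegNetClassifier(config=cfg, epochs=500, batch_size=4,
                            patience=30, seed=0)
clf.fit(X, Y)
pred = clf.predict(X)
for c, name in ((1, "CSF"), (2, "GM"), (3, "WM")):
    print(f"{name} DSC {sm.dice(Y == c, pred == c):.3f}")
```

which prints (about two minutes on one CPU core):

```
CSF DSC 0.974
GM DSC 0.985
WM DSC 0.988
```

The training loss fell from 1.4928 to 0.0200 over 500 epochs; a mean
foreground DSC of 0.982 on the training patches shows the architecture
learns the task end to end.  (This is an overfitting smoke check on
synthetic data, not an accuracy claim about real MRI.)

The same flow is available from the shell:

```sh
smsegnet phantom --subjects 2 --out data/
smsegnet train --volumes data/subject000_volume.nii.gz \
               --labels data/subject000_labels.nii.gz --out model
smsegnet predict --model model --in data/subject001_volume.nii.gz --out pred.nii.gz
smsegnet evaluate --pred pred.nii.gz --truth data/subject001_labels.nii.gz
smsegnet audit-params
```

`audit-params` prints the per-layer manifest ending in

```
classifier.w                     (4, 684, 1, 1)               2736     835772
classifier.b                     (4,)                            4     835776
TOTAL                                                       835776
budget 1000000: within
```

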