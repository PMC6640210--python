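# gliomaseg

End-to-end 2-D brain-tumor segmentation on multimodal MRI: an
Inception-module U-Net trained with a smoothed negative-log-Dice loss,
BRATS-style preprocessing, a k-fold cross-validated ablation protocol, and
a synthetic phantom generator so everything runs and tests without the
gated BRATS data.

## Who this is for

Researchers and students working on glioma segmentation who want a fully
inspectable reference implementation of this model family — including the
network and its training loop, which are written in numpy with manual,
test-verified backpropagation rather than a deep-learning framework — plus
a harness for architecture/objective ablations on synthetic data.

## The problem and the model

BRATS-style data provides four co-registered MRI modalities per patient
(FLAIR, T2, T1, T1C) and per-pixel labels for three mutually exclusive
**intra-tumoral structures**: necrotic/non-enhancing tumor core (label 1),
peritumoral edema (label 2), enhancing tumor (label 4). Nested **glioma
sub-regions** are their unions: whole tumor WT = 1∪2∪4, tumor core
TC = 1∪4, enhancing tumor ET = 4. The package supports both labeling
regimes: a pixel-wise softmax head for the disjoint structures, a
pixel-wise sigmoid head for the nested sub-regions, and lossless
conversion between the two.

The network is a U-Net whose convolutional blocks are four-branch
Inception modules (1×1 conv, 3×3 conv, cascaded 3×3 convs ≡ 5×5 receptive
field, and 3×3 max-pool + 1×1 projection; each branch emits F maps, so a
block outputs 4F channels), with conv → batch-norm → ReLU throughout,
2×2 max-pool downsampling, nearest-neighbor upsampling and skip
concatenations. The ablation baseline swaps each Inception block for two
plain 3×3 convolutions of matched depth.

Segmentation quality is the Dice similarity coefficient
DSC(P, G) = 2|P∩G| / (|P| + |G|); training minimizes its smoothed
negative-log form

    L(P, G) = −log[(2·ΣPG + γ) / (ΣP + ΣG + γ)],     γ = 100,

extended to K classes by averaging the smoothed ratio inside the log.
γ keeps the loss finite when a class is absent from both prediction and
truth. Model variants are compared over k-fold cross-validation with
two-tailed equal-variance t-tests on the per-fold mean region Dice.

## Worked example

```python
import numpy as np
from gliomaseg import (PhantomParams, generate_slice, encode_intra,
                       intra_to_subregions, dsc, multiclass_loss, LossConfig,
                       ModelConfig, build_model, binarize)

# a noise-free phantom slice: brain ellipse with nested tumor discs
params = PhantomParams(image_size=64, brain_axes=(26, 28), tumor_center=(36, 30),
                       r_wt=12, r_tc=8, r_et=4, noise_sd=0.0, seed=0)
image, labels = generate_slice(params)

intra = encode_intra(labels)              # disjoint (NET, ED, ET) masks
sub = intra_to_subregions(intra)          # nested (WT, TC, ET) masks
print("region pixel counts (WT, TC, ET):",
      [int(sub.masks[..., i].sum()) for i in range(3)])

net = build_model(ModelConfig(input_height=64, input_width=64, depth=3,
                              branch_filters=4, regime="subregion"), seed=0)
print(net.summary().splitlines()[0])

probs = net.forward(image.intensities.astype(np.float32))
pred = binarize(probs, "subregion")
print("untrained whole-tumor Dice: %.3f"
      % dsc(pred.masks[..., 0], sub.masks[..., 0]))
print("smoothed Dice loss vs truth: %.4f"
      % multiclass_loss(probs, sub.masks.astype(float), LossConfig()))
```

prints

```
region pixel counts (WT, TC, ET): [441, 197, 49]
inception U-Net, 151,355 trainable parameters
untrained whole-tumor Dice: 0.234
smoothed Dice loss vs truth: 1.8185
```

The whole-tumor disc (radius 12) covers 441 pixels and strictly contains
the core (197) and the enhancing disc (49). The untrained network's
thresholded output overlaps the truth only by chance (Dice 0.23), and the
loss sits near its typical initialization value; training drives it toward
0 (see below).

## Command line

`gliomaseg synth` generates a phantom dataset (NPZ slices + JSON manifest),
`gliomaseg preprocess` converts one patient's NIfTI volumes through the
five-step pipeline, `gliomaseg train` fits one variant on one fold,
`gliomaseg evaluate` scores a checkpoint into a per-slice region-Dice CSV,
`gliomaseg ablate` runs the full variants × folds protocol, and
`gliomaseg report` renders the mean ± SD table and the pairwise p-value
matrix. `--help` on any command lists the options.

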