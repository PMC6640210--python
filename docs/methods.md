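# Methods

## Problem and scope

`gliomaseg` implements an end-to-end 2-D brain-tumor segmentation framework
for multimodal MRI in the style of the BRATS benchmark: four co-registered
modalities per patient (FLAIR, T2, T1, T1C) and per-pixel expert labels for
three mutually exclusive *intra-tumoral structures* — necrotic and
non-enhancing tumor core (label 1), peritumoral edema (label 2), enhancing
tumor (label 4). From these, three nested *glioma sub-regions* are defined:
whole tumor WT = 1∪2∪4, tumor core TC = 1∪4, enhancing tumor ET = 4. The
package covers the label codec between the two representations, the
preprocessing pipeline, an Inception-module U-Net with a plain U-Net
ablation baseline, a smoothed negative-log-Dice objective supporting both
labeling regimes, the k-fold cross-validated ablation protocol with t-test
comparisons, and a synthetic phantom generator that stands in for the gated
BRATS data.

The network engine (convolution, batch normalization, pooling, Adam,
backpropagation) is implemented in numpy inside the package
(`gliomaseg.nn`). Analytic gradients of every layer and of the assembled
networks are verified against float64 central differences in the test
suite; convolutions are computed as im2col + BLAS matrix multiplication in
float32.

## Label codec

The intra-tumoral regime is a disjoint 3-channel one-hot stack
(NET, ED, ET); the sub-region regime is a nested stack (WT, TC, ET) with
ET ⊆ TC ⊆ WT. The conversion intra → sub-region is the union map
(WT = NET∨ED∨ET, TC = NET∨ET); its inverse is NET = TC∧¬ET, ED = WT∧¬TC.
The two are exact inverses on valid stacks, and the test suite checks the
round trip on random label maps.

Sigmoid predictions can violate the nesting hierarchy. Predicted stacks are
repaired by intersection (TC ← TC∧WT, then ET ← ET∧TC) before scoring: a
pixel is only ever removed from an inner region, never added to an outer
one, which is the minimal-change reconciliation. Ground-truth stacks are
never repaired — a hierarchy violation there is raised as an error carrying
the offending pixel count. Label 3 (present in older BRATS releases) is
rejected rather than remapped.

## Preprocessing

Five steps, in order, mirroring standard BRATS slice preparation:

1. **Brain bounding box** — the smallest box containing every pixel nonzero
   in any modality of any slice of the patient. The box is per patient (not
   per slice): per-slice boxes would deform anatomy inconsistently across a
   volume. A per-slice option exists behind a flag.
2. **Crop and resize to 128×128** — bilinear for intensities; for label
   maps, nearest-neighbor with an explicit pixel-center index map
   (src = floor((i+0.5)·in/out)), which is deterministic at half-integer
   coordinates and never invents labels.
3. **Tumor-free slice removal** — slices whose ground truth has no pixel in
   {1, 2, 4} are dropped.
4. **Intensity windowing** — per slice and per modality, the 1st/99th
   percentiles (linear-interpolation definition) map to 0/255 with clipping
   outside. A constant channel has a degenerate window and maps to zero
   with a warning. A per-volume percentile option is provided; which of the
   two the original protocol used is ambiguous.
5. **z-normalization** — per-modality mean/std computed over all pixels of
   the *training split of each fold only*, then applied to both splits.
   Fitting on the full dataset would leak validation intensity statistics
   into training; the leakage-free variant is the default.

## Architecture

The segmentation network is a U-Net whose convolutional blocks are
four-branch Inception modules: 1×1 conv, 3×3 conv, two cascaded 3×3 convs
(factorized 5×5 receptive field), and 3×3 stride-1 max pooling followed by
a 1×1 projection. Every branch emits F feature maps (the pooling branch
needs the projection to do so — pooling alone cannot change depth), so a
module maps C_in → 4F at unchanged spatial size. Each convolution is
followed by batch normalization then ReLU.

Topology for depth L and level-0 branch budget F0 (defaults L = 4,
F0 = 16): the encoder applies a block with branch budget F0·2^l then a 2×2
max pool, l = 0..L−1, halving spatial size and doubling depth per level
(feature depths 64, 128, 256, 512 at the defaults); a bottleneck block at
F0·2^L; the decoder upsamples 2× (nearest-neighbor), concatenates the
level-matched encoder feature map (doubling depth), and applies the level's
block. A 1×1 convolution reduces to K = 3 channels, followed by pixel-wise
softmax (intra regime) or sigmoid (sub-region regime). Inputs must be
divisible by 2^L. The published figure's filter counts are not recoverable
from its text, so L and F0 are declared config defaults, not claimed
originals. Weights are He-initialized, biases zero.

The K = 3 softmax has no background channel; background must be encoded as
"no class confident". At binarization a pixel whose maximum class
probability is below 0.5 is declared background, otherwise it takes its
argmax class. An optional explicit background channel (K = 4 softmax,
background dropped before scoring) is available for a probabilistically
coherent background. Sigmoid outputs are thresholded at 0.5 per channel and
hierarchy-repaired.

The background-less softmax interacts poorly with the Dice-ratio loss:
softmax forces every background pixel to place total mass 1 on some tumor
channel, and the loss is minimized by concentrating that unavoidable mass
on a single channel (inflating one denominator rather than three), which
drives that channel's probabilities above the 0.5 gate on background and
corrupts its binarized mask. On phantoms this is observable as one or two
regions failing to appear in predictions while the others are perfect. The
explicit-background-channel head removes the pathology entirely — with it
the intra regime trains to the same quality as the sigmoid regime — and is
what the package's demonstration runs use for the softmax regime. The K = 3
head remains the default for fidelity to the published description; which
background handling the original work used is not recoverable from it.

The ablation baseline replaces each Inception module with two plain 3×3
conv+BN+ReLU layers of matched output depth (4F), so block type is the only
architectural difference between the compared models.

## Objective

Evaluation uses the Dice similarity coefficient on binary masks,
DSC = 2|P∩G|/(|P|+|G|), with both-empty → 1. Training minimizes the
smoothed negative log of the soft Dice ratio:

    L(P, G) = −log[(2·ΣPG + γ) / (ΣP + ΣG + γ)],  γ > 0,

which is finite and zero-gradient-safe when a class is absent (the 0/0
instability of the raw ratio is the reason γ exists). γ defaults to 100,
an empirical value appropriate for 128×128 slices; it is dimensioned in
pixels, so much smaller images may warrant a smaller γ. The multi-class
form averages the *smoothed ratio* over the K channels inside the log,
L = −log[(1/K)·Σ_i dice_γ(P_i, G_i)]. Using the smoothed ratio per class
(rather than the raw DSC the printed composition would literally imply)
preserves the empty-class robustness that motivates γ; the alternative
composition — mean of per-class logs — is mathematically different
(Jensen's inequality) and is exposed as `LossConfig.reduction`.
Evaluation-time DSC is never smoothed. Batches are pooled into the
per-class sums (a batch is treated as one large image per class).

The analytic gradient, with s_i the smoothed ratio and D_i = ΣP_i + ΣG_i:
ds_i/dP_i[p] = (2G_i[p] − s_i)/(D_i + γ), dL/dP_i = −ds_i/dP_i /(K·mean s).
It is finite everywhere for γ > 0 and drives the training loop directly
(no autodiff).

## Experimental protocol

The 2×2 ablation crosses architecture (plain U-Net vs Inception U-Net)
with labeling regime (intra vs sub-region). Patients are split into k = 10
near-equal folds (by patient, so no patient contributes slices to both
splits of a fold; a slice-level split for literal replication is
deliberately not the default). Each variant trains once per fold with Adam
(lr0 = 1e−4, multiplied by 0.9 every 10 epochs — the decay factor is a
declared default, the original exponential-decay constant being unstated —
batch 64, 100 epochs, no early stopping, final-epoch checkpoint). Intra
predictions are combined into sub-regions before scoring, so all variants
are compared on the same (WT, TC, ET) region Dice. The default evaluates
each fold's model on its held-out fold; the pooled mode (train+val) is
available and labeled as such, since it mixes training data into the
reported score. Variant pairs are compared per region with a two-tailed
equal-variance two-sample t-test on the k fold means at α = 0.05; raw
p-values, no multiple-testing correction.

## Phantoms

A phantom slice is an elliptical brain on a zero background with a nested
three-disc tumor (ED annulus ⊃ NET annulus ⊃ ET disc), modality-specific
contrast, optional smooth multiplicative bias field, and additive Gaussian
noise (default SD 10 intensity units). The default contrast table separates
each tumor tissue from brain by ≥ 3 noise SDs on its designated modality —
edema bright on FLAIR (+70), enhancing tumor bright on T1C (+80), necrotic
core dark on T2 (−60) — so with noise off, a per-modality threshold
separates the tissues exactly and the segmentation task is solvable by a
small network. Per-patient random streams are spawned from the master seed,
making datasets reproducible under parallel generation. Phantoms emulate
the *contrast structure* of the real task, not anatomy: lesions are discs,
there is no MRI physics, no partial-volume mixing, no inter-rater label
noise, and no 3-D context. Passing phantom tests therefore demonstrates
pipeline correctness and learnability, not expected performance on BRATS.

## Scaled-down training runs

The reference protocol (~30k Adam steps: 100 epochs, batch 64, ~20k slices)
is far beyond a single-CPU numpy run, so the package's demonstration runs
compress the schedule rather than truncate it. Adam's per-coordinate update
magnitude is bounded by ≈ lr per step, so a run's total parameter
displacement is bounded by Σ lr_t; the reference schedule's budget is ~2
(30k × 1e−4 × decay). Truncating to a few hundred steps at lr 1e−4 caps
displacement at ~0.03 — He-initialized weights (~0.2–0.35) barely move, and
no faithful implementation can converge under that budget. The
demonstration schedule therefore holds the displacement budget roughly
constant: lr0 = 5e−3 with the same 0.9-per-10-epochs decay shape, 300
steps (budget ~1.5), batch 8, with a depth-3, F0 = 4 network on 32
noise-free phantom training slices — 64×64 in `scripts/acceptance.py`,
48×48 in the test suite's learnability check to keep the default test run
brief. Under this schedule both regimes reach near-perfect training Dice
and held-out region Dice at desk scale. All scaled runs are fully seeded;
the per-fold model seed derives from (master seed, variant, fold).

## Numerical choices and edge cases

- float32 network arithmetic; float64 loss and evaluation reductions.
- Batch-norm: momentum 0.9, eps 1e−5, running statistics for inference;
  conv bias is retained even though BN makes it a null direction (it is
  harmless and keeps the conv layer self-contained).
- Max-pool gradient routing: first window position attaining the max (scan
  order) receives the gradient; ties are measure-zero for continuous
  activations.
- Binarization thresholds: 0.5 for sigmoid channels and for the softmax
  background gate.
- Degenerate inputs raise typed errors: invalid label values, overlapping
  intra channels, hierarchy violations (with pixel count), all-zero
  volumes, zero-variance modalities, non-nesting phantom radii, divergent
  (NaN) training losses.
- kfold uses `np.array_split` on a seeded permutation: sizes differ by at
  most one, deterministic given the seed.

## Known limitations

- 2-D slices only; no volumetric context or 3-D variants.
- The numpy engine is single-threaded BLAS-bound; it is built for
  correctness and desk-scale experiments, not for training on the full
  BRATS dataset.
- Phantom realism is deliberately minimal (see above).
- The softmax regime's background handling is one of two defensible
  readings of a K = 3 head; both are implemented, neither is claimed as
  the original authors'.
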