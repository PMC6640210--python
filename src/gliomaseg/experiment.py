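"""Cross-validated ablation protocol for the segmentation framework.

The experimental design is a 2 x 2 ablation — plain U-Net vs Inception
U-Net, crossed with the two labeling regimes (intra-tumoral structures via
softmax vs glioma sub-regions via sigmoid) — evaluated with k-fold
cross-validation. Patients are partitioned into k near-equal folds; each
variant trains k times, holding one fold out for evaluation. Intra-regime
predictions are always combined into the nested sub-regions before scoring,
so all variants are compared on the same (WT, TC, ET) Dice scores. Variant
pairs are compared per region with a two-tailed equal-variance two-sample
t-test over the k fold means (alpha = 0.05, raw p-values, no
multiple-testing correction).

Training uses Adam with a stepwise-exponential learning-rate schedule
(lr = lr0 * decay_factor ** floor(epoch / decay_interval)) and the
multi-class smoothed negative-log-Dice loss; normalization statistics are
fitted on each fold's training split only.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import nn
from .labels import LabelMap, MaskStack, Regime
from .model import ModelConfig, SegmentationNetwork, binarize, build_baseline_unet
from .objective import LossConfig, evaluate_regions, multiclass_loss, multiclass_loss_grad
from .preprocess import DatasetStats, MultimodalSlice

__all__ = [
    "VARIANTS",
    "SliceDataset",
    "FoldAssignment",
    "TrainConfig",
    "TrainResult",
    "FoldScores",
    "AblationResult",
    "TTestResult",
    "kfold_split",
    "learning_rate",
    "train_fold",
    "evaluate_model",
    "run_ablation",
    "t_test",
    "TrainingDivergedError",
    "DegenerateSampleError",
    "build_baseline_unet",
]

logger = logging.getLogger(__name__)

#: The four ablation variants: architecture x labeling regime.
VARIANTS = (
    "unet-intra",
    "unet-subregion",
    "inception-intra",
    "inception-subregion",
)


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int, step: int):
        self.epoch, self.step = epoch, step
        super().__init__(f"non-finite training loss at epoch {epoch}, step {step}")


class DegenerateSampleError(ValueError):
    """A t-test sample with zero pooled variance (or too few observations)."""


def parse_variant(variant: str) -> tuple[str, Regime]:
    """Split a variant name into (block type, regime)."""
    try:
        arch, regime = variant.split("-")
        block = {"unet": "double_conv", "inception": "inception"}[arch]
        return block, Regime(regime)
    except (ValueError, KeyError):
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


# ---------------------------------------------------------------------------
# Data containers

@dataclass
class SliceDataset:
    """In-memory slice dataset shared by phantoms and preprocessed MRI."""

    images: np.ndarray          # (N, H, W, 4) float
    labels: np.ndarray          # (N, H, W) int
    patient_ids: list[str]
    slice_indices: list[int]

    def __post_init__(self):
        n = self.images.shape[0]
        if not (self.labels.shape[0] == n == len(self.patient_ids) == len(self.slice_indices)):
            raise ValueError("dataset components misaligned")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def patients(self) -> list[str]:
        """Unique patient ids, in first-appearance order."""
        return list(dict.fromkeys(self.patient_ids))

    @classmethod
    def from_slices(
        cls, slices: list[MultimodalSlice], labels: list[LabelMap]
    ) -> "SliceDataset":
        return cls(
            images=np.stack([s.intensities for s in slices]).astype(np.float32),
            labels=np.stack([l.values for l in labels]),
            patient_ids=[s.patient_id for s in slices],
            slice_indices=[s.slice_index for s in slices],
        )


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of patients into k mutually exclusive folds."""

    folds: tuple[tuple[str, ...], ...]

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_of(self, patient_id: str) -> int:
        for i, f in enumerate(self.folds):
            if patient_id in f:
                return i
        raise KeyError(patient_id)

    def split_indices(
        self, dataset: SliceDataset, fold_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) slice indices for holding out one fold."""
        val_patients = set(self.folds[fold_index])
        pid = np.asarray(dataset.patient_ids)
        val = np.flatnonzero(np.isin(pid, list(val_patients)))
        train = np.flatnonzero(~np.isin(pid, list(val_patients)))
        return train, val


def kfold_split(patient_ids: list[str], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly partition patients into k folds of equal or near-equal size.

    Deterministic given ``seed``; fold sizes differ by at most one. Splitting
    is by patient so that no patient contributes slices to more than one fold.
    """
    patients = list(dict.fromkeys(patient_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    shuffled = [patients[i] for i in order]
    folds = tuple(tuple(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), k))
    return FoldAssignment(folds)


# ---------------------------------------------------------------------------
# Training

@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol hyperparameters.

    The learning rate decays stepwise-exponentially: it is multiplied by
    ``decay_factor`` every ``decay_interval`` epochs, starting from ``lr0``.
    ``max_steps`` caps the total number of Adam steps (None = run all
    epochs); scaled-down runs use it to keep the schedule intact while
    bounding work.
    """

    lr0: float = 1e-4
    decay_interval: int = 10
    decay_factor: float = 0.9
    batch_size: int = 64
    epochs: int = 100
    k: int = 10
    seed: int = 0
    gamma: float = 100.0
    max_steps: int | None = None
    pooled_evaluation: bool = False  # evaluate on train+val pooled (literal protocol)

    def __post_init__(self):
        if self.k < 2 or self.batch_size < 1 or not self.lr0 > 0:
            raise ValueError("invalid TrainConfig")
        if not (0 < self.decay_factor <= 1):
            raise ValueError("decay_factor must be in (0, 1]")


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """lr0 * decay_factor ** floor(epoch / decay_interval)."""
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_interval)


def encode_targets(labels: np.ndarray, regime: Regime, background_channel: bool = False) -> np.ndarray:
    """Vectorized target stacks for a batch of label maps.

    INTRA -> disjoint (NET, ED, ET) one-hot channels (plus an explicit
    background channel if requested); SUBREGION -> nested (WT, TC, ET).
    """
    net = labels == 1
    ed = labels == 2
    et = labels == 4
    if regime is Regime.INTRA:
        chans = [net, ed, et]
        if background_channel:
            chans.append(labels == 0)
    else:
        chans = [net | ed | et, net | et, et]
    return np.stack(chans, axis=-1).astype(np.float32)


def fit_array_stats(images: np.ndarray) -> DatasetStats:
    """Per-modality mean/std over all pixels of an (N, H, W, 4) array."""
    flat = images.reshape(-1, images.shape[-1]).astype(np.float64)
    return DatasetStats(flat.mean(axis=0), flat.std(axis=0))


def normalize_array(images: np.ndarray, stats: DatasetStats) -> np.ndarray:
    return ((images - stats.mean) / stats.std).astype(np.float32)


@dataclass
class TrainResult:
    model: SegmentationNetwork
    history: pd.DataFrame          # columns: step, epoch, lr, loss
    stats: DatasetStats
    train_idx: np.ndarray
    val_idx: np.ndarray
    variant: str
    fold_index: int


def train_fold(
    variant: str,
    fold_index: int,
    assignment: FoldAssignment,
    dataset: SliceDataset,
    cfg: TrainConfig,
    model_cfg: ModelConfig | None = None,
) -> TrainResult:
    """Train one variant on one fold's training split.

    Normalization statistics are fitted on the training split only and are
    returned so evaluation can apply the identical transform. Fully seeded:
    the model seed and the batch-shuffling stream both derive from
    ``cfg.seed``, the variant and the fold index.
    """
    block, regime = parse_variant(variant)
    h, w = dataset.images.shape[1:3]
    if model_cfg is None:
        model_cfg = ModelConfig(input_height=h, input_width=w, regime=regime)
    elif model_cfg.regime is not regime:
        model_cfg = replace(model_cfg, regime=regime)

    train_idx, val_idx = assignment.split_indices(dataset, fold_index)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("empty train or validation split")

    stats = fit_array_stats(dataset.images[train_idx])
    x_train = normalize_array(dataset.images[train_idx], stats)
    y_train = encode_targets(
        dataset.labels[train_idx], regime, model_cfg.background_channel
    )

    seed = np.random.SeedSequence(
        [cfg.seed, VARIANTS.index(variant), fold_index]
    ).generate_state(1)[0] % (2 ** 31)
    net = SegmentationNetwork(model_cfg, block_type=block, seed=int(seed))
    opt = nn.Adam(net.params())
    loss_cfg = LossConfig(gamma=cfg.gamma, num_classes=model_cfg.head_channels)
    rng = np.random.default_rng(seed + 1)

    n = x_train.shape[0]
    bs = min(cfg.batch_size, n)
    rows = []
    step = 0
    for epoch in range(cfg.epochs):
        lr = learning_rate(epoch, cfg)
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = order[start : start + bs]
            xb, yb = x_train[batch], y_train[batch]
            probs = net.forward(xb, train=True)
            loss = multiclass_loss(probs, yb, loss_cfg)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch, step)
            dprobs = multiclass_loss_grad(probs, yb, loss_cfg)
            opt.zero_grad()
            net.backward(dprobs.astype(np.float32))
            opt.step(lr)
            rows.append({"step": step, "epoch": epoch, "lr": lr, "loss": loss})
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                break
        if cfg.max_steps is not None and step >= cfg.max_steps:
            break
    history = pd.DataFrame(rows, columns=["step", "epoch", "lr", "loss"])
    logger.info(
        "trained %s fold %d: %d steps, final loss %.4f",
        variant, fold_index, step, rows[-1]["loss"] if rows else float("nan"),
    )
    return TrainResult(net, history, stats, train_idx, val_idx, variant, fold_index)


def predict_stacks(
    model: SegmentationNetwork, images: np.ndarray, batch_size: int = 8
) -> list[MaskStack]:
    """Binary mask stacks for normalized images (inference mode)."""
    regime = model.config.regime
    out = []
    for start in range(0, images.shape[0], batch_size):
        probs = model.forward(images[start : start + batch_size], train=False)
        for p in probs:
            out.append(binarize(p, regime, model.config.background_channel))
    return out


def evaluate_model(
    model: SegmentationNetwork,
    dataset: SliceDataset,
    indices: np.ndarray,
    stats: DatasetStats,
) -> pd.DataFrame:
    """Per-slice (WT, TC, ET) Dice of a trained model on the given slices."""
    x = normalize_array(dataset.images[indices], stats)
    preds = predict_stacks(model, x)
    rows = []
    for j, idx in enumerate(indices):
        truth = MaskStack(
            encode_targets(dataset.labels[idx][None], Regime.INTRA)[0].astype(np.uint8),
            Regime.INTRA,
        )
        wt, tc, et = evaluate_regions(preds[j], truth)
        rows.append(
            {
                "patient_id": dataset.patient_ids[idx],
                "slice_index": dataset.slice_indices[idx],
                "WT": wt, "TC": tc, "ET": et,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "slice_index", "WT", "TC", "ET"])


# ---------------------------------------------------------------------------
# Ablation protocol and statistics

@dataclass(frozen=True)
class FoldScores:
    """Mean (WT, TC, ET) Dice of one variant on one fold's evaluation set."""

    variant: str
    fold_index: int
    region_means: tuple[float, float, float]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    significant: bool  # at alpha = 0.05

    ALPHA = 0.05


def t_test(a, b) -> TTestResult:
    """Two-tailed two-sample Student's t-test with equal variance.

    Degrees of freedom n_a + n_b - 2; significance flagged at alpha = 0.05.
    Raises :class:`DegenerateSampleError` for samples of fewer than two
    observations or zero pooled variance.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateSampleError("each sample needs >= 2 observations")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled == 0:
        raise DegenerateSampleError("zero pooled variance")
    res = sp_stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), bool(res.pvalue < TTestResult.ALPHA))


@dataclass
class AblationResult:
    fold_scores: pd.DataFrame   # variant, fold, WT, TC, ET
    summary: pd.DataFrame       # variant x (region mean, sd)
    comparisons: pd.DataFrame   # model_1, model_2, WT, TC, ET (p-values)


def run_ablation(
    dataset: SliceDataset,
    cfg: TrainConfig,
    variants: tuple[str, ...] = VARIANTS,
    model_cfg: ModelConfig | None = None,
) -> AblationResult:
    """Run the full variants x k-fold protocol and the pairwise t-tests.

    For every variant and fold: train on the fold's training split, score the
    evaluation set (held-out fold by default; train+val pooled when
    ``cfg.pooled_evaluation``), and record the fold's mean per-region Dice.
    Each pair of variants is then compared per region on its k fold means.
    The comparison table has one row per variant pair and one p-value column
    per region.
    """
    for v in variants:
        parse_variant(v)
    assignment = kfold_split(dataset.patient_ids, k=cfg.k, seed=cfg.seed)
    score_rows = []
    for variant in variants:
        for fold in range(cfg.k):
            result = train_fold(variant, fold, assignment, dataset, cfg, model_cfg)
            eval_idx = (
                np.arange(len(dataset)) if cfg.pooled_evaluation else result.val_idx
            )
            df = evaluate_model(result.model, dataset, eval_idx, result.stats)
            means = df[["WT", "TC", "ET"]].mean()
            score_rows.append(
                {
                    "variant": variant, "fold": fold,
                    "WT": means["WT"], "TC": means["TC"], "ET": means["ET"],
                }
            )
    fold_scores = pd.DataFrame(score_rows, columns=["variant", "fold", "WT", "TC", "ET"])

    summary = fold_scores.groupby("variant")[["WT", "TC", "ET"]].agg(["mean", "std"])
    summary = summary.reindex(list(variants))

    comp_rows = []
    for v1, v2 in itertools.combinations(variants, 2):
        row = {"model_1": v1, "model_2": v2}
        for region in ("WT", "TC", "ET"):
            s1 = fold_scores.loc[fold_scores.variant == v1, region].to_numpy()
            s2 = fold_scores.loc[fold_scores.variant == v2, region].to_numpy()
            try:
                row[region] = t_test(s1, s2).pvalue
            except DegenerateSampleError:
                row[region] = np.nan
        comp_rows.append(row)
    comparisons = pd.DataFrame(comp_rows, columns=["model_1", "model_2", "WT", "TC", "ET"])
    return AblationResult(fold_scores, summary, comparisons)
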