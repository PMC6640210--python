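"""Dice similarity coefficient and the smoothed negative-log-Dice loss.

Evaluation uses the plain Dice similarity coefficient on binary masks,

    DSC(P, G) = 2 |P & G| / (|P| + |G|),

with the convention DSC = 1 when both masks are empty (perfect agreement on
"no tumor"). Training minimizes a smoothed negative-log form: for a soft
prediction P in [0, 1] and binary target G,

    L(P, G) = -log[ (2 sum(P*G) + gamma) / (sum(P) + sum(G) + gamma) ],

where gamma > 0 keeps the loss finite and well-behaved when a class is
(nearly) absent — without it, an empty ground-truth segment paired with an
empty prediction yields 0/0. gamma = 100 is the default, chosen empirically
for 128x128 slices. The multi-class loss averages the smoothed Dice ratio
over the K channels *inside* the log:

    L(P, G) = -log[ (1/K) sum_i dice_gamma(P_i, G_i) ],

so a single absent class cannot dominate. The alternative composition —
mean of per-class logs — is exposed via ``LossConfig.reduction`` and is
mathematically different (Jensen's inequality).

Gradients of the loss with respect to P are closed-form and finite
everywhere for gamma > 0; they drive the numpy training loop in
:mod:`gliomaseg.nn`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .labels import MaskStack, Regime, intra_to_subregions

__all__ = [
    "LossConfig",
    "dsc",
    "smoothed_dice",
    "binary_loss",
    "multiclass_loss",
    "multiclass_loss_grad",
    "evaluate_regions",
    "evaluate_dataset",
    "REGION_NAMES",
]

REGION_NAMES = ("WT", "TC", "ET")


@dataclass(frozen=True)
class LossConfig:
    """Loss hyperparameters.

    gamma : smoothing constant, dimensionless, > 0 (default 100).
    num_classes : K, the channel count (3).
    reduction : ``"log_mean_dice"`` (default) takes -log of the mean
        per-class smoothed Dice ratio; ``"mean_log_dice"`` averages the
        per-class binary losses instead.
    """

    gamma: float = 100.0
    num_classes: int = 3
    reduction: str = "log_mean_dice"

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.reduction not in ("log_mean_dice", "mean_log_dice"):
            raise ValueError(f"unknown reduction {self.reduction!r}")


def _as_array(m) -> np.ndarray:
    if isinstance(m, MaskStack):
        return m.masks
    return np.asarray(m)


def dsc(P, G) -> float:
    """Dice similarity coefficient between two masks of equal shape.

    Evaluation path expects binary masks; soft P in [0, 1] is accepted for
    the training-time soft Dice with the identical formula. Both-empty
    returns 1.0.
    """
    P, G = _as_array(P).astype(np.float64), _as_array(G).astype(np.float64)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    denom = P.sum() + G.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (P * G).sum() / denom)


def smoothed_dice(P, G, gamma: float) -> float:
    """The gamma-smoothed Dice ratio (2 sum(PG) + gamma) / (sum(P) + sum(G) + gamma)."""
    P, G = _as_array(P).astype(np.float64), _as_array(G).astype(np.float64)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    return float((2.0 * (P * G).sum() + gamma) / (P.sum() + G.sum() + gamma))


def binary_loss(P, G, cfg: LossConfig = LossConfig()) -> float:
    """Smoothed negative-log-Dice loss for a single binary problem.

    Always finite for gamma > 0; exactly 0 when P == G (including the
    all-empty case, where the ratio is gamma/gamma = 1).
    """
    return float(-np.log(smoothed_dice(P, G, cfg.gamma)))


def _per_class_sums(P: np.ndarray, G: np.ndarray):
    """Reduce over every axis except the trailing channel axis."""
    axes = tuple(range(P.ndim - 1))
    inter = (P * G).sum(axis=axes)
    psum = P.sum(axis=axes)
    gsum = G.sum(axis=axes)
    return inter, psum, gsum


def multiclass_loss(P, G, cfg: LossConfig = LossConfig()) -> float:
    """Multi-class smoothed negative-log-Dice loss.

    ``P`` is a soft stack (..., K); ``G`` a binary stack of the same shape
    (a :class:`~gliomaseg.labels.MaskStack` is accepted). Leading axes
    (batch, height, width) are pooled into the per-class sums, so a batch is
    treated as one large image per class.
    """
    P = _as_array(P).astype(np.float64)
    G = _as_array(G).astype(np.float64)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    K = P.shape[-1]
    if K != cfg.num_classes:
        raise ValueError(f"expected {cfg.num_classes} channels, got {K}")
    inter, psum, gsum = _per_class_sums(P, G)
    ratios = (2.0 * inter + cfg.gamma) / (psum + gsum + cfg.gamma)
    if cfg.reduction == "log_mean_dice":
        return float(-np.log(ratios.mean()))
    return float(-np.log(ratios).mean())


def multiclass_loss_grad(P, G, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """Analytic gradient dL/dP of :func:`multiclass_loss`.

    With s_i = (2 I_i + gamma)/(D_i + gamma'), I_i = sum(P_i G_i),
    D_i = sum(P_i) + sum(G_i):

        d s_i / d P_i[p] = (2 G_i[p] - s_i) / (D_i + gamma)

    and for the log-of-mean reduction L = -log(mean_i s_i),
    dL/dP_i = -(1/(K * mean_s)) * ds_i/dP_i. Finite for every gamma > 0.
    """
    P = _as_array(P).astype(np.float64)
    G = _as_array(G).astype(np.float64)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    K = P.shape[-1]
    inter, psum, gsum = _per_class_sums(P, G)
    den = psum + gsum + cfg.gamma
    s = (2.0 * inter + cfg.gamma) / den
    ds_dP = (2.0 * G - s) / den  # broadcast over leading axes
    if cfg.reduction == "log_mean_dice":
        return -ds_dP / (K * s.mean())
    return -ds_dP / (K * s)


def evaluate_regions(pred: MaskStack, truth: MaskStack) -> tuple[float, float, float]:
    """Per-region Dice (WT, TC, ET) between a prediction and ground truth.

    Intra-tumoral stacks are first combined into glioma sub-regions, so a
    model trained on the intra regime is always scored on the same nested
    regions as a sub-region model. Scoring uses the un-smoothed DSC with the
    both-empty -> 1 convention.
    """
    if pred.regime is Regime.INTRA:
        pred = intra_to_subregions(pred)
    if truth.regime is Regime.INTRA:
        truth = intra_to_subregions(truth)
    return tuple(
        dsc(pred.masks[..., i], truth.masks[..., i]) for i in range(3)
    )


def evaluate_dataset(
    preds: Iterable[MaskStack],
    truths: Iterable[MaskStack],
    patient_ids: Iterable[str] | None = None,
    slice_indices: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Score a set of slices; one row per slice with columns WT, TC, ET.

    The aggregate score of a set is the arithmetic mean of the per-slice
    region DSCs (``df[["WT", "TC", "ET"]].mean()``).
    """
    rows = []
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError("prediction/truth count mismatch")
    pids = list(patient_ids) if patient_ids is not None else [""] * len(preds)
    sidx = list(slice_indices) if slice_indices is not None else list(range(len(preds)))
    for pid, si, p, g in zip(pids, sidx, preds, truths):
        wt, tc, et = evaluate_regions(p, g)
        rows.append({"patient_id": pid, "slice_index": si, "WT": wt, "TC": tc, "ET": et})
    return pd.DataFrame(rows, columns=["patient_id", "slice_index", "WT", "TC", "ET"])
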