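"""BRATS label codec: integer annotation maps and binary mask stacks.

The BRATS annotation protocol marks three mutually exclusive *intra-tumoral
structures* per pixel: necrotic and non-enhancing tumor core (label 1,
``NET``), peritumoral edema (label 2, ``ED``), and enhancing tumor (label 4,
``ET``); label 0 is background. From these, three nested *glioma sub-regions*
are defined: whole tumor (``WT`` = 1 U 2 U 4), tumor core (``TC`` = 1 U 4)
and enhancing tumor (``ET`` = 4).

This module converts losslessly between the two representations. The
intra-tumoral regime is a disjoint 3-channel one-hot stack; the sub-region
regime is a nested 3-channel stack satisfying ET <= TC <= WT pixel-wise.
Channel order is fixed: ``(NET, ED, ET)`` and ``(WT, TC, ET)``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Regime",
    "LabelMap",
    "MaskStack",
    "InvalidLabelError",
    "DisjointnessError",
    "HierarchyViolationError",
    "encode_intra",
    "intra_to_subregions",
    "subregions_to_intra",
    "repair_hierarchy",
    "VALID_LABELS",
]

#: BRATS 2018 label vocabulary. Label 3 (older releases) is rejected, not remapped.
VALID_LABELS = frozenset({0, 1, 2, 4})

LABEL_NET = 1
LABEL_ED = 2
LABEL_ET = 4


class Regime(str, enum.Enum):
    """Labeling regime of a mask stack."""

    INTRA = "intra"          #: disjoint intra-tumoral structures (NET, ED, ET)
    SUBREGION = "subregion"  #: nested glioma sub-regions (WT, TC, ET)


CHANNEL_NAMES: dict[Regime, tuple[str, str, str]] = {
    Regime.INTRA: ("NET", "ED", "ET"),
    Regime.SUBREGION: ("WT", "TC", "ET"),
}


class InvalidLabelError(ValueError):
    """An annotation value outside the BRATS vocabulary {0, 1, 2, 4}."""


class DisjointnessError(ValueError):
    """Intra-tumoral channels overlap where they must be mutually exclusive."""


class HierarchyViolationError(ValueError):
    """Sub-region nesting ET <= TC <= WT violated.

    Attributes
    ----------
    count : int
        Number of offending pixels.
    """

    def __init__(self, count: int):
        self.count = int(count)
        super().__init__(
            f"sub-region hierarchy (ET <= TC <= WT) violated at {count} pixel(s)"
        )


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel integer annotation with the BRATS label vocabulary.

    Parameters
    ----------
    values : ndarray of shape (H, W)
        Integer labels, every value in {0, 1, 2, 4}.
    """

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError(f"LabelMap must be a non-empty 2-D grid, got shape {vals.shape}")
        if not np.issubdtype(vals.dtype, np.integer):
            ivals = vals.astype(np.int64)
            if not np.array_equal(ivals, vals):
                raise InvalidLabelError("non-integer annotation values")
            vals = ivals
        bad = np.setdiff1d(np.unique(vals), sorted(VALID_LABELS))
        if bad.size:
            raise InvalidLabelError(
                f"invalid label value(s) {bad.tolist()}; allowed: {sorted(VALID_LABELS)}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def has_tumor(self) -> bool:
        """True if any pixel carries a tumor label (1, 2 or 4)."""
        return bool(np.any(self.values != 0))


@dataclass(frozen=True)
class MaskStack:
    """K=3 binary masks under a declared regime.

    ``masks`` has shape (H, W, 3) with values in {0, 1}. Structural
    constraints (disjointness for INTRA, nesting for SUBREGION) are *not*
    enforced at construction — raw network output may violate them — but are
    checked by the conversion operations and by :meth:`validate`.
    """

    masks: np.ndarray
    regime: Regime = field(default=Regime.INTRA)

    def __post_init__(self):
        m = np.asarray(self.masks)
        if m.ndim != 3 or m.shape[2] != 3:
            raise ValueError(f"MaskStack must have shape (H, W, 3), got {m.shape}")
        u = np.unique(m)
        if not np.isin(u, (0, 1)).all():
            raise ValueError("MaskStack values must be binary (0/1)")
        object.__setattr__(self, "masks", m.astype(np.uint8))
        object.__setattr__(self, "regime", Regime(self.regime))

    @property
    def channel_names(self) -> tuple[str, str, str]:
        return CHANNEL_NAMES[self.regime]

    def channel(self, name: str) -> np.ndarray:
        return self.masks[..., self.channel_names.index(name)]

    def validate(self) -> None:
        """Raise if the regime's structural invariant is violated."""
        if self.regime is Regime.INTRA:
            if np.any(self.masks.sum(axis=-1) > 1):
                raise DisjointnessError("intra-tumoral channels overlap")
        else:
            n_bad = _count_hierarchy_violations(self.masks)
            if n_bad:
                raise HierarchyViolationError(n_bad)


def _count_hierarchy_violations(masks: np.ndarray) -> int:
    wt, tc, et = masks[..., 0], masks[..., 1], masks[..., 2]
    bad = ((et == 1) & (tc == 0)) | ((tc == 1) & (wt == 0)) | ((et == 1) & (wt == 0))
    return int(bad.sum())


def encode_intra(labels: LabelMap) -> MaskStack:
    """One-hot encode a label map into the intra-tumoral regime.

    Channel ``NET`` marks label 1, ``ED`` label 2, ``ET`` label 4; background
    (label 0) belongs to no channel, so channels are disjoint by construction.
    """
    v = labels.values
    masks = np.stack([v == LABEL_NET, v == LABEL_ED, v == LABEL_ET], axis=-1)
    return MaskStack(masks.astype(np.uint8), Regime.INTRA)


def decode_intra(stack: MaskStack) -> LabelMap:
    """Inverse of :func:`encode_intra` (channels must be disjoint)."""
    if stack.regime is not Regime.INTRA:
        raise ValueError("decode_intra expects an INTRA stack")
    stack.validate()
    net, ed, et = stack.masks[..., 0], stack.masks[..., 1], stack.masks[..., 2]
    return LabelMap(net * LABEL_NET + ed * LABEL_ED + et * LABEL_ET)


def intra_to_subregions(stack: MaskStack) -> MaskStack:
    """Combine intra-tumoral structures into nested glioma sub-regions.

    WT = NET | ED | ET, TC = NET | ET, ET = ET. The output always satisfies
    the nesting invariant ET <= TC <= WT.
    """
    if stack.regime is not Regime.INTRA:
        raise ValueError(f"expected INTRA stack, got {stack.regime}")
    stack.validate()  # raises DisjointnessError on overlap
    net, ed, et = stack.masks[..., 0], stack.masks[..., 1], stack.masks[..., 2]
    wt = net | ed | et
    tc = net | et
    return MaskStack(np.stack([wt, tc, et], axis=-1), Regime.SUBREGION)


def repair_hierarchy(stack: MaskStack) -> MaskStack:
    """Restore nesting by intersecting inner regions with outer ones.

    TC <- TC & WT, then ET <- ET & TC. This is the minimal-change policy for
    hierarchy-inconsistent sigmoid predictions: a pixel is only ever removed
    from an inner region, never added to an outer one.
    """
    if stack.regime is not Regime.SUBREGION:
        raise ValueError(f"expected SUBREGION stack, got {stack.regime}")
    wt = stack.masks[..., 0]
    tc = stack.masks[..., 1] & wt
    et = stack.masks[..., 2] & tc
    return MaskStack(np.stack([wt, tc, et], axis=-1), Regime.SUBREGION)


def subregions_to_intra(stack: MaskStack, repair: bool = False) -> MaskStack:
    """Invert nested glioma sub-regions back to intra-tumoral structures.

    ET = ET, NET = TC & ~ET, ED = WT & ~TC. Requires the nesting invariant;
    with ``repair=True`` violations are first fixed by
    :func:`repair_hierarchy`, with ``repair=False`` they raise
    :class:`HierarchyViolationError` carrying the offending pixel count.
    Predicted (model-output) stacks should use ``repair=True``; ground truth
    should never need repair.
    """
    if stack.regime is not Regime.SUBREGION:
        raise ValueError(f"expected SUBREGION stack, got {stack.regime}")
    if repair:
        stack = repair_hierarchy(stack)
    else:
        n_bad = _count_hierarchy_violations(stack.masks)
        if n_bad:
            raise HierarchyViolationError(n_bad)
    wt, tc, et = stack.masks[..., 0], stack.masks[..., 1], stack.masks[..., 2]
    net = tc & (1 - et)
    ed = wt & (1 - tc)
    return MaskStack(np.stack([net, ed, et], axis=-1), Regime.INTRA)
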