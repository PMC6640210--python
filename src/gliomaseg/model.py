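"""Inception-module U-Net for multimodal brain-tumor slice segmentation.

The network is a 2-D U-Net whose convolutional blocks are four-branch
Inception modules: a 1x1 convolution, a 3x3 convolution, two cascaded 3x3
convolutions (the factorized equivalent of a 5x5 receptive field), and a
3x3 stride-1 max pool followed by a 1x1 projection. Every branch emits F
feature maps, so a module maps H x W x C_in -> H x W x 4F. Each convolution
is followed by batch normalization and ReLU.

The U topology: on the contracting path each level applies a block with
branch budget F0 * 2^l and then halves the spatial size with 2x2 max
pooling, doubling depth level by level; after the bottleneck, each
expanding level upsamples 2x, concatenates the level-matched encoder
feature map (doubling depth), and applies the level's block. A final 1x1
convolution reduces depth to the K=3 segmentation channels, followed by a
pixel-wise softmax (intra-tumoral regime: the three structures are
mutually exclusive) or sigmoid (sub-region regime: WT/TC/ET are nested,
not exclusive).

The ablation baseline (`double_conv` blocks) replaces each Inception module
with a pair of plain 3x3 conv+BN+ReLU layers of matched output depth, so
block type is the only architectural difference.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .labels import MaskStack, Regime, repair_hierarchy

__all__ = [
    "ModelConfig",
    "InceptionModuleSpec",
    "InceptionModule",
    "DoubleConvBlock",
    "SegmentationNetwork",
    "build_inception_module",
    "build_model",
    "build_baseline_unet",
    "binarize",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    input_height / input_width must be divisible by 2**depth. branch_filters
    is the per-branch filter budget F0 at level 0; it doubles per level.
    ``background_channel=True`` adds an explicit background class to the
    softmax head (internal K=4; the background channel is dropped at
    binarization), giving a probabilistically coherent background at the
    cost of deviating from the literal K=3 head.
    """

    input_height: int = 128
    input_width: int = 128
    in_channels: int = 4
    out_channels: int = 3
    depth: int = 4
    branch_filters: int = 16
    regime: Regime = Regime.INTRA
    upsample: str = "nearest"  # only nearest is implemented
    background_channel: bool = False

    def __post_init__(self):
        object.__setattr__(self, "regime", Regime(self.regime))
        d = 2 ** self.depth
        if self.input_height % d or self.input_width % d:
            raise ValueError(
                f"input {self.input_height}x{self.input_width} not divisible by 2^{self.depth}"
            )
        if self.branch_filters < 1:
            raise ValueError("branch_filters must be >= 1")
        if self.out_channels != 3:
            raise ValueError("out_channels is fixed at K=3")
        if self.background_channel and self.regime is not Regime.INTRA:
            raise ValueError("background channel only applies to the softmax (INTRA) head")

    @property
    def head_channels(self) -> int:
        return 4 if self.background_channel else 3


@dataclass(frozen=True)
class InceptionModuleSpec:
    """One Inception block: in_depth channels in, 4 * branch_filters out."""

    in_depth: int
    branch_filters: int

    def __post_init__(self):
        if self.branch_filters < 1:
            raise ValueError("branch_filters must be >= 1")
        if self.in_depth < 1:
            raise ValueError("in_depth must be >= 1")

    @property
    def out_depth(self) -> int:
        return 4 * self.branch_filters


class InceptionModule(nn.Layer):
    """Four parallel branches concatenated channel-wise; spatial size preserved."""

    def __init__(self, spec: InceptionModuleSpec, rng: np.random.Generator):
        c, f = spec.in_depth, spec.branch_filters
        self.spec = spec
        self.branch1 = nn.ConvBNReLU(c, f, 1, rng)          # 1x1
        self.branch3 = nn.ConvBNReLU(c, f, 3, rng)          # 3x3
        self.branch5a = nn.ConvBNReLU(c, f, 3, rng)         # cascaded 3x3 ...
        self.branch5b = nn.ConvBNReLU(f, f, 3, rng)         # ... -> 5x5 receptive field
        self.branch_pool = nn.MaxPool3x3Stride1()
        self.branch_pool_proj = nn.ConvBNReLU(c, f, 1, rng)  # pool branch projection to F

    def params(self):
        return (
            self.branch1.params()
            + self.branch3.params()
            + self.branch5a.params()
            + self.branch5b.params()
            + self.branch_pool_proj.params()
        )

    def forward(self, x, train):
        y1 = self.branch1.forward(x, train)
        y3 = self.branch3.forward(x, train)
        y5 = self.branch5b.forward(self.branch5a.forward(x, train), train)
        yp = self.branch_pool_proj.forward(self.branch_pool.forward(x, train), train)
        return np.concatenate([y1, y3, y5, yp], axis=-1)

    def backward(self, dy):
        f = self.spec.branch_filters
        d1, d3, d5, dp = (dy[..., i * f : (i + 1) * f] for i in range(4))
        dx = self.branch1.backward(np.ascontiguousarray(d1))
        dx = dx + self.branch3.backward(np.ascontiguousarray(d3))
        dx = dx + self.branch5a.backward(self.branch5b.backward(np.ascontiguousarray(d5)))
        dx = dx + self.branch_pool.backward(self.branch_pool_proj.backward(np.ascontiguousarray(dp)))
        return dx


class DoubleConvBlock(nn.Layer):
    """Baseline block: two plain 3x3 conv+BN+ReLU layers, matched output depth."""

    def __init__(self, spec: InceptionModuleSpec, rng: np.random.Generator):
        c, out = spec.in_depth, spec.out_depth
        self.spec = spec
        self.seq = nn.Sequential(
            nn.ConvBNReLU(c, out, 3, rng),
            nn.ConvBNReLU(out, out, 3, rng),
        )

    def params(self):
        return self.seq.params()

    def forward(self, x, train):
        return self.seq.forward(x, train)

    def backward(self, dy):
        return self.seq.backward(dy)


_BLOCKS = {"inception": InceptionModule, "double_conv": DoubleConvBlock}


def build_inception_module(
    spec: InceptionModuleSpec, seed: int | np.random.Generator = 0
) -> InceptionModule:
    """Standalone Inception block (mainly for inspection and testing)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return InceptionModule(spec, rng)


class SegmentationNetwork:
    """Encoder-decoder segmentation network over a pluggable block type.

    ``forward`` returns per-pixel class probabilities (after the regime's
    activation); ``backward`` takes dLoss/dProbabilities and pushes it
    through the activation and the whole network, accumulating parameter
    gradients.
    """

    def __init__(self, config: ModelConfig, block_type: str = "inception", seed: int = 0):
        if block_type not in _BLOCKS:
            raise ValueError(f"unknown block type {block_type!r}")
        rng = np.random.default_rng(seed)
        make = _BLOCKS[block_type]
        self.config = config
        self.block_type = block_type
        L, f0 = config.depth, config.branch_filters

        self.enc_blocks, self.pools = [], []
        c = config.in_channels
        for l in range(L):
            spec = InceptionModuleSpec(c, f0 * 2 ** l)
            self.enc_blocks.append(make(spec, rng))
            self.pools.append(nn.MaxPool2x2())
            c = spec.out_depth
        self.bottleneck = make(InceptionModuleSpec(c, f0 * 2 ** L), rng)
        c = 4 * f0 * 2 ** L

        self.ups, self.dec_blocks = [], []
        for l in reversed(range(L)):
            self.ups.append(nn.UpsampleNearest2x())
            skip_depth = 4 * f0 * 2 ** l
            spec = InceptionModuleSpec(c + skip_depth, f0 * 2 ** l)
            self.dec_blocks.append(make(spec, rng))
            c = spec.out_depth
        self.head = nn.Conv2D(c, config.head_channels, 1, rng)
        self._probs = None

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = []
        for b in self.enc_blocks:
            ps += b.params()
        ps += self.bottleneck.params()
        for b in self.dec_blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        stages = [("input", x.shape[1:])]
        skips = []
        for l, (block, pool) in enumerate(zip(self.enc_blocks, self.pools)):
            x = block.forward(x, train)
            stages.append((f"enc{l}", x.shape[1:]))
            skips.append(x)
            x = pool.forward(x, train)
            stages.append((f"pool{l}", x.shape[1:]))
        x = self.bottleneck.forward(x, train)
        stages.append(("bottleneck", x.shape[1:]))
        self._skip_depths = []
        for i, (up, block, skip) in enumerate(
            zip(self.ups, self.dec_blocks, reversed(skips))
        ):
            x = up.forward(x, train)
            stages.append((f"up{i}", x.shape[1:]))
            self._skip_depths.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            stages.append((f"concat{i}", x.shape[1:]))
            x = block.forward(x, train)
            stages.append((f"dec{i}", x.shape[1:]))
        logits = self.head.forward(x, train)
        stages.append(("head", logits.shape[1:]))
        #: per-stage output shapes of the most recent forward pass
        self.last_stage_shapes = stages
        if self.config.regime is Regime.INTRA:
            probs = nn.softmax(logits)
        else:
            probs = nn.sigmoid(logits)
        if train:
            self._probs = probs
        return probs[0] if squeeze else probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate dLoss/dProbabilities from the last training forward."""
        if self._probs is None:
            raise RuntimeError("backward requires a preceding forward(train=True)")
        if dprobs.ndim == 3:
            dprobs = dprobs[None]
        probs = self._probs
        if self.config.regime is Regime.INTRA:
            dlogits = nn.softmax_backward(probs, dprobs.astype(np.float32))
        else:
            dlogits = nn.sigmoid_backward(probs, dprobs.astype(np.float32))
        dy = self.head.backward(dlogits)
        dskips = []
        for block, up, skip_depth in zip(
            reversed(self.dec_blocks), reversed(self.ups), reversed(self._skip_depths)
        ):
            dcat = block.backward(dy)
            dskips.append(np.ascontiguousarray(dcat[..., :skip_depth]))
            dy = up.backward(np.ascontiguousarray(dcat[..., skip_depth:]))
        dy = self.bottleneck.backward(dy)
        # dskips were collected shallow-first; encoder backward runs deep-first
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy) + dskip
            dy = block.backward(dy)
        self._probs = None

    # -- introspection ------------------------------------------------------
    def shape_table(self) -> list[tuple[str, tuple[int, int, int]]]:
        """Per-stage output shapes (H, W, C) for a single input slice.

        Computed from the halving/doubling arithmetic, not from a dummy
        forward pass, so it doubles as an audit of the architecture schedule.
        """
        cfg = self.config
        h, w = cfg.input_height, cfg.input_width
        f0, L = cfg.branch_filters, cfg.depth
        rows = [("input", (h, w, cfg.in_channels))]
        for l in range(L):
            rows.append((f"enc{l}", (h, w, 4 * f0 * 2 ** l)))
            h, w = h // 2, w // 2
            rows.append((f"pool{l}", (h, w, 4 * f0 * 2 ** l)))
        rows.append(("bottleneck", (h, w, 4 * f0 * 2 ** L)))
        c = 4 * f0 * 2 ** L
        for l in reversed(range(L)):
            h, w = h * 2, w * 2
            rows.append((f"up{L - 1 - l}", (h, w, c)))
            rows.append((f"concat{L - 1 - l}", (h, w, c + 4 * f0 * 2 ** l)))
            c = 4 * f0 * 2 ** l
            rows.append((f"dec{L - 1 - l}", (h, w, c)))
        rows.append(("head", (h, w, cfg.head_channels)))
        return rows

    def summary(self) -> str:
        lines = [f"{self.block_type} U-Net, {self.n_params():,} trainable parameters"]
        for name, (h, w, c) in self.shape_table():
            lines.append(f"  {name:<12} {h:>4} x {w:<4} x {c}")
        return "\n".join(lines)


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    """The Inception-module U-Net."""
    return SegmentationNetwork(config, block_type="inception", seed=seed)


def build_baseline_unet(config: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    """Ablation control: same U topology with plain double-conv blocks."""
    return SegmentationNetwork(config, block_type="double_conv", seed=seed)


def binarize(probs: np.ndarray, regime: Regime, background_channel: bool = False) -> MaskStack:
    """Turn per-pixel probabilities into a binary mask stack.

    Intra regime (softmax): each pixel takes its argmax class, one-hot —
    unless its maximum class probability is below 0.5, in which case the
    pixel is declared background (the K=3 softmax has no background class of
    its own, so near-uniform mass means "none of the structures"). With an
    explicit background channel (K=4 input), the argmax decides directly and
    the background channel is dropped.

    Sub-region regime (sigmoid): each channel is thresholded at 0.5, then
    the nesting hierarchy is repaired by intersection.
    """
    probs = np.asarray(probs)
    regime = Regime(regime)
    if probs.ndim != 3:
        raise ValueError("binarize expects a single (H, W, K) probability map")
    if regime is Regime.INTRA:
        if background_channel:
            if probs.shape[-1] != 4:
                raise ValueError("expected 4 channels with background_channel=True")
            arg = probs.argmax(axis=-1)
            masks = np.stack([arg == k for k in range(3)], axis=-1)
        else:
            if probs.shape[-1] != 3:
                raise ValueError("expected 3 channels")
            arg = probs.argmax(axis=-1)
            fg = probs.max(axis=-1) >= 0.5
            masks = np.stack([(arg == k) & fg for k in range(3)], axis=-1)
        return MaskStack(masks.astype(np.uint8), Regime.INTRA)
    if probs.shape[-1] != 3:
        raise ValueError("expected 3 channels")
    stack = MaskStack((probs >= 0.5).astype(np.uint8), Regime.SUBREGION)
    return repair_hierarchy(stack)
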