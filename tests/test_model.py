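"""Architecture: Inception block arithmetic, U shape contract, binarization."""
import numpy as np
import pytest

import gliomaseg.nn as nn
from gliomaseg.labels import Regime
from gliomaseg.model import (
    InceptionModuleSpec,
    ModelConfig,
    SegmentationNetwork,
    binarize,
    build_baseline_unet,
    build_inception_module,
    build_model,
)
from gliomaseg.objective import LossConfig, multiclass_loss, multiclass_loss_grad


def inception_param_count_oracle(c_in: int, f: int) -> int:
    """Closed-form trainable parameter count of one Inception block.

    Each conv contributes k*k*c_in*f weights + f biases; each batch norm 2f
    (gamma, beta). Branches: 1x1; 3x3; two cascaded 3x3; pool + 1x1.
    """
    def conv_bn(k, cin, cout):
        return k * k * cin * cout + cout + 2 * cout

    return (
        conv_bn(1, c_in, f)                      # 1x1 branch
        + conv_bn(3, c_in, f)                    # 3x3 branch
        + conv_bn(3, c_in, f) + conv_bn(3, f, f)  # cascaded 3x3
        + conv_bn(1, c_in, f)                    # pool projection
    )


def shape_propagation_oracle(n, m, d, k_out, L, f0):
    """Independent re-derivation of the halving/doubling schedule."""
    rows = [("input", (n, m, d))]
    h, w = n, m
    for l in range(L):
        rows.append((f"enc{l}", (h, w, 4 * f0 * 2 ** l)))
        h, w = h // 2, w // 2
        rows.append((f"pool{l}", (h, w, 4 * f0 * 2 ** l)))
    rows.append(("bottleneck", (h, w, 4 * f0 * 2 ** L)))
    depth = 4 * f0 * 2 ** L
    for i, l in enumerate(reversed(range(L))):
        h, w = 2 * h, 2 * w
        rows.append((f"up{i}", (h, w, depth)))
        rows.append((f"concat{i}", (h, w, depth + 4 * f0 * 2 ** l)))
        depth = 4 * f0 * 2 ** l
        rows.append((f"dec{i}", (h, w, depth)))
    rows.append(("head", (h, w, k_out)))
    return rows


class TestInceptionModule:
    @pytest.mark.parametrize("size,c_in,f", [(32, 8, 4), (16, 4, 16)])
    def test_output_depth_is_four_branches(self, size, c_in, f, rng):
        mod = build_inception_module(InceptionModuleSpec(c_in, f), seed=0)
        x = rng.normal(size=(2, size, size, c_in)).astype(np.float32)
        y = mod.forward(x, train=False)
        assert y.shape == (2, size, size, 4 * f)

    @pytest.mark.parametrize("c_in,f", [(4, 16), (8, 4), (3, 2)])
    def test_parameter_count_matches_closed_form(self, c_in, f):
        mod = build_inception_module(InceptionModuleSpec(c_in, f))
        assert sum(p.size for p in mod.params()) == inception_param_count_oracle(c_in, f)

    def test_rejects_nonpositive_filters(self):
        with pytest.raises(ValueError):
            InceptionModuleSpec(4, 0)


class TestNetworkShapes:
    def test_default_config_shape_table_matches_oracle(self):
        cfg = ModelConfig()  # 128x128x4, L=4, F0=16, K=3
        net = build_model(cfg, seed=0)
        assert net.shape_table() == shape_propagation_oracle(128, 128, 4, 3, 4, 16)
        # encoder feature depths double level by level: 64, 128, 256, 512
        enc_depths = [s[1][2] for s in net.shape_table() if s[0].startswith("enc")]
        assert enc_depths == [64, 128, 256, 512]

    def test_forward_shapes_match_declared_table(self, rng):
        cfg = ModelConfig(input_height=32, input_width=32, depth=2, branch_filters=2)
        net = build_model(cfg, seed=1)
        x = rng.normal(size=(1, 32, 32, 4)).astype(np.float32)
        net.forward(x)
        assert net.last_stage_shapes == net.shape_table()

    def test_fully_convolutional_param_count_independent_of_size(self):
        n64 = build_model(ModelConfig(input_height=64, input_width=64), seed=0)
        n128 = build_model(ModelConfig(input_height=128, input_width=128), seed=0)
        assert n64.n_params() == n128.n_params()

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_height=100, input_width=100, depth=4)

    def test_baseline_same_schedule_different_params(self, rng):
        cfg = ModelConfig(input_height=32, input_width=32, depth=2, branch_filters=2)
        inc = build_model(cfg, seed=0)
        base = build_baseline_unet(cfg, seed=0)
        assert base.shape_table() == inc.shape_table()
        assert base.n_params() != inc.n_params()
        x = rng.normal(size=(1, 32, 32, 4)).astype(np.float32)
        assert base.forward(x).shape == (1, 32, 32, 3)


class TestActivations:
    def test_intra_probabilities_sum_to_one(self, rng):
        cfg = ModelConfig(input_height=16, input_width=16, depth=2,
                          branch_filters=2, regime=Regime.INTRA)
        net = build_model(cfg, seed=0)
        p = net.forward(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        assert np.abs(p.sum(axis=-1) - 1.0).max() < 1e-6

    def test_subregion_probabilities_in_unit_interval(self, rng):
        cfg = ModelConfig(input_height=16, input_width=16, depth=2,
                          branch_filters=2, regime=Regime.SUBREGION)
        net = build_model(cfg, seed=0)
        p = net.forward(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        assert np.all((p > 0) & (p < 1))
        assert np.abs(p.sum(axis=-1) - 1.0).max() > 1e-3  # not softmax-constrained


class TestBinarize:
    def test_exact_one_hot_roundtrip(self):
        probs = np.zeros((4, 4, 3))
        probs[..., 1] = 1.0
        stack = binarize(probs, Regime.INTRA)
        assert np.array_equal(stack.masks[..., 1], np.ones((4, 4), dtype=np.uint8))
        assert stack.masks[..., 0].sum() == stack.masks[..., 2].sum() == 0

    def test_subregion_below_threshold_is_empty(self):
        stack = binarize(np.full((4, 4, 3), 0.4), Regime.SUBREGION)
        assert stack.masks.sum() == 0

    def test_intra_uncertain_pixels_become_background(self):
        probs = np.full((2, 2, 3), 1 / 3)
        stack = binarize(probs, Regime.INTRA)
        assert stack.masks.sum() == 0

    def test_matches_per_pixel_rule_oracle(self, rng):
        probs = rng.random((8, 8, 3))
        # intra: argmax one-hot gated on max >= 0.5
        got = binarize(probs, Regime.INTRA)
        for r in range(8):
            for c in range(8):
                p = probs[r, c]
                exp = np.zeros(3, dtype=np.uint8)
                if p.max() >= 0.5:
                    exp[p.argmax()] = 1
                assert np.array_equal(got.masks[r, c], exp)
        # subregion: threshold then intersection repair
        got = binarize(probs, Regime.SUBREGION)
        for r in range(8):
            for c in range(8):
                wt = probs[r, c, 0] >= 0.5
                tc = (probs[r, c, 1] >= 0.5) and wt
                et = (probs[r, c, 2] >= 0.5) and tc
                assert tuple(got.masks[r, c]) == (int(wt), int(tc), int(et))
        got.validate()


class TestGradients:
    def test_backprop_matches_float64_directional_derivative(self, rng):
        """Full-network analytic gradient vs central differences (both regimes,
        both block types), computed in float64 to stay below the kink noise."""
        old = nn._DTYPE
        nn._DTYPE = np.float64
        try:
            for block in ("inception", "double_conv"):
                for regime in (Regime.INTRA, Regime.SUBREGION):
                    cfg = ModelConfig(input_height=8, input_width=8, depth=2,
                                      branch_filters=2, regime=regime)
                    net = SegmentationNetwork(cfg, block_type=block, seed=3)
                    x = rng.normal(size=(2, 8, 8, 4))
                    G = (rng.random((2, 8, 8, 3)) < 0.3).astype(float)
                    lcfg = LossConfig(gamma=5.0)

                    def loss():
                        return multiclass_loss(net.forward(x, train=True), G, lcfg)

                    p = net.forward(x, train=True)
                    d = multiclass_loss_grad(p, G, lcfg)
                    params = net.params()
                    for par in params:
                        par.zero_grad()
                    net.backward(d)
                    vs = [rng.normal(size=par.value.shape) for par in params]
                    dot = sum(float((par.grad * v).sum()) for par, v in zip(params, vs))
                    orig = [par.value.copy() for par in params]
                    eps = 1e-7
                    for par, v, o in zip(params, vs, orig):
                        par.value[...] = o + eps * v
                    lp = loss()
                    for par, v, o in zip(params, vs, orig):
                        par.value[...] = o - eps * v
                    lm = loss()
                    for par, o in zip(params, orig):
                        par.value[...] = o
                    num = (lp - lm) / (2 * eps)
                    assert dot == pytest.approx(num, rel=1e-4)
        finally:
            nn._DTYPE = old

    def test_single_adam_step_decreases_loss(self, rng):
        cfg = ModelConfig(input_height=16, input_width=16, depth=2,
                          branch_filters=2, regime=Regime.SUBREGION)
        net = build_model(cfg, seed=7)
        opt = nn.Adam(net.params())
        x = rng.normal(size=(4, 16, 16, 4)).astype(np.float32)
        G = (rng.random((4, 16, 16, 3)) < 0.3).astype(np.float32)
        lcfg = LossConfig()
        p = net.forward(x, train=True)
        loss0 = multiclass_loss(p, G, lcfg)
        opt.zero_grad()
        net.backward(multiclass_loss_grad(p, G, lcfg).astype(np.float32))
        opt.step(lr=1e-3)
        loss1 = multiclass_loss(net.forward(x, train=True), G, lcfg)
        assert loss1 < loss0
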