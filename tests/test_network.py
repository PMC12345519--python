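"""Backbone components: shapes, gate bounds, fusion limits, attention structure.

Component tests use a thin configuration (few channels) so forward passes
stay cheap; the parameter-budget checks on the default configuration live
in the acceptance suite.
"""

import numpy as np
import pytest

from dusafnet.autodiff import Tensor
from dusafnet.complexity import dusafnet_param_ledger
from dusafnet.model import DuSAFNet
from dusafnet.network import (
    GatedFusion,
    GrowthBranch,
    LocalSpanAttention,
    MultiscaleAttention,
    NetConfig,
    SharedStem,
    SkipBlock,
    SkipBranch,
    SpectralTemporalAttention,
)

THIN = NetConfig(
    stem_channels=8,
    growth_rate=4,
    growth_blocks=2,
    transition_channels=8,
    sta_ratio=4,
    msa_ratio=4,
    span=3,
    heads=2,
    proj_dim=8,
    n_classes=3,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="module")
def feat(rng):
    return Tensor(rng.standard_normal((2, 8, 12, 12)).astype(np.float32))


class TestSharedStem:
    def test_224_reduces_to_56(self, rng):
        stem = SharedStem(THIN, np.random.default_rng(1))
        stem.eval()
        x = Tensor(rng.standard_normal((3, 3, 224, 224)).astype(np.float32))
        out = stem(x)
        assert out.shape == (3, THIN.stem_channels, 56, 56)

    def test_wrong_size_rejected(self, rng):
        stem = SharedStem(THIN, np.random.default_rng(1))
        with pytest.raises(ValueError):
            stem(Tensor(np.zeros((1, 3, 100, 100), dtype=np.float32)))


class TestSpectralTemporalAttention:
    def test_output_damped_elementwise(self, feat):
        sta = SpectralTemporalAttention(8, 4, np.random.default_rng(2))
        out = sta(feat)
        assert out.shape == feat.shape
        assert np.all(np.abs(out.data) <= np.abs(feat.data) + 1e-6)

    def test_gates_bounded_in_unit_interval(self, feat):
        sta = SpectralTemporalAttention(8, 4, np.random.default_rng(3))
        u_f = feat.mean(axis=3, keepdims=True)
        a_f = sta.f2(sta.f1(u_f).relu()).sigmoid().data
        assert np.all((a_f > 0) & (a_f < 1))

    def test_constant_input_gives_uniform_gates(self):
        sta = SpectralTemporalAttention(8, 4, np.random.default_rng(4))
        x = Tensor(np.full((1, 8, 6, 6), 0.7, dtype=np.float32))
        out = sta(x).data
        # constant over both h and t by symmetry of the averaging
        assert np.allclose(out, out[..., :1, :1], atol=1e-6)


class TestGrowthBranch:
    def test_channel_growth_and_downsampling(self, feat):
        gb = GrowthBranch(THIN, np.random.default_rng(5))
        gb.eval()
        assert gb.trans_bn.gamma.data.size == THIN.stem_channels + THIN.growth_blocks * THIN.growth_rate
        out = gb(feat)
        assert out.shape == (2, THIN.transition_channels, 6, 6)

    def test_block_removal_changes_params_by_closed_form(self):
        p2 = sum(p.data.size for p in GrowthBranch(THIN, np.random.default_rng(6)).parameters())
        cfg1 = NetConfig(**{**THIN.__dict__, "growth_blocks": 1})
        p1 = sum(p.data.size for p in GrowthBranch(cfg1, np.random.default_rng(6)).parameters())
        c_in = THIN.stem_channels + THIN.growth_rate  # input channels of block 2
        g = THIN.growth_rate
        expected_delta = (2 * c_in + 9 * c_in * g) + g * THIN.transition_channels + 2 * g
        assert p2 - p1 == expected_delta


class TestSkipBranch:
    def test_output_aligned_with_growth_branch(self, feat):
        rng_ = np.random.default_rng(7)
        gb, sb = GrowthBranch(THIN, rng_), SkipBranch(THIN, rng_)
        gb.eval(), sb.eval()
        assert gb(feat).shape == sb(feat).shape

    def test_identity_limit_when_residual_zeroed(self):
        blk = SkipBlock(8, 8, stride=1, rng=np.random.default_rng(8))
        blk.eval()
        blk.bn2.gamma.data[:] = 0.0
        blk.bn2.beta.data[:] = 0.0
        x = Tensor(np.abs(np.random.default_rng(9).standard_normal((1, 8, 6, 6))).astype(np.float32))
        assert np.allclose(blk(x).data, x.data, atol=1e-6)

    def test_gradient_reaches_input(self):
        sb = SkipBranch(THIN, np.random.default_rng(10))
        x = Tensor(np.random.default_rng(11).standard_normal((1, 8, 12, 12)).astype(np.float32), requires_grad=True)
        sb(x).sum(axis=(0, 1, 2, 3)).backward()
        assert x.grad is not None and np.isfinite(x.grad).all() and np.abs(x.grad).max() > 0


class TestGatedFusion:
    def test_gate_limits_select_branches(self, rng):
        gf = GatedFusion(8, np.random.default_rng(12))
        a = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32))
        b = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32))
        gf.gate.bias.data[:] = -30.0  # gate -> 0: output ~ x_grow
        assert np.allclose(gf(a, b).data, a.data, atol=1e-4)
        gf.gate.bias.data[:] = 30.0  # gate -> 1: output ~ x_skip
        gf.gate.weight.data[:] = 0.0
        assert np.allclose(gf(a, b).data, b.data, atol=1e-4)

    def test_fixed_point_when_branches_agree(self, rng):
        gf = GatedFusion(8, np.random.default_rng(13))
        x = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32))
        assert np.allclose(gf(x, x).data, x.data, atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        gf = GatedFusion(8, np.random.default_rng(14))
        a = Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32))
        b = Tensor(np.zeros((1, 8, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError):
            gf(a, b)


class TestLocalSpanAttention:
    def test_weights_sum_to_one_within_band(self, rng):
        lsa = LocalSpanAttention(8, 12, THIN, np.random.default_rng(15))
        x = Tensor(rng.standard_normal((2, 8, 12, 10)).astype(np.float32))
        w = lsa.attention_weights(x)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)
        # no mass outside the band
        idx = np.arange(10)
        outside = np.abs(idx[:, None] - idx[None, :]) > THIN.span
        assert np.all(w[..., outside] < 1e-6)

    def test_saturated_span_equals_full_attention(self, rng):
        cfg_full = NetConfig(**{**THIN.__dict__, "span": 10})
        cfg_huge = NetConfig(**{**THIN.__dict__, "span": 1000})
        l1 = LocalSpanAttention(8, 12, cfg_full, np.random.default_rng(16))
        l2 = LocalSpanAttention(8, 12, cfg_huge, np.random.default_rng(16))
        x = Tensor(rng.standard_normal((1, 8, 12, 10)).astype(np.float32))
        assert np.allclose(l1(x).data, l2(x).data, atol=1e-6)

    def test_span_zero_attends_only_to_self(self, rng):
        cfg0 = NetConfig(**{**THIN.__dict__, "span": 0})
        lsa = LocalSpanAttention(8, 12, cfg0, np.random.default_rng(17))
        x = Tensor(rng.standard_normal((1, 8, 12, 10)).astype(np.float32))
        w = lsa.attention_weights(x)
        assert np.allclose(w, np.eye(10), atol=1e-6)

    def test_output_shape_preserved(self, rng):
        lsa = LocalSpanAttention(8, 12, THIN, np.random.default_rng(18))
        x = Tensor(rng.standard_normal((2, 8, 12, 10)).astype(np.float32))
        assert lsa(x).shape == x.shape


class TestMultiscaleAttention:
    def test_gates_and_mask_bounded(self, feat):
        msa = MultiscaleAttention(8, 4, np.random.default_rng(19))
        gates = msa.channel_gates(feat).data
        assert np.all((gates > 0) & (gates < 1))
        out = msa(feat)
        assert out.shape == feat.shape

    def test_zero_channel_zeroes_its_descriptor(self, rng):
        msa = MultiscaleAttention(8, 4, np.random.default_rng(20))
        x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        x[:, 3] = 0.0
        desc = Tensor(x).mean(axis=(2, 3)).data
        assert desc[0, 3] == 0.0

    def test_uniform_channels_give_uniform_gates(self):
        msa = MultiscaleAttention(8, 4, np.random.default_rng(21))
        # tie the SE weights across channels so symmetry is exact
        msa.fc1.weight.data[:] = 0.1
        msa.fc2.weight.data[:] = 0.1
        x = Tensor(np.full((1, 8, 4, 4), 0.5, dtype=np.float32))
        gates = msa.channel_gates(x).data
        assert np.allclose(gates, gates[0, 0])


class TestFullBackbone:
    def test_thin_forward_shapes_and_finiteness(self, rng):
        model = DuSAFNet(THIN, seed=0)
        model.eval()
        x = Tensor(rng.standard_normal((2, 3, 224, 224)).astype(np.float32))
        emb = model.backbone(x)
        assert emb.shape == (2, THIN.transition_channels, 28, 28)
        logits = model(x)
        assert logits.shape == (2, THIN.n_classes)
        assert np.isfinite(logits.data).all()

    def test_eval_forward_deterministic(self, rng):
        model = DuSAFNet(THIN, seed=1)
        model.eval()
        x = Tensor(rng.standard_normal((1, 3, 224, 224)).astype(np.float32))
        assert np.array_equal(model(x).data, model(x).data)

    @pytest.mark.parametrize("cfg", [THIN, NetConfig(stem_channels=16, growth_rate=8, growth_blocks=3, transition_channels=16, proj_dim=16, heads=4, n_classes=5)])
    def test_param_count_matches_analytic_ledger(self, cfg):
        model = DuSAFNet(cfg, seed=0)
        assert model.num_parameters() == dusafnet_param_ledger(cfg)
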