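"""DuSAFNet backbone: stem, spectral-temporal attention, dual-path
feature module, gated fusion, and temporal-spatial fusion.

Data flow for a normalized 224 x 224 x 3 spectrogram image batch::

    SharedStem (7x7 conv, BN, ReLU, 3x3/2 maxpool)        -> C0 x 56 x 56
    SpectralTemporalAttention                              (recalibration)
    GrowthBranch (dense blocks) || SkipBranch (residual)  -> C' x 28 x 28
    GatedFusion                                            (convex mix)
    LocalSpanAttention (banded multi-head over time)       (residual)
    MultiscaleAttention (channel SE + spatial mask)        -> embedding map
    Dropout(0.5)                                           -> classifier head

Feature-map axes are (batch, channel, frequency, time); the frequency
axis follows the rendered image, so row 0 is the highest band.

The channel widths, growth rate, block count and attention projection
size are not fixed by the method itself; the defaults below are
calibrated so the full model (backbone + tri-band margin head, 18
classes) lands on a 6.77 M trainable-parameter budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv3x3,
    Linear,
    Module,
    Tensor,
    avgpool2x2,
    dropout,
    maxpool2d,
    softmax,
)

__all__ = [
    "NetConfig",
    "SharedStem",
    "SpectralTemporalAttention",
    "GrowthBranch",
    "SkipBranch",
    "GatedFusion",
    "LocalSpanAttention",
    "MultiscaleAttention",
    "DuSAFNetBackbone",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture constants (defaults calibrated to the 6.77 M budget)."""

    stem_channels: int = 64  # C0
    growth_rate: int = 32  # g
    growth_blocks: int = 6  # L
    transition_channels: int = 128  # C'
    skip_blocks: int = 2
    sta_ratio: int = 4  # bottleneck ratio of the STA gates
    msa_ratio: int = 16  # bottleneck ratio of the channel-attention path
    span: int = 3  # half-width of the attention band, in time steps
    heads: int = 4
    proj_dim: int = 412  # d: token projection size of LocalSpanAttention
    dropout: float = 0.5
    n_classes: int = 18

    def __post_init__(self):
        if self.proj_dim % self.heads:
            raise ValueError("proj_dim must be divisible by heads")


class SharedStem(Module):
    """7x7/2 conv + BN + ReLU + 3x3/2 max-pool: 224 -> 56, 3 -> C0 channels."""

    def __init__(self, cfg: NetConfig, rng):
        self.conv = Conv2d(3, cfg.stem_channels, 7, stride=2, pad=3, rng=rng)
        self.bn = BatchNorm2d(cfg.stem_channels)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] != 224 or x.shape[3] != 224:
            raise ValueError("stem expects 224x224 input")
        return maxpool2d(self.bn(self.conv(x)).relu(), k=3, stride=2, pad=1)


class SpectralTemporalAttention(Module):
    """Per-channel multiplicative gates along the frequency and time axes.

    The frequency gate A_f(b,c,h) is computed from the time-averaged map
    through a two-layer 1x1-conv bottleneck with sigmoid output; the time
    gate A_t(b,c,t) symmetrically from the frequency-averaged map.  The
    output is X * A_f * A_t (broadcast), so every gate lies in (0, 1) and
    the result is elementwise damped.
    """

    def __init__(self, channels: int, ratio: int, rng):
        hidden = max(channels // ratio, 1)
        self.f1 = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.f2 = Conv2d(hidden, channels, 1, bias=True, rng=rng)
        self.t1 = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.t2 = Conv2d(hidden, channels, 1, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        u_f = x.mean(axis=3, keepdims=True)  # (B,C,H,1)
        a_f = self.f2(self.f1(u_f).relu()).sigmoid()
        u_t = x.mean(axis=2, keepdims=True)  # (B,C,1,W)
        a_t = self.t2(self.t1(u_t).relu()).sigmoid()
        return x * a_f * a_t


class GrowthBranch(Module):
    """Densely connected blocks followed by a downsampling transition.

    Each block is BN -> ReLU -> 3x3 conv emitting ``g`` channels which
    are concatenated to its input, so channels grow C0 -> C0 + L*g; the
    transition is BN -> ReLU -> 1x1 conv to C' -> 2x2 average pool.
    """

    def __init__(self, cfg: NetConfig, rng):
        from .autodiff import concat  # local alias for clarity below

        self._concat = concat
        self.bns = []
        self.convs = []
        c = cfg.stem_channels
        for _ in range(cfg.growth_blocks):
            self.bns.append(BatchNorm2d(c))
            self.convs.append(Conv2d(c, cfg.growth_rate, 3, pad=1, rng=rng))
            c += cfg.growth_rate
        self.trans_bn = BatchNorm2d(c)
        self.trans_conv = Conv2d(c, cfg.transition_channels, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        for bn, conv in zip(self.bns, self.convs):
            new = conv(bn(x).relu())
            x = self._concat([x, new], axis=1)
        return avgpool2x2(self.trans_conv(self.trans_bn(x).relu()))


class SkipBlock(Module):
    """conv-BN-ReLU-conv-BN residual block with identity or 1x1 projection."""

    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return (y + shortcut).relu()


class SkipBranch(Module):
    """Two residual blocks (first downsamples by 2) + an STA recalibration."""

    def __init__(self, cfg: NetConfig, rng):
        c0, cp = cfg.stem_channels, cfg.transition_channels
        blocks = [SkipBlock(c0, cp, stride=2, rng=rng)]
        for _ in range(cfg.skip_blocks - 1):
            blocks.append(SkipBlock(cp, cp, stride=1, rng=rng))
        self.blocks = blocks
        self.sta = SpectralTemporalAttention(cp, cfg.sta_ratio, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return self.sta(x)


class GatedFusion(Module):
    """Elementwise convex combination of the two branch outputs.

    G = sigmoid(1x1conv(x_grow + x_skip)); out = x_grow*(1-G) + x_skip*G.
    When both inputs coincide the output equals them for any gate.
    """

    def __init__(self, channels: int, rng):
        self.gate = Conv2d(channels, channels, 1, bias=True, rng=rng)

    def __call__(self, x_grow: Tensor, x_skip: Tensor) -> Tensor:
        if x_grow.shape != x_skip.shape:
            raise ValueError("branch outputs must have identical shapes")
        g = self.gate(x_grow + x_skip).sigmoid()
        one = Tensor(np.float32(1.0))
        return x_grow * (one + (-g)) + x_skip * g


class LocalSpanAttention(Module):
    """Banded multi-head self-attention over time columns, with residual.

    Each time step's column (channels x height, flattened) is a token;
    tokens are projected to ``proj_dim``, attended with a mask that only
    admits keys within ``span`` steps of the query, projected back to the
    token size and added to the input.
    """

    def __init__(self, channels: int, height: int, cfg: NetConfig, rng):
        self.heads = cfg.heads
        self.span = cfg.span
        self.d = cfg.proj_dim
        token = channels * height
        self.wq = Linear(token, self.d, rng=rng)
        self.wk = Linear(token, self.d, rng=rng)
        self.wv = Linear(token, self.d, rng=rng)
        self.wo = Linear(self.d, token, rng=rng)
        self._mask_cache: dict[int, np.ndarray] = {}

    def _mask(self, t: int) -> np.ndarray:
        if t not in self._mask_cache:
            idx = np.arange(t)
            band = np.abs(idx[:, None] - idx[None, :]) <= self.span
            self._mask_cache[t] = np.where(band, 0.0, -1e9).astype(np.float32)
        return self._mask_cache[t]

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Softmax attention matrices (B, heads, T, T) for inspection."""
        b, c, h, w = x.shape
        tokens = x.transpose(0, 3, 1, 2).reshape(b, w, c * h)
        dh = self.d // self.heads
        q = self.wq(tokens).reshape(b, w, self.heads, dh).transpose(0, 2, 1, 3)
        k = self.wk(tokens).reshape(b, w, self.heads, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)).scale(1.0 / np.sqrt(dh))
        scores = scores + Tensor(self._mask(w))
        return softmax(scores, axis=-1).data

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        tokens = x.transpose(0, 3, 1, 2).reshape(b, w, c * h)  # (B, T, C*H)
        dh = self.d // self.heads
        q = self.wq(tokens).reshape(b, w, self.heads, dh).transpose(0, 2, 1, 3)
        k = self.wk(tokens).reshape(b, w, self.heads, dh).transpose(0, 2, 1, 3)
        v = self.wv(tokens).reshape(b, w, self.heads, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)).scale(1.0 / np.sqrt(dh))
        scores = scores + Tensor(self._mask(w))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, w, self.d)
        out = self.wo(ctx) + tokens  # residual in token space
        return out.reshape(b, w, c, h).transpose(0, 2, 3, 1)


class MultiscaleAttention(Module):
    """Channel squeeze-excitation followed by a spatial sigmoid mask.

    Channel path: global-average descriptor -> two linear maps with ReLU
    -> sigmoid -> per-channel rescale.  Spatial path: depthwise 3x3 +
    pointwise 1x1 on the rescaled map -> sigmoid mask -> elementwise
    product.
    """

    def __init__(self, channels: int, ratio: int, rng):
        hidden = max(channels // ratio, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.dw = DepthwiseConv3x3(channels, rng=rng)
        self.pw = Conv2d(channels, 1, 1, bias=True, rng=rng)

    def channel_gates(self, x: Tensor) -> Tensor:
        desc = x.mean(axis=(2, 3))  # (B, C)
        return self.fc2(self.fc1(desc).relu()).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        gates = self.channel_gates(x).reshape(b, c, 1, 1)
        rescaled = x * gates
        mask = self.pw(self.dw(rescaled)).sigmoid()  # (B,1,H,W)
        return rescaled * mask


class DuSAFNetBackbone(Module):
    """Full backbone producing the embedding map handed to the classifier."""

    def __init__(self, cfg: NetConfig = NetConfig(), rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        self.stem = SharedStem(cfg, rng)
        self.sta = SpectralTemporalAttention(cfg.stem_channels, cfg.sta_ratio, rng)
        self.growth = GrowthBranch(cfg, rng)
        self.skip = SkipBranch(cfg, rng)
        self.fusion = GatedFusion(cfg.transition_channels, rng)
        self.lsa = LocalSpanAttention(cfg.transition_channels, 28, cfg, rng)
        self.msa = MultiscaleAttention(cfg.transition_channels, cfg.msa_ratio, rng)
        self._drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        x = self.sta(x)
        fused = self.fusion(self.growth(x), self.skip(x))
        x = self.lsa(fused)
        x = self.msa(x)
        return dropout(x, self.cfg.dropout, self._drop_rng, self.training)

    def embed(self, x: Tensor) -> np.ndarray:
        """Pre-pool embedding map (eval path, no dropout), flattened per sample."""
        was_training = self.training
        self.eval()
        try:
            out = self(x).data
        finally:
            self.train(was_training)
        return out.reshape(out.shape[0], -1)
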