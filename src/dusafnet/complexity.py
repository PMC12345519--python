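"""Parameter and operation accounting.

``complexity_report`` counts the model's trainable parameters (exact
integer, cross-checked against an analytic per-layer ledger) and its
multiply-accumulate count for one 224 x 224 x 3 forward pass.  MACs are
counted over convolution, linear and attention matmul layers -- the
standard profiler convention; FLOPs are reported as 2 x MACs, since the
two conventions differ exactly by that factor.

Closed-form parameter counters for two standard reference image
classifiers (a 50-layer bottleneck residual network and an
inverted-residual mobile network, each with a custom class count) are
included as fixtures for validating the counting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import NetConfig

__all__ = [
    "ComplexityReport",
    "complexity_report",
    "dusafnet_param_ledger",
    "dusafnet_mac_count",
    "resnet50_param_count",
    "mobilenetv2_param_count",
]


@dataclass(frozen=True)
class ComplexityReport:
    params: int
    macs: int

    @property
    def flops(self) -> int:
        return 2 * self.macs

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def gmacs(self) -> float:
        return self.macs / 1e9

    @property
    def gflops(self) -> float:
        return self.flops / 1e9


def _sta_params(c: int, ratio: int) -> int:
    hid = max(c // ratio, 1)
    return 2 * (c * hid + hid + hid * c + c)


def dusafnet_param_ledger(cfg: NetConfig = NetConfig()) -> int:
    """Analytic trainable-parameter count, layer by layer."""
    c0, g, L, cp = cfg.stem_channels, cfg.growth_rate, cfg.growth_blocks, cfg.transition_channels
    p = 7 * 7 * 3 * c0 + 2 * c0  # stem conv + BN
    p += _sta_params(c0, cfg.sta_ratio)
    # growth branch
    c = c0
    for _ in range(L):
        p += 2 * c + 9 * c * g  # BN + 3x3 conv
        c += g
    p += 2 * c + c * cp  # transition BN + 1x1 conv
    # skip branch: first block downsamples with projection
    p += 9 * c0 * cp + 2 * cp + 9 * cp * cp + 2 * cp + c0 * cp + 2 * cp
    for _ in range(cfg.skip_blocks - 1):
        p += 2 * (9 * cp * cp) + 4 * cp
    p += _sta_params(cp, cfg.sta_ratio)
    # gated fusion
    p += cp * cp + cp
    # local span attention
    token = cp * 28
    d = cfg.proj_dim
    p += 3 * (token * d + d) + d * token + token
    # multiscale attention
    hid = max(cp // cfg.msa_ratio, 1)
    p += cp * hid + hid + hid * cp + cp  # SE linears
    p += 9 * cp  # depthwise 3x3
    p += cp * 1 + 1  # pointwise mask conv
    # tri-band head
    p += 3 * cfg.n_classes * cp + 3
    return p


def dusafnet_mac_count(cfg: NetConfig = NetConfig()) -> int:
    """Multiply-accumulates of one 224x224x3 forward (conv/linear/attention)."""
    c0, g, L, cp = cfg.stem_channels, cfg.growth_rate, cfg.growth_blocks, cfg.transition_channels
    macs = 49 * 3 * c0 * 112 * 112  # stem conv
    hid0 = max(c0 // cfg.sta_ratio, 1)
    macs += 2 * (c0 * hid0 + hid0 * c0) * 56  # STA gate convs over H / W vectors
    c = c0
    for _ in range(L):
        macs += 9 * c * g * 56 * 56
        c += g
    macs += c * cp * 56 * 56  # transition
    macs += (9 * c0 * cp + 9 * cp * cp + c0 * cp) * 28 * 28  # skip block 1
    macs += (cfg.skip_blocks - 1) * 2 * 9 * cp * cp * 28 * 28
    hidp = max(cp // cfg.sta_ratio, 1)
    macs += 2 * (cp * hidp + hidp * cp) * 28
    macs += cp * cp * 28 * 28  # gate conv
    token, d, T = cp * 28, cfg.proj_dim, 28
    macs += 3 * token * d * T + 2 * T * T * d + d * token * T
    hid = max(cp // cfg.msa_ratio, 1)
    macs += cp * hid + hid * cp
    macs += 9 * cp * 28 * 28 + cp * 28 * 28  # depthwise + pointwise
    macs += 3 * cfg.n_classes * cp
    return macs


def complexity_report(model=None, cfg: NetConfig | None = None) -> ComplexityReport:
    """Exact parameter count of a constructed model (or of a config) + MACs."""
    if model is not None:
        params = model.num_parameters()
        cfg = model.net_cfg
    else:
        cfg = cfg or NetConfig()
        params = dusafnet_param_ledger(cfg)
    return ComplexityReport(params=params, macs=dusafnet_mac_count(cfg))


def resnet50_param_count(n_classes: int = 1000) -> int:
    """Closed-form parameter count of the standard 50-layer residual net.

    Bottleneck blocks [3, 4, 6, 3] with widths 64/128/256/512, expansion
    4, batch norm after every convolution, and a single linear head.
    """
    p = 7 * 7 * 3 * 64 + 2 * 64
    c_in = 64
    for width, blocks in zip((64, 128, 256, 512), (3, 4, 6, 3)):
        c_out = 4 * width
        for b in range(blocks):
            p += c_in * width + 2 * width  # 1x1 reduce
            p += 9 * width * width + 2 * width  # 3x3
            p += width * c_out + 2 * c_out  # 1x1 expand
            if b == 0:
                p += c_in * c_out + 2 * c_out  # projection shortcut
            c_in = c_out
    p += 2048 * n_classes + n_classes
    return p


_MBV2_CFG = [
    # (expansion t, output channels c, repeats n, stride s)
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def mobilenetv2_param_count(n_classes: int = 1000) -> int:
    """Closed-form parameter count of the standard inverted-residual
    mobile network (width multiplier 1.0)."""
    p = 9 * 3 * 32 + 2 * 32  # stem 3x3 conv + BN
    c_in = 32
    for t, c, n, _s in _MBV2_CFG:
        for _ in range(n):
            hid = c_in * t
            if t != 1:
                p += c_in * hid + 2 * hid  # expand 1x1 + BN
            p += 9 * hid + 2 * hid  # depthwise 3x3 + BN
            p += hid * c + 2 * c  # project 1x1 + BN
            c_in = c
    p += c_in * 1280 + 2 * 1280  # final 1x1 conv + BN
    p += 1280 * n_classes + n_classes
    return p
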