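"""Tri-band additive-angular-margin classifier.

The embedding map is split along the frequency (height) axis into low,
mid and high bands (low frequencies sit at the bottom rows of the map,
following the rendering convention).  Each band is average-pooled to a
channel vector and classified by its own ArcMargin branch -- cosine
similarity on the unit hypersphere with an additive angular margin ``m``
on the true class and a scale ``s`` -- and the three band logits are
fused by learnable simplex weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Module, Parameter, Tensor, cross_entropy, softmax

__all__ = ["BandConfig", "ArcMarginProduct", "TriBandArcHead", "band_slices", "head_loss"]


@dataclass(frozen=True)
class BandConfig:
    """Per-band margin hyperparameters and fusion-weight initialization.

    Scales grow and margins tighten from low to high band: high-frequency
    detail carries the most species-discriminative structure, so it gets
    the hardest margin.
    """

    s_low: float = 20.0
    m_low: float = 0.30
    s_mid: float = 30.0
    m_mid: float = 0.50
    s_high: float = 40.0
    m_high: float = 0.70
    alpha_init: tuple[float, float, float] = (0.3, 0.3, 0.4)  # (low, mid, high)

    def __post_init__(self):
        for s, m in ((self.s_low, self.m_low), (self.s_mid, self.m_mid), (self.s_high, self.m_high)):
            if s <= 0 or not (0.0 <= m < np.pi / 2):
                raise ValueError("need s > 0 and 0 <= m < pi/2")
        a = np.asarray(self.alpha_init)
        if (a < 0).any() or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError("alpha_init must lie on the simplex")


def band_slices(H: int) -> dict[str, slice]:
    """Height slices for the three bands; remainder rows go to the high band.

    Row 0 is the top of the map (highest frequencies), so the low band is
    the last ``floor(H/3)`` rows.
    """
    if H < 3:
        raise ValueError("need H >= 3 to form three bands")
    h1 = H // 3
    return {
        "high": slice(0, H - 2 * h1),
        "mid": slice(H - 2 * h1, H - h1),
        "low": slice(H - h1, H),
    }


def band_pool(feat: Tensor) -> dict[str, Tensor]:
    """Average-pool each frequency band of a (B, C, H, W) map to a C-vector."""
    H = feat.shape[2]
    slices = band_slices(H)
    return {name: _slice_rows(feat, sl).mean(axis=(2, 3)) for name, sl in slices.items()}


def _slice_rows(x: Tensor, sl: slice) -> Tensor:
    data = x.data[:, :, sl, :]
    out = Tensor(data, parents=(x,))
    if out.requires_grad:
        def back(g):
            gx = np.zeros_like(x.data)
            gx[:, :, sl, :] = g
            x._accum(gx)
        out._backward = back
    return out


class ArcMarginProduct(Module):
    """Additive-angular-margin logits for one band.

    Embeddings and class weights are L2-normalized, so logits are scaled
    cosines.  In training mode the true-class cosine cos(theta_y) is
    replaced by cos(theta_y + m); where theta_y + m would exceed pi (the
    non-monotonic region) the standard fallback cos(theta) - m*sin(m) is
    used instead.  Inference ignores labels and returns s * cos(theta).
    """

    def __init__(self, in_features: int, n_classes: int, s: float, m: float, rng):
        self.s = float(s)
        self.m = float(m)
        self.weight = Parameter(
            (rng.standard_normal((n_classes, in_features)) * 0.01).astype(np.float32)
        )

    def cosine(self, z: Tensor) -> Tensor:
        if np.any(np.linalg.norm(z.data, axis=1) < 1e-12):
            raise ValueError("zero-norm embedding: angle undefined")
        zn = z.l2normalize(axis=1)
        wn = self.weight.l2normalize(axis=1)
        return zn @ wn.transpose(1, 0)

    def __call__(self, z: Tensor, labels: np.ndarray | None = None) -> Tensor:
        cos = self.cosine(z)
        if labels is None or self.m == 0.0:
            return cos.scale(self.s)
        return _arc_margin_adjust(cos, labels, self.s, self.m)


def _arc_margin_adjust(cos: Tensor, labels: np.ndarray, s: float, m: float) -> Tensor:
    """Fused op: replace true-class cosines by cos(theta + m), scale by s."""
    c = cos.data
    n = c.shape[0]
    rows = np.arange(n)
    cy = c[rows, labels]
    sin = np.sqrt(np.clip(1.0 - cy * cy, 1e-12, None))
    cos_m, sin_m = np.cos(m), np.sin(m)
    phi = cy * cos_m - sin * sin_m
    # past theta = pi - m, cos(theta+m) is no longer monotone in theta
    monotone = cy > np.cos(np.pi - m)
    adjusted = np.where(monotone, phi, cy - m * sin_m)
    out_data = c.copy()
    out_data[rows, labels] = adjusted
    out = Tensor(s * out_data, parents=(cos,))
    if out.requires_grad:
        def back(g):
            dcos = g * s
            # d(phi)/d(cos) = cos_m + sin_m * cos/sin; fallback branch has slope 1
            slope = np.where(monotone, cos_m + sin_m * cy / sin, 1.0)
            dcos[rows, labels] *= slope.astype(np.float32)
            cos._accum(dcos)
        out._backward = back
    return out


class TriBandArcHead(Module):
    """Band pooling + three ArcMargin branches + learnable simplex fusion.

    Fusion weights are stored as softmax logits initialized so the
    normalized weights equal ``alpha_init``; they remain on the simplex
    after every optimizer step by construction.
    """

    def __init__(self, in_features: int, n_classes: int, cfg: BandConfig, rng):
        self.cfg = cfg
        self.low = ArcMarginProduct(in_features, n_classes, cfg.s_low, cfg.m_low, rng)
        self.mid = ArcMarginProduct(in_features, n_classes, cfg.s_mid, cfg.m_mid, rng)
        self.high = ArcMarginProduct(in_features, n_classes, cfg.s_high, cfg.m_high, rng)
        self.alpha_logits = Parameter(np.log(np.asarray(cfg.alpha_init, dtype=np.float32)))

    @property
    def alpha(self) -> np.ndarray:
        """Current fusion weights (low, mid, high) on the simplex."""
        a = self.alpha_logits.data
        e = np.exp(a - a.max())
        return e / e.sum()

    def band_logits(self, feat: Tensor, labels: np.ndarray | None = None) -> dict[str, Tensor]:
        pooled = band_pool(feat)
        return {
            "low": self.low(pooled["low"], labels),
            "mid": self.mid(pooled["mid"], labels),
            "high": self.high(pooled["high"], labels),
        }

    def fuse(self, bands: dict[str, Tensor]) -> Tensor:
        a = softmax(self.alpha_logits.reshape(1, 3), axis=1)
        parts = []
        for i, name in enumerate(("low", "mid", "high")):
            w = _select(a, i)
            parts.append(bands[name] * w)
        return parts[0] + parts[1] + parts[2]

    def __call__(self, feat: Tensor, labels: np.ndarray | None = None) -> Tensor:
        return self.fuse(self.band_logits(feat, labels))


def _select(a: Tensor, i: int) -> Tensor:
    """Scalar element a[0, i] as a graph node."""
    out = Tensor(a.data[0, i], parents=(a,))
    if out.requires_grad:
        def back(g):
            ga = np.zeros_like(a.data)
            ga[0, i] = g
            a._accum(ga)
        out._backward = back
    return out


def head_loss(fused_logits: Tensor, labels: np.ndarray) -> Tensor:
    """Cross-entropy over the fused margin logits."""
    return cross_entropy(fused_logits, labels)
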