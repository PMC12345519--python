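"""Full classifier (backbone + tri-band margin head) and checkpoint I/O."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np

from .autodiff import Module, Tensor
from .head import BandConfig, TriBandArcHead
from .network import DuSAFNetBackbone, NetConfig

__all__ = ["DuSAFNet", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


class DuSAFNet(Module):
    """End-to-end model: normalized image batch -> fused class logits."""

    def __init__(
        self,
        net_cfg: NetConfig = NetConfig(),
        band_cfg: BandConfig = BandConfig(),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.net_cfg = net_cfg
        self.band_cfg = band_cfg
        self.backbone = DuSAFNetBackbone(net_cfg, rng)
        self.head = TriBandArcHead(net_cfg.transition_channels, net_cfg.n_classes, band_cfg, rng)

    def __call__(self, x: Tensor, labels: np.ndarray | None = None) -> Tensor:
        return self.head(self.backbone(x), labels)

    def predict_scores(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        """Softmax class probabilities for an (N, 3, 224, 224) array."""
        self.eval()
        out = []
        for i in range(0, len(x), batch):
            logits = self(Tensor(x[i : i + batch])).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)


def save_checkpoint(model: DuSAFNet, path: str | Path, extra: dict | None = None) -> None:
    state = model.state_dict()
    meta = {
        "version": CHECKPOINT_VERSION,
        "net_cfg": asdict(model.net_cfg),
        "band_cfg": asdict(model.band_cfg),
    }
    if extra:
        meta.update(extra)
    np.savez_compressed(path, __meta__=np.array([repr(meta)]), **state)


def load_checkpoint(path: str | Path) -> tuple[DuSAFNet, dict]:
    import ast

    with np.load(path, allow_pickle=False) as data:
        meta = ast.literal_eval(str(data["__meta__"][0]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        band = dict(meta["band_cfg"])
        band["alpha_init"] = tuple(band["alpha_init"])
        model = DuSAFNet(NetConfig(**meta["net_cfg"]), BandConfig(**band))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
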