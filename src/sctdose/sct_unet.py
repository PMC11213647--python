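"""Deep-learning synthetic CT: normalization, U-Net training and inference.

CT volumes are clipped at 2000 HU and mapped to [0, 1] by
``hu / 3000 + 1/3`` (so -1000 HU -> 0 and 2000 HU -> 1); MR volumes are
scaled by their 99.995th-percentile intensity.  A 2D U-Net is trained
slice-wise with whole-batch Adam steps and an MSE loss, then applied
slice-by-slice at inference and de-normalized back to HU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._unet_net import Adam, UNet2D
from .core_io import ImageGrid

CT_CLIP_HU = 2000.0
CT_SCALE = 3000.0
MR_PERCENTILE = 99.995


@dataclass
class UNetConfig:
    """Architecture and training hyper-parameters of the sCT U-Net."""

    levels: int = 4
    convs_per_block: int = 2
    base_filters: int = 32
    dropout: float = 0.2
    lr: float = 1e-4
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass
class NormalizedPair:
    """Co-registered MR/CT slices mapped to [0, 1] for training."""

    mr_norm: np.ndarray     # (slices, H, W)
    ct_norm: np.ndarray
    mr_scale: float         # intensity at the 99.995th percentile

    def __post_init__(self):
        if self.mr_norm.shape != self.ct_norm.shape:
            raise ValueError("MR and CT slice stacks must share shape")


def normalize_ct(ct: ImageGrid | np.ndarray) -> np.ndarray:
    """Clip HU at 2000 and map affinely so [-1000, 2000] -> [0, 1]."""
    hu = ct.voxels if isinstance(ct, ImageGrid) else np.asarray(ct, float)
    return np.minimum(hu, CT_CLIP_HU) / CT_SCALE + 1.0 / 3.0


def denormalize_ct(norm: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_ct` below the 2000 HU cut-off."""
    return CT_SCALE * (np.asarray(norm, dtype=float) - 1.0 / 3.0)


def normalize_mr(mr: ImageGrid | np.ndarray):
    """Scale by the per-volume 99.995th-percentile intensity.

    Returns ``(normalized array, scale)``; values above the near-maximum may
    slightly exceed 1 and are intentionally not clipped.
    """
    vals = mr.voxels if isinstance(mr, ImageGrid) else np.asarray(mr, float)
    scale = float(np.percentile(vals, MR_PERCENTILE))
    if scale <= 0:
        raise ValueError("MR volume has no positive intensities to scale by")
    return vals / scale, scale


def make_pair(mr: ImageGrid, ct: ImageGrid) -> NormalizedPair:
    mr_norm, scale = normalize_mr(mr)
    return NormalizedPair(mr_norm=mr_norm.astype(np.float32),
                          ct_norm=normalize_ct(ct).astype(np.float32),
                          mr_scale=scale)


@dataclass
class TrainedUNet:
    net: UNet2D
    config: UNetConfig
    loss_trace: list
    train_shape: tuple | None = None   # in-plane (H, W) seen in training

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.net.parameters())}
        np.savez(directory / "weights.npz", **arrays)
        meta = {"config": asdict(self.config), "loss_trace": self.loss_trace,
                "train_shape": list(self.train_shape or ())}
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "TrainedUNet":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        config = UNetConfig(**meta["config"])
        model = cls(_build_net(config), config, meta["loss_trace"],
                    tuple(meta.get("train_shape") or ()) or None)
        with np.load(directory / "weights.npz") as data:
            for i, p in enumerate(model.net.parameters()):
                p[...] = data[f"p{i}"]
        return model


def _build_net(config: UNetConfig) -> UNet2D:
    return UNet2D(levels=config.levels, base_filters=config.base_filters,
                  convs_per_block=config.convs_per_block,
                  dropout=config.dropout, seed=config.seed)


def train_unet(pairs, config: UNetConfig | None = None) -> TrainedUNet:
    """Train on pooled slices with one whole-batch Adam step per epoch."""
    config = config or UNetConfig()
    if not pairs:
        raise ValueError("need at least one normalized MR/CT pair")
    x = np.concatenate([p.mr_norm for p in pairs]).astype(np.float32)
    y = np.concatenate([p.ct_norm for p in pairs]).astype(np.float32)
    h, w = x.shape[1:]
    div = 2 ** config.levels
    if h % div or w % div:
        raise ValueError(f"slice shape {(h, w)} must be divisible by {div} "
                         f"for a {config.levels}-level U-Net")
    net = _build_net(config)
    optim = Adam(net.parameters(), lr=config.lr)
    trace = []
    for _ in range(config.epochs):
        pred = net.forward(x, training=True)
        resid = pred - y
        loss = float(np.mean(resid ** 2))
        trace.append(loss)
        net.backward((2.0 / resid.size) * resid)
        optim.step(net.gradients())
    return TrainedUNet(net=net, config=config, loss_trace=trace,
                       train_shape=(h, w))


def infer_sct(model: TrainedUNet, mr: ImageGrid, normalized: bool = False,
              chunk: int = 8) -> ImageGrid:
    """Apply the trained net slice-wise and de-normalize to HU.

    Inference runs in eval mode (dropout off) and is deterministic; the
    output re-uses the MR geometry.
    """
    if model.train_shape and tuple(mr.shape[1:]) != tuple(model.train_shape):
        raise ValueError(f"MR in-plane shape {mr.shape[1:]} does not match "
                         f"the training shape {model.train_shape}")
    if normalized:
        mr_norm = np.asarray(mr.voxels, dtype=np.float32)
    else:
        mr_norm, _ = normalize_mr(mr)
        mr_norm = mr_norm.astype(np.float32)
    outs = []
    for start in range(0, mr_norm.shape[0], chunk):
        outs.append(model.net.forward(mr_norm[start:start + chunk],
                                      training=False))
    hu = denormalize_ct(np.concatenate(outs))
    return ImageGrid(hu, spacing=mr.spacing, origin=mr.origin,
                     modality="CT", units="HU")
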