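"""The frame-level segmentation model: a small strided-CNN encoder with a
matching upsampling decoder and additive skip connection (U-Net topology),
mapping a [n_mels x n_frames] log-Mel image to per-frame BS probabilities.

The default ``tiny_cnn`` encoder is sized for CPU training on synthetic
cohorts. An ``efficientnet_b2`` encoder choice is reserved as an optional
hook for large-scale transfer-learning setups and is not bundled here.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import Adam, Conv1d, ReLU, Upsample2x, sigmoid


@dataclass
class EncoderConfig:
    encoder: str = "tiny_cnn"
    n_mels: int = 128
    target_frames: int = 1056
    base_channels: int = 32


class SegmentationModel:
    """Tiny 1-D U-Net over the time axis (mel bins are input channels).

    Two stride-2 encoder blocks halve the frame axis twice, a bottleneck conv
    mixes context, and two nearest-neighbour upsampling blocks restore frame
    resolution; the first decoder stage adds the first encoder activation
    (skip connection). A 1x1 head collapses channels to one logit per frame,
    which also collapses the frequency axis before the sigmoid.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0):
        if config.encoder == "efficientnet_b2":
            raise NotImplementedError(
                "the efficientnet_b2 encoder is an optional transfer-learning "
                "hook; install/train it separately and load weights via "
                "load_model(); the bundled encoder is 'tiny_cnn'"
            )
        if config.encoder != "tiny_cnn":
            raise ValueError(f"unknown encoder {config.encoder!r}")
        if config.target_frames % 4 != 0:
            raise ValueError("target_frames must be divisible by 4 (two stride-2 stages)")
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        self.enc1 = Conv1d(config.n_mels, c, k=5, stride=2, rng=rng)
        self.enc2 = Conv1d(c, 2 * c, k=5, stride=2, rng=rng)
        self.mid = Conv1d(2 * c, 2 * c, k=3, stride=1, rng=rng)
        self.dec2 = Conv1d(2 * c, c, k=3, stride=1, rng=rng)
        self.dec1 = Conv1d(c, c // 2, k=3, stride=1, rng=rng)
        self.head = Conv1d(c // 2, 1, k=1, stride=1, rng=rng)
        self.up = Upsample2x()
        self.relu = [ReLU() for _ in range(5)]
        # input standardisation, fit on the training set
        self.in_mean = 0.0
        self.in_std = 1.0
        self.history: dict = {}

    @property
    def convs(self) -> list[Conv1d]:
        return [self.enc1, self.enc2, self.mid, self.dec2, self.dec1, self.head]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for c in self.convs for p in c.params))

    def make_optimizer(self, beta1, beta2, weight_decay) -> Adam:
        params = [p for c in self.convs for p in c.params]
        return Adam(params, beta1=beta1, beta2=beta2, weight_decay=weight_decay)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.in_mean) / self.in_std

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: [B, n_mels, T] raw log-Mel values -> logits [B, T]."""
        x = self._normalize(np.asarray(x, dtype=np.float64))
        h1 = self.relu[0].forward(self.enc1.forward(x, train), train)
        h2 = self.relu[1].forward(self.enc2.forward(h1, train), train)
        m = self.relu[2].forward(self.mid.forward(h2, train), train)
        d2 = self.relu[3].forward(self.dec2.forward(self.up.forward(m), train), train)
        d2 = d2 + h1  # skip connection
        d1 = self.relu[4].forward(self.dec1.forward(self.up.forward(d2), train), train)
        z = self.head.forward(d1, train)
        return z[:, 0, :]

    def backward(self, dz: np.ndarray) -> None:
        """dz: [B, T] gradient of the loss w.r.t. logits."""
        d = self.head.backward(dz[:, None, :])
        d = self.up.backward(self.dec1.backward(self.relu[4].backward(d)))
        d_skip = d  # gradient into h1 via the skip connection
        d = self.up.backward(self.dec2.backward(self.relu[3].backward(d)))
        d = self.enc2.backward(self.relu[1].backward(self.mid.backward(self.relu[2].backward(d))))
        # the two paths into enc1's activation: through the decoder and the skip
        d_h1 = self.relu[0].backward(d + d_skip)
        self.enc1.backward(d_h1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-frame BS probabilities, [B, T]."""
        return sigmoid(self.forward_logits(x, train=False))

    # -- serialisation ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, conv in zip(["enc1", "enc2", "mid", "dec2", "dec1", "head"], self.convs):
            out[f"{name}_W"] = conv.W
            out[f"{name}_b"] = conv.b
        out["in_mean"] = np.array(self.in_mean)
        out["in_std"] = np.array(self.in_std)
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self.config), sort_keys=True).encode()).hexdigest()[:16]


def build_model(encoder_cfg: EncoderConfig | None = None, seed: int = 0) -> SegmentationModel:
    """Construct the segmentation model with He-initialised weights."""
    return SegmentationModel(encoder_cfg or EncoderConfig(), seed=seed)


def save_model(model: SegmentationModel, path: str | os.PathLike) -> None:
    """Single-file checkpoint: weights + config (json) + config hash."""
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps({**asdict(model.config), "hash": model.config_hash()}).encode(), dtype=np.uint8
        ),
        **model.state_arrays(),
    )


def load_model(path: str | os.PathLike) -> SegmentationModel:
    data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
    meta = json.loads(bytes(data["__config__"]).decode())
    meta.pop("hash", None)
    model = SegmentationModel(EncoderConfig(**meta))
    for name, conv in zip(["enc1", "enc2", "mid", "dec2", "dec1", "head"], model.convs):
        conv.W = data[f"{name}_W"]
        conv.b = data[f"{name}_b"]
    model.in_mean = float(data["in_mean"])
    model.in_std = float(data["in_std"])
    return model
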