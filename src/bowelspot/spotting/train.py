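"""Spotter training (cross-entropy + dice loss, Adam with staged LR decay)
and inference from spectrogram clips to bowel-sound events."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..preprocess import AudioBuffer, SpectrogramConfig, SpectrogramTensor, highpass_offset_filter, logmel, pad_time, segment_audio
from ._nn import sigmoid
from .augment import AugmentationConfig, augment
from .events import BSEvent, FrameMask, mask_to_events, merge_touching, postprocess_events
from .model import EncoderConfig, SegmentationModel, build_model

_EPS = 1e-6


@dataclass
class TrainingConfig:
    """Optimisation recipe. Defaults follow the published recipe for the
    pretrained-encoder setting; training the bundled tiny encoder from
    scratch typically needs a larger ``lr0`` (see docs/methods.md)."""

    epochs: int = 25
    batch_size: int = 32
    lr0: float = 1e-4
    lr_decay: float = 0.85
    decay_start_epoch: int = 6
    adam_beta1: float = 0.95
    adam_beta2: float = 0.999
    weight_decay: float = 5e-7
    seed: int = 0
    encoder: str = "tiny_cnn"
    threshold: float = 0.5

    def validate(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.lr0 <= 0 or self.lr_decay <= 0:
            raise ValueError("epochs, batch_size, lr0 and lr_decay must be positive")
        if self.decay_start_epoch > self.epochs:
            raise ValueError("decay_start_epoch must not exceed epochs")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for 1-indexed ``epoch``: lr0 before the decay start,
        then multiplied by ``lr_decay`` each epoch from there on."""
        if epoch < self.decay_start_epoch:
            return self.lr0
        return self.lr0 * self.lr_decay ** (epoch - self.decay_start_epoch + 1)


def combined_loss(
    probs: np.ndarray, target: np.ndarray, valid: np.ndarray | None = None
) -> float:
    """Sum of mean binary cross-entropy and dice loss over valid frames.

    dice = 1 - 2*|p.t| / (|p| + |t| + eps); both terms are differentiable in
    the probabilities.
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: probs {p.shape} vs target {t.shape}")
    if valid is not None:
        p, t = p[valid], t[valid]
    if p.size == 0:
        raise ValueError("no valid frames")
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    bce = float(-np.mean(t * np.log(pc) + (1 - t) * np.log(1 - pc)))
    dice = 1.0 - 2.0 * float(np.sum(p * t)) / (float(np.sum(p) + np.sum(t)) + _EPS)
    return bce + dice


def _loss_and_grad(logits: np.ndarray, target: np.ndarray, valid: np.ndarray):
    """Pooled-batch loss and its gradient w.r.t. logits (zero on pad frames)."""
    p = sigmoid(logits)
    v = valid.astype(bool)
    n = max(int(v.sum()), 1)
    t = target
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    bce = float(-np.sum((t * np.log(pc) + (1 - t) * np.log(1 - pc))[v]) / n)
    s_pt = float(np.sum((p * t)[v]))
    s = float(np.sum(p[v]) + np.sum(t[v])) + _EPS
    dice = 1.0 - 2.0 * s_pt / s
    # d(bce)/dz = (p - t)/n ; d(dice)/dp = -2 t/s + 2 s_pt/s^2, dp/dz = p(1-p)
    dz = (p - t) / n + (-2.0 * t / s + 2.0 * s_pt / s**2) * p * (1 - p)
    dz[~v] = 0.0
    return bce + dice, dz


def train_spotter(
    clips: Sequence[SpectrogramTensor | np.ndarray],
    masks: Sequence[FrameMask | np.ndarray],
    cfg: TrainingConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    encoder_cfg: EncoderConfig | None = None,
) -> SegmentationModel:
    """Train the segmentation model on (spectrogram, frame-mask) pairs.

    Follows the configured schedule exactly: ``epochs`` passes in random
    batches of ``batch_size``, Adam with the configured betas and weight
    decay, and the staged learning-rate decay. Deterministic given
    ``cfg.seed``. Per-epoch pooled losses are recorded in ``model.history``.
    """
    cfg = cfg or TrainingConfig()
    cfg.validate()
    X = np.stack([c.values if isinstance(c, SpectrogramTensor) else np.asarray(c) for c in clips])
    Y = np.stack(
        [np.asarray(m.binary if isinstance(m, FrameMask) else m, dtype=np.float64) for m in masks]
    )
    V = np.ones_like(Y, dtype=bool)
    for i, m in enumerate(masks):
        if isinstance(m, FrameMask) and m.valid_frames is not None:
            V[i, m.valid_frames :] = False
    if X.shape[0] != Y.shape[0] or X.shape[2] != Y.shape[1]:
        raise ValueError("clips and masks disagree in count or frame length")
    n_pos = int(Y[V].sum())
    if n_pos == 0:
        warnings.warn("all-negative training labels: dice term is degenerate", stacklevel=2)
    elif n_pos == int(V.sum()):
        warnings.warn("all-positive training labels", stacklevel=2)

    enc = encoder_cfg or EncoderConfig(encoder=cfg.encoder, n_mels=X.shape[1], target_frames=X.shape[2])
    model = build_model(enc, seed=cfg.seed)
    model.in_mean = float(X.mean())
    model.in_std = float(X.std()) or 1.0
    opt = model.make_optimizer(cfg.adam_beta1, cfg.adam_beta2, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)

    epoch_losses: list[float] = []
    n = X.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            if aug_cfg is not None:
                pairs = [augment(X[i], Y[i], aug_cfg, rng) for i in idx]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            else:
                xb, yb = X[idx], Y[idx]
            vb = V[idx]
            logits = model.forward_logits(xb, train=True)
            loss, dz = _loss_and_grad(logits, yb, vb)
            model.backward(dz)
            grads = [g for c in model.convs for g in c.grads]
            opt.step(grads, lr)
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
    model.history = {"epoch_loss": epoch_losses, "lr": [cfg.lr_at_epoch(e) for e in range(1, cfg.epochs + 1)]}
    return model


def infer_masks(
    model: SegmentationModel, specs: Sequence[SpectrogramTensor], threshold: float = 0.5
) -> list[FrameMask]:
    """Per-clip frame probabilities from the model (padded frames stay off)."""
    if not specs:
        return []
    X = np.stack([s.values for s in specs])
    probs = model.predict_proba(X)
    return [
        FrameMask(
            probs=probs[i],
            clip_t0_s=s.clip_t0_s,
            hop_s=s.hop_s,
            win_s=s.win_s,
            valid_frames=s.valid_frames,
            threshold=threshold,
        )
        for i, s in enumerate(specs)
    ]


def infer_events(
    model: SegmentationModel,
    specs: Sequence[SpectrogramTensor],
    threshold: float = 0.5,
    channel: int = 0,
    participant_id: str = "",
    postprocess: bool = True,
) -> list[BSEvent]:
    """Threshold per-frame probabilities, extract maximal positive runs as
    events, merge events touching across clip boundaries, then apply the
    event grammar (merge < 100 ms gaps, drop < 18 ms)."""
    events: list[BSEvent] = []
    for mask in infer_masks(model, specs, threshold):
        events.extend(mask_to_events(mask, channel=channel, participant_id=participant_id))
    events = merge_touching(events)
    return postprocess_events(events) if postprocess else events


def spot_recording(
    model: SegmentationModel,
    audio: AudioBuffer,
    spec_config: SpectrogramConfig | None = None,
    threshold: float = 0.5,
) -> list[BSEvent]:
    """Full spotting path for one channel: 60 Hz high-pass, 10 s segmentation,
    log-Mel, pad to the model input length, infer, event grammar."""
    cfg = spec_config or SpectrogramConfig()
    filtered = highpass_offset_filter(audio)
    specs = [pad_time(logmel(c, cfg), cfg.target_frames) for c in segment_audio(filtered, cfg.clip_s)]
    return infer_events(
        model, specs, threshold=threshold, channel=audio.channel, participant_id=audio.participant_id
    )
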