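"""Spectrogram augmentation for spotter training: time/frequency masking,
additive white noise, and joint time shifts of spectrogram and target mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AugmentationConfig:
    max_freq_mask_bins: int = 24
    max_time_mask_frac: float = 0.10
    white_noise: bool = True
    max_time_shift_bins: int = 10
    # additive-noise amplitude: uniform SNR (dB) relative to the spread of
    # spectrogram values; the magnitude is a free design choice
    noise_snr_db: tuple[float, float] = (20.0, 40.0)

    def validate(self) -> None:
        if self.max_freq_mask_bins < 0 or self.max_time_shift_bins < 0:
            raise ValueError("augmentation bounds must be nonnegative")
        if not (0.0 <= self.max_time_mask_frac <= 1.0):
            raise ValueError("max_time_mask_frac must lie in [0, 1]")


def augment(
    spec: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Augment one (spectrogram [n_mels, T], target mask [T]) pair.

    Frequency masking zeroes up to ``max_freq_mask_bins`` contiguous Mel bins
    and time masking up to ``max_time_mask_frac`` of the frames (input only;
    the target mask is unchanged). A joint roll by up to
    ``max_time_shift_bins`` moves spectrogram and target together, so the
    labels stay aligned with the audio content.
    """
    cfg.validate()
    spec = np.array(spec, copy=True)
    mask = np.array(mask, copy=True)
    n_mels, n_frames = spec.shape

    f_width = int(rng.integers(0, cfg.max_freq_mask_bins + 1))
    if f_width > 0:
        f0 = int(rng.integers(0, n_mels - f_width + 1))
        spec[f0 : f0 + f_width, :] = 0.0

    t_max = int(np.floor(cfg.max_time_mask_frac * n_frames))
    t_width = int(rng.integers(0, t_max + 1)) if t_max > 0 else 0
    if t_width > 0:
        t0 = int(rng.integers(0, n_frames - t_width + 1))
        spec[:, t0 : t0 + t_width] = 0.0

    if cfg.white_noise:
        snr_db = rng.uniform(*cfg.noise_snr_db)
        scale = float(spec.std()) * 10.0 ** (-snr_db / 20.0)
        spec += rng.normal(0.0, scale, size=spec.shape)

    if cfg.max_time_shift_bins > 0:
        shift = int(rng.integers(-cfg.max_time_shift_bins, cfg.max_time_shift_bins + 1))
        if shift != 0:
            spec = np.roll(spec, shift, axis=1)
            mask = np.roll(mask, shift)

    return spec, mask
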