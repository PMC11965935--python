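"""Audio preprocessing: filters, 10 s segmentation, log-Mel spectrograms.

The front-end mirrors a standard audio-tagging pipeline: a 60 Hz biquad
high-pass removes sensor offset, recordings are split into non-overlapping
10 s clips, and each clip becomes a 128-bin log-Mel spectrogram computed with
a 25 ms Hann window and 10 ms hop, zero-padded along time to the model input
size of 1,056 frames. Frames are laid out without centering: frame ``i``
covers samples ``[i*hop, i*hop + win)``, so frame/time conversion is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps


class ConfigurationError(ValueError):
    """Invalid filter band, sampling rate, or spectrogram configuration."""


@dataclass
class AudioBuffer:
    """A sampled mono channel positioned on the recording timeline."""

    samples: np.ndarray
    fs_hz: int
    participant_id: str = ""
    channel: int = 0
    t0_s: float = 0.0
    valid_samples: int | None = None  # set when the tail is zero-padding

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    @property
    def n_valid(self) -> int:
        return len(self.samples) if self.valid_samples is None else self.valid_samples


@dataclass
class SpectrogramConfig:
    fs_hz: int = 16000
    clip_s: float = 10.0
    win_s: float = 0.025
    hop_s: float = 0.010
    n_mels: int = 128
    target_frames: int = 1056
    log_floor: float = 1e-10
    fmin_hz: float = 0.0
    fmax_hz: float | None = None  # defaults to Nyquist

    @property
    def win(self) -> int:
        return int(round(self.win_s * self.fs_hz))

    @property
    def hop(self) -> int:
        return int(round(self.hop_s * self.fs_hz))


@dataclass
class SpectrogramTensor:
    """Log-Mel image [n_mels x n_frames]; frame i covers [t0 + i*hop, +win)."""

    values: np.ndarray
    hop_s: float
    win_s: float
    clip_t0_s: float = 0.0
    valid_frames: int | None = None
    log_floor: float = 1e-10

    @property
    def n_mels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_valid(self) -> int:
        return self.n_frames if self.valid_frames is None else self.valid_frames


def highpass_offset_filter(audio: AudioBuffer, cutoff_hz: float = 60.0) -> AudioBuffer:
    """Remove DC/offset with a second-order (biquad) Butterworth high-pass."""
    if not 0 < cutoff_hz < audio.fs_hz / 2:
        raise ConfigurationError(
            f"high-pass cutoff {cutoff_hz} Hz must lie in (0, fs/2={audio.fs_hz / 2})"
        )
    sos = sps.butter(2, cutoff_hz, btype="highpass", fs=audio.fs_hz, output="sos")
    y = sps.sosfilt(sos, audio.samples)
    return replace(audio, samples=y)


def bandpass_zero_phase(
    audio: AudioBuffer, low_hz: float = 60.0, high_hz: float = 5000.0, order: int = 8
) -> AudioBuffer:
    """Zero-phase (forward-backward) Butterworth band-pass of the given order.

    ``order`` is the analogue filter order of one pass (8 -> 4 pole pairs);
    the forward-backward application squares the magnitude response and
    cancels the phase.
    """
    if not (0 < low_hz < high_hz < audio.fs_hz / 2):
        raise ConfigurationError(
            f"band [{low_hz}, {high_hz}] Hz invalid for fs={audio.fs_hz}"
        )
    if order % 2 != 0 or order < 2:
        raise ConfigurationError("band-pass order must be a positive even integer")
    sos = sps.butter(order // 2, [low_hz, high_hz], btype="bandpass", fs=audio.fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, audio.samples)
    return replace(audio, samples=np.ascontiguousarray(y))


def segment_audio(audio: AudioBuffer, clip_s: float = 10.0) -> list[AudioBuffer]:
    """Split into consecutive non-overlapping clips of ``clip_s`` seconds.

    The trailing remainder is zero-padded to a full clip and flagged via
    ``valid_samples``. The clips partition the input: no sample is lost or
    duplicated.
    """
    if clip_s <= 0:
        raise ConfigurationError("clip_s must be positive")
    n_clip = int(round(clip_s * audio.fs_hz))
    n = len(audio.samples)
    clips: list[AudioBuffer] = []
    for start in range(0, n, n_clip):
        chunk = audio.samples[start : start + n_clip]
        valid = None
        if len(chunk) < n_clip:
            valid = len(chunk)
            chunk = np.pad(chunk, (0, n_clip - len(chunk)))
        clips.append(
            AudioBuffer(
                samples=chunk,
                fs_hz=audio.fs_hz,
                participant_id=audio.participant_id,
                channel=audio.channel,
                t0_s=audio.t0_s + start / audio.fs_hz,
                valid_samples=valid,
            )
        )
    return clips


def hz_to_mel(f_hz):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=np.float64) / 700.0)


def mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=np.float64) / 2595.0) - 1.0)


@lru_cache(maxsize=8)
def mel_filterbank(
    fs_hz: int, n_fft: int, n_mels: int, fmin_hz: float, fmax_hz: float
) -> np.ndarray:
    """Triangular HTK-mel filterbank, unit peak, shape [n_mels, n_fft//2+1]."""
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs_hz)
    mel_pts = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, len(freqs)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_center_freqs(fs_hz: int, n_mels: int, fmin_hz: float, fmax_hz: float) -> np.ndarray:
    mel_pts = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2)
    return mel_to_hz(mel_pts)[1:-1]


def frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Frames [n_frames, win]; frame i starts at sample i*hop (no centering)."""
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    n_frames = 1 + (len(x) - win) // hop
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[:: hop][:n_frames]
    return frames


def power_spectrogram(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """STFT power, FFT size = window length, Hann window. [n_bins, n_frames]."""
    frames = frame_signal(x, win, hop)
    window = sps.get_window("hann", win, fftbins=True)
    spec = np.fft.rfft(frames * window, n=win, axis=1)
    return (spec.real**2 + spec.imag**2).T


def logmel(clip: AudioBuffer, config: SpectrogramConfig | None = None) -> SpectrogramTensor:
    """Log-Mel spectrogram of one clip (natural log of mel power + floor)."""
    cfg = config or SpectrogramConfig()
    if clip.fs_hz != cfg.fs_hz:
        raise ConfigurationError(
            f"clip sampled at {clip.fs_hz} Hz but config expects {cfg.fs_hz} Hz"
        )
    fmax = cfg.fmax_hz if cfg.fmax_hz is not None else cfg.fs_hz / 2
    pxx = power_spectrogram(clip.samples, cfg.win, cfg.hop)
    fb = mel_filterbank(cfg.fs_hz, cfg.win, cfg.n_mels, cfg.fmin_hz, fmax)
    mel_power = fb @ pxx
    values = np.log(mel_power + cfg.log_floor)
    valid = None
    if clip.valid_samples is not None:
        # frames whose start lies inside the un-padded region carry signal
        valid = int(np.ceil(clip.valid_samples / cfg.hop)) if clip.valid_samples > 0 else 0
        valid = min(valid, values.shape[1])
    return SpectrogramTensor(
        values=values,
        hop_s=cfg.hop / cfg.fs_hz,
        win_s=cfg.win / cfg.fs_hz,
        clip_t0_s=clip.t0_s,
        valid_frames=valid,
        log_floor=cfg.log_floor,
    )


def pad_time(spec: SpectrogramTensor, target_frames: int = 1056) -> SpectrogramTensor:
    """Zero-pad (at the log floor) along time to the model input length."""
    n = spec.n_frames
    if n > target_frames:
        raise ConfigurationError(
            f"spectrogram has {n} frames > target {target_frames}; clip too long"
        )
    if n == target_frames and spec.valid_frames is not None:
        return spec
    floor = float(np.log(spec.log_floor))
    padded = np.full((spec.n_mels, target_frames), floor)
    padded[:, :n] = spec.values
    return SpectrogramTensor(
        values=padded,
        hop_s=spec.hop_s,
        win_s=spec.win_s,
        clip_t0_s=spec.clip_t0_s,
        valid_frames=spec.n_valid,
        log_floor=spec.log_floor,
    )
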