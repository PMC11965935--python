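"""Per-event acoustic features, aggregation into classification windows, and
mutual-information feature ranking/selection.

Features are computed on band-pass-filtered audio over 32 ms frames with an
8 ms hop spanning the (padded) event, then averaged across frames. The
registry is 13 MFCCs plus standard spectral descriptors, zero-crossing rate,
RMS energy and event duration. MFCC indexing is 1-based with MFCC_1 = the 0th
cepstral coefficient; the "drop the first two MFCCs" selection therefore
removes the two lowest-quefrency coefficients, whose band is largely removed
by the 60 Hz high-pass anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct
from sklearn.feature_selection import mutual_info_classif

from .preprocess import AudioBuffer, mel_filterbank
from .spotting.events import BSEvent

FEATURE_WIN_S = 0.032
FEATURE_HOP_S = 0.008
N_MFCC = 13
MFCC_N_MELS = 40
ROLLOFF_FRACTION = 0.85

MFCC_NAMES = [f"MFCC_{i}" for i in range(1, N_MFCC + 1)]
FEATURE_NAMES = MFCC_NAMES + [
    "spectral_centroid_hz",
    "spectral_bandwidth_hz",
    "spectral_rolloff_hz",
    "spectral_flatness",
    "zero_crossing_rate",
    "rms_energy",
    "duration_s",
]
#: the feature set used by the published model: MFCC means without the first two
PAPER_FEATURE_NAMES = [f"mean_MFCC_{i}" for i in range(3, N_MFCC + 1)]


@dataclass
class EventFeatureVector:
    event: BSEvent
    features: dict[str, float]

    def __post_init__(self):
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features {bad} for event {self.event}")


@dataclass
class ClassificationWindow:
    """Aggregated (mean, variance) event-feature statistics over one delta-
    length window; only windows containing at least one event exist."""

    participant_id: str
    window_index: int
    delta_s: float
    n_events: int
    stats: dict[str, float]
    label: str


@dataclass
class FeatureSelection:
    scores: dict[str, float]
    selected: list[str] = field(default_factory=list)


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    n = 1 + (len(x) - win) // hop
    return np.lib.stride_tricks.sliding_window_view(x, win)[::hop][:n]


def _frame_features(frames: np.ndarray, fs: int) -> dict[str, np.ndarray]:
    """Per-frame features, vectorised over frames [n_frames, win]."""
    win = frames.shape[1]
    window = np.hanning(win)
    spec = np.fft.rfft(frames * window, axis=1)
    power = spec.real**2 + spec.imag**2  # [n_frames, n_bins]
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    psum = power.sum(axis=1) + 1e-20

    centroid = (power @ freqs) / psum
    bandwidth = np.sqrt((power * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1) / psum)
    cum = np.cumsum(power, axis=1)
    rolloff_idx = np.argmax(cum >= ROLLOFF_FRACTION * cum[:, -1:], axis=1)
    rolloff = freqs[rolloff_idx]
    flatness = np.exp(np.mean(np.log(power + 1e-20), axis=1)) / (np.mean(power, axis=1) + 1e-20)
    zcr = np.mean(np.abs(np.diff(np.signbit(frames), axis=1)), axis=1)
    rms = np.sqrt(np.mean(frames**2, axis=1))

    fb = mel_filterbank(fs, win, MFCC_N_MELS, 0.0, fs / 2)
    logmel = np.log(power @ fb.T + 1e-10)  # [n_frames, n_mels]
    mfcc = dct(logmel, type=2, norm="ortho", axis=1)[:, :N_MFCC]

    out = {name: mfcc[:, i] for i, name in enumerate(MFCC_NAMES)}
    out.update(
        spectral_centroid_hz=centroid,
        spectral_bandwidth_hz=bandwidth,
        spectral_rolloff_hz=rolloff,
        spectral_flatness=flatness,
        zero_crossing_rate=zcr,
        rms_energy=rms,
    )
    return out


def extract_event_features(audio: AudioBuffer, event: BSEvent) -> EventFeatureVector:
    """Features of one event on band-passed audio: 32 ms / 8 ms frames across
    the event, averaged. Events shorter than one frame are padded with the
    surrounding audio signal (symmetrically) to fit the frame length."""
    fs = audio.fs_hz
    win = int(round(FEATURE_WIN_S * fs))
    hop = int(round(FEATURE_HOP_S * fs))
    i0 = int(round((event.start_s - audio.t0_s) * fs))
    i1 = int(round((event.end_s - audio.t0_s) * fs))
    if i1 <= i0:
        raise ValueError("event has nonpositive duration")
    if i0 < 0 or i1 > len(audio.samples):
        raise ValueError(
            f"event [{event.start_s}, {event.end_s}] s lies outside the recording"
        )
    if i1 - i0 < win:  # pad with surrounding audio, symmetrically
        deficit = win - (i1 - i0)
        left = deficit // 2
        i0 = max(0, i0 - left)
        i1 = min(len(audio.samples), i0 + win)
        i0 = max(0, i1 - win)
    x = audio.samples[i0:i1]
    frames = _frame(x, win, hop)
    per_frame = _frame_features(frames, fs)
    feats = {name: float(np.mean(vals)) for name, vals in per_frame.items()}
    feats["duration_s"] = float(event.duration_s)
    return EventFeatureVector(event=event, features=feats)


def build_windows(
    events_with_features: list[EventFeatureVector],
    recording_span_s: float,
    delta_s: float,
    label: str,
    participant_id: str,
) -> list[ClassificationWindow]:
    """Tile [0, span) with delta-length windows, group events by start time,
    and compute per-feature mean and (population) variance. Windows without
    events are omitted — they never become classifier samples."""
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    buckets: dict[int, list[EventFeatureVector]] = {}
    n_windows = int(np.ceil(recording_span_s / delta_s))
    for ev in events_with_features:
        w = int(ev.event.start_s // delta_s)
        if 0 <= w < n_windows:
            buckets.setdefault(w, []).append(ev)
    windows = []
    for w in sorted(buckets):
        members = buckets[w]
        names = list(members[0].features)
        mat = np.array([[m.features[k] for k in names] for m in members])
        stats: dict[str, float] = {}
        for j, name in enumerate(names):
            stats[f"mean_{name}"] = float(mat[:, j].mean())
            stats[f"var_{name}"] = float(mat[:, j].var())  # population variance
        windows.append(
            ClassificationWindow(
                participant_id=participant_id,
                window_index=w,
                delta_s=delta_s,
                n_events=len(members),
                stats=stats,
                label=label,
            )
        )
    return windows


def windows_to_frame(windows: list[ClassificationWindow]) -> pd.DataFrame:
    """Window feature table: one row per classification window."""
    rows = []
    for w in windows:
        rows.append(
            {
                "participant_id": w.participant_id,
                "window_index": w.window_index,
                "delta_s": w.delta_s,
                "n_events": w.n_events,
                "label": w.label,
                **w.stats,
            }
        )
    return pd.DataFrame(rows)


META_COLUMNS = ["participant_id", "window_index", "delta_s", "n_events", "label"]


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


def rank_features_mutual_info(
    windows: pd.DataFrame, seed: int = 0, n_neighbors: int = 3
) -> FeatureSelection:
    """Mutual information of each window-level feature with the binary class
    label (nearest-neighbour estimator for continuous features), ranked
    descending. Requires both classes to be present."""
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    y = (windows["label"] == "IBD").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("mutual information needs both classes present")
    cols = feature_columns(windows)
    X = windows[cols].to_numpy(dtype=float)
    mi = mutual_info_classif(X, y, n_neighbors=n_neighbors, random_state=seed)
    order = np.argsort(-mi, kind="stable")
    scores = {cols[i]: float(mi[i]) for i in order}
    return FeatureSelection(scores=scores, selected=list(scores))


def select_paper_features(selection: FeatureSelection, mode: str = "paper", k: int = 11) -> list[str]:
    """Feature-name selection. Mode "paper" returns the 11 MFCC means
    (MFCC_3..MFCC_13, the first two excluded); "top_k" returns the k
    best-scoring names from the ranking."""
    if mode == "paper":
        missing = [n for n in PAPER_FEATURE_NAMES if n not in selection.scores]
        if missing:
            raise ValueError(f"scored features lack {missing}")
        return list(PAPER_FEATURE_NAMES)
    if mode == "top_k":
        if k > len(selection.scores):
            raise ValueError(f"k={k} exceeds the {len(selection.scores)} scored features")
        return list(selection.scores)[:k]
    raise ValueError(f"unknown selection mode {mode!r}")


@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray
    columns: list[str]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[self.columns] = (df[self.columns].to_numpy(dtype=float) - self.mean) / self.scale
        return out


def standardize(
    train_windows: pd.DataFrame, *other_windows: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, ...]:
    """Fit zero-mean/unit-SD scaling on the training windows only and apply it
    to the training set and any held-out sets. Constant features are centered
    but left unscaled."""
    if len(train_windows) == 0:
        raise ValueError("training windows must be nonempty")
    cols = columns or feature_columns(train_windows)
    X = train_windows[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    tf = Standardizer(mean, scale, cols)
    return tuple(tf.transform(df) for df in (train_windows, *other_windows))
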