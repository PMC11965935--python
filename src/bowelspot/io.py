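"""File I/O: PCM WAV audio, Audacity-style label tracks, cohort manifests.

Annotation tracks use the Audacity label-track dialect: one event per line,
``start<TAB>end<TAB>label`` with times in seconds. This is the exchange format
for both manual annotations and spotted events.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import wavfile


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled time interval on one audio channel."""

    start_s: float
    end_s: float
    label: str = "BS"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class AnnotationParseError(ValueError):
    """Raised when a label-track line cannot be parsed; carries the line number."""

    def __init__(self, line_no: int, line: str, reason: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {reason!s} in {line!r}")


def write_wav(path: str | os.PathLike, samples: np.ndarray, fs_hz: int) -> None:
    """Write a mono float signal as 16-bit PCM WAV, clipping to [-1, 1]."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, int(fs_hz), (x * 32767.0).astype(np.int16))


def read_wav(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read a WAV file, returning (float64 samples scaled to [-1, 1], fs)."""
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483647.0
    else:
        x = data.astype(np.float64)
    return x, int(fs)


def write_annotation_track(
    events: Iterable[EventAnnotation], destination: str | os.PathLike
) -> None:
    """Write events as a tab-separated Audacity label track (sorted by start)."""
    evs = sorted(events, key=lambda e: (e.start_s, e.end_s))
    with open(destination, "w") as fh:
        for e in evs:
            fh.write(f"{e.start_s:.6f}\t{e.end_s:.6f}\t{e.label}\n")


def read_annotation_track(source: str | os.PathLike) -> list[EventAnnotation]:
    """Parse a label track; malformed lines raise :class:`AnnotationParseError`."""
    events: list[EventAnnotation] = []
    with open(source) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AnnotationParseError(i, line, "expected start<TAB>end[<TAB>label]")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise AnnotationParseError(i, line, f"non-numeric time ({exc})") from None
            label = parts[2] if len(parts) >= 3 else "BS"
            events.append(EventAnnotation(start, end, label))
    return events


MANIFEST_COLUMNS = [
    "participant_id",
    "class",
    "activity",
    "fcp",
    "crp",
    "leukocytes",
    "seed",
    # simulator parameters (needed to regenerate audio from a manifest)
    "event_rate_per_min",
    "spectral_shift_hz",
    "noise_level_db",
]


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False, columns=[c for c in MANIFEST_COLUMNS if c in df.columns])


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
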