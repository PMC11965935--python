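"""Frame masks, mask<->event conversion, the event grammar, spotting metrics,
and Cohen's kappa for inter-rater agreement on time-series annotation tracks.

The event grammar follows the annotation protocol: consecutive bowel sounds
separated by less than 100 ms count as one event, and events shorter than
18 ms are discarded. The same grammar is applied to spotted events so that
model output and manual annotations share one definition of "an event".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

MIN_EVENT_DUR_S = 0.018
MERGE_GAP_S = 0.100


@dataclass(frozen=True)
class BSEvent:
    start_s: float
    end_s: float
    channel: int = 0
    participant_id: str = ""
    source: Literal["manual", "spotted"] = "manual"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class FrameMask:
    """Per-frame BS probabilities and their binarisation for one clip."""

    probs: np.ndarray
    clip_t0_s: float
    hop_s: float
    win_s: float
    valid_frames: int | None = None
    threshold: float = 0.5

    @property
    def binary(self) -> np.ndarray:
        b = np.asarray(self.probs) >= self.threshold
        nv = len(self.probs) if self.valid_frames is None else self.valid_frames
        b = b.copy()
        b[nv:] = False  # padded frames are never positive
        return b

    @property
    def n_valid(self) -> int:
        return len(self.probs) if self.valid_frames is None else self.valid_frames


@dataclass(frozen=True)
class SpottingMetrics:
    precision: float | None
    recall: float | None
    level: Literal["frame", "event"]


@dataclass(frozen=True)
class AgreementReport:
    kappa: float
    resolution_s: float
    confusion: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def events_to_mask(
    events: Sequence[BSEvent],
    clip_t0_s: float,
    n_frames: int,
    hop_s: float,
    win_s: float,
    valid_frames: int | None = None,
) -> FrameMask:
    """Binary target mask: frame i positive iff its [t0+i*hop, +win) span
    overlaps any event interval."""
    probs = np.zeros(n_frames)
    starts = clip_t0_s + np.arange(n_frames) * hop_s
    ends = starts + win_s
    for e in events:
        probs[(starts < e.end_s) & (ends > e.start_s)] = 1.0
    mask = FrameMask(probs, clip_t0_s, hop_s, win_s, valid_frames)
    if valid_frames is not None:
        mask.probs[valid_frames:] = 0.0
    return mask


def mask_to_events(mask: FrameMask, channel: int = 0, participant_id: str = "") -> list[BSEvent]:
    """Maximal runs of positive valid frames -> events.

    A run over frames [i, j] maps to the time interval
    [t0 + i*hop, t0 + j*hop + win] (the last frame's window still covers BS).
    """
    b = mask.binary[: mask.n_valid]
    events: list[BSEvent] = []
    if len(b) == 0:
        return events
    diff = np.diff(b.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0])
    if b[0]:
        starts.insert(0, 0)
    if b[-1]:
        ends.append(len(b) - 1)
    for i, j in zip(starts, ends):
        events.append(
            BSEvent(
                start_s=mask.clip_t0_s + i * mask.hop_s,
                end_s=mask.clip_t0_s + j * mask.hop_s + mask.win_s,
                channel=channel,
                participant_id=participant_id,
                source="spotted",
            )
        )
    return events


def merge_touching(events: Sequence[BSEvent]) -> list[BSEvent]:
    """Merge overlapping/abutting events (used across 10 s clip boundaries)."""
    evs = sorted(events, key=lambda e: (e.channel, e.start_s, e.end_s))
    out: list[BSEvent] = []
    for e in evs:
        if out and out[-1].channel == e.channel and e.start_s <= out[-1].end_s + 1e-9:
            prev = out.pop()
            out.append(
                BSEvent(prev.start_s, max(prev.end_s, e.end_s), e.channel, e.participant_id, e.source)
            )
        else:
            out.append(e)
    return out


def postprocess_events(
    events: Sequence[BSEvent],
    min_dur_s: float = MIN_EVENT_DUR_S,
    merge_gap_s: float = MERGE_GAP_S,
) -> list[BSEvent]:
    """Apply the annotation grammar: first merge chains with inter-event gap
    < ``merge_gap_s`` (overlaps count as gap <= 0), then drop events shorter
    than ``min_dur_s``. Idempotent and insensitive to input order."""
    by_channel: dict[int, list[BSEvent]] = {}
    for e in events:
        by_channel.setdefault(e.channel, []).append(e)
    out: list[BSEvent] = []
    for ch, evs in sorted(by_channel.items()):
        evs = sorted(evs, key=lambda e: (e.start_s, e.end_s))
        merged: list[BSEvent] = []
        for e in evs:
            if merged and e.start_s - merged[-1].end_s < merge_gap_s:
                prev = merged.pop()
                merged.append(
                    BSEvent(
                        prev.start_s,
                        max(prev.end_s, e.end_s),
                        ch,
                        e.participant_id or prev.participant_id,
                        e.source,
                    )
                )
            else:
                merged.append(e)
        out.extend(e for e in merged if e.duration_s >= min_dur_s)
    return out


def evaluate_spotting(
    pred, truth, level: Literal["frame", "event"] = "event"
) -> SpottingMetrics:
    """Precision/recall of spotted output against ground truth.

    Frame level: binary per-frame comparison of two :class:`FrameMask` of the
    same length. Event level: a predicted event is a true positive iff it
    temporally overlaps a ground-truth event; matching is one-to-one, greedy
    by start time. Undefined ratios (zero denominator) are reported as None.
    """
    if level == "frame":
        p = np.asarray(pred.binary if isinstance(pred, FrameMask) else pred, dtype=bool)
        t = np.asarray(truth.binary if isinstance(truth, FrameMask) else truth, dtype=bool)
        if p.shape != t.shape:
            raise ValueError("frame masks must share one timeline")
        tp = int(np.sum(p & t))
        precision = tp / int(np.sum(p)) if np.sum(p) > 0 else None
        recall = tp / int(np.sum(t)) if np.sum(t) > 0 else None
        return SpottingMetrics(precision, recall, "frame")
    pred_evs = sorted(pred, key=lambda e: (e.channel, e.start_s))
    truth_evs = sorted(truth, key=lambda e: (e.channel, e.start_s))
    matched_truth: set[int] = set()
    tp = 0
    for pe in pred_evs:
        for ti, te in enumerate(truth_evs):
            if ti in matched_truth or te.channel != pe.channel:
                continue
            if pe.start_s < te.end_s and pe.end_s > te.start_s:
                matched_truth.add(ti)
                tp += 1
                break
    precision = tp / len(pred_evs) if pred_evs else None
    recall = tp / len(truth_evs) if truth_evs else None
    return SpottingMetrics(precision, recall, "event")


def _discretise(events, span_s: float, resolution_s: float) -> np.ndarray:
    n = int(math.ceil(span_s / resolution_s))
    grid = np.zeros(n, dtype=bool)
    for e in events:
        i0 = int(np.floor(e.start_s / resolution_s))
        i1 = int(np.ceil(e.end_s / resolution_s))
        grid[max(i0, 0) : min(i1, n)] = True
    return grid


def cohens_kappa(
    track_a,
    track_b,
    resolution_s: float = 1.0 / 16000.0,
    span_s: float | None = None,
) -> AgreementReport:
    """Chance-corrected agreement between two annotation tracks.

    Both tracks are discretised into binary occupancy sequences at
    ``resolution_s`` over a common span, and kappa = (po - pe) / (1 - pe)
    is computed from the resulting 2x2 confusion. When pe = 1 (both tracks
    constant and identical) kappa is undefined and reported as degenerate.
    """
    if resolution_s <= 0:
        raise ValueError("resolution_s must be positive")
    if span_s is None:
        span_s = max(
            [e.end_s for e in track_a] + [e.end_s for e in track_b] + [resolution_s]
        )
    a = _discretise(track_a, span_s, resolution_s)
    b = _discretise(track_b, span_s, resolution_s)
    n = len(a)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    confusion = ((n11, n10), (n01, n00))
    return kappa_from_confusion(confusion, resolution_s)


def kappa_from_confusion(
    confusion: tuple[tuple[int, int], tuple[int, int]], resolution_s: float = 1.0
) -> AgreementReport:
    (n11, n10), (n01, n00) = confusion
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = (n11 + n00) / n
    pa1 = (n11 + n10) / n
    pb1 = (n11 + n01) / n
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if abs(1 - pe) < 1e-15:
        return AgreementReport(float("nan"), resolution_s, confusion, degenerate=True)
    return AgreementReport((po - pe) / (1 - pe), resolution_s, confusion)
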