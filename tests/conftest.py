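"""Shared fixtures. The expensive ones (trained spotter, synthetic cohorts)
are session-scoped and reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import bowelspot as bs
from bowelspot.cohort import BiomarkerPanel, ParticipantProfile
from bowelspot.preprocess import SpectrogramConfig, highpass_offset_filter, logmel, pad_time, segment_audio
from bowelspot.spotting import (
    AugmentationConfig,
    BSEvent,
    TrainingConfig,
    events_to_mask,
    postprocess_events,
    train_spotter,
)

# Study conditions for the desk-scale fixtures (fixed, not tuned per test):
# 10 participants per class, 30 min recordings, one channel, a 2-SD class
# effect for the separated cohort, and a 3e-3 initial learning rate for
# training the tiny encoder from scratch (chosen by pilot run; see
# docs/methods.md).
SEP_SEED = 42
NULL_SEED = 43
SPOT_SEED = 11
N_PER_CLASS = 10
RECORDING_S = 1800.0
DELTA_S = 600.0
CLASS_EFFECT = 2.0
SCRATCH_LR = 3e-3


def _spotting_clips(duration_s: float, seed: int, event_rate_per_min: float = 6.0):
    """High-SNR single-channel clips with ground-truth frame masks."""
    cfg = bs.CohortConfig(
        n_ibd=1, n_healthy=0, n_channels=1, recording_duration_s=duration_s,
        artefact_rate_per_min=0.5, seed=seed,
    )
    profile = ParticipantProfile(
        participant_id="SPOT01", cohort_class="IBD", disease_activity="active",
        biomarkers=BiomarkerPanel(300.0, 5.0, 8.0),
        event_rate_per_min=event_rate_per_min, spectral_shift_hz=0.0,
        noise_level_db=-40.0, seed=seed,
    )
    buffers, events = bs.synthesize_recording(profile, cfg)
    audio = highpass_offset_filter(buffers[0])
    truth = [BSEvent(e.start_s, e.end_s, 0) for e in events if e.template == "bs_burst"]
    sc = SpectrogramConfig()
    specs, masks = [], []
    for clip in segment_audio(audio, sc.clip_s):
        sp = pad_time(logmel(clip, sc), sc.target_frames)
        specs.append(sp)
        masks.append(
            events_to_mask(truth, sp.clip_t0_s, sp.n_frames, sp.hop_s, sp.win_s, sp.valid_frames)
        )
    return specs, masks, postprocess_events(truth)


@pytest.fixture(scope="session")
def spotting_fixture():
    """Tiny spotter trained for 25 epochs on ~50 high-SNR clips, plus a
    held-out recording for event-level evaluation."""
    tr_specs, tr_masks, _ = _spotting_clips(500.0, SPOT_SEED)
    te_specs, _, te_truth = _spotting_clips(200.0, SPOT_SEED + 88)
    model = train_spotter(
        tr_specs, tr_masks, TrainingConfig(lr0=SCRATCH_LR, seed=0), aug_cfg=AugmentationConfig()
    )
    return {
        "model": model,
        "train_specs": tr_specs,
        "train_masks": tr_masks,
        "test_specs": te_specs,
        "test_truth": te_truth,
    }


def _cohort_with_features(class_effect: float, seed: int, with_noise: bool):
    cfg = bs.CohortConfig(
        n_ibd=N_PER_CLASS, n_healthy=N_PER_CLASS, n_channels=1,
        recording_duration_s=RECORDING_S, class_effect=class_effect, seed=seed,
    )
    manifest = bs.generate_cohort(cfg)
    per_participant = {}
    noise_windows = []
    for prof in manifest.profiles:
        buffers, events = bs.synthesize_recording(prof, cfg)
        buf = bs.bandpass_zero_phase(buffers[0])
        bsev = [
            BSEvent(e.start_s, e.end_s, 0, prof.participant_id)
            for e in events
            if e.template == "bs_burst"
        ]
        feats = [bs.extract_event_features(buf, e) for e in bsev]
        per_participant[prof.participant_id] = (feats, RECORDING_S, prof.cohort_class)
        if with_noise:
            exclude = [BSEvent(e.start_s, e.end_s, 0) for e in events]
            pseudo = bs.sample_noise_events(RECORDING_S, exclude, 90, 0.5, seed=prof.seed)
            nfeats = [bs.extract_event_features(buf, e) for e in pseudo]
            noise_windows.extend(
                bs.build_windows(nfeats, RECORDING_S, DELTA_S, prof.cohort_class, prof.participant_id)
            )
    windows = []
    for pid, (feats, span, label) in per_participant.items():
        windows.extend(bs.build_windows(feats, span, DELTA_S, label, pid))
    out = {
        "manifest": manifest,
        "config": cfg,
        "events": per_participant,
        "windows_df": bs.windows_to_frame(windows),
    }
    if with_noise:
        out["noise_df"] = bs.windows_to_frame(noise_windows)
    return out


@pytest.fixture(scope="session")
def separated_cohort():
    """Cohort with a planted class effect (2 participant-SDs on burst center
    frequency and event rate), plus class-independent noise pseudo-windows."""
    return _cohort_with_features(CLASS_EFFECT, SEP_SEED, with_noise=True)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with class_effect = 0: classes statistically identical."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _cohort_with_features(0.0, NULL_SEED, with_noise=False)


@pytest.fixture(scope="session")
def separated_cv(separated_cohort):
    """One CV run on the separated cohort, shared by several tests."""
    df = separated_cohort["windows_df"]
    folds = bs.make_folds(df, k=5, seed=0)
    cv = bs.evaluate_cv(df, folds, bs.GBCConfig.preset("full_dataset"), seed=0)
    return {"folds": folds, "cv": cv}
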