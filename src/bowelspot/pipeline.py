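"""End-to-end orchestration: simulate -> (spot) -> features -> classify.

A :class:`RunConfig` fixes every stage's parameters and one master seed;
rerunning with the same config reproduces the report. Artifacts are written
under ``output_dir``: annotation tracks (TSV), the cohort manifest (CSV), the
window feature table (CSV), and a JSON report with a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bsio
from .classifier import (
    GBCConfig,
    correlate_biomarkers,
    evaluate_cv,
    majority_vote,
    make_folds,
    participant_metrics,
)
from .cohort import CohortConfig, CohortManifest, events_to_annotations, generate_cohort, synthesize_recording
from .features import extract_event_features, build_windows, windows_to_frame
from .preprocess import SpectrogramConfig, bandpass_zero_phase, highpass_offset_filter, logmel, pad_time, segment_audio
from .spotting import (
    BSEvent,
    TrainingConfig,
    events_to_mask,
    spot_recording,
    train_spotter,
)


@dataclass
class RunConfig:
    output_dir: str = "bowelspot_run"
    master_seed: int = 0
    annotation_source: str = "ground_truth"  # ground_truth | spotted | external_tsv
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    delta_s: float = 600.0
    k_folds: int = 5
    gbc_preset: str = "full_dataset"
    feature_mode: str = "per_fold_mi"
    n_features: int = 11
    persist_audio: bool = False
    external_annotation_dir: str | None = None
    run_classification: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("cohort", CohortConfig), ("spectrogram", SpectrogramConfig), ("training", TrainingConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations as human-readable problems; [] iff valid."""
    problems: list[str] = []
    try:
        config.cohort.validate()
    except ValueError as exc:
        problems.append(f"cohort: {exc}")
    if config.cohort.n_ibd + config.cohort.n_healthy < 2 and config.run_classification:
        problems.append("cohort: n_ibd + n_healthy must be >= 2 for classification use")
    if config.delta_s <= 0:
        problems.append("delta_s: classification window duration must be positive")
    n_participants = config.cohort.n_ibd + config.cohort.n_healthy
    if config.k_folds > n_participants:
        problems.append(
            f"k_folds: k={config.k_folds} exceeds the {n_participants} participants"
        )
    if config.annotation_source not in ("ground_truth", "spotted", "external_tsv"):
        problems.append(f"annotation_source: unknown value {config.annotation_source!r}")
    if config.annotation_source == "external_tsv":
        if not config.external_annotation_dir:
            problems.append("external_annotation_dir: required when annotation_source=external_tsv")
        elif not Path(config.external_annotation_dir).is_dir():
            problems.append(
                f"external_annotation_dir: {config.external_annotation_dir!r} does not exist"
            )
    try:
        config.training.validate()
    except ValueError as exc:
        problems.append(f"training: {exc}")
    if config.gbc_preset not in ("annotated_subset", "full_dataset"):
        problems.append(f"gbc_preset: unknown preset {config.gbc_preset!r}")
    return problems


def _train_cohort_spotter(manifest: CohortManifest, config: RunConfig):
    """Train the spotter on ground-truth-masked clips from the cohort
    (channel 0 of each participant), mirroring an annotated-subset setup."""
    spec_cfg = config.spectrogram
    clips_X, masks = [], []
    for profile in manifest.profiles:
        buffers, events = synthesize_recording(profile, manifest.config)
        audio = highpass_offset_filter(buffers[0])
        bs = [
            BSEvent(e.start_s, e.end_s, 0, profile.participant_id)
            for e in events
            if e.channel == 0 and e.template == "bs_burst"
        ]
        for clip in segment_audio(audio, spec_cfg.clip_s):
            spec = pad_time(logmel(clip, spec_cfg), spec_cfg.target_frames)
            clips_X.append(spec)
            masks.append(
                events_to_mask(
                    bs, spec.clip_t0_s, spec.n_frames, spec.hop_s, spec.win_s, spec.valid_frames
                )
            )
    return train_spotter(clips_X, masks, config.training)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    The report is a plain JSON-serialisable dict: config hash, seed, event
    counts, CV metrics, participant votes and biomarker correlations. Rerun
    with the same config reproduces it exactly.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.master_seed)
    manifest = generate_cohort(cohort_cfg)
    manifest_df = manifest.to_dataframe()
    bsio.write_manifest(manifest_df, out / "manifest.csv")

    spotter = None
    if config.annotation_source == "spotted":
        spotter = _train_cohort_spotter(manifest, config)

    all_windows = []
    event_counts: dict[str, dict[str, int]] = {}
    for profile in manifest.profiles:
        buffers, events = synthesize_recording(profile, cohort_cfg)
        truth_bs = [e for e in events if e.template == "bs_burst"]
        participant_events: list[BSEvent] = []
        participant_feats = []
        for ch, buf in enumerate(buffers):
            if config.persist_audio:
                bsio.write_wav(out / f"{profile.participant_id}_ch{ch}.wav", buf.samples, buf.fs_hz)
            truth_ann = events_to_annotations(events, channel=ch)
            bsio.write_annotation_track(
                truth_ann, out / f"{profile.participant_id}_ch{ch}_truth.txt"
            )
            if config.annotation_source == "ground_truth":
                ch_events = [
                    BSEvent(e.start_s, e.end_s, ch, profile.participant_id, "manual")
                    for e in truth_bs
                    if e.channel == ch
                ]
            elif config.annotation_source == "spotted":
                ch_events = spot_recording(spotter, buf, config.spectrogram)
                bsio.write_annotation_track(
                    [bsio.EventAnnotation(e.start_s, e.end_s, "BS") for e in ch_events],
                    out / f"{profile.participant_id}_ch{ch}_spotted.txt",
                )
            else:  # external_tsv
                track = Path(config.external_annotation_dir) / f"{profile.participant_id}_ch{ch}.txt"
                if not track.is_file():
                    raise FileNotFoundError(
                        f"annotation_source=external_tsv but {track} is missing "
                        "(stage 'simulate annotations' is disabled)"
                    )
                ch_events = [
                    BSEvent(a.start_s, a.end_s, ch, profile.participant_id, "manual")
                    for a in bsio.read_annotation_track(track)
                    if a.label != "tentative"
                ]
            filtered = bandpass_zero_phase(buf)
            feats = []
            for e in ch_events:
                try:
                    feats.append(extract_event_features(filtered, e))
                except ValueError:
                    warnings.warn(
                        f"skipping out-of-bounds event {e} on {profile.participant_id}",
                        stacklevel=2,
                    )
            participant_events.extend([f.event for f in feats])
            participant_feats.extend(feats)
        event_counts[profile.participant_id] = {
            "ground_truth_bs": len(truth_bs),
            "analysed_events": len(participant_events),
        }
        all_windows.extend(
            build_windows(
                participant_feats,
                cohort_cfg.recording_duration_s,
                config.delta_s,
                profile.cohort_class,
                profile.participant_id,
            )
        )

    windows_df = windows_to_frame(all_windows)
    windows_df.to_csv(out / "windows.csv", index=False)

    report: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "annotation_source": config.annotation_source,
        "n_participants": len(manifest),
        "n_windows": int(len(windows_df)),
        "event_counts": event_counts,
    }
    if spotter is not None:
        report["spotter"] = {
            "n_parameters": spotter.n_parameters,
            "final_epoch_loss": spotter.history["epoch_loss"][-1],
        }
    if config.run_classification and len(windows_df) > 0:
        folds = make_folds(windows_df, k=config.k_folds, seed=config.master_seed)
        cv = evaluate_cv(
            windows_df,
            folds,
            GBCConfig.preset(config.gbc_preset),
            seed=config.master_seed,
            feature_mode=config.feature_mode,
            n_features=config.n_features,
        )
        votes = majority_vote(cv.window_probs)
        truth = dict(zip(manifest_df["participant_id"], manifest_df["class"]))
        acc, sens, spec = participant_metrics(votes, truth)
        report["cv"] = {
            "per_fold": cv.per_fold,
            "mean_auroc": cv.mean_auroc,
            "sd_auroc": cv.sd_auroc,
            "mean_sensitivity": cv.mean_sensitivity,
            "mean_specificity": cv.mean_specificity,
        }
        report["participants"] = {
            "votes": [asdict(v) for v in votes],
            "accuracy": acc,
            "sensitivity": sens,
            "specificity": spec,
        }
        scores = {v.participant_id: v.mean_ibd_prob for v in votes}
        n_patients_scored = sum(1 for p in manifest.profiles if p.cohort_class == "IBD" and p.participant_id in scores)
        if n_patients_scored >= 3:
            corr = correlate_biomarkers(scores, manifest_df)
            report["biomarker_spearman_r"] = corr.spearman_r
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
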