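"""Per-event features, classification windows, MI ranking and standardisation."""

import numpy as np
import pandas as pd
import pytest

import bowelspot as bs
from bowelspot.features import (
    FEATURE_NAMES,
    PAPER_FEATURE_NAMES,
    FeatureSelection,
    feature_columns,
)
from bowelspot.preprocess import AudioBuffer
from bowelspot.spotting import BSEvent

FS = 16000


def tone_buffer(freq=500.0, dur=2.0, amp=0.5):
    t = np.arange(int(dur * FS)) / FS
    return AudioBuffer(amp * np.sin(2 * np.pi * freq * t), FS)


class TestExtractEventFeatures:
    def test_centroid_of_pure_tone(self):
        fv = bs.extract_event_features(tone_buffer(500.0), BSEvent(0.5, 1.0))
        # well within one Mel-filter width (~80 Hz at 500 Hz) of the tone
        assert abs(fv.features["spectral_centroid_hz"] - 500.0) < 80.0

    def test_amplitude_scaling_behaviour(self):
        ev = BSEvent(0.5, 1.0)
        f1 = bs.extract_event_features(tone_buffer(amp=0.25), ev)
        f2 = bs.extract_event_features(tone_buffer(amp=0.5), ev)
        assert f2.features["zero_crossing_rate"] == pytest.approx(
            f1.features["zero_crossing_rate"]
        )
        assert f2.features["rms_energy"] == pytest.approx(2 * f1.features["rms_energy"], rel=1e-9)

    def test_short_event_padded_to_single_frame(self):
        buf = tone_buffer(dur=1.0)
        fv = bs.extract_event_features(buf, BSEvent(0.500, 0.510))  # 10 ms
        assert fv.features["duration_s"] == pytest.approx(0.010)
        # a 10 ms event padded to 32 ms yields exactly one frame, so features
        # must match a direct 32 ms-window computation around the event
        assert np.isfinite(list(fv.features.values())).all()

    def test_out_of_bounds_event_rejected(self):
        with pytest.raises(ValueError):
            bs.extract_event_features(tone_buffer(dur=1.0), BSEvent(0.9, 1.5))

    def test_translation_equivariance(self):
        """Shifting audio and event together leaves features unchanged."""
        rng = np.random.default_rng(0)
        burst = rng.standard_normal(int(0.2 * FS)) * 0.3
        shift_samples = int(0.4 * FS)  # multiple of the 8 ms hop
        x1 = np.zeros(2 * FS)
        x1[FS // 2 : FS // 2 + len(burst)] = burst
        x2 = np.roll(x1, shift_samples)
        f1 = bs.extract_event_features(AudioBuffer(x1, FS), BSEvent(0.5, 0.7))
        f2 = bs.extract_event_features(AudioBuffer(x2, FS), BSEvent(0.9, 1.1))
        for name in FEATURE_NAMES:
            if name == "duration_s":
                continue
            assert f1.features[name] == pytest.approx(f2.features[name], rel=1e-6, abs=1e-9)


def _fake_event_features(values_by_event, delta_starts):
    """Feature vectors with controlled values at given start times."""
    out = []
    for t0, val in zip(delta_starts, values_by_event):
        feats = {name: float(val) for name in FEATURE_NAMES}
        feats["duration_s"] = 0.1
        out.append(
            bs.EventFeatureVector(event=BSEvent(t0, t0 + 0.1), features=feats)
        )
    return out


class TestBuildWindows:
    def test_every_window_occupied(self):
        evs = _fake_event_features(np.arange(6.0), np.arange(6) * 600.0 + 10.0)
        wins = bs.build_windows(evs, 3600.0, 600.0, "IBD", "P1")
        assert [w.window_index for w in wins] == list(range(6))
        assert all(w.n_events == 1 for w in wins)

    def test_empty_windows_omitted(self):
        evs = _fake_event_features([1.0, 2.0], [10.0, 1210.0])  # windows 0 and 2
        wins = bs.build_windows(evs, 1800.0, 600.0, "IBD", "P1")
        assert [w.window_index for w in wins] == [0, 2]

    def test_single_event_window_zero_variance(self):
        evs = _fake_event_features([3.0], [10.0])
        wins = bs.build_windows(evs, 600.0, 600.0, "healthy", "P1")
        assert all(v == 0.0 for k, v in wins[0].stats.items() if k.startswith("var_"))

    def test_mean_and_population_variance(self):
        evs = _fake_event_features([1.0, 3.0], [10.0, 20.0])
        wins = bs.build_windows(evs, 600.0, 600.0, "IBD", "P1")
        assert wins[0].stats["mean_MFCC_1"] == pytest.approx(2.0)
        assert wins[0].stats["var_MFCC_1"] == pytest.approx(1.0)  # population var

    def test_events_partition_into_windows(self):
        starts = np.random.default_rng(3).uniform(0, 1800, size=40)
        evs = _fake_event_features(np.ones(40), starts)
        wins = bs.build_windows(evs, 1800.0, 600.0, "IBD", "P1")
        assert sum(w.n_events for w in wins) == 40
        assert len(wins) <= int(np.ceil(1800.0 / 600.0))


def _window_table(rng, n_per_class=30, shift_sd=0.0):
    """Window-level table with one planted informative feature."""
    rows = []
    for label, mu in (("healthy", 0.0), ("IBD", shift_sd)):
        for i in range(n_per_class):
            rows.append(
                {
                    "participant_id": f"{label[:1]}{i:02d}",
                    "window_index": 0,
                    "delta_s": 600.0,
                    "n_events": 3,
                    "label": label,
                    "mean_MFCC_3": rng.normal(mu, 1.0),
                    "mean_MFCC_4": rng.normal(0.0, 1.0),  # pure noise
                }
            )
    return pd.DataFrame(rows)


class TestMutualInformation:
    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(0)
        df = _window_table(rng, shift_sd=2.0)
        df["mean_MFCC_4"] = 1.234
        sel = bs.rank_features_mutual_info(df, seed=0)
        # within the kNN estimator's noise floor of zero
        assert sel.scores["mean_MFCC_4"] == pytest.approx(0.0, abs=0.05)

    def test_label_copy_feature_scores_near_entropy(self):
        rng = np.random.default_rng(1)
        df = _window_table(rng, shift_sd=0.0)
        df["mean_MFCC_3"] = (df["label"] == "IBD").astype(float) + rng.normal(
            0, 1e-4, len(df)
        )
        sel = bs.rank_features_mutual_info(df, seed=0)
        assert sel.scores["mean_MFCC_3"] == pytest.approx(np.log(2.0), abs=0.15)

    def test_planted_shift_outranks_noise(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = _window_table(rng, shift_sd=2.0)
            sel = bs.rank_features_mutual_info(df, seed=seed)
            wins += sel.scores["mean_MFCC_3"] > sel.scores["mean_MFCC_4"]
        assert wins >= 95

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(5)
        df = _window_table(rng, shift_sd=2.0)
        s1 = bs.rank_features_mutual_info(df, seed=0).scores["mean_MFCC_3"]
        df2 = df.copy()
        df2["mean_MFCC_3"] = np.exp(df2["mean_MFCC_3"] / 2.0)
        s2 = bs.rank_features_mutual_info(df2, seed=0).scores["mean_MFCC_3"]
        assert s1 == pytest.approx(s2, abs=0.1)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        df = _window_table(rng)
        with pytest.raises(ValueError):
            bs.rank_features_mutual_info(df[df["label"] == "IBD"], seed=0)


class TestSelection:
    def scores_all(self):
        return FeatureSelection(
            scores={f"mean_{n}": 1.0 for n in FEATURE_NAMES}
            | {f"var_{n}": 0.5 for n in FEATURE_NAMES}
        )

    def test_paper_mode_excludes_first_two_mfccs(self):
        names = bs.select_paper_features(self.scores_all(), "paper")
        assert len(names) == 11
        assert names == PAPER_FEATURE_NAMES
        assert "mean_MFCC_1" not in names and "mean_MFCC_2" not in names

    def test_top_k_all_and_best(self):
        sel = self.scores_all()
        assert bs.select_paper_features(sel, "top_k", k=len(sel.scores)) == list(sel.scores)
        rng = np.random.default_rng(2)
        df = _window_table(rng, shift_sd=2.0)
        ranking = bs.rank_features_mutual_info(df, seed=0)
        assert bs.select_paper_features(ranking, "top_k", k=1) == ["mean_MFCC_3"]

    def test_missing_names_rejected(self):
        with pytest.raises(ValueError):
            bs.select_paper_features(FeatureSelection(scores={"mean_MFCC_3": 1.0}), "paper")


class TestStandardize:
    def test_train_becomes_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = _window_table(rng, shift_sd=1.0)
        (out,) = bs.standardize(df)
        cols = feature_columns(df)
        assert np.all(np.abs(out[cols].mean()) < 1e-9)
        assert np.all(np.abs(out[cols].std(ddof=0) - 1) < 1e-9)

    def test_heldout_at_train_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        df = _window_table(rng, shift_sd=1.0)
        cols = feature_columns(df)
        held = df.head(1).copy()
        held[cols] = df[cols].mean().to_numpy()
        _, out = bs.standardize(df, held)
        assert np.all(np.abs(out[cols].to_numpy()) < 1e-9)

    def test_refit_on_transformed_is_identity(self):
        rng = np.random.default_rng(2)
        df = _window_table(rng, shift_sd=1.0)
        (once,) = bs.standardize(df)
        (twice,) = bs.standardize(once)
        cols = feature_columns(df)
        assert np.allclose(once[cols].to_numpy(), twice[cols].to_numpy())
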