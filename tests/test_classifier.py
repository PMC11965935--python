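"""Folds, SMOTE, gradient boosting, CV metrics, voting and correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest

import bowelspot as bs
from bowelspot.classifier import POSITIVE_CLASS, ParticipantPrediction
from bowelspot.features import FEATURE_NAMES


def window_table(n_patients, n_healthy, windows_each=4, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for klass, n, mu in (("IBD", n_patients, shift), ("healthy", n_healthy, 0.0)):
        for i in range(n):
            pid = f"{klass[:1]}{i:02d}"
            centre = rng.normal(mu, 0.5)
            for w in range(windows_each):
                row = {
                    "participant_id": pid,
                    "window_index": w,
                    "delta_s": 600.0,
                    "n_events": 3,
                    "label": klass,
                }
                for name in FEATURE_NAMES[:6]:
                    row[f"mean_{name}"] = rng.normal(centre, 0.5)
                rows.append(row)
    return pd.DataFrame(rows)


class TestMakeFolds:
    def test_group_integrity(self):
        df = window_table(6, 8, seed=1)
        folds = bs.make_folds(df, k=4, seed=0)
        folds.validate_group_integrity()
        for pid in df["participant_id"].unique():
            assigned = np.unique(folds.fold_of_window[folds.groups == pid])
            assert len(assigned) == 1

    def test_nine_patients_one_per_fold(self):
        """With k = number of patients each validation fold holds windows of
        exactly one patient (the annotated-subset CV layout)."""
        df = window_table(9, 18, seed=2)
        folds = bs.make_folds(df, k=9, seed=0)
        labels = df["label"].to_numpy()
        pids = df["participant_id"].to_numpy()
        for f in range(9):
            val_pids = set(pids[(folds.fold_of_window == f) & (labels == "IBD")])
            assert len(val_pids) == 1

    def test_leave_one_participant_out_limit(self):
        df = window_table(2, 3, seed=3)
        folds = bs.make_folds(df, k=5, seed=0)
        for f in range(5):
            assert len(set(folds.groups[folds.fold_of_window == f])) == 1

    def test_k_exceeding_participants_rejected(self):
        df = window_table(2, 2)
        with pytest.raises(ValueError):
            bs.make_folds(df, k=5, seed=0)


class TestSmote:
    def test_balances_counts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(90, 5))
        y = np.r_[np.ones(30), np.zeros(60)].astype(int)
        X2, y2 = bs.oversample_smote(X, y, seed=0)
        assert (y2 == 1).sum() == (y2 == 0).sum() == 60
        assert np.array_equal(X2[:90], X)  # originals preserved

    def test_already_balanced_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        X2, y2 = bs.oversample_smote(X, y, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_synthetic_samples_inside_minority_box(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.uniform(5, 6, size=(8, 4)), rng.uniform(-1, 1, size=(40, 4))])
        y = np.r_[np.ones(8), np.zeros(40)].astype(int)
        X2, y2 = bs.oversample_smote(X, y, seed=0)
        synth = X2[48:]
        lo, hi = X[:8].min(axis=0), X[:8].max(axis=0)
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_single_minority_sample_duplicates_with_warning(self):
        X = np.vstack([[[5.0, 5.0]], np.zeros((4, 2))])
        y = np.array([1, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="duplication"):
            X2, y2 = bs.oversample_smote(X, y, seed=0)
        assert (y2 == 1).sum() == 4


class TestGBC:
    def test_presets(self):
        a = bs.GBCConfig.preset("annotated_subset")
        assert (a.n_estimators, a.learning_rate) == (50, 1e-4)
        b = bs.GBCConfig.preset("full_dataset")
        assert (b.n_estimators, b.learning_rate) == (100, 0.001)
        assert a.loss == "exponential" and a.split_criterion == "friedman_mse"

    def test_separable_blobs_high_training_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(2, 1, (100, 3))])
        y = np.r_[np.zeros(100), np.ones(100)].astype(int)
        model = bs.train_gbc(X, y, bs.GBCConfig.preset("full_dataset"), seed=0)
        probs = model.predict_proba(X)[:, 1]
        assert roc_auc_score(y, probs) >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bs.train_gbc(np.zeros((10, 2)), np.zeros(10), seed=0)


def brute_force_auroc(y, scores):
    """Pairwise concordance probability (ties count half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluateCV:
    def test_separable_cohort_perfect_folds(self):
        df = window_table(6, 6, shift=5.0, seed=4)
        folds = bs.make_folds(df, k=4, seed=0)
        cv = bs.evaluate_cv(df, folds, bs.GBCConfig.preset("full_dataset"), seed=0, feature_mode="all")
        for fold in cv.per_fold:
            assert fold["auroc"] == 1.0
            assert fold["sensitivity"] == 1.0 and fold["specificity"] == 1.0

    def test_summary_equals_recomputation(self):
        df = window_table(5, 7, shift=1.0, seed=5)
        folds = bs.make_folds(df, k=3, seed=0)
        cv = bs.evaluate_cv(df, folds, seed=0, feature_mode="all")
        aurocs = [f["auroc"] for f in cv.per_fold if f["auroc"] is not None]
        assert cv.mean_auroc == pytest.approx(np.mean(aurocs))
        assert cv.sd_auroc == pytest.approx(np.std(aurocs))

    def test_auroc_matches_pairwise_concordance(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        y = (rng.random(120) < 0.4).astype(int)
        scores = rng.random(120)
        scores[y == 1] += 0.2
        assert roc_auc_score(y, scores) == pytest.approx(brute_force_auroc(y, scores))

    def test_probabilities_cover_all_validation_windows(self):
        df = window_table(4, 5, shift=2.0, seed=7)
        folds = bs.make_folds(df, k=3, seed=0)
        cv = bs.evaluate_cv(df, folds, seed=0, feature_mode="all")
        assert len(cv.window_probs) == len(df)


class TestMajorityVote:
    def probs(self, pid, calls):
        return {(pid, i): (0.9 if c else 0.1) for i, c in enumerate(calls)}

    def test_clear_majority(self):
        votes = bs.majority_vote(self.probs("P1", [1] * 6 + [0] * 4))
        assert votes[0].voted_label == POSITIVE_CLASS

    def test_exact_half_ties_to_ibd(self):
        votes = bs.majority_vote(self.probs("P1", [1] * 5 + [0] * 5))
        assert votes[0].fraction_windows_ibd == pytest.approx(0.5)
        assert votes[0].voted_label == POSITIVE_CLASS  # 'at least 50%'

    def test_no_positive_windows(self):
        votes = bs.majority_vote(self.probs("P1", [0, 0, 0, 0]))
        assert votes[0].voted_label == "healthy"


class TestParticipantMetrics:
    def test_hand_confusion(self):
        preds = [
            ParticipantPrediction("a", 0.9, 1.0, "IBD"),
            ParticipantPrediction("b", 0.4, 0.0, "healthy"),
            ParticipantPrediction("c", 0.2, 0.0, "healthy"),
            ParticipantPrediction("d", 0.1, 0.0, "healthy"),
        ]
        truth = {"a": "IBD", "b": "IBD", "c": "healthy", "d": "healthy"}
        acc, sens, spec = bs.participant_metrics(preds, truth)
        assert (acc, sens, spec) == (0.75, 0.5, 1.0)

    def test_all_correct(self):
        preds = [
            ParticipantPrediction("a", 0.9, 1.0, "IBD"),
            ParticipantPrediction("b", 0.1, 0.0, "healthy"),
        ]
        acc, sens, spec = bs.participant_metrics(preds, {"a": "IBD", "b": "healthy"})
        assert acc == sens == spec == 1.0

    def test_class_swap_symmetry(self):
        preds = [
            ParticipantPrediction("a", 0.9, 1.0, "IBD"),
            ParticipantPrediction("b", 0.6, 1.0, "IBD"),
            ParticipantPrediction("c", 0.2, 0.0, "healthy"),
        ]
        truth = {"a": "IBD", "b": "healthy", "c": "healthy"}
        _, sens, spec = bs.participant_metrics(preds, truth)
        swapped_preds = [
            ParticipantPrediction(p.participant_id, p.mean_ibd_prob, p.fraction_windows_ibd,
                                  "healthy" if p.voted_label == "IBD" else "IBD")
            for p in preds
        ]
        swapped_truth = {k: ("healthy" if v == "IBD" else "IBD") for k, v in truth.items()}
        _, sens2, spec2 = bs.participant_metrics(swapped_preds, swapped_truth)
        assert (sens, spec) == (spec2, sens2)


class TestCorrelations:
    def manifest(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "participant_id": [f"P{i:02d}" for i in range(n)],
                "class": ["IBD"] * n,
                "fcp": rng.uniform(10, 600, n),
                "crp": rng.uniform(0.5, 20, n),
                "leukocytes": rng.uniform(4, 12, n),
            }
        )

    def test_monotone_scores_give_r_one(self):
        man = self.manifest()
        scores = {pid: fcp / 1000 for pid, fcp in zip(man["participant_id"], man["fcp"])}
        rep = bs.correlate_biomarkers(scores, man)
        assert rep.spearman_r["fcp"] == pytest.approx(1.0)

    def test_reversed_order_negates_r(self):
        man = self.manifest(seed=1)
        scores = {pid: fcp for pid, fcp in zip(man["participant_id"], man["fcp"])}
        r1 = bs.correlate_biomarkers(scores, man).spearman_r["fcp"]
        scores_neg = {k: -v for k, v in scores.items()}
        r2 = bs.correlate_biomarkers(scores_neg, man).spearman_r["fcp"]
        assert r1 == pytest.approx(-r2)

    def test_independent_biomarker_rarely_correlates(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(10_000 + seed)  # independent of the manifest draws
            man = self.manifest(n=24, seed=seed)
            scores = {pid: rng.random() for pid in man["participant_id"]}
            r = bs.correlate_biomarkers(scores, man).spearman_r["fcp"]
            hits += abs(r) < 0.5
        assert hits >= 38  # |r| < 0.5 in >= 95% of null draws at n=24

    def test_constant_scores_degenerate(self):
        man = self.manifest()
        rep = bs.correlate_biomarkers({pid: 0.5 for pid in man["participant_id"]}, man)
        assert rep.degenerate and np.isnan(rep.spearman_r["fcp"])

    def test_too_few_patients_rejected(self):
        man = self.manifest(n=2)
        with pytest.raises(ValueError):
            bs.correlate_biomarkers({"P00": 0.1, "P01": 0.2}, man)


class TestNoiseControlPlumbing:
    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            bs.noise_control_check(pd.DataFrame())

    def test_sampled_segments_avoid_events(self):
        from bowelspot.spotting import BSEvent

        exclude = [BSEvent(10.0 * i, 10.0 * i + 3.0) for i in range(10)]
        segs = bs.sample_noise_events(100.0, exclude, 20, 0.5, seed=0)
        for s in segs:
            for e in exclude:
                assert s.end_s <= e.start_s or s.start_s >= e.end_s

    def test_class_dependent_noise_is_detectable(self):
        """Positive control: when noise level depends on class, noise-only
        features separate the cohorts (AUROC > 0.8)."""
        cfg = bs.CohortConfig(
            n_ibd=5, n_healthy=5, n_channels=1, recording_duration_s=600.0,
            class_effect=0.0, noise_class_shift_db=10.0, seed=17,
        )
        manifest = bs.generate_cohort(cfg)
        windows = []
        for prof in manifest.profiles:
            buffers, events = bs.synthesize_recording(prof, cfg)
            buf = bs.bandpass_zero_phase(buffers[0])
            exclude = [bs.spotting.BSEvent(e.start_s, e.end_s, 0) for e in events]
            pseudo = bs.sample_noise_events(600.0, exclude, 30, 0.5, seed=prof.seed)
            feats = [bs.extract_event_features(buf, e) for e in pseudo]
            windows.extend(bs.build_windows(feats, 600.0, 200.0, prof.cohort_class, prof.participant_id))
        df = bs.windows_to_frame(windows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auroc = bs.noise_control_check(df, k=5, seed=0)
        assert auroc > 0.8
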