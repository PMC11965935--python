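"""IBD-vs-healthy classification over window features: gradient boosting with
SMOTE balancing inside group-stratified k-fold CV, participant-level majority
voting, window-duration sweep, biomarker correlation and the noise control.

The cross-validation contract is strict about leakage: participants are
assigned whole to folds, and standardisation parameters, feature selection
and SMOTE all come from the training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .features import (
    ClassificationWindow,
    EventFeatureVector,
    FeatureSelection,
    build_windows,
    feature_columns,
    rank_features_mutual_info,
    select_paper_features,
    standardize,
    windows_to_frame,
)
from .spotting.events import BSEvent

POSITIVE_CLASS = "IBD"


@dataclass
class GBCConfig:
    """Gradient-boosting hyperparameters. ``split_criterion`` records the
    Friedman-MSE split rule, which is what the underlying implementation
    uses for its trees."""

    n_estimators: int = 100
    learning_rate: float = 0.001
    loss: str = "exponential"
    split_criterion: str = "friedman_mse"

    def __post_init__(self):
        if self.n_estimators < 1 or self.learning_rate <= 0:
            raise ValueError("n_estimators >= 1 and learning_rate > 0 required")

    @classmethod
    def preset(cls, name: str) -> "GBCConfig":
        if name == "annotated_subset":
            return cls(n_estimators=50, learning_rate=1e-4)
        if name == "full_dataset":
            return cls(n_estimators=100, learning_rate=0.001)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class FoldAssignment:
    k: int
    fold_of_window: np.ndarray  # validation-fold index per window row
    groups: np.ndarray  # participant_id per window row

    def validate_group_integrity(self) -> None:
        table: dict[str, int] = {}
        for pid, f in zip(self.groups, self.fold_of_window):
            if pid in table and table[pid] != f:
                raise AssertionError(f"participant {pid} spans folds {table[pid]} and {f}")
            table[pid] = int(f)


@dataclass
class CVResult:
    per_fold: list[dict]
    window_probs: dict[tuple[str, int], float]
    window_labels: dict[tuple[str, int], str]
    selected_features: list[list[str]]
    n_folds_skipped_auroc: int = 0

    def _agg(self, key: str) -> tuple[float, float]:
        vals = [f[key] for f in self.per_fold if f.get(key) is not None]
        if not vals:
            return float("nan"), float("nan")
        return float(np.mean(vals)), float(np.std(vals))

    @property
    def mean_auroc(self) -> float:
        return self._agg("auroc")[0]

    @property
    def sd_auroc(self) -> float:
        return self._agg("auroc")[1]

    @property
    def mean_sensitivity(self) -> float:
        return self._agg("sensitivity")[0]

    @property
    def sd_sensitivity(self) -> float:
        return self._agg("sensitivity")[1]

    @property
    def mean_specificity(self) -> float:
        return self._agg("specificity")[0]

    @property
    def sd_specificity(self) -> float:
        return self._agg("specificity")[1]


@dataclass(frozen=True)
class ParticipantPrediction:
    participant_id: str
    mean_ibd_prob: float
    fraction_windows_ibd: float
    voted_label: str


@dataclass
class SweepResult:
    delta_grid_s: list[float]
    mean_auroc: list[float]
    sd_auroc: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_s": self.delta_grid_s, "mean_auroc": self.mean_auroc, "sd_auroc": self.sd_auroc}
        )


@dataclass(frozen=True)
class CorrelationReport:
    spearman_r: dict[str, float]
    n: int
    degenerate: bool = False


def make_folds(windows: pd.DataFrame, k: int, seed: int = 0) -> FoldAssignment:
    """Assign whole participants to k folds, balancing each class's window
    counts across folds (greedy, largest participants first; ties broken by
    a seeded shuffle). With one patient per fold feasible (k = number of
    patients), every fold's validation set contains exactly one patient."""
    pids = windows["participant_id"].to_numpy()
    labels = windows["label"].to_numpy()
    per_participant = (
        pd.DataFrame({"participant_id": pids, "label": labels})
        .groupby("participant_id")
        .agg(label=("label", "first"), n=("label", "size"))
        .reset_index()
    )
    n_participants = len(per_participant)
    if k > n_participants:
        raise ValueError(f"k={k} exceeds the {n_participants} participants")
    if per_participant["label"].nunique() < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    fold_of_pid: dict[str, int] = {}
    class_load = {lab: np.zeros(k) for lab in per_participant["label"].unique()}
    total_load = np.zeros(k)
    count_load = {lab: np.zeros(k, dtype=int) for lab in class_load}
    # minority class first so its participants spread one per fold when possible
    class_order = per_participant["label"].value_counts().index[::-1]
    for lab in class_order:
        sub = per_participant[per_participant["label"] == lab].copy()
        sub = sub.iloc[rng.permutation(len(sub))]
        sub = sub.sort_values("n", ascending=False, kind="stable")
        for _, row in sub.iterrows():
            # fewest participants of this class, then lightest class load, then total
            order = sorted(
                range(k),
                key=lambda f: (count_load[lab][f], class_load[lab][f], total_load[f], f),
            )
            f = order[0]
            fold_of_pid[row["participant_id"]] = f
            class_load[lab][f] += row["n"]
            count_load[lab][f] += 1
            total_load[f] += row["n"]
    fold_of_window = np.array([fold_of_pid[p] for p in pids])
    fa = FoldAssignment(k=k, fold_of_window=fold_of_window, groups=pids)
    fa.validate_group_integrity()
    for f in range(k):
        val_labels = set(labels[fold_of_window == f])
        if len(val_labels) < 2:
            warnings.warn(
                f"fold {f} validation set contains a single class; AUROC will be skipped",
                stacklevel=2,
            )
    return fa


def oversample_smote(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: new samples are convex combinations of
    a minority sample and one of its k nearest minority neighbours. Original
    samples are preserved; class counts come out equal."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    rng = np.random.default_rng(seed)
    if len(Xm) == 1:
        warnings.warn("single minority sample: falling back to duplication", stacklevel=2)
        synth = np.repeat(Xm, need, axis=0)
    else:
        k = min(k_neighbors, len(Xm) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        base = rng.integers(0, len(Xm), size=need)
        pick = rng.integers(1, k + 1, size=need)  # skip self at position 0
        u = rng.uniform(0.0, 1.0, size=(need, 1))
        neighbours = Xm[idx[base, pick]]
        synth = Xm[base] + u * (neighbours - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    return X_out, y_out


def train_gbc(
    X: np.ndarray, y: np.ndarray, cfg: GBCConfig | None = None, seed: int = 0
) -> GradientBoostingClassifier:
    """Fit the boosted-tree ensemble (exponential loss, Friedman-MSE splits)."""
    cfg = cfg or GBCConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = GradientBoostingClassifier(
        n_estimators=cfg.n_estimators,
        learning_rate=cfg.learning_rate,
        loss=cfg.loss,
        random_state=seed,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 9_973 + fold * 101 + 17) % (2**31))


def evaluate_cv(
    windows: pd.DataFrame,
    folds: FoldAssignment,
    cfg: GBCConfig | None = None,
    seed: int = 0,
    feature_mode: str = "per_fold_mi",
    n_features: int = 11,
    threshold: float = 0.5,
) -> CVResult:
    """Group-stratified CV: per fold, select features and fit standardisation
    on the training windows, SMOTE-balance the training set, fit the GBC and
    score the validation windows (AUROC; sensitivity/specificity at the 0.5
    probability threshold). Folds whose validation set has one class get no
    AUROC and are excluded from the AUROC mean with a warning."""
    cfg = cfg or GBCConfig()
    folds.validate_group_integrity()
    y_all = (windows["label"] == POSITIVE_CLASS).to_numpy().astype(int)
    per_fold: list[dict] = []
    window_probs: dict[tuple[str, int], float] = {}
    window_labels: dict[tuple[str, int], str] = {}
    selected_all: list[list[str]] = []
    skipped = 0
    for f in range(folds.k):
        val = folds.fold_of_window == f
        train = ~val
        if val.sum() == 0:
            continue
        assert not set(windows.loc[train, "participant_id"]) & set(
            windows.loc[val, "participant_id"]
        ), "participant leaks between train and validation"
        df_tr, df_va = windows[train], windows[val]
        fold_seed = _fold_seed(seed, f)
        if feature_mode == "paper":
            sel = select_paper_features(
                FeatureSelection(scores={c: 0.0 for c in feature_columns(windows)}), "paper"
            )
        elif feature_mode == "per_fold_mi":
            ranking = rank_features_mutual_info(df_tr, seed=fold_seed)
            sel = select_paper_features(ranking, "top_k", k=min(n_features, len(ranking.scores)))
        elif feature_mode == "all":
            sel = feature_columns(windows)
        else:
            raise ValueError(f"unknown feature_mode {feature_mode!r}")
        selected_all.append(sel)
        df_tr_s, df_va_s = standardize(df_tr, df_va, columns=sel)
        X_tr = df_tr_s[sel].to_numpy(dtype=float)
        y_tr = y_all[train]
        X_tr, y_tr = oversample_smote(X_tr, y_tr, seed=fold_seed)
        model = train_gbc(X_tr, y_tr, cfg, seed=fold_seed)
        X_va = df_va_s[sel].to_numpy(dtype=float)
        probs = model.predict_proba(X_va)[:, list(model.classes_).index(1)]
        y_va = y_all[val]
        for (pid, widx), p, lab in zip(
            zip(df_va["participant_id"], df_va["window_index"]), probs, df_va["label"]
        ):
            window_probs[(pid, int(widx))] = float(p)
            window_labels[(pid, int(widx))] = lab
        calls = probs >= threshold
        tp = int(np.sum(calls & (y_va == 1)))
        tn = int(np.sum(~calls & (y_va == 0)))
        fp = int(np.sum(calls & (y_va == 0)))
        fn = int(np.sum(~calls & (y_va == 1)))
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        if len(np.unique(y_va)) < 2:
            warnings.warn(f"fold {f}: single-class validation set, AUROC undefined", stacklevel=2)
            auroc = None
            skipped += 1
        else:
            auroc = float(roc_auc_score(y_va, probs))
        per_fold.append({"fold": f, "auroc": auroc, "sensitivity": sens, "specificity": spec})
    return CVResult(
        per_fold=per_fold,
        window_probs=window_probs,
        window_labels=window_labels,
        selected_features=selected_all,
        n_folds_skipped_auroc=skipped,
    )


def majority_vote(
    window_probs: dict[tuple[str, int], float], threshold: float = 0.5
) -> list[ParticipantPrediction]:
    """Hard majority voting: a participant is called IBD iff at least 50% of
    their windows are called IBD (window call = probability >= 0.5); ties go
    to IBD by the 'at least' rule. Also reports the mean IBD probability,
    the participant-level classification score."""
    by_pid: dict[str, list[float]] = {}
    for (pid, _), p in window_probs.items():
        by_pid.setdefault(pid, []).append(p)
    out = []
    for pid in sorted(by_pid):
        probs = by_pid[pid]
        if not probs:
            raise ValueError(f"participant {pid} has zero classified windows")
        frac = float(np.mean([p >= threshold for p in probs]))
        out.append(
            ParticipantPrediction(
                participant_id=pid,
                mean_ibd_prob=float(np.mean(probs)),
                fraction_windows_ibd=frac,
                voted_label=POSITIVE_CLASS if frac >= 0.5 else "healthy",
            )
        )
    return out


def participant_metrics(
    predictions: list[ParticipantPrediction], truth: dict[str, str]
) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity) of voted labels, IBD positive."""
    missing = [p.participant_id for p in predictions if p.participant_id not in truth]
    if missing:
        raise ValueError(f"no ground-truth class for {missing}")
    tp = fp = tn = fn = 0
    for p in predictions:
        is_pos = truth[p.participant_id] == POSITIVE_CLASS
        called_pos = p.voted_label == POSITIVE_CLASS
        tp += is_pos and called_pos
        fn += is_pos and not called_pos
        fp += (not is_pos) and called_pos
        tn += (not is_pos) and not called_pos
    n = tp + fp + tn + fn
    acc = (tp + tn) / n if n else float("nan")
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return acc, sens, spec


DEFAULT_DELTA_GRID_S = [1.0, 5.0, 10.0, 30.0, 60.0, 120.0, 300.0, 600.0]


def sweep_window_duration(
    participant_events: dict[str, tuple[list[EventFeatureVector], float, str]],
    delta_grid_s: list[float] | None = None,
    k: int = 5,
    cfg: GBCConfig | None = None,
    seed: int = 0,
    feature_mode: str = "per_fold_mi",
    n_features: int = 11,
) -> SweepResult:
    """Re-window, re-select, retrain and re-evaluate for every window duration
    delta in the grid; reports mean and SD of AUROC per delta.

    ``participant_events`` maps participant -> (event feature vectors,
    recording span in s, class label)."""
    grid = sorted(delta_grid_s or DEFAULT_DELTA_GRID_S)
    if not grid:
        raise ValueError("delta grid must be nonempty")
    means, sds = [], []
    for delta in grid:
        all_windows: list[ClassificationWindow] = []
        for pid, (evs, span, label) in participant_events.items():
            all_windows.extend(build_windows(evs, span, delta, label, pid))
        if not all_windows:
            means.append(float("nan"))
            sds.append(float("nan"))
            continue
        df = windows_to_frame(all_windows)
        folds = make_folds(df, k=k, seed=seed)
        res = evaluate_cv(
            df, folds, cfg, seed=seed, feature_mode=feature_mode, n_features=n_features
        )
        means.append(res.mean_auroc)
        sds.append(res.sd_auroc)
    return SweepResult(delta_grid_s=grid, mean_auroc=means, sd_auroc=sds)


def correlate_biomarkers(
    participant_scores: dict[str, float], biomarkers: pd.DataFrame
) -> CorrelationReport:
    """Spearman correlation between the per-patient IBD classification score
    (mean window probability) and each biomarker, patients only.

    ``biomarkers`` needs columns participant_id, class, fcp, crp, leukocytes.
    """
    patients = biomarkers[biomarkers["class"] == POSITIVE_CLASS]
    patients = patients[patients["participant_id"].isin(participant_scores)]
    if len(patients) < 3:
        raise ValueError("need at least 3 patients with biomarkers and scores")
    scores = np.array([participant_scores[p] for p in patients["participant_id"]])
    degenerate = bool(np.all(scores == scores[0]))
    rs: dict[str, float] = {}
    for col in ("fcp", "crp", "leukocytes"):
        if degenerate:
            rs[col] = float("nan")
        else:
            r, _ = sstats.spearmanr(scores, patients[col].to_numpy(dtype=float))
            rs[col] = float(r)
    return CorrelationReport(spearman_r=rs, n=len(patients), degenerate=degenerate)


def sample_noise_events(
    span_s: float,
    exclude: list[BSEvent],
    n_segments: int,
    segment_dur_s: float = 0.5,
    seed: int = 0,
) -> list[BSEvent]:
    """Pseudo-events over BS-free stretches of the recording, for the noise
    control benchmark. Segments avoid all intervals in ``exclude``."""
    if span_s <= segment_dur_s:
        raise ValueError("span too short for noise segments")
    rng = np.random.default_rng(seed)
    out: list[BSEvent] = []
    for _ in range(n_segments * 20):
        if len(out) >= n_segments:
            break
        start = rng.uniform(0.0, span_s - segment_dur_s)
        end = start + segment_dur_s
        if all(end <= e.start_s or start >= e.end_s for e in exclude):
            out.append(BSEvent(start, end, source="spotted"))
    return sorted(out, key=lambda e: e.start_s)


def noise_control_check(
    noise_windows: pd.DataFrame,
    k: int = 5,
    cfg: GBCConfig | None = None,
    seed: int = 0,
    feature_mode: str = "per_fold_mi",
    n_features: int = 11,
) -> float:
    """Mean CV AUROC when classifying cohorts from noise-only pseudo-event
    windows. Near 0.5 indicates the classifier needs genuine BS content."""
    if len(noise_windows) == 0:
        raise ValueError("empty noise segment windows")
    folds = make_folds(noise_windows, k=k, seed=seed)
    res = evaluate_cv(
        noise_windows, folds, cfg, seed=seed, feature_mode=feature_mode, n_features=n_features
    )
    return res.mean_auroc
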