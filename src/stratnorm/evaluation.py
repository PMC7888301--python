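"""Leave-one-participant-out evaluation and layer-wise probing.

Two protocols measure cross-subject behavior of the classifier:

* **LOPO cross-validation**: each fold trains on all participants but
  one and tests on the held-out participant, the strictest test of
  cross-subject generalization. Results are per-participant accuracies
  plus a pooled confusion matrix.
* **Layer probing**: the model is retrained in a three-fold design with
  2/3 of participants for training and 1/3 for testing; activations of
  the test participants are recorded at five probe points (normalized
  input, three normalized hidden layers, softmax output) and an RBF-SVM
  is cross-validated on each, once with emotion labels and once with
  participant identities. Participant-ID accuracy above chance
  quantifies how much individual "brain signature" survives at each
  depth; stratified normalization is expected to suppress it early.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable, LABEL_NEUTRAL, LABEL_POSITIVE
from .model import TRACE_LAYERS, TrainConfig, forward, predict, train_model
from .normalization import (
    NormConfig,
    apply_minmax_global,
    apply_minmax_stratified,
    fit_minmax_global,
)

__all__ = [
    "ConfusionMatrix",
    "LOPOResult",
    "ProbeConfig",
    "ProbeReport",
    "lopo_cross_validation",
    "pooled_accuracy",
    "class_recalls",
    "class_precisions",
    "accuracy_correlation",
    "probe_protocol",
    "chance_level",
]

#: Display order of classes in confusion matrices.
BINARY_CLASSES = ("positive", "negative")
TERNARY_CLASSES = ("positive", "neutral", "negative")


@dataclass
class ConfusionMatrix:
    """Integer counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pooled_accuracy(cm: ConfusionMatrix) -> float:
    """Diagonal share of all counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def class_recalls(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-true-class diagonal share (row-normalized)."""
    row_tot = cm.counts.sum(axis=1)
    if (row_tot == 0).any():
        raise ValueError("a true class has no rows")
    return {
        name: float(cm.counts[i, i] / row_tot[i])
        for i, name in enumerate(cm.class_names)
    }


def class_precisions(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-predicted-class diagonal share (column-normalized)."""
    col_tot = cm.counts.sum(axis=0)
    if (col_tot == 0).any():
        raise ValueError("a predicted class has no columns")
    return {
        name: float(cm.counts[i, i] / col_tot[i])
        for i, name in enumerate(cm.class_names)
    }


def accuracy_correlation(acc_a, acc_b) -> float:
    """Pearson product-moment correlation between two accuracy vectors."""
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant vector has no defined correlation")
    return float(sps.pearsonr(a, b).statistic)


def chance_level(class_counts) -> dict[str, float]:
    """Uniform (1/n) and majority-class baselines for given class counts."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 0).any() or counts.sum() == 0:
        raise ValueError("class counts must be non-negative with a positive sum")
    present = counts[counts > 0]
    return {
        "uniform": 1.0 / len(present),
        "majority": float(present.max() / counts.sum()),
    }


# --------------------------------------------------------------------------
# Shared fold preparation


def _encode_labels(labels: np.ndarray, labeling: str):
    """Row mask and internal label codes for a labeling scheme.

    Binary drops neutral trials and codes negative=0, positive=1;
    ternary keeps negative=0, neutral=1, positive=2.
    """
    if labeling == "binary":
        mask = labels != LABEL_NEUTRAL
        return mask, (labels[mask] == LABEL_POSITIVE).astype(np.int64)
    if labeling == "ternary":
        mask = np.ones(len(labels), dtype=bool)
        return mask, labels.astype(np.int64)
    raise ValueError(f"labeling must be 'binary' or 'ternary', got {labeling!r}")


def _display_confusion(y_true, y_pred, labeling) -> ConfusionMatrix:
    names = BINARY_CLASSES if labeling == "binary" else TERNARY_CLASSES
    n = len(names)
    counts = np.zeros((n, n), dtype=np.int64)
    # internal code c maps to display row (n - 1 - c): positive first.
    for t, p in zip(y_true, y_pred):
        counts[n - 1 - t, n - 1 - p] += 1
    return ConfusionMatrix(counts=counts, class_names=names)


def _minmax_for_fold(
    X: np.ndarray,
    strata: np.ndarray,
    train_rows: np.ndarray,
    norm: NormConfig,
) -> np.ndarray:
    """Min-max normalize the feature matrix for one train/test split."""
    if norm.mode == "stratified":
        # Per-stratum statistics never mix train and test participants.
        return apply_minmax_stratified(X, strata)
    stats = fit_minmax_global(X[train_rows])
    out = np.empty_like(X, dtype=np.float64)
    out[train_rows] = apply_minmax_global(X[train_rows], stats, clip=False)
    test_rows = ~train_rows
    if test_rows.any():
        out[test_rows] = apply_minmax_global(
            X[test_rows], stats, clip=norm.clip_test_minmax
        )
    return out


@dataclass
class LOPOResult:
    participants: list[int]
    accuracies: np.ndarray  # per held-out participant
    confusion: ConfusionMatrix
    labeling: str
    norm_mode: str

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        """Sample (n−1) standard deviation across folds."""
        return float(self.accuracies.std(ddof=1))

    @property
    def sd_population(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def to_dict(self) -> dict:
        return {
            "labeling": self.labeling,
            "norm": self.norm_mode,
            "participants": list(map(int, self.participants)),
            "per_fold": [float(a) for a in self.accuracies],
            "mean": self.mean,
            "sd": self.sd,
            "confusion": self.confusion.counts.tolist(),
            "classes": list(self.confusion.class_names),
        }


def lopo_cross_validation(
    features: FeatureTable,
    labeling: str = "ternary",
    norm: NormConfig | None = None,
    cfg: TrainConfig | None = None,
) -> LOPOResult:
    """Leave-one-participant-out cross-validation of the classifier.

    For each participant p: train on every other participant's rows, test
    on p's rows. In stratified mode the held-out participant's
    normalization statistics come from their own trial rows per session
    (participant identity is metadata, available without labels).
    """
    norm = norm or NormConfig()
    cfg = cfg or TrainConfig()
    features.validate()
    mask, y = _encode_labels(features.labels, labeling)
    sub = features.subset(mask)
    strata = sub.strata
    participants = sorted(np.unique(sub.participants))
    if len(participants) < 2:
        raise ValueError("LOPO needs at least 2 participants")
    n_classes = 2 if labeling == "binary" else 3
    accuracies = []
    confusion = None
    for fold, held_out in enumerate(participants):
        test_mask = sub.participants == held_out
        train_rows = ~test_mask
        if len(np.unique(y[train_rows])) < n_classes:
            raise ValueError(
                f"fold {held_out}: a class is absent from the training rows"
            )
        Xn = _minmax_for_fold(sub.X, strata, train_rows, norm)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        params, _ = train_model(
            Xn[train_rows], y[train_rows], strata[train_rows], fold_cfg, norm
        )
        y_pred, _ = predict(params, Xn[test_mask], strata[test_mask])
        y_test = y[test_mask]
        accuracies.append(float((y_pred == y_test).mean()))
        cm = _display_confusion(y_test, y_pred, labeling)
        confusion = cm if confusion is None else ConfusionMatrix(
            confusion.counts + cm.counts, cm.class_names
        )
    return LOPOResult(
        participants=list(map(int, participants)),
        accuracies=np.asarray(accuracies),
        confusion=confusion,
        labeling=labeling,
        norm_mode=norm.mode,
    )


# --------------------------------------------------------------------------
# Layer probing


@dataclass
class ProbeConfig:
    n_folds: int = 3
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    cv_folds: int = 5
    seed: int = 0


@dataclass
class ProbeReport:
    layers: tuple[str, ...]
    # (n_folds, n_layers) per-fold mean CV accuracies
    emotion_acc: np.ndarray
    participant_acc: np.ndarray
    chance_emotion: dict[str, float]
    chance_participant: dict[str, float]
    labeling: str
    norm_mode: str

    def layer_mean(self, task: str, layer: str) -> float:
        arr = self.emotion_acc if task == "emotion" else self.participant_acc
        return float(arr[:, self.layers.index(layer)].mean())

    def layer_sd(self, task: str, layer: str) -> float:
        arr = self.emotion_acc if task == "emotion" else self.participant_acc
        return float(arr[:, self.layers.index(layer)].std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "labeling": self.labeling,
            "norm": self.norm_mode,
            "layers": list(self.layers),
            "emotion_acc": self.emotion_acc.tolist(),
            "participant_acc": self.participant_acc.tolist(),
            "chance_emotion": self.chance_emotion,
            "chance_participant": self.chance_participant,
        }


def _probe_one(Z, labels, probe_cfg: ProbeConfig) -> float:
    clf = make_pipeline(
        StandardScaler(),
        SVC(C=probe_cfg.svm_c, kernel="rbf", gamma=probe_cfg.svm_gamma),
    )
    cv = StratifiedKFold(
        n_splits=probe_cfg.cv_folds, shuffle=True, random_state=probe_cfg.seed
    )
    return float(cross_val_score(clf, Z, labels, cv=cv).mean())


def probe_protocol(
    features: FeatureTable,
    labeling: str = "ternary",
    norm: NormConfig | None = None,
    cfg: TrainConfig | None = None,
    probe_cfg: ProbeConfig | None = None,
) -> ProbeReport:
    """Measure emotion and participant-identity information per layer.

    Participants are split (seeded) into ``n_folds`` disjoint test
    groups. For each fold the classifier is trained on the remaining
    participants; activations at the five probe points are recorded for
    the pooled test-participant rows only, and an RBF-SVM is scored by
    stratified cross-validation on each layer for both tasks.
    """
    norm = norm or NormConfig()
    cfg = cfg or TrainConfig()
    probe_cfg = probe_cfg or ProbeConfig()
    features.validate()
    mask, y = _encode_labels(features.labels, labeling)
    sub = features.subset(mask)
    strata = sub.strata
    participants = np.array(sorted(np.unique(sub.participants)))
    if len(participants) < 2 * probe_cfg.n_folds:
        raise ValueError(
            f"probing needs >= 2 test participants per fold "
            f"({len(participants)} participants, {probe_cfg.n_folds} folds)"
        )
    rng = np.random.default_rng(probe_cfg.seed)
    order = rng.permutation(len(participants))
    groups = [participants[order[i :: probe_cfg.n_folds]] for i in range(probe_cfg.n_folds)]
    emo = np.empty((probe_cfg.n_folds, len(TRACE_LAYERS)))
    pid = np.empty_like(emo)
    chance_emo = chance_part = None
    for fold, test_group in enumerate(groups):
        test_mask = np.isin(sub.participants, test_group)
        train_rows = ~test_mask
        Xn = _minmax_for_fold(sub.X, strata, train_rows, norm)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        params, _ = train_model(
            Xn[train_rows], y[train_rows], strata[train_rows], fold_cfg, norm
        )
        _, trace = forward(params, Xn[test_mask], strata[test_mask], phase="eval")
        y_test = y[test_mask]
        pid_test = sub.participants[test_mask]
        for li, layer in enumerate(TRACE_LAYERS):
            Z = trace.layer(layer)
            emo[fold, li] = _probe_one(Z, y_test, probe_cfg)
            pid[fold, li] = _probe_one(Z, pid_test, probe_cfg)
        if fold == 0:
            chance_emo = chance_level(np.bincount(y_test))
            chance_part = chance_level(
                np.unique(pid_test, return_counts=True)[1]
            )
    return ProbeReport(
        layers=TRACE_LAYERS,
        emotion_acc=emo,
        participant_acc=pid,
        chance_emotion=chance_emo,
        chance_participant=chance_part,
        labeling=labeling,
        norm_mode=norm.mode,
    )
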