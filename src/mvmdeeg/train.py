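"""Training loop, cross-validation protocols and metrics.

Two protocols are provided: epoch-level stratified k-fold (the
subject-dependent setting) and patient-level k-fold in which every
patient's epochs land in exactly one fold, so test folds contain only
unseen patients (the subject-independent setting). Training uses Adam
with a step learning-rate decay and a cross-entropy objective, fully
seeded for bit-reproducible runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .model import HybridClassifier, ModelConfig

__all__ = [
    "TrainConfig",
    "EvalReport",
    "make_epoch_folds",
    "make_subject_folds",
    "train_model",
    "evaluate",
    "cross_validate",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 200
    lr: float = 1e-3
    lr_step: int = 5
    lr_gamma: float = 0.1
    lr_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("lr_gamma must be in (0, 1]")


@dataclass
class EvalReport:
    """Classification metrics for one run.

    ``acc``, ``sen`` and ``spe`` are percentages; sensitivity is the
    recall of the positive (focal, class 1) class and specificity the
    recall of class 0 on binary tasks. For multi-class tasks ``sen`` and
    ``spe`` are macro-averaged one-vs-rest recalls. ``weighted_f1`` is
    the class-frequency-weighted mean of per-class F1 scores, in [0, 1].
    """

    acc: float
    sen: float
    spe: float
    weighted_f1: float
    confusion: np.ndarray
    confusion_row_normalized: np.ndarray
    per_class_recall: np.ndarray = field(default_factory=lambda: np.empty(0))


def make_epoch_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment per epoch (subject-dependent protocol).

    Returns an integer fold index in [0, k) per sample; folds are
    disjoint, exhaustive and class-stratified, deterministic under seed.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if counts[counts > 0].min() < k:
        raise ValueError(f"need at least {k} samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = i
    return folds


def make_subject_folds(
    epoch_patient_ids: np.ndarray, k: int = 3, seed: int = 0
) -> np.ndarray:
    """Patient-level k-fold assignment (subject-independent protocol).

    Unique patient ids are shuffled with the seed and split into k
    near-equal groups; every epoch inherits its patient's fold, so no
    patient contributes to more than one fold.
    """
    ids = np.asarray(epoch_patient_ids)
    patients = np.unique(ids)
    if len(patients) < k:
        raise ValueError(f"need at least {k} distinct patients")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(patients)
    folds = np.empty(len(ids), dtype=int)
    for i, group in enumerate(np.array_split(shuffled, k)):
        folds[np.isin(ids, group)] = i
    return folds


def train_model(
    model: HybridClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> tuple[HybridClassifier, list[float]]:
    """Fit the classifier with Adam + step LR decay + cross-entropy.

    ``features`` is (n, in_maps, F, T); ``labels`` integer classes.
    Returns the trained model and the per-epoch mean training loss.
    Raises on NaN loss.
    """
    if len(features) == 0:
        raise ValueError("empty dataset")
    labels = np.asarray(labels, dtype=int)
    if labels.max() >= model.cfg.n_classes:
        raise ValueError("label outside model's class range")
    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(model.parameters(), lr=cfg.lr)
    sched = ad.StepLR(opt, cfg.lr_step, cfg.lr_gamma, cfg.lr_floor)
    history: list[float] = []
    n = len(features)
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(features[idx])
            loss = ad.cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("training loss became non-finite")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        sched.step()
    return model, history


def evaluate(
    model_or_pred, features: np.ndarray | None = None, labels: np.ndarray = None
) -> EvalReport:
    """Evaluate a trained model (or precomputed predictions) on a dataset.

    Accepts either ``evaluate(model, features, labels)`` or
    ``evaluate(y_pred, labels=y_true)`` / a confusion matrix via
    :func:`report_from_confusion`.
    """
    if isinstance(model_or_pred, HybridClassifier):
        preds = []
        for start in range(0, len(features), 256):
            preds.append(model_or_pred.predict(features[start : start + 256]))
        y_pred = np.concatenate(preds)
    else:
        y_pred = np.asarray(model_or_pred, dtype=int)
    y_true = np.asarray(labels, dtype=int)
    n_classes = max(
        int(y_true.max()), int(y_pred.max()),
        (model_or_pred.cfg.n_classes - 1) if isinstance(model_or_pred, HybridClassifier) else 0,
    ) + 1
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    wf1 = float(f1_score(y_true, y_pred, average="weighted", zero_division=0))
    return report_from_confusion(cm, weighted_f1=wf1)


def report_from_confusion(cm: np.ndarray, weighted_f1: float | None = None) -> EvalReport:
    """Metrics from an n x n confusion matrix with rows = true class.

    For 2 classes: SEN is the recall of class 1 (focal anchored as the
    positive class), SPE the recall of class 0. For more classes both
    are macro averages of one-vs-rest recall and specificity.
    """
    cm = np.asarray(cm, dtype=float)
    n = cm.shape[0]
    total = cm.sum()
    acc = 100.0 * np.trace(cm) / total
    row_sums = cm.sum(axis=1)
    safe = np.where(row_sums > 0, row_sums, 1.0)
    recall = np.diag(cm) / safe
    if n == 2:
        sen = 100.0 * recall[1]
        spe = 100.0 * recall[0]
    else:
        sen = 100.0 * recall.mean()
        spec_c = []
        for c in range(n):
            tn = total - row_sums[c] - cm[:, c].sum() + cm[c, c]
            spec_c.append(tn / (total - row_sums[c]))
        spe = 100.0 * float(np.mean(spec_c))
    if weighted_f1 is None:
        precision = np.diag(cm) / np.where(cm.sum(axis=0) > 0, cm.sum(axis=0), 1.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
        weighted_f1 = float((row_sums / total) @ f1)
    row_norm = cm / safe[:, None]
    return EvalReport(
        acc=float(acc),
        sen=float(sen),
        spe=float(spe),
        weighted_f1=float(weighted_f1),
        confusion=cm,
        confusion_row_normalized=row_norm,
        per_class_recall=recall,
    )


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    folds: np.ndarray,
) -> tuple[list[EvalReport], np.ndarray]:
    """Train and evaluate once per fold; returns per-fold reports."""
    reports = []
    for f in np.unique(folds):
        train_idx = folds != f
        test_idx = folds == f
        model = HybridClassifier(model_cfg)
        model, _ = train_model(model, features[train_idx], labels[train_idx], train_cfg)
        reports.append(evaluate(model, features[test_idx], labels[test_idx]))
    return reports, folds
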