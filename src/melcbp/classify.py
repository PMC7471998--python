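"""Multi-kernel SVM classification and subject-wise evaluation.

The two sparse representations (spatial and temporal) are mapped through
separate linear kernels on unit-L2-normalized features; the classifier
operates on their convex combination ``K = sum_z c_z K_z`` (c_z >= 0,
sum 1).  The combination weights are picked by stratified inner
cross-validation on the training subjects only.  Multi-class decisions use
the one-vs-one decomposition of the binary kernel SVM dual.

Evaluation follows leave-one-subject-out (LOSO): each fold holds out every
clip of one subject, so reported accuracy measures generalization to
unseen people rather than unseen clips.  Overall accuracy is
``100 * sum_i T_i / sum_i S_i`` over subjects (T_i correct, S_i total) and
macro-F1 averages per-class F1 with absent classes contributing zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "KernelCombo",
    "TrainedClassifier",
    "EvalReport",
    "StratificationError",
    "normalize_rows",
    "linear_kernel",
    "combine_kernels",
    "fit_mksvm",
    "tune_kernel_weights",
    "loso_folds",
    "accuracy",
    "confusion_matrix",
    "macro_f1",
]

DEFAULT_WEIGHT_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


class StratificationError(ValueError):
    """A class cannot be represented in every inner CV fold."""


@dataclass(frozen=True)
class KernelCombo:
    """Non-negative kernel weights summing to one, one per feature type."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("kernel weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"kernel weights must sum to 1, got {w.sum()}")


def normalize_rows(A: np.ndarray) -> np.ndarray:
    """Scale each row to unit L2 norm (zero rows are left untouched)."""
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    return np.divide(A, norms, out=A.astype(float).copy(), where=norms > 0)


def linear_kernel(A: np.ndarray, B: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Gram matrix of row inner products; rows unit-normalized by default."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    if normalize:
        A, B = normalize_rows(A), normalize_rows(B)
    return A @ B.T


def combine_kernels(K_list: list[np.ndarray], combo: KernelCombo) -> np.ndarray:
    """Elementwise weighted sum of same-shape kernel matrices."""
    if len(K_list) != len(combo.weights):
        raise ValueError("one weight per kernel required")
    shapes = {k.shape for k in K_list}
    if len(shapes) != 1:
        raise ValueError(f"kernel shapes differ: {sorted(shapes)}")
    out = np.zeros(K_list[0].shape)
    for w, K in zip(combo.weights, K_list):
        out += w * K
    return out


@dataclass
class TrainedClassifier:
    """A multi-kernel SVM fitted on precomputed training kernels."""

    svc: SVC = field(repr=False)
    combo: KernelCombo
    C: float
    n_train: int

    def predict(self, K_test_list: list[np.ndarray]) -> np.ndarray:
        """Predict labels from test-vs-train kernel matrices."""
        K = combine_kernels(K_test_list, self.combo)
        if K.shape[1] != self.n_train:
            raise ValueError(f"expected {self.n_train} training columns, got {K.shape[1]}")
        return self.svc.predict(K)


def fit_mksvm(
    K_train_list: list[np.ndarray],
    labels: np.ndarray,
    combo: KernelCombo,
    C: float = 1.0,
) -> TrainedClassifier:
    """Train a one-vs-one SVM on the combined precomputed kernel."""
    K = combine_kernels(K_train_list, combo)
    if K.shape[0] != K.shape[1]:
        raise ValueError("training kernels must be square")
    min_eig = float(np.linalg.eigvalsh(K).min()) if K.shape[0] <= 500 else 0.0
    if min_eig < -1e-6:
        warnings.warn(f"combined kernel is not PSD (min eigenvalue {min_eig:.3g})")
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(K, np.asarray(labels, dtype=int))
    return TrainedClassifier(svc=svc, combo=combo, C=C, n_train=K.shape[0])


def tune_kernel_weights(
    features_by_type: list[np.ndarray],
    labels: np.ndarray,
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID,
    inner_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> KernelCombo:
    """Pick the kernel weights maximizing mean inner-CV accuracy.

    The grid parametrizes two-kernel combinations (c_1, 1 - c_1); ties are
    broken toward the smallest c_1.  Folds are stratified by class and
    shuffled with ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(features_by_type) != 2:
        raise ValueError("expected two feature types (spatial, temporal)")
    _, counts = np.unique(labels, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise StratificationError("every class needs at least 2 samples for inner CV")
    n_splits = min(inner_folds, min_count)
    kernels = [linear_kernel(F, F) for F in features_by_type]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(labels.size), labels))

    best_c1, best_acc = None, -1.0
    for c1 in sorted(weight_grid):
        combo = KernelCombo((float(c1), float(1.0 - c1)))
        accs = []
        for tr, te in folds:
            clf = fit_mksvm([K[np.ix_(tr, tr)] for K in kernels], labels[tr], combo, C)
            pred = clf.predict([K[np.ix_(te, tr)] for K in kernels])
            accs.append(float(np.mean(pred == labels[te])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:  # strict: first (smallest c1) wins ties
            best_acc, best_c1 = mean_acc, float(c1)
    return KernelCombo((best_c1, 1.0 - best_c1))


def loso_folds(subject_ids: list[str] | np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds: one per distinct subject, in sorted order."""
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if subjects.size < 2:
        raise ValueError("LOSO requires at least two distinct subjects")
    folds = []
    for s in subjects:
        test = np.flatnonzero(subject_ids == s)
        train = np.flatnonzero(subject_ids != s)
        folds.append((train, test))
    return folds


def accuracy(per_subject_correct, per_subject_total) -> float:
    """Pooled accuracy in percent: 100 * sum T_i / sum S_i."""
    T = np.asarray(per_subject_correct, dtype=float)
    S = np.asarray(per_subject_total, dtype=float)
    if (T < 0).any() or (T > S).any():
        raise ValueError("need 0 <= T_i <= S_i")
    if S.sum() == 0:
        raise ValueError("no test samples")
    return 100.0 * float(T.sum()) / float(S.sum())


def confusion_matrix(truth: np.ndarray, predictions: np.ndarray, c: int) -> np.ndarray:
    """(c, c) count matrix; rows = true class, columns = predicted."""
    truth = np.asarray(truth, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    for arr, name in ((truth, "truth"), (predictions, "predictions")):
        if arr.min() < 1 or arr.max() > c:
            raise ValueError(f"{name} labels must lie in 1..{c}")
    mat = np.zeros((c, c), dtype=np.int64)
    np.add.at(mat, (truth - 1, predictions - 1), 1)
    return mat


def macro_f1(predictions: np.ndarray, truth: np.ndarray, c: int) -> float:
    """Unweighted mean of per-class F1; classes with p + r = 0 contribute 0."""
    mat = confusion_matrix(truth, predictions, c)
    f1s = []
    for i in range(c):
        tp = mat[i, i]
        pred_i = mat[:, i].sum()
        true_i = mat[i, :].sum()
        p = tp / pred_i if pred_i else 0.0
        r = tp / true_i if true_i else 0.0
        f1s.append(2 * p * r / (p + r) if (p + r) > 0 else 0.0)
    return float(np.mean(f1s))


@dataclass
class EvalReport:
    """Aggregated LOSO results."""

    subjects: list[str]
    per_subject_correct: list[int]
    per_subject_total: list[int]
    overall_accuracy: float  # percent
    macro_f1: float  # fraction in [0, 1]
    confusion: np.ndarray = field(repr=False)
    class_names: list[str] = field(default_factory=list)
    predictions: np.ndarray = field(default=None, repr=False)
    truth: np.ndarray = field(default=None, repr=False)

    @property
    def per_subject_accuracy(self) -> list[float]:
        return [
            100.0 * t / s if s else 0.0
            for t, s in zip(self.per_subject_correct, self.per_subject_total)
        ]

    def to_dict(self) -> dict:
        return {
            "overall_accuracy_percent": self.overall_accuracy,
            "macro_f1": self.macro_f1,
            "class_names": self.class_names,
            "per_subject": [
                {"subject": s, "correct": int(t), "total": int(n), "accuracy_percent": a}
                for s, t, n, a in zip(
                    self.subjects,
                    self.per_subject_correct,
                    self.per_subject_total,
                    self.per_subject_accuracy,
                )
            ],
            "confusion": self.confusion.tolist(),
        }

    def save_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_confusion_csv(self, path) -> None:
        import pandas as pd

        names = self.class_names or [str(i + 1) for i in range(self.confusion.shape[0])]
        pd.DataFrame(self.confusion, index=names, columns=names).to_csv(path)
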