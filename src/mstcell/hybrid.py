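"""Hybrid classification head: max-abs scaling → PCA(512) → SVM.

After calibration, each image becomes a 32,768-dim flatten-layer feature
vector. The head rescales every feature to ``[-1, 1]`` by its training-set
maximum absolute value, projects onto the leading 512 principal components,
and classifies the 512-dim coordinates with a support vector machine. An
LDA projector variant (capped at ``n_classes - 1 = 3`` dimensions) is kept
for ablation comparisons. All fitting statistics come from the training set
only; test features are transformed with the frozen training parameters.

The projected coordinates are also the substrate for the differentiation-
degree scoring in :mod:`mstcell.diffscore`.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.preprocessing import MaxAbsScaler
from sklearn.svm import SVC

from .types import CLASS_ORDER, CellClass

__all__ = ["HybridHead", "EvalReport", "fit_head", "project", "classify",
           "evaluate", "load_head"]

CLASS_NAMES = tuple(c.value for c in CLASS_ORDER)


def _round1(x: float) -> float:
    """Half-up rounding to one decimal, as percentages are reported."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, columns = recognised) and metrics.

    Percentages are stored at full precision; ``summary()`` prints them
    half-up rounded to one decimal.
    """

    confusion: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        m = np.asarray(self.confusion, dtype=np.int64)
        k = len(self.class_names)
        if m.shape != (k, k) or (m < 0).any():
            raise ValueError(f"confusion matrix must be {k}x{k} nonnegative")
        self.confusion = m

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy = trace / total, in percent."""
        return 100.0 * np.trace(self.confusion) / self.total

    @property
    def recall(self) -> np.ndarray:
        """Per-class recall in percent (row-normalised diagonal)."""
        row = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.diag(self.confusion) / row
        return 100.0 * np.where(row > 0, r, np.nan)

    @property
    def precision(self) -> np.ndarray:
        col = self.confusion.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.diag(self.confusion) / col
        return 100.0 * np.where(col > 0, p, np.nan)

    @property
    def f_score(self) -> np.ndarray:
        """Per-class F1 in percent (harmonic mean of precision and recall)."""
        p, r = self.precision, self.recall
        with np.errstate(invalid="ignore", divide="ignore"):
            f = 2 * p * r / (p + r)
        return np.where((p + r) > 0, f, 0.0)

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.confusion, index=self.class_names,
                          columns=self.class_names)
        df["recall_%"] = [_round1(v) for v in self.recall]
        df["f_score_%"] = [_round1(v) for v in self.f_score]
        return df

    def summary(self) -> str:
        lines = [f"Overall accuracy: {_round1(self.accuracy)}% "
                 f"({np.trace(self.confusion)}/{self.total})",
                 "", self.to_frame().to_string()]
        return "\n".join(lines)

    def write(self, csv_path, txt_path=None) -> None:
        self.to_frame().to_csv(csv_path)
        if txt_path is not None:
            from pathlib import Path
            Path(txt_path).write_text(self.summary() + "\n")


class HybridHead:
    """Fitted scaling + projector + SVM stack with a frozen class order."""

    def __init__(self, scaler: MaxAbsScaler, projector, kind: str, svm: SVC,
                 n_features: int):
        self.scaler = scaler
        self.projector = projector
        self.projector_kind = kind
        self.svm = svm
        self.n_features = n_features
        self.class_order = CLASS_ORDER

    @property
    def n_components(self) -> int:
        if self.projector_kind == "pca":
            return self.projector.n_components_
        return self.projector.transform(
            np.zeros((1, self.n_features))).shape[1]

    def _check(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if f.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features}-dim features, "
                             f"got {f.shape[1]}")
        if not np.isfinite(f).all():
            raise ValueError("features contain non-finite entries")
        return f

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)


def load_head(path) -> HybridHead:
    with open(path, "rb") as fh:
        head = pickle.load(fh)
    if not isinstance(head, HybridHead):
        raise ValueError(f"{path} does not contain a HybridHead")
    return head


def fit_head(train_features: np.ndarray, labels, k: int = 512,
             projector: str = "pca", kernel: str = "rbf", C: float = 1.0,
             seed: int = 0) -> HybridHead:
    """Fit scaling, projection and SVM on training features only.

    ``k`` is silently capped at the feature count and sample count (PCA rank
    bound) with a warning; the LDA projector is additionally capped at
    ``n_classes - 1``. The SVM uses the one-vs-one multiclass strategy
    (scikit-learn's default for :class:`~sklearn.svm.SVC`).
    """
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("train_features must be 2-D (samples x features)")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if projector not in ("pca", "lda"):
        raise ValueError(f"projector must be 'pca' or 'lda', got {projector!r}")
    y = np.array([CLASS_ORDER.index(l) if isinstance(l, CellClass)
                  else CLASS_ORDER.index(CellClass.parse(l)) for l in labels])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit the head")
    if counts.min() < 2:
        small = CLASS_ORDER[classes[counts.argmin()]].value
        raise ValueError(f"class {small} has fewer than 2 training samples")

    scaler = MaxAbsScaler().fit(X)
    # zero-variance features keep factor 1 (MaxAbsScaler convention)
    Xs = scaler.transform(X)

    if projector == "pca":
        k_eff = min(k, X.shape[1], X.shape[0])
        if k_eff < k:
            warnings.warn(f"PCA dimension capped at {k_eff} "
                          f"(requested {k}, rank bound)", stacklevel=2)
        proj = PCA(n_components=k_eff, svd_solver="auto",
                   random_state=seed).fit(Xs)
    else:
        k_eff = min(k, len(classes) - 1, X.shape[1])
        if k_eff < k:
            warnings.warn(f"LDA dimension capped at {k_eff} "
                          f"(requested {k}; at most n_classes-1)", stacklevel=2)
        proj = LinearDiscriminantAnalysis(n_components=k_eff).fit(Xs, y)

    Z = proj.transform(Xs)
    svm = SVC(kernel=kernel, C=C, decision_function_shape="ovo",
              random_state=seed).fit(Z, y)
    return HybridHead(scaler, proj, projector, svm, X.shape[1])


def project(head: HybridHead, features: np.ndarray) -> np.ndarray:
    """Project feature vectors to head coordinates (PCA or LDA axes).

    For PCA this is ``components @ (scaled(f) - center)`` with axes ordered
    by decreasing explained variance.
    """
    f = head._check(features)
    return head.projector.transform(head.scaler.transform(f))


def classify(head: HybridHead, features: np.ndarray) -> list[CellClass]:
    """Predicted class labels, in the fixed (IPSC, MSC, RGC, RPE) order."""
    f = head._check(features)
    z = head.projector.transform(head.scaler.transform(f))
    return [CLASS_ORDER[int(i)] for i in head.svm.predict(z)]


def _as_indices(labels) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, CellClass):
            out.append(CLASS_ORDER.index(l))
        elif isinstance(l, (int, np.integer)) and 0 <= int(l) < len(CLASS_ORDER):
            out.append(int(l))
        else:
            out.append(CLASS_ORDER.index(CellClass.parse(l)))
    return np.array(out, dtype=int)


def evaluate(pred_labels, true_labels) -> EvalReport:
    """Confusion matrix (rows = truth) plus recall, F score and accuracy."""
    pred = _as_indices(pred_labels)
    true = _as_indices(true_labels)
    if len(pred) != len(true) or len(pred) == 0:
        raise ValueError("prediction and truth lists must be equal-length "
                         "and nonempty")
    m = _sk_confusion(true, pred, labels=range(len(CLASS_ORDER)))
    return EvalReport(confusion=m)
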