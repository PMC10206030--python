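"""Four-class SVM evaluation of the movement-class feature matrix.

The model is a one-vs-one ensemble of soft-margin support-vector
machines with a Gaussian radial-basis-function kernel and penalty
``C = 0.3``, evaluated by stratified ten-fold cross-validation.  Feature
normalisation (z-score by default) is fitted on each fold's training
rows only, so no information leaks from the held-out rows through the
scaling.  The class order NC < LF < TR < SE is the documented encoding
and tie-break order.

The public surface follows a model/results pattern:
:class:`CompensationSVM` is built from a feature matrix, its
:meth:`~CompensationSVM.fit` returns a :class:`FittedCompensationSVM`,
and :meth:`~CompensationSVM.crossvalidate` returns an
:class:`EvaluationReport` carrying per-fold accuracies, the pooled
confusion matrix, per-class precision/recall/F1 and a ``summary()``
table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ConfigurationError, TrainingError
from .features import META_COLUMNS
from .recording import CLASSES


@dataclass
class ClassifierConfig:
    """Classifier and cross-validation settings.

    ``gamma_rule`` controls the RBF width: ``inverse_nfeat_var`` is
    1/(n_features * Var(X)) on the normalised training rows (sklearn's
    "scale"), ``inverse_nfeat`` is 1/n_features, ``fixed`` uses
    ``gamma_value``.  ``split_unit`` sets the cross-validation grain:
    ``window`` (random row-level split), ``trial`` (all windows of a
    trial stay together) or ``subject`` (leave-subjects-out).
    """

    C: float = 0.3
    kernel: str = "rbf"
    gamma_rule: str = "inverse_nfeat_var"
    gamma_value: Optional[float] = None
    multiclass: str = "one_vs_one"
    folds: int = 10
    split_unit: str = "window"
    normalization: str = "zscore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError("C must be > 0")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.kernel != "rbf":
            raise ConfigurationError("only the rbf kernel is supported")
        if self.gamma_rule not in ("inverse_nfeat_var", "inverse_nfeat", "fixed"):
            raise ConfigurationError(f"unknown gamma_rule {self.gamma_rule!r}")
        if self.gamma_rule == "fixed" and not self.gamma_value:
            raise ConfigurationError("gamma_rule='fixed' requires gamma_value")
        if self.split_unit not in ("window", "trial", "subject"):
            raise ConfigurationError(f"unknown split_unit {self.split_unit!r}")
        if self.normalization not in ("zscore", "minmax"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")

    @property
    def gamma(self):
        return {
            "inverse_nfeat_var": "scale",
            "inverse_nfeat": "auto",
            "fixed": self.gamma_value,
        }[self.gamma_rule]


class Normalizer:
    """Per-feature affine normalisation fitted on training rows only."""

    def __init__(self, kind: str = "zscore") -> None:
        if kind not in ("zscore", "minmax"):
            raise ConfigurationError(f"unknown normalization {kind!r}")
        self.kind = kind
        self.shift_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise TrainingError("cannot fit normalisation on empty data")
        if self.kind == "zscore":
            self.shift_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
        else:
            lo, hi = X.min(axis=0), X.max(axis=0)
            self.shift_, self.scale_ = lo, hi - lo
        zero = self.scale_ == 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature(s) mapped to 0",
                stacklevel=2,
            )
            # scale 1 with shift at the constant value maps the feature to 0
            self.scale_ = np.where(zero, 1.0, self.scale_)
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        if self.shift_ is None:
            raise TrainingError("Normalizer not fitted")
        return (np.asarray(X, dtype=float) - self.shift_) / self.scale_

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        if self.shift_ is None:
            raise TrainingError("Normalizer not fitted")
        return np.asarray(Z, dtype=float) * self.scale_ + self.shift_


def evaluate_metrics(confusion: np.ndarray, classes: Sequence[str] = CLASSES) -> Dict:
    """Per-class precision/recall/F1, accuracy and macro-F1 from a
    confusion matrix (rows = true, columns = predicted).

    Zero denominators (a class never predicted / never present) yield 0
    with a warning rather than NaN.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ConfigurationError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ConfigurationError("confusion matrix entries must be nonnegative")
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    total = float(cm.sum())

    def _safe(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        bad = den == 0
        if np.any(bad):
            warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
        return np.where(bad, 0.0, num / np.where(bad, 1.0, den))

    precision = _safe(diag, col, "precision")
    recall = _safe(diag, row, "recall")
    pr = precision + recall
    f1 = _safe(2 * precision * recall, np.where(pr == 0, 0.0, pr), "F1")
    per_class = {
        c: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for c, p, r, f in zip(classes, precision, recall, f1)
    }
    accuracy = float(diag.sum() / total) if total > 0 else 0.0
    if total == 0:
        warnings.warn("empty confusion matrix; all metrics 0", stacklevel=2)
    return {
        "per_class": per_class,
        "accuracy": accuracy,
        "macro_f1": float(np.mean(f1)),
    }


@dataclass
class EvaluationReport:
    """Cross-validation results.

    ``accuracy`` is the mean of the per-fold accuracies (the headline
    number); ``pooled_accuracy`` pools all held-out predictions into one
    confusion matrix first — both are reported because the averaging
    convention is a genuine degree of freedom.
    """

    fold_accuracies: List[float]
    confusion: np.ndarray  # pooled, rows = true, cols = predicted
    classes: Tuple[str, ...]
    per_class: Dict[str, Dict[str, float]]
    accuracy: float
    pooled_accuracy: float
    macro_f1: float
    config: ClassifierConfig
    feature_mode: str = ""  # provenance: signal type / window restriction
    #: per-fold diagnostics: training-side normalisation shift and the
    #: held-out row indices (not serialised; used to audit leakage)
    fold_details: Optional[List[Dict]] = None

    def summary(self) -> str:
        lines = []
        lines.append("Compensatory-movement SVM cross-validation")
        lines.append("=" * 58)
        cfg = self.config
        lines.append(
            f"kernel=rbf  C={cfg.C}  folds={cfg.folds}  split={cfg.split_unit}"
            f"  norm={cfg.normalization}  seed={cfg.seed}"
        )
        if self.feature_mode:
            lines.append(f"features: {self.feature_mode}")
        lines.append("-" * 58)
        lines.append(f"accuracy (mean of folds): {self.accuracy:8.4f}")
        lines.append(f"accuracy (pooled):        {self.pooled_accuracy:8.4f}")
        lines.append(f"macro F1:                 {self.macro_f1:8.4f}")
        lines.append("-" * 58)
        lines.append(f"{'class':>6} {'precision':>10} {'recall':>10} {'F1':>10}")
        for c in self.classes:
            m = self.per_class[c]
            lines.append(
                f"{c:>6} {m['precision']:>10.4f} {m['recall']:>10.4f} {m['f1']:>10.4f}"
            )
        lines.append("-" * 58)
        lines.append("confusion matrix (rows = true, cols = predicted)")
        header = "      " + "".join(f"{c:>8}" for c in self.classes)
        lines.append(header)
        for c, row in zip(self.classes, self.confusion):
            lines.append(f"{c:>6}" + "".join(f"{int(v):>8}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> Dict:
        return {
            "config": asdict(self.config),
            "feature_mode": self.feature_mode,
            "folds": [{"accuracy": a} for a in self.fold_accuracies],
            "confusion": self.confusion.astype(int).tolist(),
            "classes": list(self.classes),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "macro_f1": self.macro_f1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class CompensationSVM:
    """One-vs-one RBF-SVM model over a labeled feature matrix.

    Parameters
    ----------
    X : ndarray (n_rows, n_features)
    y : sequence of class labels (subset of NC/LF/TR/SE order)
    config : ClassifierConfig
    trial_ids, subject_ids : optional row annotations enabling
        trial-level / subject-level cross-validation splits.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[str],
        config: Optional[ClassifierConfig] = None,
        trial_ids: Optional[Sequence[str]] = None,
        subject_ids: Optional[Sequence[str]] = None,
        feature_mode: str = "",
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise TrainingError("X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise TrainingError("X must be finite")
        self.y = np.asarray(list(y))
        if len(self.y) != len(self.X):
            raise TrainingError("X and y lengths differ")
        self.classes = tuple(c for c in CLASSES if c in set(self.y))
        if len(self.classes) < 2:
            raise TrainingError("need at least 2 classes to train")
        unknown = set(self.y) - set(CLASSES)
        if unknown:
            raise TrainingError(f"unknown labels {sorted(unknown)}")
        self.config = config or ClassifierConfig()
        self.trial_ids = None if trial_ids is None else np.asarray(list(trial_ids))
        self.subject_ids = None if subject_ids is None else np.asarray(list(subject_ids))
        self.feature_mode = feature_mode
        # integer encoding in documented class order (tie-break order)
        self._code = {c: i for i, c in enumerate(CLASSES)}
        self._yc = np.array([self._code[c] for c in self.y])

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: Optional[ClassifierConfig] = None,
        label_col: str = "label",
        feature_mode: str = "",
    ) -> "CompensationSVM":
        """Build from a feature DataFrame (meta columns auto-detected)."""
        feat_cols = [c for c in df.columns if c not in META_COLUMNS and c != "subject_id"]
        trial_ids = df["trial_id"] if "trial_id" in df else None
        subject_ids = (
            df["subject_id"]
            if "subject_id" in df
            else (df["trial_id"].str.split("_").str[0] if "trial_id" in df else None)
        )
        return cls(
            df[feat_cols].to_numpy(dtype=float),
            df[label_col],
            config=config,
            trial_ids=trial_ids,
            subject_ids=subject_ids,
            feature_mode=feature_mode,
        )

    def _svc(self) -> SVC:
        cfg = self.config
        return SVC(
            C=cfg.C,
            kernel="rbf",
            gamma=cfg.gamma,
            decision_function_shape="ovo",
            cache_size=500,
        )

    def fit(self) -> "FittedCompensationSVM":
        """Train on all rows; returns the fitted model."""
        norm = Normalizer(self.config.normalization).fit(self.X)
        svc = self._svc()
        svc.fit(norm.apply(self.X), self._yc)
        return FittedCompensationSVM(model=self, normalizer=norm, svc=svc)

    # -- cross-validation ------------------------------------------------

    def _fold_indices(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        cfg = self.config
        n = len(self.y)
        if cfg.folds > n:
            raise TrainingError(f"folds ({cfg.folds}) exceed rows ({n})")
        if cfg.split_unit == "window":
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
            return list(skf.split(self.X, self._yc))
        if cfg.split_unit == "trial":
            if self.trial_ids is None:
                raise TrainingError("trial-level split requires trial_ids")
            units, labels = self.trial_ids, None
        else:
            if self.subject_ids is None:
                raise TrainingError("subject-level split requires subject_ids")
            units, labels = self.subject_ids, None
        uniq = pd.unique(units)
        if cfg.split_unit == "trial":
            # stratify trials by their class label
            unit_label = {u: self.y[units == u][0] for u in uniq}
            n_splits = min(cfg.folds, len(uniq))
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
            ul = np.array([unit_label[u] for u in uniq])
            folds = []
            for tr, te in skf.split(uniq.reshape(-1, 1), ul):
                te_units = set(uniq[te])
                mask = np.array([u in te_units for u in units])
                folds.append((np.nonzero(~mask)[0], np.nonzero(mask)[0]))
            return folds
        # subject-level: round-robin partition of shuffled subjects
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(uniq))
        n_splits = min(cfg.folds, len(uniq))
        folds = []
        for k in range(n_splits):
            te_units = set(uniq[order[k::n_splits]])
            mask = np.array([u in te_units for u in units])
            folds.append((np.nonzero(~mask)[0], np.nonzero(mask)[0]))
        return folds

    def crossvalidate(self) -> EvaluationReport:
        """Stratified k-fold cross-validation with per-fold normalisation."""
        k = len(CLASSES)
        confusion = np.zeros((k, k), dtype=int)
        fold_acc: List[float] = []
        fold_details: List[Dict] = []
        for tr_idx, te_idx in self._fold_indices():
            tr_y = self._yc[tr_idx]
            if len(np.unique(tr_y)) < 2:
                raise TrainingError("a training fold contains a single class")
            norm = Normalizer(self.config.normalization).fit(self.X[tr_idx])
            svc = self._svc()
            svc.fit(norm.apply(self.X[tr_idx]), tr_y)
            pred = svc.predict(norm.apply(self.X[te_idx]))
            true = self._yc[te_idx]
            fold_acc.append(float(np.mean(pred == true)))
            np.add.at(confusion, (true, pred), 1)
            fold_details.append(
                {
                    "test_indices": np.asarray(te_idx).copy(),
                    "norm_shift": norm.shift_.copy(),
                    "norm_scale": norm.scale_.copy(),
                }
            )
        metrics = evaluate_metrics(confusion, CLASSES)
        return EvaluationReport(
            fold_accuracies=fold_acc,
            confusion=confusion,
            classes=CLASSES,
            per_class=metrics["per_class"],
            accuracy=float(np.mean(fold_acc)),
            pooled_accuracy=metrics["accuracy"],
            macro_f1=metrics["macro_f1"],
            config=self.config,
            feature_mode=self.feature_mode,
            fold_details=fold_details,
        )


@dataclass
class FittedCompensationSVM:
    """A trained normaliser + SVM pair."""

    model: CompensationSVM
    normalizer: Normalizer
    svc: SVC

    def predict(self, X: np.ndarray) -> np.ndarray:
        codes = self.svc.predict(self.normalizer.apply(np.asarray(X, dtype=float)))
        return np.array([CLASSES[c] for c in codes])

    @property
    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.X) == self.model.y))
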