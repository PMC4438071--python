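"""SVM classification harness with leave-one-video-out and
leave-one-subject-out cross-validation.

The protocol mirrors the standard micro-expression evaluation: histogram
features per video, a support-vector classifier with a linear, RBF or
degree-6 polynomial kernel, and pooled recognition accuracy (correct test
predictions over all samples) under either

* LOVO — one fold per video, each video tested once against all others; or
* LOSO — one fold per subject, all of a subject's videos held out together,
  so accuracy is not inflated by subject identity leaking between folds.

Hyperparameters follow the common defaults of classical SVM tooling:
regularization C = 1, RBF/poly kernel width gamma = 1/n_features, one-vs-one
multi-class.  Features are assumed to be L1-normalized histograms already in
[0, 1]; an optional standardization switch exists but defaults off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "Sample",
    "Corpus",
    "CVScheme",
    "KernelSpec",
    "EvalReport",
    "make_folds",
    "cross_validated_accuracy",
]


@dataclass
class Sample:
    """One video sample: identifiers, label and (optionally) its feature row."""

    sample_id: str
    subject_id: str
    label: str
    features: np.ndarray | None = None
    video: np.ndarray | None = None


@dataclass
class Corpus:
    """A labeled multi-subject collection of samples."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids are not unique")
        lengths = {s.features.size for s in self.samples if s.features is not None}
        if len(lengths) > 1:
            raise ValueError(f"feature vectors have mixed lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def classes(self) -> list[str]:
        return sorted({s.label for s in self.samples})

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.samples})

    def feature_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) ordered by sample_id."""
        ordered = sorted(self.samples, key=lambda s: s.sample_id)
        missing = [s.sample_id for s in ordered if s.features is None]
        if missing:
            raise ValueError(f"samples without features: {missing[:5]}")
        X = np.stack([s.features for s in ordered])
        y = np.array([s.label for s in ordered])
        return X, y

    @classmethod
    def from_tables(cls, features: pd.DataFrame, labels: pd.DataFrame) -> "Corpus":
        """Build from a feature table (index sample_id) and a labels table
        with columns sample_id, subject_id, label."""
        labels = labels.set_index("sample_id") if "sample_id" in labels.columns else labels
        samples = []
        for sid, row in features.iterrows():
            if sid not in labels.index:
                raise KeyError(f"sample {sid!r} missing from labels table")
            meta = labels.loc[sid]
            samples.append(
                Sample(str(sid), str(meta["subject_id"]), str(meta["label"]),
                       row.to_numpy(dtype=float))
            )
        return cls(samples)


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation mode: 'lovo' (per video) or 'loso' (per subject)."""

    mode: Literal["lovo", "loso"] = "loso"

    def __post_init__(self) -> None:
        if self.mode not in ("lovo", "loso"):
            raise ValueError(f"mode must be 'lovo' or 'loso', got {self.mode!r}")


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel configuration."""

    kind: Literal["linear", "rbf", "poly"] = "linear"
    degree: int = 6
    C: float = 1.0
    gamma: float | str = "auto"  # 'auto' = 1/n_features

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf", "poly"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def build(self, seed: int) -> SVC:
        return SVC(
            kernel=self.kind,
            degree=self.degree,
            C=self.C,
            gamma=self.gamma,
            decision_function_shape="ovo",
            random_state=seed,
        )


@dataclass
class EvalReport:
    """Cross-validation outcome: pooled accuracy plus per-fold predictions."""

    accuracy: float
    predictions: pd.DataFrame  # columns: fold, sample_id, subject_id, true, predicted
    confusion: pd.DataFrame
    skipped_folds: list[int] = field(default_factory=list)


def make_folds(
    corpus: Corpus, scheme: CVScheme
) -> list[tuple[list[str], list[str]]]:
    """Ordered (train sample_ids, test sample_ids) pairs for the scheme.

    LOVO: one fold per sample.  LOSO: one fold per subject, that subject's
    videos all held out.  Ordering is deterministic (sorted by id).
    """
    if not corpus.samples:
        raise ValueError("empty corpus")
    ids = sorted(s.sample_id for s in corpus.samples)
    if scheme.mode == "lovo":
        return [([i for i in ids if i != test], [test]) for test in ids]
    subjects = corpus.subjects
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    by_subject = {
        subj: sorted(s.sample_id for s in corpus.samples if s.subject_id == subj)
        for subj in subjects
    }
    folds = []
    for subj in subjects:
        test = by_subject[subj]
        train = [i for i in ids if i not in set(test)]
        folds.append((train, test))
    return folds


def cross_validated_accuracy(
    corpus: Corpus,
    scheme: CVScheme,
    kernel: KernelSpec = KernelSpec(),
    seed: int = 0,
    *,
    standardize: bool = False,
) -> EvalReport:
    """Pooled cross-validated recognition accuracy.

    Accuracy = correctly classified test samples / all test samples, pooled
    over folds (not macro-averaged).  Folds whose training data lacks a
    second class are skipped with a warning and reported.  Fixed seed gives
    identical output regardless of sample ordering.
    """
    by_id = {s.sample_id: s for s in corpus.samples}
    folds = make_folds(corpus, scheme)
    rows = []
    skipped: list[int] = []
    for k, (train_ids, test_ids) in enumerate(folds):
        y_train = np.array([by_id[i].label for i in train_ids])
        if len(np.unique(y_train)) < 2:
            warnings.warn(
                f"fold {k}: training data has a single class; fold skipped",
                stacklevel=2,
            )
            skipped.append(k)
            continue
        X_train = np.stack([by_id[i].features for i in train_ids])
        X_test = np.stack([by_id[i].features for i in test_ids])
        if standardize:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        clf = kernel.build(seed)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        for i, p in zip(test_ids, pred):
            rows.append(
                {
                    "fold": k,
                    "sample_id": i,
                    "subject_id": by_id[i].subject_id,
                    "true": by_id[i].label,
                    "predicted": p,
                }
            )
    predictions = pd.DataFrame(
        rows, columns=["fold", "sample_id", "subject_id", "true", "predicted"]
    )
    if predictions.empty:
        raise ValueError("all folds were skipped; cannot compute accuracy")
    accuracy = float((predictions["true"] == predictions["predicted"]).mean())
    confusion = pd.crosstab(
        predictions["true"], predictions["predicted"], dropna=False
    ).reindex(index=corpus.classes, columns=corpus.classes, fill_value=0)
    return EvalReport(accuracy, predictions, confusion, skipped)
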