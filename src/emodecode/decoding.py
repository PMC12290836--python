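"""Within-subject binary decoding of trial labels from beta patterns.

Supports the two analysis shapes of the study:

* within-modality decoding with leave-one-block-out cross-validation
  (one fold per acquisition block; train on the other blocks), and
* directional cross-modal decoding (train on all trials of one
  modality, test on all trials of another; no CV because train and test
  sets are distinct by construction).

The classifier is a linear max-margin machine (C-SVC, C = 1 by
default); decoding accuracy is the percentage of correctly classified
test trials, averaged over folds, and the AUC is the rank statistic of
the pooled signed decision values (ties credited 0.5).

The same engine decodes any binary label column (emotion or modality)
from any feature matrix, which also covers the supplementary
modality-vs-modality and motion-parameter control analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._svm import smo_solve
from .datasets import ClassifierSpec, SubjectDataset, VoxelMask
from .errors import ConfigError, CrossValidationError, DesignError, MaskError

__all__ = [
    "TrialSelection",
    "DecodingSpec",
    "DecodingResult",
    "extract_features",
    "leave_one_block_out_folds",
    "decode",
    "decode_matrix",
    "compute_auc",
]


# ---------------------------------------------------------------------------
# selections and specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSelection:
    """Predicate over trial-table rows (None = no constraint)."""

    modalities: tuple[str, ...] | None = None
    emotions: tuple[str, ...] | None = None
    blocks: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("modalities", "emotions", "blocks"):
            val = getattr(self, name)
            if val is not None and not isinstance(val, tuple):
                object.__setattr__(self, name, tuple(val))

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(table), dtype=bool)
        if self.modalities is not None:
            m &= table["modality"].isin(self.modalities).to_numpy()
        if self.emotions is not None:
            m &= table["emotion"].isin(self.emotions).to_numpy()
        if self.blocks is not None:
            m &= table["block"].isin(self.blocks).to_numpy()
        return m

    @classmethod
    def modality(cls, *modalities: str) -> "TrialSelection":
        return cls(modalities=tuple(modalities))


@dataclass(frozen=True)
class DecodingSpec:
    """What to decode: label column, train/test selections, CV scheme.

    Invariants: ``cv='none'`` requires an explicit test selection
    disjoint from the training selection (checked against the actual
    trial table at decode time); ``cv='leave_one_block_out'`` requires
    train and test selections to coincide.
    """

    label_column: str = "emotion"
    train: TrialSelection = field(default_factory=TrialSelection)
    test: TrialSelection | None = None
    cv: str = "leave_one_block_out"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)

    def __post_init__(self) -> None:
        if self.label_column not in ("emotion", "modality"):
            raise ConfigError(f"unknown label column {self.label_column!r}")
        if self.cv not in ("leave_one_block_out", "none"):
            raise ConfigError(f"unknown cv scheme {self.cv!r}")
        if self.cv == "none" and self.test is None:
            raise ConfigError("cv='none' requires an explicit test selection")
        if self.cv == "leave_one_block_out" and self.test is not None \
                and self.test != self.train:
            raise ConfigError(
                "leave-one-block-out requires train and test selections to coincide"
            )

    @classmethod
    def within_modality(cls, modality: str, **kwargs) -> "DecodingSpec":
        return cls(train=TrialSelection.modality(modality), **kwargs)

    @classmethod
    def cross_modal(cls, train_modality: str, test_modality: str, **kwargs) -> "DecodingSpec":
        return cls(
            train=TrialSelection.modality(train_modality),
            test=TrialSelection.modality(test_modality),
            cv="none",
            **kwargs,
        )


@dataclass(frozen=True)
class DecodingResult:
    """Accuracy/AUC of one decode; one fold for cv='none'."""

    mean_accuracy: float
    fold_accuracies: tuple[float, ...]
    auc: float
    n_train: tuple[int, ...]
    n_test: tuple[int, ...]
    decision_values: np.ndarray
    true_labels: np.ndarray
    classes: tuple[str, str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)


# ---------------------------------------------------------------------------
# feature extraction and folds
# ---------------------------------------------------------------------------

def extract_features(
    dataset: SubjectDataset,
    mask: VoxelMask,
    selection: TrialSelection | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Feature matrix (selected trials x in-mask voxels) + matching rows.

    Columns follow the fixed lexicographic (x, y, z) voxel-index order of
    the mask-brain intersection, so the layout is reproducible and
    independent of how the mask was constructed.  Rows keep trial order.
    """
    mask.check_compatible(dataset.shape, dataset.space if mask.space != "native" else None)
    effective = mask.grid & dataset.brain_mask
    if not effective.any():
        raise MaskError(
            f"empty mask: {mask.name!r} does not intersect the brain mask"
        )
    sel_mask = selection.mask(dataset.trials.table) if selection is not None \
        else np.ones(dataset.n_trials, dtype=bool)
    if not sel_mask.any():
        raise MaskError("empty selection: no trials match the predicate")
    coords = np.argwhere(effective)  # C-order == lexicographic
    rows = np.nonzero(sel_mask)[0]
    X = dataset.betas[rows][:, coords[:, 0], coords[:, 1], coords[:, 2]]
    return np.ascontiguousarray(X), dataset.trials.table.iloc[rows].reset_index(drop=True)


def leave_one_block_out_folds(
    trials, selection: TrialSelection | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per block: test = that block's trials, train = all others.

    Indices are positions within the selected subset (trial order).
    Folds partition the selection; raises if fewer than two blocks.
    """
    table = trials.table if hasattr(trials, "table") else trials
    sel_mask = selection.mask(table) if selection is not None \
        else np.ones(len(table), dtype=bool)
    blocks = table.loc[sel_mask, "block"].to_numpy()
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise CrossValidationError(
            "cannot cross-validate: selection spans fewer than two blocks"
        )
    pos = np.arange(len(blocks))
    folds = []
    for b in uniq:
        test = pos[blocks == b]
        train = pos[blocks != b]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# numeric core (Gram-cached so permutation reruns are cheap)
# ---------------------------------------------------------------------------

class SplitCache:
    """Per-split Gram matrices; reusable across label permutations.

    Train-fitted z-scoring is label-independent, so it is applied before
    the Gram is built and stays valid for permuted labels.
    """

    __slots__ = ("train", "test", "K_train", "K_cross")

    def __init__(self, X_train: np.ndarray, X_test: np.ndarray,
                 train: np.ndarray, test: np.ndarray, scaling: str):
        if scaling == "zscore_train":
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd < 1e-12] = 1.0
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd
        self.train = train
        self.test = test
        self.K_train = np.ascontiguousarray(X_train @ X_train.T)
        self.K_cross = np.ascontiguousarray(X_test @ X_train.T)


def build_split_caches(
    X: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    scaling: str = "none",
) -> list[SplitCache]:
    return [SplitCache(X[tr], X[te], tr, te, scaling) for tr, te in splits]


def accuracy_from_caches(
    caches: Sequence[SplitCache],
    y_signed: np.ndarray,
    C: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the classifier over cached splits for a given label vector.

    Returns (fold accuracies in percent, pooled decision values, pooled
    signed true labels).  A decision value of exactly zero is classified
    as the negative (lexicographically first) class.
    """
    fold_acc = np.empty(len(caches))
    decisions = []
    labels = []
    for k, cache in enumerate(caches):
        y_tr = y_signed[cache.train]
        if np.all(y_tr > 0) or np.all(y_tr < 0):
            raise CrossValidationError(
                "cannot cross-validate: single-class training set in a fold"
            )
        alpha, b, _ = smo_solve(cache.K_train, y_tr, float(C), 1e-4, 100_000)
        d = cache.K_cross @ (alpha * y_tr) + b
        y_te = y_signed[cache.test]
        pred = np.where(d > 0, 1.0, -1.0)
        fold_acc[k] = 100.0 * np.mean(pred == y_te)
        decisions.append(d)
        labels.append(y_te)
    return fold_acc, np.concatenate(decisions), np.concatenate(labels)


def _signed_labels(labels: np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise DesignError(
            f"design mismatch: decoding needs exactly 2 classes, got {classes}"
        )
    y = np.where(np.asarray(labels) == classes[1], 1.0, -1.0)
    return y, (classes[0], classes[1])


def decode_matrix(
    X: np.ndarray,
    labels: Sequence[str],
    blocks: Sequence[int] | None = None,
    classifier: ClassifierSpec | None = None,
    cv: str = "leave_one_block_out",
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> DecodingResult:
    """Decode a binary label from an arbitrary feature matrix.

    Either ``blocks`` (for leave-one-block-out CV) or explicit
    ``splits`` (train/test row-index pairs) must be given.  This is the
    generic engine behind :func:`decode`; it also serves feature tables
    that are not voxel patterns (e.g. motion parameters).
    """
    classifier = classifier or ClassifierSpec()
    labels = np.asarray(labels)
    y_signed, classes = _signed_labels(labels)
    if splits is None:
        if cv != "leave_one_block_out" or blocks is None:
            raise ConfigError("decode_matrix needs blocks for CV or explicit splits")
        blocks = np.asarray(blocks)
        uniq = np.unique(blocks)
        if len(uniq) < 2:
            raise CrossValidationError(
                "cannot cross-validate: selection spans fewer than two blocks"
            )
        pos = np.arange(len(blocks))
        splits = [(pos[blocks != b], pos[blocks == b]) for b in uniq]
    caches = build_split_caches(np.asarray(X, dtype=np.float64), splits,
                                classifier.scaling)
    fold_acc, decisions, y_pooled = accuracy_from_caches(caches, y_signed, classifier.C)
    auc = _auc_signed(decisions, y_pooled)
    return DecodingResult(
        mean_accuracy=float(fold_acc.mean()),
        fold_accuracies=tuple(float(a) for a in fold_acc),
        auc=auc,
        n_train=tuple(len(c.train) for c in caches),
        n_test=tuple(len(c.test) for c in caches),
        decision_values=decisions,
        true_labels=np.where(y_pooled > 0, classes[1], classes[0]),
        classes=classes,
        provenance={
            "cv": cv,
            "C": classifier.C,
            "scaling": classifier.scaling,
            "n_features": int(np.asarray(X).shape[1]),
        },
    )


def decode(dataset: SubjectDataset, mask: VoxelMask, spec: DecodingSpec) -> DecodingResult:
    """Run one decoding analysis on a subject.

    Leave-one-block-out CV for within-modality specs; a single directed
    train/test split for cross-modal specs (with a leakage guard: the
    two selections must not share trials).
    """
    table = dataset.trials.table
    if spec.cv == "leave_one_block_out":
        X, sub = extract_features(dataset, mask, spec.train)
        folds = leave_one_block_out_folds(dataset.trials, spec.train)
        labels = sub[spec.label_column].to_numpy()
        result = decode_matrix(X, labels, classifier=spec.classifier, splits=folds)
        prov_cv = "leave_one_block_out"
    else:
        train_mask = spec.train.mask(table)
        test_mask = spec.test.mask(table)
        if (train_mask & test_mask).any():
            raise ConfigError(
                "leakage: cv='none' train and test selections share trials"
            )
        X_tr, sub_tr = extract_features(dataset, mask, spec.train)
        X_te, sub_te = extract_features(dataset, mask, spec.test)
        X = np.vstack([X_tr, X_te])
        labels = np.concatenate(
            [sub_tr[spec.label_column].to_numpy(), sub_te[spec.label_column].to_numpy()]
        )
        tr = np.arange(len(X_tr))
        te = np.arange(len(X_tr), len(X_tr) + len(X_te))
        result = decode_matrix(X, labels, classifier=spec.classifier, splits=[(tr, te)])
        prov_cv = "none"
    prov = dict(result.provenance)
    prov.update(cv=prov_cv, label_column=spec.label_column, mask=mask.name,
                subject=dataset.subject_id)
    return DecodingResult(
        mean_accuracy=result.mean_accuracy,
        fold_accuracies=result.fold_accuracies,
        auc=result.auc,
        n_train=result.n_train,
        n_test=result.n_test,
        decision_values=result.decision_values,
        true_labels=result.true_labels,
        classes=result.classes,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _auc_signed(decisions: np.ndarray, y_signed: np.ndarray) -> float:
    n_pos = int(np.sum(y_signed > 0))
    n_neg = int(np.sum(y_signed < 0))
    if len(decisions) < 2 or n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(decisions)  # average ranks: ties credited 0.5
    u = ranks[y_signed > 0].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auc(decision_values: Sequence[float], labels: Sequence[str],
                positive_label: str | None = None) -> float:
    """Area under the ROC curve from signed decision values.

    Equals P(score of a random positive-class trial > score of a random
    negative-class trial) + 0.5 P(tie); for emotion decoding the
    positive class is fear.  Invariant under strictly increasing score
    transforms.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise DesignError("design mismatch: AUC needs exactly 2 classes")
    pos = positive_label if positive_label is not None else classes[1]
    if pos not in classes:
        raise ConfigError(f"positive label {pos!r} not among classes {classes}")
    y_signed = np.where(labels == pos, 1.0, -1.0)
    return _auc_signed(np.asarray(decision_values, dtype=float), y_signed)
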