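"""Cross-subject linear-SVM decoding of pretrial-rest beta maps.

Each subject contributes one beta map per class (self coded +1, other coded
-1).  Validity is assessed with subject-level k-fold cross-validation (k=6 by
default, 5-6 subjects per fold at n=32) and a per-subject label-flip
permutation null; the pre-self pattern is the weight map of the SVM fit on
all subjects' maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .types import CvResult, PatternMap, PermutationNull

__all__ = [
    "FeatureMatrix",
    "assemble_features",
    "crossval_accuracy",
    "permutation_null",
    "derive_pattern",
    "mask_battery",
    "corrected_alpha",
]


@dataclass
class FeatureMatrix:
    """Rows are (subject, class) beta maps over in-mask voxels.

    Row order is subject-major with the self row first; labels are +1 (self)
    and -1 (other).
    """

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.X.shape[0] != len(self.y) or len(self.y) != len(self.subjects):
            raise ValueError("inconsistent row counts")
        uniq, counts = np.unique(self.subjects, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("expected exactly two rows per subject")
        self._unique_subjects = uniq

    @property
    def n_subjects(self) -> int:
        return len(self._unique_subjects)


def assemble_features(beta_pairs: Sequence[tuple[PatternMap, PatternMap]],
                      mask: np.ndarray,
                      subjects: Optional[Sequence[str]] = None) -> FeatureMatrix:
    """Stack per-subject (self, other) beta maps into a feature matrix.

    Columns are in-mask voxels in fixed C-scan order; any non-finite in-mask
    value is an error naming the offending voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if subjects is None:
        subjects = [f"sub-{i:04d}" for i in range(len(beta_pairs))]
    rows, labels, subj = [], [], []
    for sid, (m_self, m_other) in zip(subjects, beta_pairs):
        for pm, lab in ((m_self, +1), (m_other, -1)):
            if pm.values.shape != mask.shape:
                raise ValueError("beta map does not share the mask grid")
            v = pm.values[mask]
            bad = ~np.isfinite(v)
            if bad.any():
                vox = np.argwhere(mask)[np.flatnonzero(bad)[0]]
                raise ValueError(
                    f"non-finite value for subject {sid} at voxel {tuple(vox)}")
            rows.append(v)
            labels.append(lab)
            subj.append(sid)
    return FeatureMatrix(X=np.asarray(rows), y=np.asarray(labels),
                         subjects=np.asarray(subj), mask=mask)


def _fold_subjects(subjects: np.ndarray, k: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(subjects)
    return [np.asarray(f) for f in np.array_split(perm, k)]


def _kfold_accuracy(features: FeatureMatrix, folds: list[np.ndarray]):
    accs = []
    for test_subj in folds:
        test = np.isin(features.subjects, test_subj)
        train = ~test
        Xtr, Xte = features.X[train], features.X[test]
        # per-feature centering fit on the training fold only (no leakage)
        mu = Xtr.mean(axis=0)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xtr - mu, features.y[train])
        accs.append(float(np.mean(clf.predict(Xte - mu) == features.y[test])))
    return np.asarray(accs)


def crossval_accuracy(features: FeatureMatrix, k: int = 6,
                      seed: int = 0) -> CvResult:
    """Subject-level k-fold cross-validated accuracy of the linear SVM.

    Subjects are randomly partitioned (seed-controlled) into k near-equal
    folds; both rows of a subject stay in the same fold, so every train and
    test split is class balanced.
    """
    uniq = features._unique_subjects
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds {len(uniq)} subjects")
    rng = np.random.default_rng(seed)
    folds = _fold_subjects(uniq, k, rng)
    accs = _kfold_accuracy(features, folds)
    weights = np.array([2 * len(f) for f in folds], dtype=float)
    mean_acc = float(np.sum(accs * weights) / weights.sum())
    return CvResult(folds=[list(f) for f in folds], fold_accuracies=accs,
                    accuracy=mean_acc, k=k)


def permutation_null(features: FeatureMatrix, k: int = 6, n_perm: int = 1000,
                     seed: int = 0, observed: Optional[float] = None) -> PermutationNull:
    """Per-subject label-flip permutation null of the k-fold accuracy.

    Each permutation independently relabels each subject's (self, other) pair
    with probability 1/2, re-partitions subjects into folds, and reruns the
    full cross-validation; p is the add-one proportion of null accuracies at
    or above the observed accuracy (ties count against significance).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = crossval_accuracy(features, k=k, seed=seed).accuracy
    uniq = features._unique_subjects
    null = np.empty(n_perm)
    y0 = features.y.copy()
    for i in range(n_perm):
        flips = rng.random(len(uniq)) < 0.5
        flip_subj = uniq[flips]
        y = np.where(np.isin(features.subjects, flip_subj), -y0, y0)
        perm_feats = FeatureMatrix(X=features.X, y=y, subjects=features.subjects,
                                   mask=features.mask)
        folds = _fold_subjects(uniq, k, rng)
        accs = _kfold_accuracy(perm_feats, folds)
        weights = np.array([2 * len(f) for f in folds], dtype=float)
        null[i] = float(np.sum(accs * weights) / weights.sum())
    p = (np.sum(null >= observed) + 1.0) / (n_perm + 1.0)
    return PermutationNull(n_perm=n_perm, null_accuracies=null,
                           observed=float(observed), p=float(p), seed=seed)


def derive_pattern(features: FeatureMatrix) -> PatternMap:
    """Fit the linear SVM on all rows; map weights back to mask voxels.

    Positive weights favor the self class.
    """
    if np.allclose(features.X, features.X[0]):
        raise ValueError("degenerate features: all rows identical")
    mu = features.X.mean(axis=0)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(features.X - mu, features.y)
    w = clf.coef_.ravel()
    if features.mask is None:
        raise ValueError("feature matrix lacks a mask to map weights onto")
    vals = np.full(features.mask.shape, np.nan)
    vals[features.mask] = w
    return PatternMap(vals, features.mask, source="svm_weights", label="preself")


def corrected_alpha(battery_size: int, alpha_family: float = 0.05) -> float:
    """Bonferroni threshold for a battery of classifier models."""
    if battery_size < 1:
        raise ValueError("battery_size must be >= 1")
    return alpha_family / battery_size


def mask_battery(beta_pairs: Sequence[tuple[PatternMap, PatternMap]],
                 masks: dict[str, np.ndarray], k: int = 6, n_perm: int = 1000,
                 alpha_family: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Cross-validation + permutation test per mask, Bonferroni flagged."""
    if not masks:
        raise ValueError("need at least one mask")
    thresh = corrected_alpha(len(masks), alpha_family)
    rows = []
    for name, mask in masks.items():
        feats = assemble_features(beta_pairs, mask)
        cv = crossval_accuracy(feats, k=k, seed=seed)
        null = permutation_null(feats, k=k, n_perm=n_perm, seed=seed,
                                observed=cv.accuracy)
        rows.append({"mask": name, "n_voxels": int(mask.sum()),
                     "accuracy": cv.accuracy, "p": null.p,
                     "pass_corrected": null.p < thresh})
    out = pd.DataFrame(rows)
    out.attrs["corrected_alpha"] = thresh
    return out
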