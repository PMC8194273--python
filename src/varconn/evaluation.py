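"""Cross-validation designs, ROC/AUC, and cross-fold importance summaries.

Two K-fold designs are provided:

* *subject-unaware*: the K-way split is performed within each subject's
  segments and the per-subject chunks are stacked, so every subject
  contributes to both the training and the test side of every fold —
  the optimistic design;
* *leave-p-subjects-out*: subjects (not segments) are partitioned into K
  class-balanced groups, so test subjects are never seen in training —
  the clinically realistic design.

Per fold, a random forest is trained and ROC/AUC computed on the test
scores; Gini importances are aggregated across folds by minimum (was the
feature consistently important?) and mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .connectivity import FeatureTable
from .forest import RandomForest
from .io import ValidationError

Folds = list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx) per fold


def subject_unaware_folds(
    table: FeatureTable, n_folds: int, seed: int | None = None, shuffle: bool = False
) -> Folds:
    """K-fold split stratified *within* each subject.

    Each subject's segments (in temporal order, or shuffled when
    ``shuffle=True``) are cut into K near-equal chunks; fold k tests on
    the union of every subject's k-th chunk.  Folds are disjoint and
    cover all segments; every subject appears on both sides of every
    fold.
    """
    if n_folds < 2:
        raise ValidationError("K must be >= 2")
    rng = np.random.default_rng(seed)
    per_subject: dict[str, list[int]] = {}
    for i, (sid, seg_idx) in enumerate(zip(table.subject_ids, table.segment_indices)):
        per_subject.setdefault(sid, []).append(i)
    test_sets: list[list[int]] = [[] for _ in range(n_folds)]
    for sid, idx in per_subject.items():
        idx = sorted(idx, key=lambda i: table.segment_indices[i])
        if len(idx) < n_folds:
            raise ValidationError(
                f"subject {sid!r} has {len(idx)} segments, fewer than K={n_folds}"
            )
        idx = np.asarray(idx)
        if shuffle:
            rng.shuffle(idx)
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            test_sets[k].extend(chunk.tolist())
    all_idx = np.arange(table.n_segments)
    folds: Folds = []
    for k in range(n_folds):
        test = np.asarray(sorted(test_sets[k]), dtype=int)
        train = np.setdiff1d(all_idx, test)
        folds.append((train, test))
    return folds


def leave_p_subjects_out_folds(
    table: FeatureTable,
    n_folds: int,
    per_fold: tuple[int, int] = (2, 2),
    seed: int = 0,
) -> Folds:
    """K-fold split at the subject level, class balanced.

    ``per_fold`` = (controls, patients) held out per fold.  Subjects are
    assigned to folds by a seeded class-stratified shuffle; every fold
    tests on all segments of its held-out subjects, so no subject ever
    appears on both sides.
    """
    if n_folds < 2:
        raise ValidationError("K must be >= 2")
    subj_label: dict[str, int] = {}
    for sid, lab in zip(table.subject_ids, table.labels):
        prev = subj_label.setdefault(sid, int(lab))
        if prev != lab:
            raise ValidationError(f"subject {sid!r} has inconsistent labels")
    by_class = {
        c: sorted(s for s, l in subj_label.items() if l == c) for c in (0, 1)
    }
    n_ctrl, n_pat = per_fold
    if len(by_class[0]) != n_folds * n_ctrl or len(by_class[1]) != n_folds * n_pat:
        raise ValidationError(
            f"subject counts ({len(by_class[0])} controls, {len(by_class[1])} "
            f"patients) do not divide into {n_folds} folds of {per_fold}"
        )
    rng = np.random.default_rng(seed)
    groups: list[list[str]] = [[] for _ in range(n_folds)]
    for c, count in ((0, n_ctrl), (1, n_pat)):
        order = np.asarray(by_class[c], dtype=object)
        rng.shuffle(order)
        for k in range(n_folds):
            groups[k].extend(order[k * count : (k + 1) * count].tolist())
    sid_arr = np.asarray(table.subject_ids, dtype=object)
    all_idx = np.arange(table.n_segments)
    folds: Folds = []
    for k in range(n_folds):
        mask = np.isin(sid_arr, groups[k])
        folds.append((all_idx[~mask], all_idx[mask]))
    return folds


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC curve (threshold sweep) and trapezoidal AUC.

    The AUC equals the normalised Mann-Whitney U statistic; ties are
    handled by the midrank convention.  Returns ``((fpr, tpr), auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValidationError("both classes must be present to compute ROC/AUC")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return (fpr, tpr), auc


@dataclass
class FoldResult:
    """Per-fold test scores, ROC/AUC and normalised feature importances."""

    fold_index: int
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    importances: np.ndarray
    test_subjects: list[str] = field(default_factory=list)


def run_cv(
    table: FeatureTable,
    folds: Folds,
    n_trees: int = 200,
    min_leaf: int = 10,
    feature_fraction: float = 0.025,
    seed: int = 0,
) -> list[FoldResult]:
    """Train/evaluate one forest per fold; deterministic given ``seed``."""
    results = []
    for k, (train, test) in enumerate(folds):
        model = RandomForest(
            n_trees=n_trees, min_leaf=min_leaf,
            feature_fraction=feature_fraction, seed=seed * 1009 + k,
        ).fit(table.X[train], table.labels[train])
        scores = model.predict_proba(table.X[test])
        (fpr, tpr), auc = roc_auc(scores, table.labels[test])
        results.append(
            FoldResult(
                fold_index=k, scores=scores, labels=table.labels[test],
                fpr=fpr, tpr=tpr, auc=auc,
                importances=model.feature_importances_,
                test_subjects=sorted({table.subject_ids[i] for i in test}),
            )
        )
    return results


def mean_auc(results: Sequence[FoldResult]) -> float:
    """Unweighted arithmetic mean of the per-fold AUCs."""
    return float(np.mean([r.auc for r in results]))


@dataclass
class ImportanceSummary:
    """Min and mean feature importance across folds, with rankings."""

    feature_names: list[str]
    i_min: np.ndarray
    i_avg: np.ndarray

    def top(self, k: int = 10, by: str = "min") -> pd.DataFrame:
        """Top-k features ranked (descending) by ``'min'`` or ``'avg'``."""
        vals = {"min": self.i_min, "avg": self.i_avg}[by]
        order = np.argsort(-vals, kind="stable")[:k]
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in order],
                "i_min": self.i_min[order],
                "i_avg": self.i_avg[order],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "i_min": self.i_min, "i_avg": self.i_avg}
        )


def summarize_importance(
    results: Sequence[FoldResult], feature_names: Sequence[str]
) -> ImportanceSummary:
    """Per-feature minimum and mean importance over folds.

    The minimum flags features that were important in *every* fold; the
    mean aggregates overall relevance.
    """
    if not results:
        raise ValidationError("need at least one fold result")
    stack = np.stack([r.importances for r in results])
    if stack.shape[1] != len(feature_names):
        raise ValidationError("fold importances do not match the feature space")
    return ImportanceSummary(
        feature_names=list(feature_names),
        i_min=stack.min(axis=0),
        i_avg=stack.mean(axis=0),
    )
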