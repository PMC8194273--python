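"""Cross-validation partitioners, per-fold evaluation and importance summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varconn import (
    ValidationError,
    leave_p_subjects_out_folds,
    roc_auc,
    run_cv,
    subject_unaware_folds,
    summarize_importance,
)
from varconn.connectivity import FeatureTable
from varconn.evaluation import FoldResult, mean_auc


def synthetic_table(n_subjects=6, segs_per_subject=4, n_features=8, seed=0,
                    labels=None, effect=0.0):
    """A small feature table with optional class effect on feature 0."""
    rng = np.random.default_rng(seed)
    rows, sids, labs, segidx = [], [], [], []
    if labels is None:
        labels = [i % 2 for i in range(n_subjects)]
    for s in range(n_subjects):
        for k in range(segs_per_subject):
            x = rng.standard_normal(n_features)
            x[0] += effect * labels[s]
            rows.append(x)
            sids.append(f"s{s:02d}")
            labs.append(labels[s])
            segidx.append(k)
    return FeatureTable(
        X=np.array(rows), feature_names=[f"f{i}" for i in range(n_features)],
        subject_ids=sids, labels=np.array(labs), segment_indices=np.array(segidx),
    )


class TestSubjectUnawareFolds:
    def test_cohort_28x21_k7(self):
        table = synthetic_table(n_subjects=28, segs_per_subject=21)
        folds = subject_unaware_folds(table, 7)
        for train, test in folds:
            assert len(test) == 28 * 3
            train_subj = {table.subject_ids[i] for i in train}
            test_subj = {table.subject_ids[i] for i in test}
            assert train_subj == test_subj  # every subject on both sides

    def test_k_below_two_rejected(self):
        table = synthetic_table()
        with pytest.raises(ValidationError):
            subject_unaware_folds(table, 1)

    def test_subject_with_too_few_segments_named(self):
        table = synthetic_table(n_subjects=3, segs_per_subject=2)
        with pytest.raises(ValidationError, match="s0"):
            subject_unaware_folds(table, 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_subjects=st.integers(2, 8),
        segs=st.integers(2, 9),
        k=st.integers(2, 5),
    )
    def test_partition_property(self, n_subjects, segs, k):
        if segs < k:
            return
        table = synthetic_table(n_subjects=n_subjects, segs_per_subject=segs)
        folds = subject_unaware_folds(table, k)
        all_test = np.concatenate([t for _, t in folds])
        assert len(all_test) == len(set(all_test.tolist())) == table.n_segments
        for train, test in folds:
            assert set(train.tolist()).isdisjoint(test.tolist())
            assert len(train) + len(test) == table.n_segments


class TestLeavePSubjectsOutFolds:
    def test_cohort_14_14_k7(self):
        labels = [0] * 14 + [1] * 14
        table = synthetic_table(n_subjects=28, segs_per_subject=3, labels=labels)
        folds = leave_p_subjects_out_folds(table, 7, per_fold=(2, 2), seed=1)
        assert len(folds) == 7
        for train, test in folds:
            train_subj = {table.subject_ids[i] for i in train}
            test_subj = {table.subject_ids[i] for i in test}
            assert len(train_subj) == 24 and len(test_subj) == 4
            assert train_subj.isdisjoint(test_subj)
            test_labels = [table.labels[i] for i in test]
            assert sum(test_labels) == 2 * 3  # 2 patients x 3 segments

    def test_three_plus_three_k3(self):
        table = synthetic_table(n_subjects=6, segs_per_subject=2,
                                labels=[0, 0, 0, 1, 1, 1])
        folds = leave_p_subjects_out_folds(table, 3, per_fold=(1, 1), seed=0)
        assert len(folds) == 3
        covered = set()
        for _, test in folds:
            covered |= {table.subject_ids[i] for i in test}
        assert len(covered) == 6

    def test_indivisible_counts_rejected(self):
        table = synthetic_table(n_subjects=5, segs_per_subject=2,
                                labels=[0, 0, 0, 1, 1])
        with pytest.raises(ValidationError):
            leave_p_subjects_out_folds(table, 2, per_fold=(1, 1), seed=0)

    def test_no_subject_leakage_random_shapes(self):
        for seed in range(5):
            table = synthetic_table(n_subjects=8, segs_per_subject=3,
                                    labels=[0, 1] * 4, seed=seed)
            folds = leave_p_subjects_out_folds(table, 4, per_fold=(1, 1), seed=seed)
            for train, test in folds:
                assert not (
                    {table.subject_ids[i] for i in train}
                    & {table.subject_ids[i] for i in test}
                )


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_hand_counted_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRunCv:
    def test_strong_effect_high_auc(self):
        table = synthetic_table(n_subjects=8, segs_per_subject=6, effect=4.0,
                                labels=[0, 1] * 4, seed=3)
        folds = subject_unaware_folds(table, 3)
        results = run_cv(table, folds, n_trees=40, min_leaf=5,
                         feature_fraction=0.5, seed=0)
        assert len(results) == 3
        assert mean_auc(results) >= 0.95
        for r in results:
            assert r.importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_subject_level_shuffled_labels_chance_auc(self):
        aucs = []
        for seed in range(8):
            table = synthetic_table(n_subjects=8, segs_per_subject=6, effect=0.0,
                                    labels=[0, 1] * 4, seed=seed)
            folds = leave_p_subjects_out_folds(table, 4, per_fold=(1, 1), seed=seed)
            results = run_cv(table, folds, n_trees=30, min_leaf=5,
                             feature_fraction=0.5, seed=seed)
            aucs.append(mean_auc(results))
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_deterministic_given_seed(self):
        table = synthetic_table(n_subjects=6, segs_per_subject=4, effect=2.0)
        folds = subject_unaware_folds(table, 2)
        a = run_cv(table, folds, n_trees=10, min_leaf=3, feature_fraction=0.5, seed=5)
        b = run_cv(table, folds, n_trees=10, min_leaf=3, feature_fraction=0.5, seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.scores, rb.scores)
            np.testing.assert_array_equal(ra.importances, rb.importances)


class TestImportanceSummary:
    def _fold(self, k, imps):
        imps = np.asarray(imps, dtype=float)
        return FoldResult(
            fold_index=k, scores=np.array([0.2, 0.8]), labels=np.array([0, 1]),
            fpr=np.array([0, 1]), tpr=np.array([0, 1]), auc=1.0,
            importances=imps,
        )

    def test_single_fold_min_equals_avg(self):
        folds = [self._fold(0, [0.25, 0.75])]
        s = summarize_importance(folds, ["a", "b"])
        np.testing.assert_array_equal(s.i_min, s.i_avg)

    def test_min_and_avg_arithmetic(self):
        folds = [
            self._fold(0, [0.1, 0.9]),
            self._fold(1, [0.0, 1.0]),
            self._fold(2, [0.1, 0.9]),
        ]
        s = summarize_importance(folds, ["a", "b"])
        assert s.i_min[0] == pytest.approx(0.0)
        assert s.i_avg[0] == pytest.approx(0.2 / 3)

    def test_min_never_exceeds_avg(self):
        rng = np.random.default_rng(0)
        folds = []
        for k in range(5):
            v = rng.uniform(0, 1, 7)
            folds.append(self._fold(k, v / v.sum()))
        s = summarize_importance(folds, [f"f{i}" for i in range(7)])
        assert (s.i_min <= s.i_avg + 1e-12).all()

    def test_rankings_descending_and_named(self):
        folds = [self._fold(0, [0.2, 0.5, 0.3])]
        s = summarize_importance(folds, ["x", "y", "z"])
        top = s.top(3, by="avg")
        assert list(top["feature"]) == ["y", "z", "x"]
        assert top["i_avg"].is_monotonic_decreasing

    def test_mismatched_feature_space_rejected(self):
        with pytest.raises(ValidationError):
            summarize_importance([self._fold(0, [0.5, 0.5])], ["a", "b", "c"])
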