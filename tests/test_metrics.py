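"""Evaluation suite: AUROC, kappa, bootstrap, reader tests, cohort tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystovit.metrics import (
    AgreementMatrix,
    agreement_matrix,
    bootstrap_auc_ci,
    bootstrap_ci,
    classification_metrics,
    cohens_kappa,
    cohort_summary,
    confusion,
    macro_ovr_auc,
    paired_reader_test,
    roc_auc,
    task_report,
)
from cystovit.utils import percent, round_half_up


def pair_counting_auc(scores, labels):
    """Brute-force oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_textbook_four_subject_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_and_ties(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle_on_200_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)   # force some ties
            assert abs(roc_auc(scores, labels)
                       - pair_counting_auc(scores, labels)) < 1e-12

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                              st.integers(0, 1)), min_size=4, max_size=60))
    def test_complement_symmetry(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        flipped = [1 - y for y in labels]
        assert roc_auc(scores, labels) + roc_auc(scores, flipped) == \
            pytest.approx(1.0, abs=1e-12)


class TestMacroOvr:
    def test_one_hot_scores_give_perfect_macro(self):
        grades = np.array([0, 1, 2, 3, 4, 5, 2, 3])
        scores = np.eye(6)[grades]
        assert macro_ovr_auc(scores, grades) == 1.0

    def test_uniform_scores_give_half(self):
        grades = np.array([0, 1, 2, 0, 1, 2])
        assert macro_ovr_auc(np.full((6, 6), 1 / 6), grades) == pytest.approx(0.5)

    def test_matches_loop_oracle_on_nine_subject_table(self):
        grades = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        rng = np.random.default_rng(4)
        scores = rng.random((9, 6))
        with pytest.warns(UserWarning, match="absent"):
            got = macro_ovr_auc(scores, grades)
        expected = np.mean([pair_counting_auc(scores[:, g], (grades == g).astype(int))
                            for g in (0, 1, 2)])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_grade_rejected(self):
        with pytest.raises(ValueError):
            macro_ovr_auc(np.random.rand(4, 6), [2, 2, 2, 2])


class TestClassificationMetrics:
    def test_all_correct_is_all_ones(self):
        m = classification_metrics([1, 0, 1], [1, 0, 1])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == m["f1"] == 1.0

    def test_hand_counted_two_by_two(self):
        # TP=3, FN=1, TN=5, FP=1
        truth = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = classification_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.75)

    def test_inverted_predictions_on_balanced_data(self):
        truth = [0, 1, 0, 1]
        pred = [1, 0, 1, 0]
        assert classification_metrics(pred, truth)["accuracy"] == 0.0

    def test_six_class_macro_averages_present_grades(self):
        truth = [0, 0, 3, 3, 5]
        pred = [0, 3, 3, 3, 5]
        m = classification_metrics(pred, truth, n_classes=6)
        assert set(m["per_grade"]) == {0, 3, 5}
        assert m["sensitivity"] == pytest.approx(
            np.mean([m["per_grade"][g]["sensitivity"] for g in (0, 3, 5)]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestConfusion:
    def test_identity_for_perfect_and_total_count(self):
        assert np.array_equal(confusion([0, 1, 2], [0, 1, 2], 3), np.eye(3))
        C = confusion([0, 0, 1, 2, 2, 2], [0, 1, 1, 2, 0, 2], 3)
        assert C.sum() == 6

    def test_hand_tallied_three_by_three(self):
        truth = [0, 0, 1, 1, 2, 2, 2]
        pred = [0, 1, 1, 1, 2, 0, 2]
        expected = np.array([[1, 1, 0], [0, 2, 0], [1, 0, 2]])
        assert np.array_equal(confusion(pred, truth, 3), expected)


class TestKappa:
    def test_identical_ratings(self):
        assert cohens_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_hand_computed_two_by_two_table(self):
        # table [[20,5],[10,15]]: p_o=0.7, p_e=0.5 -> kappa 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, size=10000)
        b = rng.integers(0, 3, size=10000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 4, size=200)
        b = rng.integers(0, 4, size=200)
        perm = np.array([2, 0, 3, 1])
        assert cohens_kappa(perm[a], perm[b]) == pytest.approx(
            cohens_kappa(a, b), abs=1e-12)

    def test_degenerate_constant_raters(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        a = rng.integers(0, 4, size=300)
        b = (a + rng.integers(0, 2, size=300)) % 4
        assert cohens_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)

    def test_weighted_variants(self, rng):
        from sklearn.metrics import cohen_kappa_score
        a = rng.integers(0, 5, size=200)
        b = rng.integers(0, 5, size=200)
        for w in ("linear", "quadratic"):
            assert cohens_kappa(a, b, weighted=w) == pytest.approx(
                cohen_kappa_score(a, b, weights=w), abs=1e-12)


class TestBootstrap:
    def test_constant_statistic_gives_point_interval(self):
        lo, hi, redrawn = bootstrap_ci(lambda idx: 0.42, 50, B=100, seed=0)
        assert (lo, hi) == (0.42, 0.42)
        assert redrawn == 0

    def test_same_seed_reproduces_interval(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]

        def stat(idx):
            return roc_auc(scores[idx], labels[idx])

        a = bootstrap_ci(stat, 80, B=200, seed=3)
        b = bootstrap_ci(stat, 80, B=200, seed=3)
        assert a == b

    def test_interval_contains_point_estimate(self, rng):
        scores = rng.normal(size=200) + 1.2 * (labels := rng.integers(0, 2, 200))
        point = roc_auc(scores, labels)

        def stat(idx):
            return roc_auc(scores[idx], labels[idx])

        lo, hi, _ = bootstrap_ci(stat, 200, B=500, seed=1)
        assert lo <= point <= hi

    def test_vectorized_fast_path_matches_generic(self, rng):
        scores = rng.normal(size=200) + (labels := rng.integers(0, 2, 200))

        def stat(idx):
            return roc_auc(scores[idx], labels[idx])

        lo_a, hi_a, _ = bootstrap_ci(stat, 200, B=4000, seed=7)
        lo_b, hi_b = bootstrap_auc_ci(scores, labels, B=4000, seed=7)
        # same estimator, independent resampling streams: agree within MC error
        assert abs(lo_a - lo_b) < 0.015 and abs(hi_a - hi_b) < 0.015


class TestReaderComparisons:
    def test_identical_conditions(self):
        t, p = paired_reader_test([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_reader_test([0.9, 0.8, 0.7], [0.8, 0.7, 0.6])

    def test_four_reader_example_matches_textbook_formula(self):
        a = np.array([0.91, 0.84, 0.78, 0.88])
        b = np.array([0.86, 0.80, 0.77, 0.81])
        t, p = paired_reader_test(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert 0 < p < 1


class TestAgreement:
    def _table(self, ratings):
        rows = []
        for reader, values in ratings.items():
            for subject, v in enumerate(values):
                rows.append(dict(subject_id=f"S{subject}", reader_id=reader,
                                 condition="unassisted", task="lvur", value=v))
        return pd.DataFrame(rows)

    def test_identical_readers_give_all_ones(self):
        table = self._table({"r1": [0, 1, 2, 1], "r2": [0, 1, 2, 1]})
        mat = agreement_matrix(table, "unassisted")
        assert np.array_equal(mat.kappa, np.ones((2, 2)))
        assert mat.mean_kappa == 1.0

    def test_three_reader_mean_matches_hand_average(self):
        ratings = {"r1": [0, 1, 2, 1, 0, 2], "r2": [0, 1, 1, 1, 0, 2],
                   "r3": [0, 2, 2, 1, 1, 2]}
        mat = agreement_matrix(self._table(ratings), "unassisted")
        k12 = cohens_kappa(ratings["r1"], ratings["r2"])
        k13 = cohens_kappa(ratings["r1"], ratings["r3"])
        k23 = cohens_kappa(ratings["r2"], ratings["r3"])
        assert mat.mean_kappa == pytest.approx(np.mean([k12, k13, k23]))
        assert np.allclose(mat.kappa, mat.kappa.T)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            AgreementMatrix(readers=["a", "b"],
                            kappa=np.array([[1.0, 0.2], [0.3, 1.0]]))


class TestCohortSummary:
    def test_printed_style_percentages(self):
        assert percent(780, 1270) == 61.42
        assert percent(239, 381) == 62.73
        assert percent(541, 889) == 60.85
        assert round_half_up(0.125, 2) == 0.13   # half-up, not banker's

    def test_phantom_manifest_counts_are_exact(self, tmp_path):
        from cystovit import PhantomConfig, generate_dataset
        df = generate_dataset(PhantomConfig(n_patients=15, seed=2), tmp_path)
        summary = cohort_summary(df)
        assert summary["patients"] == 15
        assert summary["images"] == len(df)
        assert summary["male"][0] + summary["female"][0] == 15
        for side, col in (("left", "lvur"), ("right", "rvur")):
            counts = summary["grade_counts"][side]
            assert sum(counts.values()) == len(df)
            assert counts == {g: int((df[col] == g).sum()) for g in range(6)}
        assert summary["bladder"]["abnormal"][0] == int(df["bladder"].sum())

    def test_missing_columns_enumerated(self):
        with pytest.raises(ValueError, match="missing columns"):
            cohort_summary(pd.DataFrame({"patient_id": ["a"]}))


def test_task_report_invariants(rng):
    scores = rng.random((60, 2))
    scores /= scores.sum(axis=1, keepdims=True)
    truth = rng.integers(0, 2, size=60)
    truth[:2] = [0, 1]
    rep = task_report(scores, truth, "bladder", 2, B=200, seed=0)
    for name, v in rep.point.items():
        lo, hi = rep.ci[name]
        assert lo <= v <= hi
    assert rep.confusion.sum() == 60
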