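"""Ranking, forward selection, splitting, and confusion-matrix arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.model_selection import StratifiedKFold

from eegdem.classify import (ConfusionCounts, classify_task, encode_labels,
                             evaluate, f1_from_pr, forward_select,
                             metrics_from_counts, rank_features, split_and_cv)


class TestRankFeatures:
    def test_label_copy_ranks_first_with_r_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3], 30).astype(float)
        fm = pd.DataFrame({"noise": rng.standard_normal(90), "copy": y})
        ranked = rank_features(fm, y)
        assert ranked.iloc[0]["feature"] == "copy"
        assert ranked.iloc[0]["r"] == pytest.approx(1.0)

    def test_negated_labels_rank_first_by_magnitude(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1, 2, 3], 30).astype(float)
        fm = pd.DataFrame({"noise": rng.standard_normal(90), "neg": -y})
        ranked = rank_features(fm, y)
        assert ranked.iloc[0]["feature"] == "neg"
        assert ranked.iloc[0]["r"] == pytest.approx(-1.0)

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(2)
        y = np.repeat([1, 2, 3], 334)[:1000].astype(float)
        fm = pd.DataFrame({"noise": rng.standard_normal(1000)})
        assert rank_features(fm, y)["abs_r"].iloc[0] < 0.1

    def test_constant_feature_warns_and_gets_zero(self):
        y = np.repeat([1, 2], 10).astype(float)
        fm = pd.DataFrame({"const": np.ones(20), "ok": np.arange(20.0)})
        with pytest.warns(UserWarning):
            ranked = rank_features(fm, y)
        assert ranked.set_index("feature").loc["const", "r"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_features(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1, 1]))


class TestForwardSelect:
    def test_single_separating_feature(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1, 2], 50)
        sep = np.where(y == 1, -5.0, 5.0) + rng.normal(0, 0.1, 100)
        fm = pd.DataFrame({"sep": sep,
                           "noise": rng.standard_normal(100)})
        ranked = rank_features(fm, y.astype(float))
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        selected, curve = forward_select(ranked, fm, y, "lda", cv)
        assert selected == ["sep"]
        assert curve[0] == pytest.approx(1.0)

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(4)
        y = np.repeat([1, 2], 100)
        fm = pd.DataFrame(rng.standard_normal((200, 5)),
                          columns=list("abcde"))
        ranked = rank_features(fm, y.astype(float))
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        _, curve = forward_select(ranked, fm, y, "lda", cv)
        assert abs(curve.max() - 0.5) < 0.12   # ~2 binomial SDs at n=200

    def test_curve_length_matches_features_evaluated(self):
        rng = np.random.default_rng(5)
        y = np.repeat([1, 2], 20)
        fm = pd.DataFrame(rng.standard_normal((40, 7)),
                          columns=list("abcdefg"))
        ranked = rank_features(fm, y.astype(float))
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        _, curve = forward_select(ranked, fm, y, "svm", cv)
        assert len(curve) == 7
        _, curve3 = forward_select(ranked, fm, y, "svm", cv, max_features=3)
        assert len(curve3) == 3


class TestSplitAndCv:
    def test_eighty_twenty_arithmetic(self):
        y = np.repeat([1, 2], 50)
        x = pd.DataFrame({"f": np.arange(100.0)})
        tr, te, cv = split_and_cv(x, y, seed=0)
        assert len(tr) == 80 and len(te) == 20
        folds = list(cv.split(x.iloc[tr], y[tr]))
        assert all(len(va) == 16 for _, va in folds)

    def test_seed_reproducibility(self):
        y = np.repeat([1, 2, 3], 20)
        x = pd.DataFrame({"f": np.arange(60.0)})
        a = split_and_cv(x, y, seed=5)
        b = split_and_cv(x, y, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_grouped_mode_keeps_subjects_on_one_side(self):
        rng = np.random.default_rng(6)
        subjects = np.repeat(np.arange(30), 10)
        y = np.repeat(np.tile([1, 2, 3], 10), 10)
        x = pd.DataFrame({"f": rng.standard_normal(300)})
        tr, te, _ = split_and_cv(x, y, seed=0, groups=subjects)
        assert set(subjects[tr]).isdisjoint(subjects[te])

    def test_small_class_rejected(self):
        y = np.array([1] * 50 + [2] * 5)
        x = pd.DataFrame({"f": np.arange(55.0)})
        with pytest.raises(ValueError):
            split_and_cv(x, y, seed=0)


class TestEvaluate:
    def test_confusion_arithmetic(self):
        """TP=8, FN=2, FP=3, TN=7 -> RC 0.800, PC 0.727, F1 0.762, acc 0.750."""
        m = metrics_from_counts(ConfusionCounts(tp=8, tn=7, fp=3, fn=2))
        assert m["recall"] == pytest.approx(0.800, abs=5e-4)
        assert m["precision"] == pytest.approx(0.727, abs=5e-4)
        assert m["f1"] == pytest.approx(0.762, abs=5e-4)
        assert m["accuracy"] == pytest.approx(0.750, abs=5e-4)

    def test_perfect_predictions(self):
        y = np.array([1, 1, 2, 2, 2])
        m = evaluate(y, y)
        assert all(m[k] == 1.0 for k in ("recall", "precision", "f1",
                                         "accuracy"))

    def test_binary_positive_class_is_patient(self):
        y_true = np.array([1, 1, 1, 3, 3, 3])
        y_pred = np.array([1, 1, 3, 3, 3, 3])
        m = evaluate(y_true, y_pred)
        assert m["positive_class"] == 3
        assert m["recall"] == pytest.approx(1.0)       # all AD found
        assert m["precision"] == pytest.approx(0.75)

    def test_three_class_macro_average(self):
        y_true = np.array([1, 1, 2, 2, 3, 3])
        y_pred = np.array([1, 2, 2, 2, 3, 1])
        m = evaluate(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(4 / 6)
        per = m["per_class"]
        assert m["recall"] == pytest.approx(
            np.mean([per[c]["recall"] for c in (1, 2, 3)]))

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            evaluate(np.array([1]), np.array([1, 2]))

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_f1_bounds(self, pc, rc):
        f1 = f1_from_pr(pc, rc)
        assert f1 <= min(2 * rc, 2 * pc) + 1e-12
        assert f1 <= max(rc, pc) + 1e-12
        assert f1 >= min(rc, pc) - 1e-12


@pytest.fixture(scope="module")
def toy_cohort():
    """Separable three-class toy: one informative feature per epoch row."""
    rng = np.random.default_rng(7)
    rows = []
    for gi, group in enumerate(("HC", "MCI", "AD")):
        for s in range(12):
            sid = f"{group}{s}"
            for e in range(5):
                rows.append({"subject_id": sid, "epoch": e,
                             "signal": gi + rng.normal(0, 0.15),
                             "noise": rng.standard_normal()})
    fm = pd.DataFrame(rows)
    groups = fm["subject_id"].str.extract(r"([A-Z]+)")[0]
    return fm, groups


class TestClassifyTask:
    def test_three_class_task_on_separable_data(self, toy_cohort):
        fm, groups = toy_cohort
        rep = classify_task(fm, groups, fm["subject_id"], task="hc-mci-ad",
                            classifier="lda", seed=0)
        assert rep.metrics["accuracy"] > 0.9
        assert rep.selected_features[0] == "signal"

    def test_subject_split_mode_recorded(self, toy_cohort):
        fm, groups = toy_cohort
        rep = classify_task(fm, groups, fm["subject_id"], task="hc-mci",
                            classifier="svm", seed=0, split="subject")
        assert rep.split_mode == "subject"
        assert rep.metrics["accuracy"] > 0.9

    def test_encode_labels(self):
        np.testing.assert_array_equal(encode_labels(["HC", "AD", "MCI"]),
                                      [1, 3, 2])
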