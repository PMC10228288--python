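"""Tests for SVM training, majority voting and confusion-matrix metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import GroupKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from dermoct.classify import (
    BENIGN,
    MELANOMA,
    ConfusionMatrix,
    TrainedModel,
    TrainingError,
    assert_grouped_split,
    confusion,
    metrics,
    predict_image,
    tally_votes,
    train,
)

# Printed per-ROI vote counts and winners of the twelve held-out lesions
# used as a fixture for the majority-vote rule.
VOTE_TABLE = [
    ("melanoma", 150, 33, 117, "melanoma"),
    ("melanoma", 150, 33, 117, "melanoma"),
    ("melanoma", 147, 32, 115, "melanoma"),
    ("melanoma", 150, 30, 120, "melanoma"),
    ("melanoma", 150, 40, 110, "melanoma"),
    ("melanoma", 150, 25, 125, "melanoma"),
    ("benign", 152, 103, 49, "benign"),
    ("benign", 152, 106, 46, "benign"),
    ("benign", 152, 127, 25, "benign"),
    ("benign", 152, 132, 20, "benign"),
    ("benign", 152, 137, 15, "benign"),
    ("benign", 152, 141, 11, "benign"),
]

REFERENCE_CM = ConfusionMatrix(tp=746, tn=704, fp=193, fn=166)


def two_clouds(n=200, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0, 1, (n, 5))
    Xb = rng.normal(sep / np.sqrt(5), 1, (n, 5))
    X = np.vstack([Xa, Xb])
    y = np.array([BENIGN] * n + [MELANOMA] * n)
    return X, y


class TestTrain:
    def test_separable_clouds_fit_near_perfectly(self):
        X, y = two_clouds()
        model = train(X, y, seed=0)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_shuffled_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (400, 5))
        y = np.array([BENIGN, MELANOMA] * 200)
        groups = np.repeat(np.arange(40), 10)
        y = rng.permutation(y)
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        acc = cross_val_score(clf, X, y, groups=groups, cv=GroupKFold(5)).mean()
        assert 0.4 <= acc <= 0.6

    def test_single_class_input_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(TrainingError):
            train(X, np.array([BENIGN] * 10))

    def test_deterministic_given_seed(self):
        X, y = two_clouds(n=50)
        a = train(X, y, seed=3)
        b = train(X, y, seed=3)
        assert np.array_equal(a.support_vectors, b.support_vectors)
        assert np.array_equal(a.dual_coef, b.dual_coef)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = two_clouds(n=60, sep=2.0, seed=2)
        model = train(X, y, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = TrainedModel.from_json(path)
        Xt = two_clouds(n=40, sep=2.0, seed=9)[0]
        assert np.array_equal(model.predict(Xt), restored.predict(Xt))
        # the explicit kernel expansion matches sklearn's decision values
        assert np.allclose(model.decision_function(Xt), restored.decision_function(Xt))

    def test_column_mismatch_rejected(self):
        X, y = two_clouds(n=30)
        model = train(X, y)
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 4)))


class TestVoting:
    @pytest.mark.parametrize("true, n, nb, nm, winner", VOTE_TABLE)
    def test_published_vote_counts_reproduce_winners(self, true, n, nb, nm, winner):
        labels = [BENIGN] * nb + [MELANOMA] * nm
        assert nb + nm == n
        pred = tally_votes(labels)
        assert (pred.n_benign, pred.n_melanoma, pred.winner) == (nb, nm, winner)

    def test_tie_goes_to_melanoma_by_default(self):
        pred = tally_votes([BENIGN] * 5 + [MELANOMA] * 5)
        assert pred.winner == MELANOMA

    def test_tie_break_is_configurable(self):
        pred = tally_votes([BENIGN] * 5 + [MELANOMA] * 5, tie_break=BENIGN)
        assert pred.winner == BENIGN

    def test_vote_invariant_to_roi_ordering(self):
        rng = np.random.default_rng(7)
        labels = [BENIGN] * 30 + [MELANOMA] * 21
        shuffled = list(rng.permutation(labels))
        assert tally_votes(labels).winner == tally_votes(shuffled).winner

    def test_predict_image_counts_sum_to_roi_count(self):
        X, y = two_clouds(n=40, sep=2.0)
        model = train(X, y)
        pred = predict_image(model, X[:25], image_id="img0")
        assert pred.n_benign + pred.n_melanoma == 25

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            tally_votes(["benign", "basalioma"])


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        t = [BENIGN] * 10 + [MELANOMA] * 10
        cm = confusion(t, t)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    def test_all_benign_prediction(self):
        t = [BENIGN] * 10 + [MELANOMA] * 10
        cm = confusion(t, [BENIGN] * 20)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (10, 10, 0, 0)

    def test_reference_counts_round_trip(self):
        cm = REFERENCE_CM
        true = [BENIGN] * (cm.tp + cm.fn) + [MELANOMA] * (cm.fp + cm.tn)
        pred = (
            [BENIGN] * cm.tp + [MELANOMA] * cm.fn
            + [BENIGN] * cm.fp + [MELANOMA] * cm.tn
        )
        assert confusion(true, pred) == cm

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([BENIGN], [BENIGN, MELANOMA])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)


class TestMetrics:
    def test_reference_matrix_benign_row(self):
        m = metrics(REFERENCE_CM, positive_class=BENIGN)
        assert (m.precision_pct, m.recall_pct, m.f1_pct) == (79, 82, 81)

    def test_reference_matrix_melanoma_row(self):
        m = metrics(REFERENCE_CM, positive_class=MELANOMA)
        assert (m.precision_pct, m.recall_pct, m.f1_pct) == (81, 78, 80)

    def test_single_true_positive_is_all_100(self):
        m = metrics(ConfusionMatrix(tp=1, tn=0, fp=0, fn=0))
        assert (m.precision_pct, m.recall_pct, m.f1_pct) == (100, 100, 100)

    def test_zero_denominator_flags_undefined(self):
        m = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert m.undefined and np.isnan(m.precision)

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(0, 1000), tn=st.integers(0, 1000),
        fp=st.integers(0, 1000), fn=st.integers(0, 1000),
    )
    def test_swapping_classes_transposes_the_matrix(self, tp, tn, fp, fn):
        cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        sw = cm.swapped()
        assert (sw.tp, sw.tn, sw.fp, sw.fn) == (tn, tp, fn, fp)
        a = metrics(cm, positive_class=MELANOMA)
        b = metrics(sw, positive_class=BENIGN)
        assert (np.isnan(a.precision) and np.isnan(b.precision)) or a == b

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(1, 1000), tn=st.integers(0, 1000),
        fp=st.integers(0, 1000), fn=st.integers(0, 1000),
    )
    def test_f1_lies_between_precision_and_recall(self, tp, tn, fp, fn):
        m = metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12


class TestGroupedSplit:
    def test_overlapping_ids_rejected(self):
        with pytest.raises(TrainingError):
            assert_grouped_split(["a", "b"], ["b", "c"])

    def test_disjoint_ids_accepted(self):
        assert_grouped_split(["a", "b"], ["c", "d"])
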