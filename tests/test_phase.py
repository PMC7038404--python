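"""Phase labeling rule, point-set construction, and the SVM classifier."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grfest import (ClassifierSpec, SimulationConfig, build_point_sets,
                    evaluate_classifier, label_phases, simulate_study,
                    train_classifier)
from grfest.phase import FLIGHT, GROUND, PhaseClassifier


# ---------------------------------------------------------------- labeling

def test_threshold_rule_examples():
    labels = label_phases(np.array([0.06, 0.04, 0.05, 0.0, 2.5]))
    assert list(labels) == [GROUND, FLIGHT, GROUND, FLIGHT, GROUND]


def test_all_zero_series_is_all_flight():
    assert np.all(label_phases(np.zeros(50)) == FLIGHT)


def test_non_finite_rejected():
    with pytest.raises(ValueError):
        label_phases(np.array([0.1, np.nan]))


@given(st.lists(st.floats(0, 5, allow_nan=False), min_size=1, max_size=30),
       st.integers(0, 29), st.floats(0.0, 2.0))
def test_labeling_monotone_in_grf(values, idx, bump):
    """Raising any single sample never flips a ground label to flight."""
    grf = np.asarray(values)
    before = label_phases(grf)
    grf2 = grf.copy()
    grf2[idx % len(grf)] += bump
    after = label_phases(grf2)
    assert not np.any((before == GROUND) & (after == FLIGHT))


# -------------------------------------------------------------- point sets

def _two_type_study(n_subjects, jumps=1, seed=31):
    cfg = SimulationConfig(n_subjects=n_subjects, jumps_per_type=jumps,
                           seed=seed)
    return simulate_study(cfg)


def test_point_sets_balanced_and_sized():
    study = _two_type_study(3)
    spec = ClassifierSpec(sensor_subset=("sacrum",), seed=0)
    Xtr, ytr, Xte, yte = build_point_sets(study[:2], study[2:], spec)
    assert Xtr.shape == (500, 1) and ytr.shape == (500,)
    assert Xte.shape == (200, 1) and yte.shape == (200,)
    assert set(np.unique(ytr)) <= {FLIGHT, GROUND}


def test_point_sets_feature_dimension_follows_subset():
    study = _two_type_study(3)
    spec = ClassifierSpec(sensor_subset=("sacrum", "shin_l", "thoracic"))
    Xtr, *_ = build_point_sets(study[:2], study[2:], spec)
    assert Xtr.shape[1] == 3


def test_point_sets_deterministic_under_seed():
    study = _two_type_study(3)
    spec = ClassifierSpec(sensor_subset=("sacrum",), seed=7)
    a = build_point_sets(study[:2], study[2:], spec)
    b = build_point_sets(study[:2], study[2:], spec)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_point_sets_insufficient_points_error():
    study = _two_type_study(3)
    spec = ClassifierSpec(sensor_subset=("sacrum",), n_train=10 ** 6)
    with pytest.raises(ValueError, match="balanced points"):
        build_point_sets(study[:2], study[2:], spec)


# ------------------------------------------------------------- classifier

def _separable_points(n=500, seed=0):
    """Flight magnitudes in a band near 1 g, ground impacts well above."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.concatenate([rng.normal(1.0, 0.05, half),
                        np.abs(rng.normal(4.0, 0.5, n - half))])[:, None]
    y = np.concatenate([np.full(half, FLIGHT), np.full(n - half, GROUND)])
    return X, y.astype(np.int8)


def test_classifier_separable_high_cv_accuracy():
    X, y = _separable_points()
    clf = train_classifier(X, y, ClassifierSpec(seed=0))
    assert clf.cv_accuracy_ >= 0.99


def test_classifier_shuffled_labels_chance_accuracy(rng):
    X, y = _separable_points()
    clf = train_classifier(X, rng.permutation(y), ClassifierSpec(seed=0))
    assert 0.4 <= clf.cv_accuracy_ <= 0.6


def test_classifier_rejects_single_class():
    X, _ = _separable_points()
    with pytest.raises(ValueError, match="single class"):
        PhaseClassifier().fit(X, np.zeros(len(X)))


def test_classifier_duplication_invariance():
    # fixed hyperparameters: grid-search CV on duplicated folds may
    # legitimately break score ties differently
    X, y = _separable_points()
    kw = dict(C_grid=(10.0,), gamma_grid=(1.0,), seed=0)
    a = PhaseClassifier(**kw).fit(X, y)
    b = PhaseClassifier(**kw).fit(np.repeat(X, 2, axis=0), np.repeat(y, 2))
    grid = np.linspace(0, 6, 200)[:, None]
    np.testing.assert_array_equal(a.predict(grid), b.predict(grid))
    np.testing.assert_allclose(a.svm_.decision_function(grid),
                               b.svm_.decision_function(grid), atol=1e-6)


# ---------------------------------------------------------- confusion matrix

class _Stub:
    def __init__(self, out):
        self.out = np.asarray(out)

    def predict(self, X):
        return self.out[: len(X)]


def test_confusion_perfect_predictions():
    y = np.tile([FLIGHT, GROUND], 100)
    cm = evaluate_classifier(_Stub(y), np.zeros((200, 1)), y)
    assert cm.percent_overall == 100.0
    assert cm.n == 200


def test_confusion_all_ground_on_balanced_set():
    y = np.tile([FLIGHT, GROUND], 100)
    cm = evaluate_classifier(_Stub(np.full(200, GROUND)), np.zeros((200, 1)), y)
    assert cm.percent_overall == 50.0
    assert cm.percent_ground == 100.0 and cm.percent_flight == 0.0


def test_confusion_matches_brute_force_recount(rng):
    y = rng.integers(0, 2, 300).astype(np.int8)
    pred = rng.integers(0, 2, 300).astype(np.int8)
    cm = evaluate_classifier(_Stub(pred), np.zeros((300, 1)), y)
    assert cm.percent_overall == pytest.approx(
        100.0 * sum(int(a == b) for a, b in zip(pred, y)) / 300)
    assert cm.counts.sum() == 300
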