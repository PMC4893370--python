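"""Random forest training, ROC/AUC correctness, operating points, CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import pair_count_auc
from srtoct.classify import (ModelConfig, OperatingPoint, classify_at,
                             cross_validate, predict_scores, roc_curve,
                             select_operating_point, train)


def blobs(n_per_class=25, sep=4.0, d=3, seed=0):
    """Well-separated two-class Gaussian features (no scans needed)."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, 1.0, (n_per_class, d)),
                   rng.normal(sep, 1.0, (n_per_class, d))])
    y = np.repeat([0, 1], n_per_class)
    return X, y


# ---------------------------------------------------------------------------
# ROC / AUC


def test_auc_matches_pair_counting_fixed_example():
    roc = roc_curve(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    assert roc.auc == pytest.approx(0.75, abs=1e-12)
    assert roc.fpr[0] == roc.tpr[0] == 0.0
    assert roc.fpr[-1] == roc.tpr[-1] == 1.0
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(st.data())
def test_auc_equals_pair_statistic(data):
    """Trapezoidal AUC equals exhaustive pos/neg pair counting (ties = 1/2)."""
    n = data.draw(st.integers(4, 50))
    scores = np.array(data.draw(st.lists(
        st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n)))
    labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if labels.min() == labels.max():
        labels[0], labels[-1] = 0, 1
    assert roc_curve(scores, labels).auc == pytest.approx(
        pair_count_auc(scores, labels), abs=1e-12)


def test_auc_with_ties_uses_half_credit():
    scores = np.array([0.5, 0.5, 0.5, 0.5])
    labels = np.array([0, 1, 0, 1])
    assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=1e-12)


def test_chance_level_auc():
    rng = np.random.default_rng(123)
    scores = rng.random(1000)
    labels = rng.integers(0, 2, 1000)
    assert 0.45 <= roc_curve(scores, labels).auc <= 0.55


def test_roc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Operating points


def test_operating_points_on_enumerated_example():
    roc = roc_curve(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    op100 = select_operating_point(roc, "specificity_100")
    assert op100.threshold > 0.4
    assert op100.achieved_spec == 1.0 and op100.achieved_sens == 0.5
    op95 = select_operating_point(roc, "specificity_95")
    assert op95.achieved_spec >= 0.95
    sens100 = select_operating_point(roc, "sensitivity_100")
    assert sens100.achieved_sens == 1.0
    assert sens100.threshold < 0.35


def test_perfect_separation_hits_all_criteria():
    roc = roc_curve(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
    for criterion in ("specificity_100", "specificity_95", "sensitivity_100"):
        op = select_operating_point(roc, criterion)
        assert op.achieved_sens == 1.0 and op.achieved_spec == 1.0


def test_unknown_criterion_rejected():
    roc = roc_curve(np.array([0.1, 0.9]), np.array([0, 1]))
    with pytest.raises(ValueError, match="criterion"):
        select_operating_point(roc, "specificity_50")


# ---------------------------------------------------------------------------
# Training and prediction


def test_training_on_separable_data_and_determinism():
    X, y = blobs()
    cfg = ModelConfig(n_trees=50, seed=7)
    model = train(X, y, cfg)
    assert roc_curve(predict_scores(model, X), y).auc > 0.99
    X_test, _ = blobs(seed=99)
    s1 = predict_scores(model, X_test)
    s2 = predict_scores(train(X, y, cfg), X_test)
    np.testing.assert_array_equal(s1, s2)
    # training selects the clinical operating points
    assert set(model.operating_points) == {"specificity_100", "specificity_95",
                                           "sensitivity_100"}


def test_single_class_training_rejected():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="single class"):
        train(X, np.ones(10, dtype=int))


def test_score_at_threshold_is_negative_call():
    X, y = blobs(n_per_class=10)
    model = train(X, y, ModelConfig(n_trees=10, seed=0))
    score = float(predict_scores(model, X[:1])[0])
    op = OperatingPoint(criterion="specificity_95", threshold=score,
                        achieved_sens=1.0, achieved_spec=1.0)
    assert classify_at(model, X[:1], op)[0] == 0  # strict >


def test_raising_threshold_never_adds_positives():
    X, y = blobs()
    model = train(X, y, ModelConfig(n_trees=20, seed=1))
    scores = predict_scores(model, X)
    previous = None
    for thr in np.linspace(0, 1, 21):
        op = OperatingPoint("specificity_95", thr, 0, 0)
        n_pos = int(classify_at(model, X, op).sum())
        if previous is not None:
            assert n_pos <= previous
        previous = n_pos
    assert np.all((scores >= 0) & (scores <= 1))


def test_feature_length_mismatch_rejected():
    X, y = blobs(d=4)
    model = train(X, y, ModelConfig(n_trees=5, seed=0))
    with pytest.raises(ValueError, match="feature length"):
        predict_scores(model, X[:, :3])


# ---------------------------------------------------------------------------
# Cross-validation


def test_cross_validation_separable_null_and_determinism():
    X, y = blobs(n_per_class=30)
    cfg = ModelConfig(n_trees=25, cv_iterations=10, seed=11)
    cv = cross_validate(X, y, cfg)
    assert cv.aucs.size == 10
    assert cv.mean_auc > 0.95
    cv2 = cross_validate(X, y, cfg)
    np.testing.assert_array_equal(cv.aucs, cv2.aucs)

    # permuted labels destroy separability
    rng = np.random.default_rng(5)
    y_perm = rng.permutation(y)
    cv_null = cross_validate(X, y_perm, cfg)
    assert 0.35 <= cv_null.mean_auc <= 0.65


def test_cross_validation_split_sizes():
    X, y = blobs(n_per_class=20)
    cfg = ModelConfig(cv_iterations=3, n_trees=5, train_fraction=102 / 153, seed=2)
    cv = cross_validate(X, y, cfg)
    # pooled held-out scores: ceil(40 * (1 - 102/153)) = 14 per iteration
    assert cv.pooled_scores.size == 3 * 14
    assert cv.pooled_auc > 0.9


def test_cross_validation_needs_samples():
    with pytest.raises(ValueError, match="at least 4"):
        cross_validate(np.zeros((3, 2)), np.array([0, 1, 1]))
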