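"""Classifiers: MLE oracle checks, boosting guarantees, shared contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import adpep
from adpep import classify as clf


@pytest.fixture(scope="module")
def rng_local():
    return np.random.default_rng(99)


def blobs(rng, n=200, sep=4.0):
    n2 = n // 2
    X = np.vstack([rng.normal(0, 1, size=(n2, 2)),
                   rng.normal(sep, 1, size=(n - n2, 2))])
    y = np.r_[np.zeros(n2, dtype=int), np.ones(n - n2, dtype=int)]
    return X, y


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_logistic_intercept_only_reduction():
    X = np.zeros((40, 3))
    y = np.r_[np.ones(10, dtype=int), np.zeros(30, dtype=int)]
    model = clf.train_logistic(X, y)
    assert model.parameters["beta0"] == pytest.approx(np.log(0.25 / 0.75),
                                                      abs=1e-8)
    assert np.allclose(model.parameters["beta"], 0, atol=1e-8)
    assert np.allclose(model.predict_proba(X), 0.25, atol=1e-8)


def test_logistic_matches_generic_optimizer_on_worked_dataset():
    """Small worked fit cross-checked against scipy on the log-likelihood."""
    X = np.array([[0.0], [1.0], [2.0], [3.0], [1.0], [2.0]])
    y = np.array([0, 0, 1, 1, 1, 0])  # overlapping classes: finite MLE

    def negll(params):
        eta = params[0] + X.ravel() * params[1]
        return -np.sum(y * eta - np.logaddexp(0, eta))

    ref = optimize.minimize(negll, [0.0, 0.0], method="BFGS",
                            options={"gtol": 1e-12})
    model = clf.train_logistic(X, y)
    assert model.parameters["beta0"] == pytest.approx(ref.x[0], abs=1e-4)
    assert model.parameters["beta"][0] == pytest.approx(ref.x[1], abs=1e-4)


def test_logistic_near_separable_limit():
    X = np.array([[0.0], [0.0], [1.0], [1.0], [0.0], [1.0]])
    y = np.array([0, 0, 1, 1, 0, 1])
    with pytest.warns(RuntimeWarning):
        model = clf.train_logistic(X, y)
    p = model.predict_proba(X)
    assert (p[y == 1] > 0.99).all() and (p[y == 0] < 0.01).all()


def test_logistic_rescaling_equivariance(rng_local):
    X, y = blobs(rng_local, sep=2.0)
    m1 = clf.train_logistic(X, y)
    scale = 7.5
    m2 = clf.train_logistic(X * np.array([scale, 1.0]), y)
    assert m2.parameters["beta"][0] * scale == pytest.approx(
        m1.parameters["beta"][0], rel=1e-5)
    assert np.allclose(m1.predict_proba(X),
                       m2.predict_proba(X * np.array([scale, 1.0])),
                       atol=1e-7)


def test_logistic_label_swap_symmetry(rng_local):
    X, y = blobs(rng_local, sep=2.0)
    p = clf.train_logistic(X, y).predict_proba(X)
    q = clf.train_logistic(X, 1 - y).predict_proba(X)
    assert np.allclose(p, 1 - q, atol=1e-7)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def test_svm_separates_blobs(rng_local):
    X, y = blobs(rng_local, n=200, sep=4.0)
    model = clf.train_svm(X, y, seed=0)
    assert (model.predict(X) == y).mean() >= 0.99
    p = model.predict_proba(X)
    assert ((p >= 0) & (p <= 1)).all()


def test_svm_duplication_leaves_boundary_unchanged(rng_local):
    X, y = blobs(rng_local, n=120, sep=3.0)
    m1 = clf.train_svm(X, y, seed=0)
    m2 = clf.train_svm(np.vstack([X, X]), np.r_[y, y], seed=0)
    # the induced classification of the training sample is unchanged
    assert (m1.predict(X) == m2.predict(X)).all()
    # and the decision surfaces agree closely away from the margin
    s1, s2 = m1.decision_scores(X), m2.decision_scores(X)
    mask = np.abs(s1) > 0.5
    assert (np.sign(s1[mask]) == np.sign(s2[mask])).all()


def test_svm_two_point_margin_midpoint():
    X = np.array([[0.0, 0.0], [2.0, 0.0]])
    y = np.array([0, 1])
    model = clf.train_svm(X, y, kernel="linear")
    # the midpoint of the two support vectors is on the decision boundary
    assert model.decision_scores(np.array([[1.0, 0.0]]))[0] == \
        pytest.approx(0.0, abs=1e-6)


def test_svm_rejects_unknown_kernel(rng_local):
    X, y = blobs(rng_local, n=40)
    with pytest.raises(ValueError, match="kernel"):
        clf.train_svm(X, y, kernel="poly3-custom")


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

def test_adaboost_degenerate_single_stump():
    X = np.array([[0.1], [0.2], [0.8], [0.9]])
    y = np.array([0, 0, 1, 1])
    model = clf.train_adaboost(X, y, rounds=50)
    stumps = model.parameters["stumps"]
    assert len(stumps) == 1 and stumps[0]["error"] == 0.0
    assert (model.predict(X) == y).all()


def test_adaboost_round_guarantees(rng_local):
    X = rng_local.normal(size=(150, 5))
    y = (X[:, 0] + 0.6 * X[:, 1] + rng_local.normal(0, 0.8, 150) > 0)
    model = clf.train_adaboost(X, y.astype(int), rounds=40)
    errors = [s["error"] for s in model.parameters["stumps"]]
    assert all(e < 0.5 for e in errors)
    # classic exponential-loss bound on training error
    bound = np.prod([2 * np.sqrt(e * (1 - e)) for e in errors])
    train_err = (model.predict(X) != y).mean()
    assert train_err <= bound + 1e-12


def test_adaboost_training_error_nonincreasing_in_rounds(rng_local):
    X = rng_local.normal(size=(120, 4))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)  # needs several stumps
    errs = []
    for T in (1, 5, 20, 60):
        m = clf.train_adaboost(X, y, rounds=T)
        errs.append((m.predict(X) != y).mean())
    assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


def test_adaboost_deterministic_and_label_symmetric(rng_local):
    X = rng_local.normal(size=(80, 3))
    y = (X[:, 0] > 0.2).astype(int)
    m1 = clf.train_adaboost(X, y, rounds=25)
    m2 = clf.train_adaboost(X, y, rounds=25)
    assert m1.to_json() == m2.to_json()
    p = m1.predict_proba(X)
    q = clf.train_adaboost(X, 1 - y, rounds=25).predict_proba(X)
    assert np.allclose(p, 1 - q, atol=1e-12)


def test_adaboost_rejects_bad_rounds(rng_local):
    X = rng_local.normal(size=(10, 2))
    y = (X[:, 0] > 0).astype(int)
    with pytest.raises(ValueError):
        clf.train_adaboost(X, y, rounds=0)


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------

def test_predict_is_thresholded_proba(rng_local):
    X, y = blobs(rng_local, n=100, sep=1.0)
    for method in ("logistic", "svm", "adaboost"):
        model = clf.train(method, X, y)
        p = model.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()
        assert (model.predict(X) == (p >= 0.5).astype(int)).all()


def test_zero_model_ties_go_to_class_one():
    model = clf.TrainedClassifier(
        method="logistic", feature_names=["a"],
        parameters={"beta": np.zeros(1), "beta0": 0.0})
    X = np.array([[1.0], [2.0]])
    assert np.allclose(model.predict_proba(X), 0.5)
    assert (model.predict(X) == 1).all()


def test_feature_mismatch_is_named(rng_local):
    X = pd.DataFrame(rng_local.normal(size=(30, 2)), columns=["a", "b"])
    y = (X["a"] > 0).astype(int).to_numpy()
    model = clf.train_logistic(X, y)
    bad = X.rename(columns={"b": "c"})
    with pytest.raises(clf.FeatureMismatchError, match="b"):
        model.predict(bad)


@pytest.mark.parametrize("method", ["logistic", "svm", "adaboost"])
def test_serialization_roundtrip(method, rng_local):
    X, y = blobs(rng_local, n=80, sep=2.0)
    model = clf.train(method, X, y)
    clone = clf.TrainedClassifier.from_json(model.to_json())
    assert np.allclose(model.predict_proba(X), clone.predict_proba(X),
                       atol=1e-12)
    assert clone.feature_names == model.feature_names


def test_dual_efficacy_flag():
    probs = np.array([0.5, 0.95, 0.41, 0.59, 0.05])
    flags = adpep.dual_efficacy_flag(probs, delta=0.1)
    assert flags.tolist() == [True, False, True, True, False]
    # monotone non-decreasing coverage in delta
    fractions = [adpep.dual_efficacy_flag(probs, d).mean()
                 for d in (0.01, 0.1, 0.3, 0.49)]
    assert all(a <= b for a, b in zip(fractions, fractions[1:]))
    with pytest.raises(ValueError):
        adpep.dual_efficacy_flag(probs, delta=0.6)
    with pytest.raises(ValueError):
        adpep.dual_efficacy_flag(np.array([1.2]), delta=0.1)
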