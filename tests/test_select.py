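"""Lasso selection: limiting cases, optimality conditions, recovery."""

import numpy as np
import pandas as pd
import pytest

from adpep import select as sel


def make_logistic_data(rng, n=300, p=20, informative=0, coef=2.0):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i:03d}" for i in range(p)])
    beta = np.zeros(p)
    beta[:informative] = coef
    eta = X.to_numpy() @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    # ensure both classes
    y[0], y[1] = 0, 1
    return X, y


@pytest.fixture(scope="module")
def rng_local():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_moments_and_roundtrip(rng_local):
    X, _ = make_logistic_data(rng_local)
    X["const"] = 3.5
    Xs, rec = sel.standardize(X)
    assert np.allclose(Xs.mean(), 0, atol=1e-12)
    nonconst = [c for c in X.columns if c != "const"]
    assert np.allclose(Xs[nonconst].std(ddof=0), 1, atol=1e-12)
    assert rec.zero_variance == ["const"]
    # constant column centered, not scaled
    assert np.allclose(Xs["const"], 0)
    # round trip
    back = rec.inverse_transform(Xs)
    assert np.allclose(back.to_numpy(), X.to_numpy(), atol=1e-9)
    # idempotent on already-standardized values
    Xs2, _ = sel.standardize(Xs[nonconst])
    assert np.allclose(Xs2.to_numpy(), Xs[nonconst].to_numpy(), atol=1e-9)


def test_standardize_rejects_nonfinite():
    X = pd.DataFrame({"a": [1.0, np.nan, 2.0]})
    with pytest.raises(ValueError):
        sel.standardize(X)


# ---------------------------------------------------------------------------
# path behaviour
# ---------------------------------------------------------------------------

def test_all_zero_at_lambda_max(rng_local):
    X, y = make_logistic_data(rng_local, informative=3)
    Xs, _ = sel.standardize(X)
    lmax = sel.lambda_max(Xs, y)
    path = sel.fit_lasso_path(Xs, y, lambda_grid=np.array([lmax * 1.01,
                                                           lmax]))
    assert path.nonzero_counts()[0] == 0
    assert path.nonzero_counts()[1] == 0
    assert sel.selected_features(path, lmax) == []


def test_tiny_lambda_matches_unpenalized_mle(rng_local):
    """Near lambda = 0 the fit approaches the ordinary logistic MLE."""
    import statsmodels.api as sm
    X, y = make_logistic_data(rng_local, n=400, p=4, informative=2, coef=1.0)
    path = sel.fit_lasso_path(
        X, y, lambda_grid=np.geomspace(sel.lambda_max(X, y), 1e-6, 8),
        tol=1e-8)
    ours = path.coefficients.iloc[:, -1].to_numpy()
    mle = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
    assert np.allclose(ours, mle.params[1:], atol=2e-3)
    assert path.intercepts[-1] == pytest.approx(mle.params[0], abs=2e-3)


def test_kkt_conditions_along_path(rng_local):
    X, y = make_logistic_data(rng_local, n=250, p=15, informative=3)
    Xs, _ = sel.standardize(X)
    path = sel.fit_lasso_path(Xs, y, n_lambda=12, tol=1e-8)
    Xv = Xs.to_numpy()
    for i in range(len(path.lambda_grid)):
        viol = sel.kkt_violation(Xv, y.astype(float),
                                 path.coefficients.iloc[:, i].to_numpy(),
                                 path.intercepts[i], path.lambda_grid[i])
        assert viol < 1e-3 * max(1.0, path.lambda_grid[i])


def test_agrees_with_liblinear(rng_local):
    """Independent solver cross-check at a mid-path penalty."""
    from sklearn.linear_model import LogisticRegression
    X, y = make_logistic_data(rng_local, n=300, p=10, informative=3)
    Xs, _ = sel.standardize(X)
    lam = sel.lambda_max(Xs, y) * 0.05
    path = sel.fit_lasso_path(Xs, y, lambda_grid=np.array([lam]), tol=1e-9)
    ref = LogisticRegression(penalty="l1", C=1.0 / lam, solver="liblinear",
                             tol=1e-9, max_iter=100_000,
                             intercept_scaling=1000.0)
    ref.fit(Xs.to_numpy(), y)
    assert np.allclose(path.coefficients.iloc[:, 0].to_numpy(),
                       ref.coef_.ravel(), atol=5e-4)


def test_nonzero_counts_monotone_at_large_lambda_end(rng_local):
    X, y = make_logistic_data(rng_local, n=300, p=25, informative=5)
    Xs, _ = sel.standardize(X)
    path = sel.fit_lasso_path(Xs, y, n_lambda=30, min_ratio=1e-2)
    counts = path.nonzero_counts()
    head = counts[:10]  # large-lambda end of the decreasing grid
    assert all(a <= b for a, b in zip(head, head[1:]))


def test_path_continuity_under_warm_starts(rng_local):
    X, y = make_logistic_data(rng_local, n=300, p=10, informative=3)
    Xs, _ = sel.standardize(X)
    path = sel.fit_lasso_path(Xs, y, n_lambda=60, min_ratio=1e-2)
    deltas = np.abs(np.diff(path.coefficients.to_numpy(), axis=1)).max(axis=0)
    assert np.median(deltas) < 0.1


def test_selection_invariant_to_column_permutation(rng_local):
    X, y = make_logistic_data(rng_local, n=300, p=12, informative=4)
    perm = list(np.random.default_rng(5).permutation(X.columns))
    a = sel.select_features(X, y, n_lambda=20, min_ratio=1e-2, folds=5)
    b = sel.select_features(X[perm], y, n_lambda=20, min_ratio=1e-2, folds=5)
    assert set(a.selected_features) == set(b.selected_features)


# ---------------------------------------------------------------------------
# penalty choice
# ---------------------------------------------------------------------------

def test_choose_lambda_single_point_grid(rng_local):
    X, y = make_logistic_data(rng_local, n=120, p=5, informative=2)
    Xs, _ = sel.standardize(X)
    lam = sel.lambda_max(Xs, y) * 0.1
    path = sel.fit_lasso_path(Xs, y, lambda_grid=np.array([lam]))
    assert sel.choose_lambda(path, Xs, y, folds=5) == lam


def test_choose_lambda_minimizer_property(rng_local):
    X, y = make_logistic_data(rng_local, n=300, p=10, informative=3)
    Xs, _ = sel.standardize(X)
    path = sel.fit_lasso_path(Xs, y, n_lambda=15, min_ratio=1e-2)
    chosen = sel.choose_lambda(path, Xs, y, folds=5, seed=3)
    dev = path.cv_deviance.set_index("lambda")["mean_deviance"]
    assert dev[chosen] <= dev.iloc[0] + 1e-12  # beats the all-zero model


def test_pure_noise_selects_nearly_nothing(rng_local):
    X, y = make_logistic_data(rng_local, n=400, p=50, informative=0)
    path = sel.select_features(X, y, n_lambda=25, folds=5, seed=1)
    assert len(path.selected_features) <= 5


def test_planted_features_recovered(rng_local):
    X, y = make_logistic_data(rng_local, n=500, p=60, informative=5,
                              coef=2.0)
    path = sel.select_features(X, y, n_lambda=30, folds=5, seed=2)
    planted = {f"f{i:03d}" for i in range(5)}
    assert planted <= set(path.selected_features)
    assert len(path.selected_features) < 60


# ---------------------------------------------------------------------------
# error handling and reporting
# ---------------------------------------------------------------------------

def test_input_validation(rng_local):
    X, y = make_logistic_data(rng_local, n=50, p=3)
    with pytest.raises(ValueError):
        sel.fit_lasso_path(X, np.full(50, 2))
    with pytest.raises(ValueError):
        sel.fit_lasso_path(X.iloc[:20], y)
    path = sel.fit_lasso_path(X, y, n_lambda=5)
    with pytest.raises(ValueError):
        sel.choose_lambda(path, X.iloc[:5], y[:5], folds=10)


def test_off_grid_lambda_warns(rng_local):
    X, y = make_logistic_data(rng_local, n=80, p=4)
    path = sel.fit_lasso_path(X, y, n_lambda=5)
    with pytest.warns(RuntimeWarning, match="nearest"):
        sel.selected_features(path, path.lambda_grid[0] * 3.14159)


def test_selection_report_is_serializable(rng_local):
    import json
    X, y = make_logistic_data(rng_local, n=100, p=5, informative=2)
    path = sel.select_features(X, y, n_lambda=8, folds=5)
    doc = json.loads(json.dumps(path.report()))
    assert doc["n_selected"] == len(path.selected_features)
    assert len(doc["nonzero_counts"]) == len(doc["lambda_grid"])
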