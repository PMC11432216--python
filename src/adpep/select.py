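"""L1-penalized logistic feature selection.

The selection stage maximizes the penalized log-likelihood

    L(beta) = sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]
              - lambda * sum_j |beta_j|,        p_i = sigmoid(b0 + x_i' beta)

with an unpenalized intercept, over a decreasing grid of penalties, picks
the penalty by cross-validated binomial deviance, and keeps the features
whose coefficients survive at the chosen penalty.

The solver is a proximal-Newton coordinate descent in the style of glmnet:
an outer loop forms the iteratively-reweighted quadratic approximation of
the log-likelihood, an inner loop runs cyclic soft-threshold updates with
an active-set strategy, and the path is fitted from the largest penalty
down with warm starts.  The hot loops are numba-compiled.

Features are standardized (mean 0, unit variance) before fitting by
default; zero-variance columns are centered, flagged, and excluded from
penalized fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.model_selection import StratifiedKFold

NONZERO_THRESHOLD = 1e-8
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-4
DEFAULT_TOL = 1e-5          # max coefficient change per outer iteration
DEFAULT_MAX_SWEEPS = 100_000
_PROB_CLIP = 1e-5           # glmnet-style clip keeping IRLS weights positive


@dataclass
class Standardization:
    """Per-column center/scale record; invertible."""

    center: pd.Series
    scale: pd.Series
    zero_variance: list[str]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table - self.center) / self.scale

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table * self.scale + self.center


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """Center every column to mean 0 and scale to unit variance.

    Zero-variance columns are centered but not scaled (scale 1) and listed
    in the returned record so the caller can exclude them from penalized
    fitting.
    """
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature table contains non-finite values")
    center = table.mean(axis=0)
    std = table.std(axis=0, ddof=0)
    zero_var = list(table.columns[std.to_numpy() == 0.0])
    scale = std.copy()
    scale[scale == 0.0] = 1.0
    record = Standardization(center=center, scale=scale,
                             zero_variance=zero_var)
    return record.transform(table), record


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_weighted_lasso(X, z, w, beta, b0, lam, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted least-squares surrogate.

    Minimizes 0.5 * sum_i w_i (z_i - b0 - x_i'beta)^2 + lam * sum_j |beta_j|
    in place, returning (b0, sweeps_used).  Uses an active-set strategy:
    full sweeps alternate with sweeps over the current nonzero set until a
    full sweep changes nothing beyond tolerance.
    """
    n, p = X.shape
    # residual r = z - b0 - X beta
    r = z - b0
    for j in range(p):
        if beta[j] != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * beta[j]
    xtwx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xtwx[j] = s
    wsum = w.sum()
    active = np.zeros(p, dtype=np.bool_)
    sweeps = 0
    full_pass = True
    while sweeps < max_sweeps:
        sweeps += 1
        max_delta = 0.0
        # intercept (unpenalized)
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / wsum
        if d0 != 0.0:
            b0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
        for j in range(p):
            if not full_pass and not active[j]:
                continue
            if xtwx[j] <= 0.0:
                continue
            old = beta[j]
            rho = 0.0
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            rho += xtwx[j] * old
            if rho > lam:
                new = (rho - lam) / xtwx[j]
            elif rho < -lam:
                new = (rho + lam) / xtwx[j]
            else:
                new = 0.0
            d = new - old
            if d != 0.0:
                beta[j] = new
                for i in range(n):
                    r[i] -= X[i, j] * d
                if abs(d) > max_delta:
                    max_delta = abs(d)
            active[j] = new != 0.0
        if max_delta < tol:
            if full_pass:
                break
            full_pass = True      # converged on active set; verify fully
        else:
            full_pass = False
    return b0, sweeps


@njit(cache=True)
def _fit_penalized_logistic(X, y, beta, b0, lam, tol, max_sweeps):
    """Proximal-Newton outer loop for one penalty value.

    Warm-startable: ``beta``/``b0`` are updated in place from their current
    values.  Returns (b0, converged).
    """
    n, p = X.shape
    converged = False
    for _outer in range(100):
        eta = np.empty(n)
        for i in range(n):
            s = b0
            for j in range(p):
                if beta[j] != 0.0:
                    s += X[i, j] * beta[j]
            eta[i] = s
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.empty(n)
        z = np.empty(n)
        for i in range(n):
            pi = prob[i]
            if pi < _PROB_CLIP:
                pi = _PROB_CLIP
            elif pi > 1.0 - _PROB_CLIP:
                pi = 1.0 - _PROB_CLIP
            wi = pi * (1.0 - pi)
            w[i] = wi
            z[i] = eta[i] + (y[i] - prob[i]) / wi
        beta_old = beta.copy()
        b0_old = b0
        b0, _ = _cd_weighted_lasso(X, z, w, beta, b0, lam, tol * 0.1,
                                   max_sweeps)
        delta = abs(b0 - b0_old)
        for j in range(p):
            d = abs(beta[j] - beta_old[j])
            if d > delta:
                delta = d
        if delta < tol:
            converged = True
            break
    return b0, converged


def penalized_loglik(X, y, beta, b0: float, lam: float) -> float:
    """The objective maximized by the solver (for diagnostics/tests)."""
    eta = X @ beta + b0
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll - lam * float(np.abs(beta).sum())


def kkt_violation(X, y, beta, b0: float, lam: float) -> float:
    """Max violation of the subgradient optimality conditions.

    At an optimum, |grad_j| <= lam where beta_j = 0 and grad_j = -sign *
    lam where beta_j != 0 (grad is the unpenalized score); the intercept
    score must vanish.
    """
    eta = X @ beta + b0
    resid = y - 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ resid
    viol = abs(float(resid.sum()))  # intercept score must vanish
    for j in range(len(beta)):
        if abs(beta[j]) > NONZERO_THRESHOLD:
            viol = max(viol, abs(grad[j] - lam * np.sign(beta[j])))
        else:
            viol = max(viol, max(0.0, abs(grad[j]) - lam))
    return viol


# ---------------------------------------------------------------------------
# path fitting and penalty choice
# ---------------------------------------------------------------------------

@dataclass
class LassoSelection:
    """Coefficient path over a decreasing penalty grid."""

    lambda_grid: np.ndarray          # decreasing
    coefficients: pd.DataFrame       # features x lambda columns
    intercepts: np.ndarray
    feature_names: list[str]
    standardization: Standardization | None = None
    chosen_lambda: float | None = None
    cv_deviance: pd.DataFrame | None = None   # lambda x mean deviance
    converged: bool = True
    selected_features: list[str] = field(default_factory=list)

    def nonzero_counts(self) -> np.ndarray:
        return (self.coefficients.abs()
                > NONZERO_THRESHOLD).sum(axis=0).to_numpy()

    def report(self) -> dict:
        """JSON-serializable selection report."""
        return {
            "chosen_lambda": self.chosen_lambda,
            "lambda_grid": [float(l) for l in self.lambda_grid],
            "nonzero_counts": [int(c) for c in self.nonzero_counts()],
            "n_selected": len(self.selected_features),
            "selected_features": list(self.selected_features),
            "standardized": self.standardization is not None,
        }


def _validate_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("y must be binary with both classes present")
    return y.astype(float)


def lambda_max(X, y) -> float:
    """Smallest penalty at which all penalized coefficients are zero.

    From the subgradient condition at the intercept-only fit:
    ``max_j |x_j' (y - mean(y))|``.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - y.mean()
    return float(np.abs(Xv.T @ resid).max())


def default_lambda_grid(X, y, n_lambda: int = DEFAULT_N_LAMBDA,
                        min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                        ) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        raise ValueError("all features are orthogonal to the labels")
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


#: stop the path once this fraction of the null deviance is explained
DEVIANCE_EXPLAINED_MAX = 0.999


def _fit_path_arrays(Xv: np.ndarray, y: np.ndarray, grid: np.ndarray,
                     tol: float, max_sweeps: int
                     ) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Warm-started path fit; may stop early on saturated deviance.

    Once a fit explains more than ``DEVIANCE_EXPLAINED_MAX`` of the null
    deviance the remaining (smaller) penalties would only inflate nearly
    unconstrained coefficients, so the last solution is carried forward to
    the remaining grid points.  Returns (coefs, intercepts, converged,
    n_fitted).
    """
    p = Xv.shape[1]
    coefs = np.empty((p, len(grid)))
    intercepts = np.empty(len(grid))
    beta = np.zeros(p)
    b0 = float(np.log(y.mean() / (1.0 - y.mean())))
    null_dev = -2.0 * float(np.sum(y * b0 - np.logaddexp(0.0, b0)))
    all_ok = True
    n_fitted = len(grid)
    for i, lam in enumerate(grid):
        b0, ok = _fit_penalized_logistic(Xv, y, beta, b0, lam, tol,
                                         max_sweeps)
        all_ok &= ok
        coefs[:, i] = beta
        intercepts[i] = b0
        eta = Xv @ beta + b0
        dev = -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if 1.0 - dev / null_dev > DEVIANCE_EXPLAINED_MAX and \
                i < len(grid) - 1:
            coefs[:, i + 1:] = beta[:, None]
            intercepts[i + 1:] = b0
            n_fitted = i + 1
            break
    return coefs, intercepts, all_ok, n_fitted


def fit_lasso_path(X: pd.DataFrame, y,
                   lambda_grid: np.ndarray | None = None,
                   n_lambda: int = DEFAULT_N_LAMBDA,
                   min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                   tol: float = DEFAULT_TOL,
                   max_sweeps: int = DEFAULT_MAX_SWEEPS,
                   standardization: Standardization | None = None,
                   ) -> LassoSelection:
    """Fit the penalized logistic model at every grid penalty, warm-started
    from the largest penalty down.

    ``X`` is used as given (standardize first if desired); ``lambda_grid``
    defaults to ``n_lambda`` log-spaced values from ``lambda_max`` down to
    ``1e-4 * lambda_max``.
    """
    y = _validate_binary(y)
    if len(X) != len(y):
        raise ValueError("X rows and y length differ")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y, n_lambda=n_lambda,
                                          min_ratio=min_ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if (np.diff(lambda_grid) > 0).any():
        raise ValueError("lambda_grid must be non-increasing")
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    coefs, intercepts, ok, n_fitted = _fit_path_arrays(
        Xv, y, lambda_grid, tol, max_sweeps)
    if not ok:
        warnings.warn("lasso path: some fits hit the iteration cap",
                      RuntimeWarning, stacklevel=2)
    # grid entries past an early deviance-saturation stop are dropped
    lambda_grid = lambda_grid[:n_fitted]
    coefs = coefs[:, :n_fitted]
    intercepts = intercepts[:n_fitted]
    return LassoSelection(
        lambda_grid=lambda_grid,
        coefficients=pd.DataFrame(coefs, index=list(X.columns),
                                  columns=[f"{l:.6g}" for l in lambda_grid]),
        intercepts=intercepts,
        feature_names=list(X.columns),
        standardization=standardization,
        converged=ok,
    )


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * log-likelihood."""
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def choose_lambda(path: LassoSelection, X: pd.DataFrame, y,
                  folds: int = 10, seed: int = 0,
                  tol: float = DEFAULT_TOL,
                  max_sweeps: int = DEFAULT_MAX_SWEEPS) -> float:
    """Penalty minimizing mean cross-validated binomial deviance.

    Stratified k-fold; ties are broken toward the larger (sparser)
    penalty.  The path object supplies the grid; the data are refit (full
    warm-started path) inside each fold.
    """
    y = _validate_binary(y)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    grid = path.lambda_grid
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=seed)
    dev = np.zeros((folds, len(grid)))
    for f, (tr, te) in enumerate(splitter.split(Xv, y)):
        coefs, intercepts, _, _ = _fit_path_arrays(
            np.ascontiguousarray(Xv[tr]), y[tr], grid, tol, max_sweeps)
        eta = Xv[te] @ coefs + intercepts[None, :]
        probs = 1.0 / (1.0 + np.exp(-eta))
        for i in range(len(grid)):
            dev[f, i] = _deviance(y[te], probs[:, i])
    mean_dev = dev.mean(axis=0)
    best = 0
    for i in range(1, len(grid)):
        if mean_dev[i] < mean_dev[best]:
            best = i
    path.chosen_lambda = float(grid[best])
    path.cv_deviance = pd.DataFrame(
        {"lambda": grid, "mean_deviance": mean_dev})
    path.selected_features = selected_features(path, path.chosen_lambda)
    return path.chosen_lambda


def selected_features(path: LassoSelection, lam: float) -> list[str]:
    """Feature names with |beta| above threshold at penalty ``lam``.

    A penalty not on the grid snaps to the nearest grid point with a
    warning.  Names come back in original column order.
    """
    grid = path.lambda_grid
    idx = int(np.argmin(np.abs(grid - lam)))
    if not np.isclose(grid[idx], lam, rtol=1e-9, atol=0):
        warnings.warn(
            f"lambda {lam:.6g} not on the grid; using nearest grid point "
            f"{grid[idx]:.6g}", RuntimeWarning, stacklevel=2)
    beta = path.coefficients.iloc[:, idx]
    return [name for name, b in zip(path.feature_names, beta)
            if abs(b) > NONZERO_THRESHOLD]


def select_features(table: pd.DataFrame, y,
                    n_lambda: int = DEFAULT_N_LAMBDA,
                    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                    folds: int = 10, seed: int = 0,
                    do_standardize: bool = True,
                    tol: float = DEFAULT_TOL,
                    max_sweeps: int = DEFAULT_MAX_SWEEPS) -> LassoSelection:
    """One-call selection: standardize, fit path, choose penalty by CV.

    Zero-variance columns are excluded from the penalized fit (they carry
    no information on this sample) and can never be selected.
    """
    record = None
    X = table
    if do_standardize:
        X, record = standardize(table)
    keep = [c for c in X.columns
            if record is None or c not in record.zero_variance]
    X = X[keep]
    path = fit_lasso_path(X, y, n_lambda=n_lambda, min_ratio=min_ratio,
                          tol=tol, max_sweeps=max_sweeps,
                          standardization=record)
    choose_lambda(path, X, y, folds=folds, seed=seed, tol=tol,
                  max_sweeps=max_sweeps)
    return path
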