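"""Three classifiers with a shared probabilistic interface.

* ``logistic`` — maximum-likelihood logistic regression fitted by
  iteratively reweighted least squares, with an optional tiny ridge for
  stability under (near-)separation;
* ``svm`` — soft-margin support vector machine (scikit-learn SVC) whose
  decision scores are mapped to probabilities by a Platt-style logistic
  calibration fitted on out-of-fold scores;
* ``adaboost`` — discrete AdaBoost over depth-1 threshold stumps, written
  out explicitly so round weights, tie-breaks and the probability transform
  are fully reproducible.

All models predict label 1 iff P(y=1|x) >= 0.5 (ties go to 1), and expose a
dual-efficacy flag for peptides whose predicted probability sits near 0.5,
i.e. candidates plausibly active against both diabetes types.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

STABILIZING_RIDGE = 1e-8
DEFAULT_ADABOOST_ROUNDS = 100
MODEL_FORMAT_VERSION = 1


class FeatureMismatchError(ValueError):
    """Prediction input columns differ from the training columns."""


@dataclass
class TrainedClassifier:
    """Fitted state of one method plus the exact feature contract."""

    method: str                      # logistic | svm | adaboost
    feature_names: list[str]
    parameters: dict[str, Any]
    training_meta: dict[str, Any] = field(default_factory=dict)

    # -- shared interface ---------------------------------------------------

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise FeatureMismatchError(
                    f"feature columns mismatch: missing {missing}, "
                    f"extra {extra}")
            return X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise FeatureMismatchError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got shape {X.shape}")
        return X

    def decision_scores(self, X) -> np.ndarray:
        """Real-valued scores monotone in P(y=1|x) (used for ROC curves)."""
        M = self._matrix(X)
        p = self.parameters
        if self.method == "logistic":
            return M @ np.asarray(p["beta"]) + p["beta0"]
        if self.method == "svm":
            return _svm_decision(p, M)
        if self.method == "adaboost":
            return _adaboost_score(p["stumps"], M)
        raise ValueError(f"unknown method {self.method!r}")

    def predict_proba(self, X) -> np.ndarray:
        """P(y=1|x) for every row."""
        s = self.decision_scores(X)
        if self.method == "logistic":
            return _sigmoid(s)
        if self.method == "svm":
            a, b = self.parameters["platt"]
            return _sigmoid(a * s + b)
        # adaboost: logistic transform of twice the additive margin
        return _sigmoid(2.0 * s)

    def predict(self, X) -> np.ndarray:
        """Label 1 iff P(y=1|x) >= 0.5; ties go to class 1."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "format_version": MODEL_FORMAT_VERSION,
            "method": self.method,
            "feature_names": self.feature_names,
            "parameters": _jsonable(self.parameters),
            "training_meta": _jsonable(self.training_meta),
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        params = doc["parameters"]
        for key in ("beta", "support_vectors", "dual_coef"):
            if key in params:
                params[key] = np.asarray(params[key], dtype=float)
        return cls(method=doc["method"], feature_names=doc["feature_names"],
                   parameters=params, training_meta=doc["training_meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.clip(z, -700, 700)
    return 1.0 / (1.0 + np.exp(-z))


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(np.asarray(X).shape[1])])
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary over {0, 1}")
    if len(M) != len(y):
        raise ValueError("X rows and y length differ")
    if not np.isfinite(M).all():
        raise ValueError("X contains non-finite values")
    return M, y, names


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------

def train_logistic(X, y, ridge: float = 0.0, tol: float = 1e-10,
                   max_iter: int = 200) -> TrainedClassifier:
    """Maximum-likelihood logistic fit via iteratively reweighted least
    squares.

    The log-likelihood ``sum_i [y_i log p_i + (1-y_i) log(1-p_i)]`` with
    ``p_i = sigmoid(beta0 + x_i' beta)`` is maximized by Newton steps.  If
    the sample is (near-)separable or has more features than rows, a tiny
    ridge (1e-8) on the non-intercept coefficients keeps the optimum finite;
    a warning reports which stabilization fired.
    """
    M, y, names = _as_xy(X, y)
    n, p = M.shape
    if n <= p and ridge == 0.0:
        warnings.warn(
            f"n={n} <= p={p}: adding stabilizing ridge {STABILIZING_RIDGE}",
            RuntimeWarning, stacklevel=2)
        ridge = STABILIZING_RIDGE
    Xd = np.column_stack([np.ones(n), M])
    penalty = np.full(p + 1, ridge)
    penalty[0] = 0.0  # intercept never penalized
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        prob = _sigmoid(eta)
        w = prob * (1.0 - prob)
        grad = Xd.T @ (y - prob) - penalty * beta
        hess = (Xd * w[:, None]).T @ Xd + np.diag(penalty + 1e-12)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
        if ridge == 0.0 and np.abs(beta[1:]).max() > 30.0:
            warnings.warn(
                "perfect or near-perfect separation detected; continuing "
                f"with stabilizing ridge {STABILIZING_RIDGE}",
                RuntimeWarning, stacklevel=2)
            ridge = STABILIZING_RIDGE
            penalty = np.full(p + 1, ridge)
            penalty[0] = 0.0
    return TrainedClassifier(
        method="logistic", feature_names=names,
        parameters={"beta": beta[1:], "beta0": float(beta[0])},
        training_meta={"ridge": ridge, "iterations": it,
                       "converged": converged})


# ---------------------------------------------------------------------------
# support vector machine
# ---------------------------------------------------------------------------

def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def _svm_decision(params: dict, M: np.ndarray) -> np.ndarray:
    sv = np.asarray(params["support_vectors"], dtype=float)
    dual = np.asarray(params["dual_coef"], dtype=float)
    if params["kernel"] == "rbf":
        K = _rbf_kernel(sv, M, params["gamma"])
    else:  # linear
        K = sv @ M.T
    return dual @ K + params["intercept"]


def train_svm(X, y, C: float = 1.0, kernel: str = "rbf",
              gamma: float | None = None, seed: int = 0,
              calibration_folds: int = 5) -> TrainedClassifier:
    """Soft-margin SVM with Platt-calibrated probabilities.

    ``gamma`` defaults to 1/(number of features).  Labels are mapped to
    {-1, +1} internally; the stored state (support vectors, dual
    coefficients, intercept) reproduces the decision function without
    scikit-learn objects, so serialized models reload exactly.  Probability
    calibration fits a one-dimensional logistic model on decision scores
    obtained out-of-fold on the training data (falling back to in-sample
    scores when a class is too small to fold).
    """
    M, y, names = _as_xy(X, y)
    if kernel not in ("rbf", "linear"):
        raise ValueError(f"unsupported kernel {kernel!r} (rbf or linear); "
                         "custom kernels are not accepted")
    if gamma is None:
        gamma = 1.0 / M.shape[1]
    svc = SVC(C=C, kernel=kernel, gamma=gamma, random_state=seed)
    svc.fit(M, y)

    # out-of-fold decision scores for Platt calibration
    counts = np.bincount(y, minlength=2)
    k = min(calibration_folds, counts.min())
    if k >= 2:
        scores = np.empty(len(y))
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, te in folds.split(M, y):
            sub = SVC(C=C, kernel=kernel, gamma=gamma, random_state=seed)
            sub.fit(M[tr], y[tr])
            scores[te] = sub.decision_function(M[te])
    else:
        scores = svc.decision_function(M)
    platt = train_logistic(scores[:, None], y, ridge=STABILIZING_RIDGE)
    a = float(platt.parameters["beta"][0])
    b = float(platt.parameters["beta0"])

    return TrainedClassifier(
        method="svm", feature_names=names,
        parameters={
            "kernel": kernel, "gamma": float(gamma), "C": float(C),
            "support_vectors": svc.support_vectors_,
            "dual_coef": svc.dual_coef_.ravel(),
            "intercept": float(svc.intercept_[0]),
            "platt": [a, b],
        },
        training_meta={"seed": seed, "n_support": int(svc.support_.size),
                       "calibration_folds": int(k) if k >= 2 else 0})


# ---------------------------------------------------------------------------
# AdaBoost with decision stumps
# ---------------------------------------------------------------------------

def _stump_predict(M: np.ndarray, feature: int, threshold: float,
                   polarity: int) -> np.ndarray:
    """+1/-1 prediction of one stump: polarity * sign(x_f > threshold)."""
    return polarity * np.where(M[:, feature] > threshold, 1.0, -1.0)


def _adaboost_score(stumps: Sequence[dict], M: np.ndarray) -> np.ndarray:
    score = np.zeros(len(M))
    for s in stumps:
        score += s["alpha"] * _stump_predict(M, s["feature"], s["threshold"],
                                             s["polarity"])
    return score


def _best_stump(Xs: np.ndarray, order: np.ndarray, ypm: np.ndarray,
                w: np.ndarray) -> tuple[int, float, int, float]:
    """Weighted-error-minimizing threshold stump.

    For every feature the candidate thresholds are the midpoints between
    distinct consecutive sorted values plus an 'everything left' split
    (constant stump).  Ties break toward the lowest feature index, then the
    lowest threshold, then polarity +1.
    Returns (feature, threshold, polarity, weighted_error).
    """
    n, p = Xs.shape
    w_sorted = w[order]                        # n x p gathers
    y_sorted = ypm[order]
    pos = w_sorted * (y_sorted > 0)
    neg = w_sorted * (y_sorted < 0)
    cum_pos = np.cumsum(pos, axis=0)
    cum_neg = np.cumsum(neg, axis=0)
    # split after sorted position i: left = x <= threshold -> predicted -1
    # under polarity +1, so error(+1) = P_w(y=+1, left) + P_w(y=-1, right)
    err_plus = cum_pos + (cum_neg[-1, :] - cum_neg)
    vals = np.take_along_axis(Xs, order, axis=0)
    valid = np.ones_like(err_plus, dtype=bool)
    valid[:-1, :] = vals[1:, :] > vals[:-1, :]  # distinct neighbors only
    thresholds = np.empty_like(vals)
    thresholds[:-1, :] = 0.5 * (vals[:-1, :] + vals[1:, :])
    thresholds[-1, :] = vals[-1, :]            # all-left constant stump
    err_plus = np.where(valid, err_plus, np.inf)
    err_minus = np.where(valid, 1.0 - err_plus, np.inf)

    best = (np.inf, 0, np.inf, 0)  # (error, feature, threshold, polarity idx)
    for polarity_idx, err in ((0, err_plus), (1, err_minus)):
        flat = int(np.argmin(err.T))           # feature-major order
        f, i = divmod(flat, n)
        e = err[i, f]
        thr = thresholds[i, f]
        cand = (e, f, thr, polarity_idx)
        # lexicographic tie-break: error, feature, threshold, polarity(+1<-1)
        if cand[0] < best[0] - 1e-15 or (
                abs(cand[0] - best[0]) <= 1e-15 and
                (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3])):
            best = cand
    e, f, thr, pol_idx = best
    return f, float(thr), (1 if pol_idx == 0 else -1), float(e)


def train_adaboost(X, y, rounds: int = DEFAULT_ADABOOST_ROUNDS,
                   ) -> TrainedClassifier:
    """Discrete AdaBoost over depth-1 threshold stumps.

    Round t fits the stump minimizing the weighted 0-1 error ``eps_t``,
    weighs it by ``alpha_t = 0.5 * ln((1 - eps_t)/eps_t)``, and reweights
    instances multiplicatively.  Boosting stops early when ``eps_t = 0``
    (the stump is kept with the error floored at 1e-12) or ``eps_t >= 1/2``
    (the stump is discarded).  The additive score ``sum_t alpha_t h_t(x)``
    maps to a probability through ``sigmoid(2 * score)``.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    M, y, names = _as_xy(X, y)
    ypm = y * 2.0 - 1.0
    n = len(y)
    order = np.argsort(M, axis=0, kind="stable")
    w = np.full(n, 1.0 / n)
    stumps: list[dict] = []
    for _ in range(rounds):
        f, thr, pol, eps = _best_stump(M, order, ypm, w)
        if eps >= 0.5:
            break
        eps_floored = max(eps, 1e-12)
        alpha = 0.5 * np.log((1.0 - eps_floored) / eps_floored)
        h = _stump_predict(M, f, thr, pol)
        stumps.append({"feature": int(f), "feature_name": names[f],
                       "threshold": thr, "polarity": int(pol),
                       "alpha": float(alpha), "error": float(eps)})
        if eps <= 1e-12:
            break
        w = w * np.exp(-alpha * ypm * h)
        w = w / w.sum()
    return TrainedClassifier(
        method="adaboost", feature_names=names,
        parameters={"stumps": stumps},
        training_meta={"rounds_requested": rounds,
                       "rounds_used": len(stumps)})


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

TRAINERS = {"logistic": train_logistic, "svm": train_svm,
            "adaboost": train_adaboost}


def train(method: str, X, y, **kwargs) -> TrainedClassifier:
    if method not in TRAINERS:
        raise ValueError(f"unknown method {method!r}; "
                         f"choose from {sorted(TRAINERS)}")
    return TRAINERS[method](X, y, **kwargs)


def predict(model: TrainedClassifier, X) -> np.ndarray:
    return model.predict(X)


def predict_proba(model: TrainedClassifier, X) -> np.ndarray:
    return model.predict_proba(X)


def dual_efficacy_flag(probabilities, delta: float = 0.1) -> np.ndarray:
    """Flag peptides whose P(y=1|x) lies within ``delta`` of 0.5.

    Such balanced probabilities mark candidates for possible dual efficacy
    against both diabetes types.
    """
    if not 0.0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= 0.5 - delta) & (p <= 0.5 + delta)
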