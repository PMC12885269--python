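"""Severity predictors mapping 0-10 feature scores to the PHQ-8 scale.

Three estimator families, all scikit-learn compatible (``fit`` / ``predict``
/ ``get_params`` / ``set_params``, fitted attributes with trailing
underscores):

``LinearSeverityRegressor``
    The primary model: ordinary least squares on z-scored features.
    Standardization parameters are estimated on the training rows only and
    reapplied verbatim at prediction time, so no test-set statistic can leak
    into the fit.

``SVRSeverityRegressor``
    Epsilon-insensitive support vector regression with an RBF kernel; the
    penalty C is selected by leave-one-out cross-validation on the training
    set (MAE criterion, ties broken toward the smallest C).

``StackingSeverityRegressor``
    A two-level ensemble: one linear base model per feature category, whose
    leave-one-out out-of-fold training predictions form the design matrix of
    a linear meta-model.

Evaluation reports MAE (primary), RMSE and R² on the PHQ-8 point scale,
with R² computed as 1 − SS_res/SS_tot against the evaluation-set mean — the
coefficient of determination, which can be negative out of sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.svm import SVR

PHQ8_MAX = 24


class RankDeficiencyError(ValueError):
    """Design matrix is not full column rank."""

    def __init__(self, collinear: list[str]):
        self.collinear = collinear
        super().__init__(
            f"design matrix is rank deficient; collinear features: {collinear}"
        )


@dataclass(frozen=True)
class Standardizer:
    """Per-feature location/scale estimated on training rows (sample SD,
    ddof=1 by default)."""

    mean: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{i}" for i in range(arr.shape[1])]
    )
    return arr, names


def fit_standardizer(X, feature_names=None, ddof: int = 1) -> Standardizer:
    """Estimate z-scoring parameters on training rows.

    Raises if any feature has (near-)zero variance, naming the feature.
    """
    arr, names = _as_matrix(X, feature_names)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=ddof)
    dead = [names[j] for j in np.flatnonzero(scale <= 1e-12)]
    if dead:
        raise ValueError(f"zero-variance features on train: {dead}")
    return Standardizer(mean=mean, scale=scale, feature_names=tuple(names))


def apply_standardizer(std: Standardizer, X) -> np.ndarray:
    arr, names = _as_matrix(X, std.feature_names)
    if tuple(names) != std.feature_names:
        raise ValueError(
            f"feature mismatch: expected {list(std.feature_names)}, got {names}"
        )
    return std.transform(arr)


def _collinear_columns(Xz: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns pivoted past the numerical rank are the dependents
    _, r, piv = sla.qr(Xz, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xz.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


class LinearSeverityRegressor(BaseEstimator, RegressorMixin):
    """Ordinary least squares on internally z-scored features.

    Parameters
    ----------
    ddof : int, default 1
        Degrees-of-freedom convention for the z-scoring SD (1 = sample SD).
        Affects coefficients only by a per-feature scalar, never predictions.
    rank_deficient : {"error", "pinv"}, default "error"
        On a rank-deficient design, either raise naming the collinear
        features, or take the minimum-norm least-squares solution.
    clip : bool, default False
        Clip predictions to the PHQ-8 range [0, 24].

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Standardized regression coefficients (per z-scored feature).
    intercept_ : float
    standardizer_ : Standardizer
    feature_names_in_ : ndarray of feature names seen during fit.
    """

    def __init__(self, ddof: int = 1, rank_deficient: str = "error", clip: bool = False):
        self.ddof = ddof
        self.rank_deficient = rank_deficient
        self.clip = clip

    def fit(self, X, y):
        arr, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, d = arr.shape
        if len(y) != n:
            raise ValueError("X and y have different numbers of rows")
        if n < d + 1:
            raise ValueError(f"need at least {d + 1} rows to fit {d} features")
        self.standardizer_ = fit_standardizer(arr, names, ddof=self.ddof)
        Xz = self.standardizer_.transform(arr)
        design = np.column_stack([np.ones(n), Xz])
        if np.linalg.matrix_rank(design) < d + 1:
            if self.rank_deficient == "error":
                raise RankDeficiencyError(_collinear_columns(Xz, names))
            if self.rank_deficient != "pinv":
                raise ValueError(f"unknown rank_deficient policy {self.rank_deficient!r}")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = d
        return self

    def _validate_X(self, X) -> np.ndarray:
        arr, names = _as_matrix(X, self.feature_names_in_)
        expected = list(self.feature_names_in_)
        if names != expected:
            if isinstance(X, pd.DataFrame) and set(names) == set(expected):
                arr = X[expected].to_numpy(dtype=float)
            else:
                raise ValueError(f"feature mismatch: expected {expected}, got {names}")
        return arr

    def predict(self, X):
        arr = self._validate_X(X)
        pred = self.standardizer_.transform(arr) @ self.coef_ + self.intercept_
        return np.clip(pred, 0, PHQ8_MAX) if self.clip else pred


def _loocv_predictions(fit_predict, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Generic leave-one-out out-of-fold predictions.  ``fit_predict(Xtr,
    ytr, xrow)`` returns the held-out prediction."""
    n = len(y)
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        out[i] = fit_predict(X[mask], y[mask], X[i : i + 1])
    return out


class SVRSeverityRegressor(BaseEstimator, RegressorMixin):
    """RBF-kernel support vector regression with LOOCV-selected C.

    The grid defaults to 16 log-spaced points 2^-5 … 2^10; epsilon defaults
    to 0.1 and gamma to 1/(d · pooled feature variance) on the z-scored
    features.  Selection minimizes leave-one-out MAE on the training set,
    breaking ties toward the smallest C.
    """

    def __init__(self, C_grid=None, epsilon: float = 0.1, gamma=None, ddof: int = 1):
        self.C_grid = C_grid
        self.epsilon = epsilon
        self.gamma = gamma
        self.ddof = ddof

    def _grid(self) -> np.ndarray:
        if self.C_grid is None:
            return np.logspace(-5, 10, num=16, base=2.0)
        grid = np.asarray(self.C_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("C grid must be non-empty and positive")
        return grid

    def fit(self, X, y):
        arr, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        self.standardizer_ = fit_standardizer(arr, names, ddof=self.ddof)
        Xz = self.standardizer_.transform(arr)
        gamma = self.gamma
        if gamma is None:
            gamma = 1.0 / (Xz.shape[1] * Xz.var())  # sklearn "scale" convention
        grid = self._grid()
        maes = np.empty(len(grid))
        for k, C in enumerate(grid):
            def fp(Xtr, ytr, xrow, C=C):
                svr = SVR(kernel="rbf", C=C, epsilon=self.epsilon, gamma=gamma)
                return float(svr.fit(Xtr, ytr).predict(xrow)[0])

            maes[k] = mean_absolute_error(y, _loocv_predictions(fp, Xz, y))
        order = np.lexsort((grid, maes))  # min MAE, ties -> smallest C
        self.C_ = float(grid[order[0]])
        self.loocv_mae_ = {float(c): float(m) for c, m in zip(grid, maes)}
        self.gamma_ = float(gamma)
        self.svr_ = SVR(kernel="rbf", C=self.C_, epsilon=self.epsilon, gamma=gamma)
        self.svr_.fit(Xz, y)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def predict(self, X):
        arr, names = _as_matrix(X, self.feature_names_in_)
        if names != list(self.feature_names_in_):
            raise ValueError("feature mismatch")
        return self.svr_.predict(self.standardizer_.transform(arr))


class StackingSeverityRegressor(BaseEstimator, RegressorMixin):
    """Two-level stacking over feature categories.

    One :class:`LinearSeverityRegressor` is fit per category; their
    leave-one-out out-of-fold predictions on the training set form the
    meta-design matrix, on which a linear meta-model (OLS with intercept) is
    fit.  Base models are then refit on the full training set, and test
    predictions feed the meta-model.

    Parameters
    ----------
    categories : dict mapping category name -> list of feature names.
    """

    def __init__(self, categories: dict[str, list[str]] | None = None,
                 rank_deficient: str = "error"):
        self.categories = categories
        self.rank_deficient = rank_deficient

    def fit(self, X, y):
        if not self.categories or len(self.categories) < 2:
            raise ValueError("stacking requires >= 2 categories")
        if not isinstance(X, pd.DataFrame):
            raise ValueError("stacking requires a DataFrame with named features")
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        for cat, qids in self.categories.items():
            if not qids:
                raise ValueError(f"category {cat!r} has no features")
            missing = [q for q in qids if q not in X.columns]
            if missing:
                raise ValueError(f"category {cat!r}: features {missing} absent from X")
        self.category_names_ = list(self.categories)
        meta = np.empty((n, len(self.category_names_)))
        for j, cat in enumerate(self.category_names_):
            sub = X[self.categories[cat]].to_numpy(dtype=float)

            def fp(Xtr, ytr, xrow, cat=cat):
                m = LinearSeverityRegressor(rank_deficient=self.rank_deficient)
                return float(m.fit(Xtr, ytr).predict(xrow)[0])

            meta[:, j] = _loocv_predictions(fp, sub, y)
        design = np.column_stack([np.ones(n), meta])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.meta_intercept_ = float(beta[0])
        self.meta_coef_ = beta[1:]
        self.base_models_ = {}
        for cat in self.category_names_:
            m = LinearSeverityRegressor(rank_deficient=self.rank_deficient)
            self.base_models_[cat] = m.fit(X[self.categories[cat]], y)
        self.feature_names_in_ = np.asarray(
            [q for cat in self.category_names_ for q in self.categories[cat]],
            dtype=object,
        )
        self.oof_meta_design_ = meta
        return self

    def predict(self, X):
        if not isinstance(X, pd.DataFrame):
            raise ValueError("stacking requires a DataFrame with named features")
        base = np.column_stack(
            [self.base_models_[cat].predict(X[self.categories[cat]])
             for cat in self.category_names_]
        )
        return base @ self.meta_coef_ + self.meta_intercept_


@dataclass(frozen=True)
class PredictionMetrics:
    """MAE/RMSE in PHQ-8 points; R² is 1 − SS_res/SS_tot on the evaluation
    set (None when n < 2, where the total sum of squares is undefined)."""

    mae: float
    rmse: float
    r2: float | None
    n: int

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2, "n": self.n}


def evaluate_predictions(y_true, y_pred) -> PredictionMetrics:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    n = len(y_true)
    mae = float(mean_absolute_error(y_true, y_pred))
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    r2 = float(r2_score(y_true, y_pred)) if n >= 2 and np.ptp(y_true) > 0 else None
    return PredictionMetrics(mae=mae, rmse=rmse, r2=r2, n=n)


# --- thin functional wrappers ----------------------------------------------


def fit_ols(X, y, rank_deficient: str = "error") -> LinearSeverityRegressor:
    return LinearSeverityRegressor(rank_deficient=rank_deficient).fit(X, y)


def fit_svr_loocv(X, y, C_grid=None, **kwargs) -> SVRSeverityRegressor:
    return SVRSeverityRegressor(C_grid=C_grid, **kwargs).fit(X, y)


def fit_stacking(X, y, categories: dict[str, list[str]]) -> StackingSeverityRegressor:
    return StackingSeverityRegressor(categories=categories).fit(X, y)


def save_model(model, path) -> None:
    """Persist a fitted severity model as JSON (coefficients, standardizer,
    hyperparameters; SVR support data included explicitly)."""
    import json
    from pathlib import Path

    def std_dict(std: Standardizer) -> dict:
        return {"mean": std.mean.tolist(), "scale": std.scale.tolist(),
                "feature_names": list(std.feature_names)}

    if isinstance(model, LinearSeverityRegressor):
        blob = {
            "family": "ols",
            "params": model.get_params(),
            "standardizer": std_dict(model.standardizer_),
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
        }
    elif isinstance(model, SVRSeverityRegressor):
        blob = {
            "family": "svr_rbf",
            "params": {"epsilon": model.epsilon, "ddof": model.ddof},
            "standardizer": std_dict(model.standardizer_),
            "C": model.C_,
            "gamma": model.gamma_,
            "support_vectors": model.svr_.support_vectors_.tolist(),
            "dual_coef": model.svr_.dual_coef_.tolist(),
            "svr_intercept": model.svr_.intercept_.tolist(),
        }
    elif isinstance(model, StackingSeverityRegressor):
        blob = {
            "family": "stacking",
            "categories": {c: list(q) for c, q in model.categories.items()},
            "meta_intercept": model.meta_intercept_,
            "meta_coef": model.meta_coef_.tolist(),
            "base": {
                c: {
                    "standardizer": std_dict(m.standardizer_),
                    "coef": m.coef_.tolist(),
                    "intercept": m.intercept_,
                }
                for c, m in model.base_models_.items()
            },
        }
    else:
        raise TypeError(f"cannot persist model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(blob, indent=2))


def load_model(path):
    import json
    from pathlib import Path

    blob = json.loads(Path(path).read_text())

    def std_from(d) -> Standardizer:
        return Standardizer(
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            feature_names=tuple(d["feature_names"]),
        )

    family = blob["family"]
    if family == "ols":
        m = LinearSeverityRegressor(**blob["params"])
        m.standardizer_ = std_from(blob["standardizer"])
        m.coef_ = np.asarray(blob["coef"], dtype=float)
        m.intercept_ = float(blob["intercept"])
        m.feature_names_in_ = np.asarray(
            blob["standardizer"]["feature_names"], dtype=object
        )
        m.n_features_in_ = len(m.coef_)
        return m
    if family == "svr_rbf":
        m = SVRSeverityRegressor(**blob["params"])
        m.standardizer_ = std_from(blob["standardizer"])
        m.C_ = float(blob["C"])
        m.gamma_ = float(blob["gamma"])
        m.feature_names_in_ = np.asarray(
            blob["standardizer"]["feature_names"], dtype=object
        )
        m.n_features_in_ = len(m.feature_names_in_)
        sv = np.asarray(blob["support_vectors"], dtype=float)
        dual = np.asarray(blob["dual_coef"], dtype=float)
        b = np.asarray(blob["svr_intercept"], dtype=float)

        class _KernelPredictor:
            def predict(self, Xz, _sv=sv, _dual=dual, _b=b, _g=m.gamma_):
                d2 = ((Xz[:, None, :] - _sv[None, :, :]) ** 2).sum(-1)
                return (np.exp(-_g * d2) @ _dual.ravel()) + _b[0]

        m.svr_ = _KernelPredictor()
        return m
    if family == "stacking":
        m = StackingSeverityRegressor(categories=blob["categories"])
        m.category_names_ = list(blob["categories"])
        m.meta_intercept_ = float(blob["meta_intercept"])
        m.meta_coef_ = np.asarray(blob["meta_coef"], dtype=float)
        m.base_models_ = {}
        for c, sub in blob["base"].items():
            base = LinearSeverityRegressor()
            base.standardizer_ = std_from(sub["standardizer"])
            base.coef_ = np.asarray(sub["coef"], dtype=float)
            base.intercept_ = float(sub["intercept"])
            base.feature_names_in_ = np.asarray(
                sub["standardizer"]["feature_names"], dtype=object
            )
            base.n_features_in_ = len(base.coef_)
            m.base_models_[c] = base
        m.feature_names_in_ = np.asarray(
            [q for c in m.category_names_ for q in m.categories[c]], dtype=object
        )
        return m
    raise ValueError(f"unknown model family {family!r}")


def fit_univariate_models(X, y, B: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-feature simple regression with a z-scored predictor.

    Returns one row per feature with the standardized slope, percentile
    bootstrap CI and p (pairs resampling, re-standardizing within each
    resample), and BH-FDR q across all features.  Rows are sorted by
    |estimate| descending, ties broken by input feature order.
    """
    from .interpret import bootstrap_infer, fdr_adjust, significance_tiers

    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()

    def std_slope(x_col: np.ndarray, y_col: np.ndarray) -> float:
        sd = x_col.std(ddof=1)
        if sd <= 1e-12:
            return np.nan
        xz = (x_col - x_col.mean()) / sd
        design = np.column_stack([np.ones(len(xz)), xz])
        beta, *_ = np.linalg.lstsq(design, y_col, rcond=None)
        return float(beta[1])

    rows = []
    for j, qid in enumerate(X.columns):
        x = X[qid].to_numpy(dtype=float)
        est, lo, hi, p, _ = bootstrap_infer(
            lambda xx, yy: std_slope(xx, yy), (x, y), B=B,
            seed=seed + j,
        )
        rows.append({"qid": str(qid), "estimate": est, "ci_low": lo, "ci_high": hi, "p": p})
    report = pd.DataFrame(rows)
    report["q"] = fdr_adjust(report["p"].to_numpy())
    report["tier"] = significance_tiers(report["p"].to_numpy(), report["q"].to_numpy())
    report["_order"] = np.arange(len(report))
    report = report.sort_values(
        by=["estimate", "_order"],
        key=lambda s: -s.abs() if s.name == "estimate" else s,
    ).drop(columns="_order").reset_index(drop=True)
    return report
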