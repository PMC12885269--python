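"""Feature-contribution statistics with bootstrap and FDR inference.

Three interpretive statistics for a fitted severity model:

* **Structure coefficients** — the Pearson correlation between each raw
  feature and the model's predicted outcome over held-out evaluation rows.
  Unlike partial regression coefficients, structure coefficients stay
  interpretable under multicollinearity: a feature sharing variance with the
  predicted outcome shows a large r even when its partial coefficient is
  suppressed by correlated peers.
* **Standardized betas** — the multiple-regression coefficients on z-scored
  features, comparable across features.
* **Ablation ΔMAE** — the change in test MAE after removing one feature and
  refitting, a direct (but collinearity-sensitive) importance measure.

Uncertainty is quantified by a seeded percentile bootstrap (95% CI; two-sided
sign-based p with a +1/(B+1) continuity correction), and multiplicity across
the feature set by Benjamini–Hochberg FDR.  For test-set statistics the model
is fit once on the training rows and held fixed; the bootstrap resamples
evaluation rows only.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .models import LinearSeverityRegressor, evaluate_predictions


class BootstrapResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_undefined: int


def _percentile_p(draws: np.ndarray) -> float:
    """Two-sided sign-based bootstrap p with +1 continuity correction."""
    b = len(draws)
    n_le = int((draws <= 0).sum())
    n_ge = int((draws >= 0).sum())
    return min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (b + 1))


def bootstrap_infer(
    statistic: Callable[..., float],
    data: Sequence[np.ndarray],
    B: int = 10_000,
    seed: int = 0,
    max_undefined_frac: float = 0.01,
) -> BootstrapResult:
    """Percentile bootstrap over rows.

    ``data`` is a sequence of equal-length arrays resampled jointly;
    ``statistic(*resampled)`` returns a scalar (NaN marks an undefined
    resample, e.g. a constant column for a correlation).  Undefined draws are
    dropped and counted; more than ``max_undefined_frac`` of B undefined is an
    error.  The point estimate is the statistic on the full data.  Fully
    reproducible from ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must have equal length")
    estimate = float(statistic(*arrays))
    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        draws[b] = statistic(*(a[idx] for a in arrays))
    valid = draws[~np.isnan(draws)]
    n_undefined = B - len(valid)
    if n_undefined > max_undefined_frac * B:
        raise ValueError(
            f"statistic undefined on {n_undefined}/{B} bootstrap resamples"
        )
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return BootstrapResult(estimate, float(lo), float(hi), _percentile_p(valid), n_undefined)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, returned in the
    original order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_tiers(p: np.ndarray, q: np.ndarray, alpha: float = 0.05) -> list[str]:
    """fdr_significant (q < alpha) / nominal (p < alpha only) / ns."""
    return [
        "fdr_significant" if qq < alpha else ("nominal" if pp < alpha else "ns")
        for pp, qq in zip(p, q)
    ]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx <= 1e-300 or sy <= 1e-300:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def structure_coefficients(model, X) -> pd.Series:
    """Per-feature Pearson correlation between raw feature values and the
    model's predictions over the evaluation rows.  Constant features yield
    NaN (flagged, not zero)."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    yhat = np.asarray(model.predict(X), dtype=float)
    return pd.Series(
        {str(c): pearson_r(X[c].to_numpy(dtype=float), yhat) for c in X.columns},
        name="structure_r",
    )


def _sorted_report(report: pd.DataFrame) -> pd.DataFrame:
    report = report.copy()
    report["_order"] = np.arange(len(report))
    report = report.sort_values(
        by=["estimate", "_order"],
        key=lambda s: -s.abs() if s.name == "estimate" else s,
    ).drop(columns="_order").reset_index(drop=True)
    return report


def _finalize(rows: list[dict], kind: str, n: int, B: int, seed: int) -> pd.DataFrame:
    report = pd.DataFrame(rows)
    report["q"] = fdr_adjust(report["p"].to_numpy())
    report["tier"] = significance_tiers(report["p"].to_numpy(), report["q"].to_numpy())
    report["kind"] = kind
    report["n"] = n
    report["B"] = B
    report["seed"] = seed
    return _sorted_report(report)


def structure_report(model, X_eval, B: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Structure-coefficient report with bootstrap CIs over evaluation rows
    (model held fixed) and BH-FDR across the feature set."""
    if not isinstance(X_eval, pd.DataFrame):
        X_eval = pd.DataFrame(np.asarray(X_eval, dtype=float))
    yhat = np.asarray(model.predict(X_eval), dtype=float)
    rows = []
    for j, qid in enumerate(X_eval.columns):
        x = X_eval[qid].to_numpy(dtype=float)
        res = bootstrap_infer(pearson_r, (x, yhat), B=B, seed=seed + j)
        rows.append(
            {"qid": str(qid), "estimate": res.estimate, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p": res.p}
        )
    return _finalize(rows, "structure_r", len(X_eval), B, seed)


def beta_report(X_train, y_train, B: int = 10_000, seed: int = 0,
                rank_deficient: str = "error") -> pd.DataFrame:
    """Standardized multiple-regression coefficients with a pairs bootstrap
    (resampling training rows and refitting the full model each draw)."""
    if not isinstance(X_train, pd.DataFrame):
        X_train = pd.DataFrame(np.asarray(X_train, dtype=float))
    y = np.asarray(y_train, dtype=float).ravel()
    n, d = X_train.shape
    full = LinearSeverityRegressor(rank_deficient=rank_deficient).fit(X_train, y)
    arr = X_train.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.full((B, d), np.nan)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, yb = arr[idx], y[idx]
        sd = Xb.std(axis=0, ddof=1)
        if np.any(sd <= 1e-12):
            continue  # undefined draw: a feature went constant
        Xz = (Xb - Xb.mean(axis=0)) / sd
        design = np.column_stack([np.ones(n), Xz])
        beta, *_ = np.linalg.lstsq(design, yb, rcond=None)
        draws[b] = beta[1:]
    rows = []
    for j, qid in enumerate(X_train.columns):
        col = draws[:, j]
        valid = col[~np.isnan(col)]
        if len(valid) < 0.99 * B:
            raise ValueError(f"{qid}: bootstrap undefined on >1% of resamples")
        lo, hi = np.percentile(valid, [2.5, 97.5])
        rows.append(
            {"qid": str(qid), "estimate": float(full.coef_[j]), "ci_low": float(lo),
             "ci_high": float(hi), "p": _percentile_p(valid)}
        )
    return _finalize(rows, "standardized_beta", n, B, seed)


def ablation_importance(X_train, y_train, X_test, y_test,
                        rank_deficient: str = "pinv") -> pd.Series:
    """Per-feature ΔMAE = test MAE after removing the feature (and refitting
    on train) minus the full model's test MAE.

    Uses the minimum-norm solution by default so that exactly collinear
    features (whose removal cannot change the fitted subspace) get ΔMAE ~ 0
    instead of an error.
    """
    if not isinstance(X_train, pd.DataFrame):
        X_train = pd.DataFrame(np.asarray(X_train, dtype=float))
        X_test = pd.DataFrame(np.asarray(X_test, dtype=float), columns=X_train.columns)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    full = LinearSeverityRegressor(rank_deficient=rank_deficient).fit(X_train, y_train)
    mae_full = evaluate_predictions(y_test, full.predict(X_test)).mae
    out = {}
    for qid in X_train.columns:
        rest = [c for c in X_train.columns if c != qid]
        sub = LinearSeverityRegressor(rank_deficient=rank_deficient).fit(
            X_train[rest], y_train
        )
        mae_wo = evaluate_predictions(y_test, sub.predict(X_test[rest])).mae
        out[str(qid)] = mae_wo - mae_full
    return pd.Series(out, name="ablation_delta_mae")


def ablation_report(X_train, y_train, X_test, y_test, B: int = 10_000,
                    seed: int = 0, rank_deficient: str = "pinv") -> pd.DataFrame:
    """Ablation ΔMAE report with bootstrap CIs over test rows (all models fit
    once on train and held fixed) and BH-FDR across features."""
    if not isinstance(X_train, pd.DataFrame):
        X_train = pd.DataFrame(np.asarray(X_train, dtype=float))
        X_test = pd.DataFrame(np.asarray(X_test, dtype=float), columns=X_train.columns)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    full = LinearSeverityRegressor(rank_deficient=rank_deficient).fit(X_train, y_train)
    abs_err_full = np.abs(y_test - full.predict(X_test))
    rows = []
    for j, qid in enumerate(X_train.columns):
        rest = [c for c in X_train.columns if c != qid]
        sub = LinearSeverityRegressor(rank_deficient=rank_deficient).fit(
            X_train[rest], y_train
        )
        abs_err_wo = np.abs(y_test - sub.predict(X_test[rest]))
        res = bootstrap_infer(
            lambda a, b: float(a.mean() - b.mean()),
            (abs_err_wo, abs_err_full),
            B=B, seed=seed + j,
        )
        rows.append(
            {"qid": str(qid), "estimate": res.estimate, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p": res.p}
        )
    return _finalize(rows, "ablation_delta_mae", len(y_test), B, seed)


def coefficient_report(kind: str, *, model=None, X_eval=None, X_train=None,
                       y_train=None, X_test=None, y_test=None,
                       B: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Dispatch to the requested report kind: ``structure_r`` (needs model +
    X_eval), ``standardized_beta`` (needs X_train + y_train) or
    ``ablation_delta_mae`` (needs train and test data)."""
    if kind == "structure_r":
        if model is None or X_eval is None:
            raise ValueError("structure_r needs model and X_eval")
        return structure_report(model, X_eval, B=B, seed=seed)
    if kind == "standardized_beta":
        if X_train is None or y_train is None:
            raise ValueError("standardized_beta needs X_train and y_train")
        return beta_report(X_train, y_train, B=B, seed=seed)
    if kind == "ablation_delta_mae":
        if any(v is None for v in (X_train, y_train, X_test, y_test)):
            raise ValueError("ablation_delta_mae needs train and test data")
        return ablation_report(X_train, y_train, X_test, y_test, B=B, seed=seed)
    raise ValueError(f"unknown report kind {kind!r}")


def plot_coefficient_report(report: pd.DataFrame, path=None, categories=None):
    """Dot-and-error-bar feature ladder (largest |estimate| at the top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {"clinical_symptoms": "tab:red", "linguistic_patterns": "tab:cyan",
               "cognitive_distortions": "tab:purple"}
    n = len(report)
    fig, ax = plt.subplots(figsize=(6, 0.32 * n + 1.2))
    ys = np.arange(n)[::-1]
    for y, (_, row) in zip(ys, report.iterrows()):
        color = palette.get((categories or {}).get(row["qid"]), "tab:gray")
        filled = row["tier"] == "fdr_significant"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color=color, lw=1.2)
        ax.plot(row["estimate"], y, "o", color=color,
                mfc=color if filled else "white", ms=6)
    ax.axvline(0.0, color="0.6", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(report["qid"])
    ax.set_xlabel(str(report["kind"].iloc[0]))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
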