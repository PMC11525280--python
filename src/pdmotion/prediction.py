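"""Sparse linear prediction of the total UPDRS-III motor score.

An elastic net (mixed L1/L2 penalty) selects a sparse subset of the 62
motor metrics. Hyperparameters are chosen by grid search under a model-
complexity cap: any candidate whose degrees of freedom (count of nonzero
coefficients on the full-data fit) exceed 50% of the cohort size is
discarded, and among the survivors the pair with the highest leave-one-out
cross-validated R^2 wins. Features are re-standardized inside every
training fold so the held-out subject never leaks into the scaling. The
selected LOOCV performance is reported directly (one grid search plus
LOOCV, not nested cross-validation; the optimistic-selection caveat is
documented in the methods note).

The penalized objective is

    (1/2n) * sum (y - b0 - X b)^2 + lam * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)

with mixing ``alpha`` in (0, 1] and penalty ``lam`` >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from pdmotion.errors import ConfigError, ValidationError

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))
N_LAMBDA = 50
LAMBDA_MIN_RATIO = 1e-3
DF_CAP_FRAC = 0.5
SOLVER_TOL = 1e-7
#: Looser duality-gap tolerance for the hyperparameter-search paths; the
#: selected model is refit at SOLVER_TOL.
PATH_TOL = 1e-5
MAX_ITER = 50_000


@dataclass
class ElasticNetFit:
    """A fitted elastic net with its standardization frozen."""

    intercept: float
    coef: np.ndarray           # coefficients on standardized features
    alpha: float               # L1/L2 mixing
    lam: float                 # penalty strength
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: Optional[list[str]] = None

    @property
    def df(self) -> int:
        """Degrees of freedom: number of nonzero coefficients."""
        return int(np.count_nonzero(self.coef))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef.size:
            raise ValidationError(
                f"feature mismatch: model has {self.coef.size}, input has {X.shape[1]}"
            )
        return self.intercept + ((X - self.x_mean) / self.x_sd) @ self.coef


@dataclass
class CVReport:
    """Per-subject predictions and summary accuracy."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scheme: str = "loo"
    extra: dict = field(default_factory=dict)

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.y_true - self.y_pred)))

    @property
    def r2(self) -> float:
        ss_res = float(np.sum((self.y_true - self.y_pred) ** 2))
        ss_tot = float(np.sum((self.y_true - self.y_true.mean()) ** 2))
        return 1.0 - ss_res / ss_tot


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _check_finite(X: np.ndarray, y: np.ndarray) -> None:
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in X or y (impute first)")


def fit_enet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    feature_names: Optional[list[str]] = None,
) -> ElasticNetFit:
    """Fit the elastic net at one (alpha, lam), standardizing X internally
    and centering y (intercept = training mean of y)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 subjects")
    Xs, mean, sd = _standardize_fit(X)
    y_mean = y.mean()
    if lam <= 0:
        # unpenalized limit: least squares on standardized features
        coef, *_ = np.linalg.lstsq(Xs, y - y_mean, rcond=None)
    else:
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False,
            tol=SOLVER_TOL, max_iter=MAX_ITER,
        )
        model.fit(Xs, y - y_mean)
        coef = model.coef_.copy()
    return ElasticNetFit(
        intercept=float(y_mean), coef=coef, alpha=alpha, lam=lam,
        x_mean=mean, x_sd=sd, feature_names=feature_names,
    )


def enet_objective(X: np.ndarray, y: np.ndarray, fit: ElasticNetFit) -> float:
    """Value of the penalized objective at a fit (standardized scale)."""
    Xs = (np.asarray(X, float) - fit.x_mean) / fit.x_sd
    r = np.asarray(y, float) - fit.intercept - Xs @ fit.coef
    n = y.shape[0]
    penalty = fit.lam * (
        fit.alpha * np.abs(fit.coef).sum() + 0.5 * (1 - fit.alpha) * (fit.coef**2).sum()
    )
    return float(0.5 * (r @ r) / n + penalty)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty shrinking every coefficient to zero."""
    Xs, _, _ = _standardize_fit(np.asarray(X, float))
    yc = np.asarray(y, float) - np.mean(y)
    return float(np.max(np.abs(Xs.T @ yc)) / (X.shape[0] * max(alpha, 1e-12)))


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = N_LAMBDA,
    min_ratio: float = LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(X, y, alpha)
    return lmax * np.logspace(0.0, math.log10(min_ratio), n_lambda)


def loocv(X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> CVReport:
    """Leave-one-out CV by explicit per-fold refitting.

    Each fold re-standardizes on its n-1 training subjects and predicts
    the held-out subject; no shortcut formulas are used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n = y.size
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 subjects")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = fit_enet(X[mask], y[mask], alpha, lam)
        preds[i] = fit.predict(X[i : i + 1])[0]
    return CVReport(y_true=y.copy(), y_pred=preds)


def _warm_path_coefs(
    Xs: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray,
    tol: float = PATH_TOL,
) -> np.ndarray:
    """Coefficients along a descending penalty path with warm starts."""
    model = ElasticNet(
        alpha=lambdas[0], l1_ratio=alpha, fit_intercept=False,
        tol=tol, max_iter=MAX_ITER, warm_start=True, precompute=True,
    )
    out = np.empty((lambdas.size, Xs.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for j, lam in enumerate(lambdas):
            model.set_params(alpha=lam)
            model.fit(Xs, yc)
            out[j] = model.coef_
    return out


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    lambda_grids: Optional[dict[float, np.ndarray]] = None,
    df_cap_frac: float = DF_CAP_FRAC,
    n_lambda: int = N_LAMBDA,
    feature_names: Optional[list[str]] = None,
    _test_row_fn: Optional[Callable[[int], np.ndarray]] = None,
) -> tuple[ElasticNetFit, CVReport]:
    """Hyperparameter grid search under the degrees-of-freedom cap.

    For every (alpha, lam): LOOCV R^2 (per-fold refits with warm starts
    along the penalty path) and the full-data DF. Pairs whose DF exceeds
    ``floor(df_cap_frac * n)`` are discarded; the surviving pair with the
    highest LOOCV R^2 wins, ties broken by smaller DF then larger penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n = y.size
    if not len(alpha_grid):
        raise ConfigError("alpha grid is empty")
    alphas = list(alpha_grid)
    if lambda_grids is None:
        lambda_grids = {a: lambda_grid(X, y, a, n_lambda=n_lambda) for a in alphas}
    cap = math.floor(df_cap_frac * n)

    # full-data DF per (alpha, lam); the cap is enforced on these fits
    Xs_full, _, _ = _standardize_fit(X)
    yc_full = y - y.mean()
    dfs = {
        a: np.count_nonzero(_warm_path_coefs(Xs_full, yc_full, a, lambda_grids[a]), axis=1)
        for a in alphas
    }
    accepted = {a: np.flatnonzero(dfs[a] <= cap) for a in alphas}
    if not any(idx.size for idx in accepted.values()):
        raise ConfigError(
            "every grid point violates the DF cap; extend the lambda grid upward"
        )

    # LOOCV predictions, only for grid points surviving the cap
    preds = {a: np.empty((lambda_grids[a].size, n)) for a in alphas}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xs, mean, sd = _standardize_fit(X[mask])
        yc = y[mask] - y[mask].mean()
        row = X[i] if _test_row_fn is None else _test_row_fn(i)
        xs_test = (row - mean) / sd
        for a in alphas:
            if accepted[a].size == 0:
                continue
            jmax = int(accepted[a].max())
            coefs = _warm_path_coefs(Xs, yc, a, lambda_grids[a][: jmax + 1])
            preds[a][: jmax + 1, i] = y[mask].mean() + coefs @ xs_test

    best = None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for a in alphas:
        lams = lambda_grids[a]
        for j in accepted[a]:
            lam = lams[j]
            r2 = 1.0 - float(np.sum((y - preds[a][j]) ** 2)) / ss_tot
            key = (r2, -int(dfs[a][j]), lam)
            if best is None or key > best[0]:
                best = (key, a, lam, preds[a][j].copy())
    _, a_best, lam_best, pred_best = best
    fit = fit_enet(X, y, a_best, lam_best, feature_names=feature_names)
    max_accepted_df = max(
        int(dfs[a][accepted[a]].max()) for a in alphas if accepted[a].size
    )
    report = CVReport(
        y_true=y.copy(), y_pred=pred_best,
        extra={
            "alpha": a_best, "lambda": lam_best, "df": fit.df, "df_cap": cap,
            "max_accepted_df": max_accepted_df,
            "n_accepted": int(sum(idx.size for idx in accepted.values())),
        },
    )
    return fit, report


def transfer_predict(fit: ElasticNetFit, X_new: np.ndarray, y_new: np.ndarray) -> CVReport:
    """Apply a frozen fit (coefficients + standardization) to a new visit."""
    y_new = np.asarray(y_new, dtype=float)
    preds = fit.predict(np.asarray(X_new, dtype=float))
    return CVReport(y_true=y_new.copy(), y_pred=preds, scheme="transfer")


def cluster_augmented_fit(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    **grid_kwargs,
) -> tuple[ElasticNetFit, CVReport]:
    """Grid search with one-hot cluster indicators appended to the features.

    Indicators are penalized like any other feature. To avoid leaking the
    held-out subject's own cluster label, its indicator within each LOOCV
    fold is taken from its nearest neighbour (standardized metric space)
    among the training subjects — the best-matching-unit analogue that
    works for any label source.
    """
    X = np.asarray(X, dtype=float)
    clusters = np.asarray(clusters)
    if clusters.shape[0] != X.shape[0]:
        raise ValidationError("cluster labels not aligned with subjects")
    uniq = np.unique(clusters)
    if uniq.size == 1:
        return grid_search(X, y, **grid_kwargs)
    onehot = (clusters[:, None] == uniq[None, :]).astype(float)
    X_aug = np.column_stack([X, onehot])

    Xs, _, _ = _standardize_fit(X)

    def test_row(i: int) -> np.ndarray:
        d = np.linalg.norm(Xs - Xs[i], axis=1)
        d[i] = np.inf
        nn = int(np.argmin(d))
        ind = (clusters[nn] == uniq).astype(float)
        return np.concatenate([X[i], ind])

    return grid_search(X_aug, y, _test_row_fn=test_row, **grid_kwargs)
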