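"""Penalized prediction of cognitive scores from gaze metrics.

The predictive layer mirrors the study protocol: z-score metrics and the
target score, hold out ~20% of participants, choose the L1 penalty by
leave-one-out cross-validated RMSE on the training part, refit at the chosen
penalty, and report test-set r, R^2, MAE and RMSE (errors in SD units of the
standardized response, so a negative R^2 flags a model worse than the
test-mean baseline).

The objective is ``(1/2n)||y - Xb||^2 + lambda ||b||_1`` (the coordinate-
descent normalization), so the analytic all-zero threshold on standardized
data is ``lambda_max = max_j |x_j . y| / n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, lasso_path
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


@dataclass
class SplitResult:
    """Seeded participant split with train-only standardization."""

    X_train: pd.DataFrame
    y_train: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series
    predictor_means: pd.Series
    predictor_sds: pd.Series
    y_mean: float
    y_sd: float
    train_ids: list[str]
    test_ids: list[str]
    n_dropped_missing: int = 0


def split_and_standardize(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    target: str,
    predictors: list[str] | None = None,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> SplitResult:
    """Seeded 80/20 participant split with leakage-free z-scoring.

    Standardization statistics come from the training rows only and are
    applied to both parts. Participants with any missing predictor or target
    value are dropped (counted in ``n_dropped_missing``). Train fraction maps
    to the nearest-integer train size.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if target not in scores.columns:
        raise ValueError(f"target {target!r} is not a score column")
    if predictors is None:
        from .metrics import METRIC_COLUMNS

        predictors = [c for c in METRIC_COLUMNS if c in metrics.columns]
    data = metrics.merge(scores[["participant_id", target]], on="participant_id")
    complete = data.dropna(subset=[*predictors, target])
    n_dropped = len(data) - len(complete)
    n = len(complete)
    if n < 5:
        raise ValueError(f"only {n} complete participants; need at least 5")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 3), n - 2)
    train = complete.iloc[order[:n_train]]
    test = complete.iloc[order[n_train:]]

    mu = train[predictors].mean()
    sd = train[predictors].std(ddof=1)
    zero = sd[sd == 0.0]
    if len(zero):
        raise ValueError(f"zero-SD predictor(s) on the training part: {list(zero.index)}")
    y_mu = float(train[target].mean())
    y_sd = float(train[target].std(ddof=1))
    if y_sd == 0.0:
        raise ValueError(f"target {target!r} has zero SD on the training part")

    return SplitResult(
        X_train=(train[predictors] - mu) / sd,
        y_train=(train[target] - y_mu) / y_sd,
        X_test=(test[predictors] - mu) / sd,
        y_test=(test[target] - y_mu) / y_sd,
        predictor_means=mu,
        predictor_sds=sd,
        y_mean=y_mu,
        y_sd=y_sd,
        train_ids=list(train["participant_id"]),
        test_ids=list(test["participant_id"]),
        n_dropped_missing=n_dropped,
    )


def lasso_coefficients(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Coefficients and intercept of one L1 fit at a fixed penalty.

    This is the single-penalty solve behind :class:`LassoLOOCV`; at
    ``alpha >= alpha_max`` every coefficient is exactly zero, and as
    ``alpha -> 0`` the solution approaches ordinary least squares.
    """
    fit = Lasso(alpha=alpha, tol=tol, max_iter=max_iter).fit(X, y)
    return fit.coef_, float(fit.intercept_)


class LassoLOOCV(RegressorMixin, BaseEstimator):
    """L1-penalized regression with the penalty chosen by LOOCV RMSE.

    The penalty grid is ``n_alphas`` log-spaced values descending from the
    analytic ``alpha_max`` (at which every coefficient is exactly zero) down
    to ``alpha_max * alpha_min_ratio``. For every grid value the LOOCV RMSE
    is assembled from n leave-one-out refits (computed as one coordinate-
    descent path per fold); ties in the minimum resolve toward the larger
    penalty (the sparser model). The final coefficients are a refit on all
    training rows at the selected penalty.

    Attributes
    ----------
    alphas_ : descending penalty grid
    loocv_rmse_ : LOOCV RMSE per grid value
    alpha_ : selected penalty
    coef_, intercept_ : refit at ``alpha_``
    """

    def __init__(
        self,
        n_alphas: int = 100,
        alpha_min_ratio: float = 1e-4,
        max_iter: int = 100_000,
        tol: float = 1e-4,
        refit_tol: float = 1e-8,
    ):
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.max_iter = max_iter
        self.tol = tol
        self.refit_tol = refit_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 training rows for LOOCV")
        self.n_features_in_ = X.shape[1]
        yc = y - y.mean()
        alpha_max = float(np.max(np.abs(X.T @ yc)) / n)
        if alpha_max == 0.0:  # response orthogonal to every predictor
            alpha_max = 1.0
        self.alpha_max_ = alpha_max
        self.alphas_ = alpha_max * np.logspace(
            0.0, np.log10(self.alpha_min_ratio), self.n_alphas
        )

        press = np.zeros(self.n_alphas)  # sum of squared LOO prediction errors
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            # center per fold: lasso_path solves without an intercept
            mu_x = X[keep].mean(axis=0)
            mu_y = y[keep].mean()
            _, coefs, _ = lasso_path(
                X[keep] - mu_x,
                y[keep] - mu_y,
                alphas=self.alphas_,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            preds = (X[i] - mu_x) @ coefs + mu_y
            press += (preds - y[i]) ** 2
        self.loocv_rmse_ = np.sqrt(press / n)
        best = float(np.min(self.loocv_rmse_))
        # grid is descending, so the first index at the minimum is the largest alpha
        sel = int(np.flatnonzero(self.loocv_rmse_ <= best)[0])
        self.alpha_ = float(self.alphas_[sel])

        self.coef_, self.intercept_ = lasso_coefficients(
            X, y, self.alpha_, tol=self.refit_tol, max_iter=self.max_iter
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def selected_predictors(self, names: list[str]) -> dict[str, float]:
        """Nonzero standardized coefficients keyed by predictor name."""
        check_is_fitted(self, "coef_")
        return {nm: float(b) for nm, b in zip(names, self.coef_) if b != 0.0}


def fit_lasso_loocv(X, y, n_alphas: int = 100, alpha_min_ratio: float = 1e-4) -> LassoLOOCV:
    """Functional wrapper over :class:`LassoLOOCV`."""
    return LassoLOOCV(n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio).fit(X, y)


@dataclass
class ModelPerformance:
    """Test-set performance estimates (standardized-response scale)."""

    r: float
    r2: float
    mae: float
    rmse: float


def evaluate_on_test(model, X_test, y_test) -> ModelPerformance:
    """r, R^2, MAE and RMSE of a fitted model on the held-out part.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the *test-set* response mean,
    so it may be negative; r is the Pearson correlation of predictions and
    observations (0 when the predictions are constant).
    """
    y = np.asarray(y_test, dtype=float)
    if len(y) < 3:
        raise ValueError("test set needs at least 3 rows")
    pred = np.asarray(model.predict(X_test), dtype=float)
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if pred.std() == 0.0 or y.std() == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    return ModelPerformance(
        r=r,
        r2=r2,
        mae=float(np.abs(resid).mean()),
        rmse=float(np.sqrt((resid**2).mean())),
    )


def run_lasso_analysis(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    target: str,
    predictors: list[str] | None = None,
    train_fraction: float = 0.8,
    seed: int | None = None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-4,
) -> dict:
    """Full split -> LOOCV penalty selection -> test evaluation, as a report dict."""
    split = split_and_standardize(
        metrics, scores, target, predictors, train_fraction=train_fraction, seed=seed
    )
    model = LassoLOOCV(n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio).fit(
        split.X_train.to_numpy(), split.y_train.to_numpy()
    )
    perf = evaluate_on_test(model, split.X_test.to_numpy(), split.y_test.to_numpy())
    names = list(split.X_train.columns)
    return {
        "target": target,
        "predictors": names,
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "n_dropped_missing": split.n_dropped_missing,
        "alpha_max": model.alpha_max_,
        "alpha_selected": model.alpha_,
        "alphas": list(map(float, model.alphas_)),
        "loocv_rmse": list(map(float, model.loocv_rmse_)),
        "coefficients": {nm: float(b) for nm, b in zip(names, model.coef_)},
        "selected": model.selected_predictors(names),
        "performance": {
            "r": perf.r,
            "r2": perf.r2,
            "mae": perf.mae,
            "rmse": perf.rmse,
        },
        "seed": seed,
    }
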