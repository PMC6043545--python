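"""From-scratch ridge regression with cross-validated shrinkage.

The exploitation-status drivers are strongly multicollinear (prices
move together, climate indices covary, dummies overlap), so ordinary
least squares

    beta_hat = (X'X)^{-1} X'y

is unstable.  The ridge estimator stabilizes it by penalizing the
coefficient norm,

    beta_ridge(lambda) = (X'X + lambda * I_p)^{-1} X'y,

the minimizer of the penalized sum of squares

    sum_i (y_i - sum_j x_ij beta_j)^2 + lambda * sum_j beta_j^2.

Implementation contract:

* all predictors (dummies included) are standardized to mean 0 / unit
  variance before penalization, so a single lambda is meaningful across
  heterogeneous units; returned coefficients are back-transformed;
* the intercept is unpenalized, handled by centering the response;
* solves use a Cholesky factorization of (Z'Z + lambda*I), never an
  explicit inverse;
* lambda multiplies the *sum* of squares by default; ``lambda_scale=
  "mean"`` divides the loss by n instead (the convention of popular
  penalized-regression software), which rescales lambda by n — reported
  lambdas are not comparable across the two conventions.

``cv_select`` chooses lambda by seeded k-fold (default 10) cross-
validation, re-standardizing inside each training fold, and reports
both the MSE-minimizing lambda and the one-standard-error lambda (the
largest lambda whose mean CV error is within one standard error of the
minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .errors import SingularMatrixError, ValidationError
from .features import RESPONSE_COLUMN, feature_columns

_MAX_COND = 1e12


def _as_matrix(X, columns=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    x = np.asarray(X, dtype=float)
    if x.ndim != 2:
        raise ValidationError("X must be two-dimensional")
    return x, (list(columns) if columns is not None else [f"x{j}" for j in range(x.shape[1])])


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to unit (population) variance.

    Zero-variance columns are centered but left unscaled (scale 1), so
    they become all-zero and draw a zero coefficient under any positive
    penalty.
    """
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, means, scales


@dataclass
class RidgeFit:
    """One fitted ridge (or OLS, lambda=0) model."""

    lam: float
    intercept: float
    coefficients: dict[str, float]  # original predictor scale
    coef_standardized: dict[str, float]  # per-SD scale used in the solve
    means: dict[str, float]
    scales: dict[str, float]
    n: int
    p: int
    lambda_scale: str = "sum"

    @property
    def columns(self) -> list[str]:
        return list(self.coefficients)

    def coef_vector(self, standardized: bool = False) -> np.ndarray:
        src = self.coef_standardized if standardized else self.coefficients
        return np.array([src[c] for c in self.columns])

    def predict(self, X) -> np.ndarray:
        x, cols = _as_matrix(X, self.columns)
        if isinstance(X, pd.DataFrame):
            x = X[self.columns].to_numpy(dtype=float)
        elif x.shape[1] != self.p:
            raise ValidationError(f"expected {self.p} predictors, got {x.shape[1]}")
        return self.intercept + x @ self.coef_vector()


def ols_fit(X, y, columns=None, intercept: bool = True) -> RidgeFit:
    """Ordinary least squares via the normal equations.

    Solves (X'X)^{-1} X'y directly on the given design (an intercept
    column is prepended unless ``intercept=False``), with no
    standardization — the unpenalized solution is invariant to it.

    Raises
    ------
    SingularMatrixError
        If X'X is singular or numerically ill-conditioned; use a
        positive ridge penalty instead.
    """
    x, cols = _as_matrix(X, columns)
    yv = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != yv.size:
        raise ValidationError(f"X has {x.shape[0]} rows but y has {yv.size}")
    a = np.column_stack([np.ones(x.shape[0]), x]) if intercept else x
    gram = a.T @ a
    if np.linalg.cond(gram) > _MAX_COND:
        raise SingularMatrixError(
            "X'X is singular or ill-conditioned; a positive lambda regularizes it"
        )
    beta = np.linalg.solve(gram, a.T @ yv)
    if intercept:
        b0, slopes = float(beta[0]), beta[1:]
    else:
        b0, slopes = 0.0, beta
    n, p = x.shape
    return RidgeFit(
        lam=0.0,
        intercept=b0,
        coefficients=dict(zip(cols, slopes)),
        coef_standardized=dict(zip(cols, slopes * x.std(axis=0, ddof=0))),
        means=dict(zip(cols, x.mean(axis=0))),
        scales=dict(zip(cols, x.std(axis=0, ddof=0))),
        n=n,
        p=p,
    )


def ols_min_norm(X, y, columns=None) -> RidgeFit:
    """Minimum-norm least squares on the standardized design (SVD).

    For exactly collinear designs — e.g. a full dummy encoding plus an
    intercept — the least-squares solution is a family; this returns
    the representative with the smallest standardized-coefficient norm,
    the limit of the ridge solution as lambda -> 0.  On full-rank
    designs it coincides with :func:`ols_fit`.
    """
    x, cols = _as_matrix(X, columns)
    yv = np.asarray(y, dtype=float).ravel()
    z, means, scales = standardize(x)
    ybar = yv.mean()
    b = np.linalg.lstsq(z, yv - ybar, rcond=None)[0]
    coef_orig = b / scales
    return RidgeFit(
        lam=0.0,
        intercept=ybar - float(coef_orig @ means),
        coefficients=dict(zip(cols, coef_orig)),
        coef_standardized=dict(zip(cols, b)),
        means=dict(zip(cols, means)),
        scales=dict(zip(cols, scales)),
        n=x.shape[0],
        p=x.shape[1],
    )


def ridge_fit(X, y, lam: float, columns=None, lambda_scale: str = "sum") -> RidgeFit:
    """Ridge estimator at a fixed penalty.

    Parameters
    ----------
    X
        n x p predictor matrix (DataFrame or array); no intercept
        column — the intercept is handled internally and unpenalized.
    y
        Response vector.
    lam
        Non-negative shrinkage constant.
    lambda_scale
        ``"sum"`` (penalty against the raw sum of squared errors,
        default) or ``"mean"`` (against the mean squared error;
        equivalent to ``"sum"`` with lambda * n).
    """
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")
    if lambda_scale not in ("sum", "mean"):
        raise ValidationError(f"lambda_scale must be 'sum' or 'mean', got {lambda_scale!r}")
    x, cols = _as_matrix(X, columns)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n != yv.size:
        raise ValidationError(f"X has {n} rows but y has {yv.size}")
    if n < 2:
        raise ValidationError("need at least 2 observations")

    lam_eff = lam * n if lambda_scale == "mean" else lam
    z, means, scales = standardize(x)
    ybar = yv.mean()
    yc = yv - ybar
    gram = z.T @ z
    rhs = z.T @ yc
    a = gram + lam_eff * np.eye(p)
    try:
        if lam_eff == 0 and np.linalg.cond(gram) > _MAX_COND:
            raise LinAlgError("ill-conditioned")
        b = cho_solve(cho_factor(a, lower=True), rhs)
    except LinAlgError as exc:
        raise SingularMatrixError(
            "X'X (+ lambda*I) is singular or ill-conditioned; "
            "a positive lambda regularizes it"
        ) from exc

    coef_orig = b / scales
    intercept = ybar - float(coef_orig @ means)
    return RidgeFit(
        lam=float(lam),
        intercept=intercept,
        coefficients=dict(zip(cols, coef_orig)),
        coef_standardized=dict(zip(cols, b)),
        means=dict(zip(cols, means)),
        scales=dict(zip(cols, scales)),
        n=n,
        p=p,
        lambda_scale=lambda_scale,
    )


def penalized_rss(Z, y, beta, lam: float) -> float:
    """The penalized sum of squares at ``beta``.

    ``Z`` and ``y`` are taken as given (pass the standardized matrix and
    centered response to evaluate the objective the solver minimizes).
    """
    z = np.asarray(Z, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    if z.shape != (yv.size, b.size):
        raise ValidationError("dimension mismatch between Z, y and beta")
    resid = yv - z @ b
    return float(resid @ resid + lam * b @ b)


def default_lambda_grid(X, y, n_points: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max_j |z_j' y_c|."""
    x, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    z, _, _ = standardize(x)
    lam_max = float(np.max(np.abs(z.T @ (yv - yv.mean()))))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_points)


@dataclass
class PathResult:
    """Coefficient trace along a lambda grid (standardized scale)."""

    lambdas: np.ndarray
    coefs: np.ndarray  # len(grid) x p, standardized scale
    coefs_original: np.ndarray
    intercepts: np.ndarray
    deviance_explained: np.ndarray  # 1 - RSS/TSS on the training data
    columns: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.lambdas):
            for j, c in enumerate(self.columns):
                rows.append(
                    {
                        "lambda": lam,
                        "variable": c,
                        "coefficient": self.coefs_original[i, j],
                        "deviance_explained": self.deviance_explained[i],
                    }
                )
        return pd.DataFrame(rows)


def lambda_path(X, y, grid, columns=None, lambda_scale: str = "sum") -> PathResult:
    """Ridge trace: one fit per lambda plus training deviance explained."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0) or np.unique(grid).size != grid.size:
        raise ValidationError("grid must be distinct non-negative lambdas")
    x, cols = _as_matrix(X, columns)
    yv = np.asarray(y, dtype=float).ravel()
    tss = float(((yv - yv.mean()) ** 2).sum())
    coefs = np.empty((grid.size, x.shape[1]))
    coefs_orig = np.empty_like(coefs)
    intercepts = np.empty(grid.size)
    dev = np.empty(grid.size)
    for i, lam in enumerate(grid):
        fit = ridge_fit(x, yv, float(lam), columns=cols, lambda_scale=lambda_scale)
        coefs[i] = fit.coef_vector(standardized=True)
        coefs_orig[i] = fit.coef_vector()
        intercepts[i] = fit.intercept
        rss = float(((yv - fit.predict(x)) ** 2).sum())
        dev[i] = 1.0 - rss / tss if tss > 0 else np.nan
    return PathResult(grid, coefs, coefs_orig, intercepts, dev, cols)


@dataclass
class CVResult:
    """k-fold cross-validation summary along a lambda grid."""

    lambda_grid: np.ndarray  # descending
    mean_mse: np.ndarray
    se_mse: np.ndarray
    fold_mse: np.ndarray  # k x len(grid)
    lambda_min: float
    lambda_1se: float
    k: int
    seed: int
    fold_assignment: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambda_grid, "mean_mse": self.mean_mse, "se_mse": self.se_mse}
        )


def cv_select(X, y, k: int = 10, grid=None, seed: int = 0, lambda_scale: str = "sum") -> CVResult:
    """Choose lambda by seeded k-fold cross-validation.

    Rows are randomly partitioned into k near-equal folds; for every
    lambda the held-out MSE is averaged across folds.  Standardization
    happens inside each training fold only (no leakage).  Ties at the
    minimal mean MSE break toward the largest lambda (more shrinkage).
    """
    x, cols = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if k < 2 or k > n:
        raise ValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    if grid is None:
        grid = default_lambda_grid(x, yv)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(folds):
        assignment[idx] = f

    fold_mse = np.empty((k, grid.size))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        xt, yt = x[train_mask], yv[train_mask]
        xh, yh = x[test_idx], yv[test_idx]
        z, means, scales = standardize(xt)
        ybar = yt.mean()
        gram = z.T @ z
        rhs = z.T @ (yt - ybar)
        zh = (xh - means) / scales
        for i, lam in enumerate(grid):
            lam_eff = lam * xt.shape[0] if lambda_scale == "mean" else lam
            try:
                b = cho_solve(cho_factor(gram + lam_eff * np.eye(x.shape[1]), lower=True), rhs)
            except LinAlgError as exc:
                raise SingularMatrixError(f"fold {f}: singular system at lambda={lam}") from exc
            pred = ybar + zh @ b
            fold_mse[f, i] = float(np.mean((yh - pred) ** 2))

    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    # grid is descending: first index attaining the min is the largest lambda
    i_min = int(np.flatnonzero(mean_mse == mean_mse.min())[0])
    threshold = mean_mse[i_min] + se_mse[i_min]
    i_1se = int(np.flatnonzero(mean_mse <= threshold)[0])
    return CVResult(
        lambda_grid=grid,
        mean_mse=mean_mse,
        se_mse=se_mse,
        fold_mse=fold_mse,
        lambda_min=float(grid[i_min]),
        lambda_1se=float(grid[i_1se]),
        k=k,
        seed=seed,
        fold_assignment=assignment,
    )


@dataclass
class FitReport:
    """Train/test evaluation plus the final full-data refit."""

    cv: CVResult
    train_fit: RidgeFit
    full_fit: RidgeFit
    test_mse: float
    test_r2: float
    deviance_explained: float  # full-data fit, 1 - RSS/TSS
    n_train: int
    n_test: int
    seed: int


def fit_and_test(
    table: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    k: int = 10,
    seed: int = 0,
    grid=None,
    lambda_scale: str = "sum",
    predictors: list[str] | None = None,
    response: str = RESPONSE_COLUMN,
) -> FitReport:
    """The full inference: split, cross-validate, evaluate, refit.

    Rows are randomly split into training (2/3 by default) and test
    sets; lambda_min comes from k-fold CV on the training set; test MSE
    and R^2 are computed from the training-only fit applied to held-out
    rows; the primary coefficient estimates come from refitting at
    lambda_min on the full data.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    cols = predictors if predictors is not None else [c for c in feature_columns() if c in table.columns]
    x = table[cols].to_numpy(dtype=float)
    yv = table[response].to_numpy(dtype=float)
    n = len(table)
    n_train = int(round(train_fraction * n))
    if n_train < k or n - n_train < 1:
        raise ValidationError(f"degenerate split: n={n}, n_train={n_train}, k={k}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    if grid is None:
        grid = default_lambda_grid(x[train_idx], yv[train_idx])
    cv = cv_select(x[train_idx], yv[train_idx], k=k, grid=grid, seed=int(rng.integers(2**31)), lambda_scale=lambda_scale)

    train_fit = ridge_fit(x[train_idx], yv[train_idx], cv.lambda_min, columns=cols, lambda_scale=lambda_scale)
    pred_test = train_fit.predict(x[test_idx])
    resid = yv[test_idx] - pred_test
    test_mse = float(np.mean(resid**2))
    tss = float(((yv[test_idx] - yv[test_idx].mean()) ** 2).sum())
    test_r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else np.nan

    full_fit = ridge_fit(x, yv, cv.lambda_min, columns=cols, lambda_scale=lambda_scale)
    rss_full = float(((yv - full_fit.predict(x)) ** 2).sum())
    tss_full = float(((yv - yv.mean()) ** 2).sum())
    dev = 1.0 - rss_full / tss_full if tss_full > 0 else np.nan
    return FitReport(
        cv=cv,
        train_fit=train_fit,
        full_fit=full_fit,
        test_mse=test_mse,
        test_r2=test_r2,
        deviance_explained=dev,
        n_train=n_train,
        n_test=n - n_train,
        seed=seed,
    )
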