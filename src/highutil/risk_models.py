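"""Risk-adjustment models: OLS linear regression and gradient-boosted trees.

Both models regress log10 PMPM on the Table-style exogenous covariates
(conditions, demographics, county, plan).  The residual ``y - yhat`` is
the quantity of interest: it isolates spending the measured risk factors
do not explain.  The boosted-tree model (regularized squared-error
objective, 1000 trees by default) is fit on a random 60% training split
with hyperparameters chosen by 5-fold cross-validation minimizing mean
squared error, and scored on train, held-out test, and all rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr as scipy_qr
from sklearn.model_selection import GridSearchCV, train_test_split
from statsmodels.stats.diagnostic import het_breuschpagan
from xgboost import XGBRegressor

from .cohort_features import DesignMatrix

logger = logging.getLogger(__name__)

DEFAULT_CV_GRID = {"max_depth": [3, 5, 7],
                   "min_child_weight": [10, 50, 200]}


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("vectors must be the same length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass
class LinearFit:
    beta: pd.Series
    fitted: np.ndarray
    residuals: pd.Series          # indexed by member_id
    r_squared: float
    f_test_p: float
    bp_statistic: float
    bp_p: float
    dropped_columns: list[str] = field(default_factory=list)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove exactly collinear columns via pivoted QR; keep the rest.

    Only exact (numerical-rank) collinearity is removed — correlated but
    distinct covariates are retained.
    """
    A = X.to_numpy(float)
    _, r, piv = scipy_qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == A.shape[1]:
        return X, []
    keep = sorted(piv[:rank])
    dropped = [X.columns[i] for i in sorted(piv[rank:])]
    logger.warning("dropping exactly collinear design columns: %s", dropped)
    return X.iloc[:, keep], dropped


def fit_linear(design: DesignMatrix) -> LinearFit:
    """Ordinary least squares on the design matrix, with fit diagnostics.

    Reports R-squared, the overall F-test p-value, and the Breusch-Pagan
    heteroscedasticity test on the residuals.
    """
    X, dropped = _drop_collinear(design.X)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns for OLS")
    if np.var(design.y) == 0:
        # degenerate response: intercept carries the mean, slopes are zero
        beta = pd.Series(0.0, index=X.columns)
        if "intercept" in beta.index:
            beta["intercept"] = float(np.mean(design.y))
        fitted = np.full(n, float(np.mean(design.y)))
        return LinearFit(
            beta=beta, fitted=fitted,
            residuals=pd.Series(design.y - fitted, index=design.member_ids,
                                name="residual"),
            r_squared=0.0, f_test_p=np.nan, bp_statistic=0.0, bp_p=1.0,
            dropped_columns=design.dropped_columns + dropped)
    res = sm.OLS(design.y, X.to_numpy(float)).fit()
    resid = pd.Series(res.resid, index=design.member_ids, name="residual")
    if p > 1 and np.var(res.resid) > 0:
        bp_stat, bp_p, _, _ = breusch_pagan(res.resid, X.to_numpy(float))
    else:
        bp_stat, bp_p = 0.0, 1.0
    return LinearFit(
        beta=pd.Series(res.params, index=X.columns),
        fitted=np.asarray(res.fittedvalues),
        residuals=resid,
        r_squared=float(res.rsquared),
        f_test_p=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else np.nan,
        bp_statistic=float(bp_stat),
        bp_p=float(bp_p),
        dropped_columns=design.dropped_columns + dropped,
    )


def breusch_pagan(residuals: np.ndarray, X: np.ndarray) -> tuple[float, float, float, float]:
    """Breusch-Pagan LM test of heteroscedasticity.

    Auxiliary regression of squared residuals on X; LM statistic is
    chi-square with (columns - 1) degrees of freedom under the null of
    constant variance.  Returns (lm, lm_p, f, f_p).
    """
    residuals = np.asarray(residuals, float)
    if np.allclose(residuals, residuals[0]):
        return 0.0, 1.0, 0.0, 1.0
    lm, lm_p, fval, f_p = het_breuschpagan(residuals, np.asarray(X, float))
    return float(lm), float(lm_p), float(fval), float(f_p)


def qq_data(residuals: np.ndarray) -> pd.DataFrame:
    """Ordered (theoretical normal quantile, standardized residual) pairs.

    Residuals are standardized to mean 0, SD 1 and sorted; theoretical
    quantiles use the symmetric plotting positions (i - 0.5) / n.
    """
    residuals = np.asarray(residuals, float)
    n = len(residuals)
    if n < 10:
        raise ValueError("need at least 10 residuals for a Q-Q curve")
    sd = residuals.std()
    if sd == 0:
        raise ValueError("zero residual variance")
    std = np.sort((residuals - residuals.mean()) / sd)
    pp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"theoretical": stats.norm.ppf(pp), "observed": std})


@dataclass
class GBMFit:
    model: XGBRegressor
    best_params: dict
    r_squared_train: float
    r_squared_test: float
    r_squared_overall: float
    residuals: pd.Series          # all rows, indexed by member_id
    split_seed: int
    cv_results: pd.DataFrame | None = None


def fit_gbm(design: DesignMatrix,
            n_estimators: int = 1000,
            learning_rate: float = 0.03,
            cv_grid: dict | None = None,
            split_seed: int = 0,
            test_size: float = 0.4,
            n_folds: int = 5) -> GBMFit:
    """Gradient-boosted regression trees with held-out adequacy check.

    40% of rows are held out; 5-fold CV on the 60% training split selects
    max depth and minimum child weight by minimum mean squared error; the
    selected model is refit on the full training split and residuals are
    computed for every row.  Similar train/test R-squared indicates the
    ensemble is not overfitting.
    """
    if cv_grid is None:
        cv_grid = DEFAULT_CV_GRID
    X = design.X.drop(columns=["intercept"], errors="ignore").to_numpy(float)
    y = np.asarray(design.y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response")
    n = len(y)
    if n < n_folds * 2:
        raise ValueError("too few rows for the requested CV folds")

    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=test_size, random_state=split_seed)

    base = XGBRegressor(
        n_estimators=n_estimators, learning_rate=learning_rate,
        objective="reg:squarederror", tree_method="hist",
        reg_lambda=1.0, n_jobs=1, random_state=split_seed)
    grid_sizes = [len(v) for v in cv_grid.values()]
    if int(np.prod(grid_sizes)) > 1:
        search = GridSearchCV(base, cv_grid, cv=n_folds,
                              scoring="neg_mean_squared_error", n_jobs=1)
        search.fit(X[idx_train], y[idx_train])
        best_params = search.best_params_
        model = search.best_estimator_
        cv_results = pd.DataFrame(search.cv_results_)
        logger.info("GBM CV selected %s", best_params)
    else:
        best_params = {k: v[0] for k, v in cv_grid.items()}
        model = base.set_params(**best_params)
        model.fit(X[idx_train], y[idx_train])
        cv_results = None

    yhat = model.predict(X)
    resid = pd.Series(y - yhat, index=design.member_ids, name="residual")
    return GBMFit(
        model=model,
        best_params=dict(best_params),
        r_squared_train=r_squared(y[idx_train], yhat[idx_train]),
        r_squared_test=r_squared(y[idx_test], yhat[idx_test]),
        r_squared_overall=r_squared(y, yhat),
        residuals=resid,
        split_seed=split_seed,
        cv_results=cv_results,
    )
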