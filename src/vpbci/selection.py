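"""Predictor selection for the arm-length estimation error.

Pipeline used to find which sensorimotor and cognitive measures explain the
arm-length Estimated Error (EE) in the older group:

1. **screening** -- columns that are (near-)constant (all participants but
   at most one share a single value) are dropped: they carry no usable
   variance and can distort the penalised fit;
2. **Lasso selection** -- an L1-penalised linear model over a 100-point
   log-spaced penalty path, the penalty chosen by leave-one-out
   cross-validated mean squared error (the minimising lambda, not 1-SE);
   predictors are z-scored internally so selection is invariant to affine
   rescaling of any column;
3. **OLS report** -- an unpenalised least-squares fit on the retained
   predictors with per-term t and p values, R-squared, adjusted R-squared,
   the model F test and Cohen's f2 = R2 / (1 - R2).

:class:`ArmErrorPredictorSelector` exposes the three stages as one
scikit-learn estimator; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso, lasso_path
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PREDICTOR_COLUMNS",
    "RESPONSE_COLUMN",
    "OlsReport",
    "screen_predictors",
    "pooled_zscore",
    "lasso_select",
    "ols_report",
    "ArmErrorPredictorSelector",
]

#: Canonical predictor-table columns.
PREDICTOR_COLUMNS = (
    "arm_tactile_2pd",
    "hand_tactile_2pd",
    "sigma_pj",
    "sigma_ol",
    "sigma_mj",
    "digit_span_forward",
    "tmt_b_minus_a",
)
RESPONSE_COLUMN = "ee_arm_length"


class EmptyDesignError(ValueError):
    """All predictor columns were screened out."""


def screen_predictors(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop near-constant predictor columns.

    A column is excluded when all participants but at most one share the
    same value (the zero-variance rule).  Returns the reduced table and the
    list of excluded column names.
    """
    if table.empty:
        raise EmptyDesignError("predictor table is empty")
    excluded = []
    for col in table.columns:
        top_count = table[col].value_counts().iloc[0]
        if top_count >= len(table) - 1:
            excluded.append(col)
    reduced = table.drop(columns=excluded)
    if reduced.shape[1] == 0:
        raise EmptyDesignError("all predictor columns were screened out")
    return reduced, excluded


def pooled_zscore(values, population) -> np.ndarray:
    """Two-stage normalisation for cross-population scores (e.g., TMT B-A).

    Values are z-scored within each population (removing cultural or
    demographic offsets between norm tables) and the result is z-scored
    again across the pooled sample.
    """
    values = np.asarray(values, dtype=float)
    population = np.asarray(population)
    out = np.empty_like(values)
    for pop in np.unique(population):
        mask = population == pop
        sd = values[mask].std(ddof=1) if mask.sum() > 1 else 0.0
        out[mask] = (values[mask] - values[mask].mean()) / (sd if sd > 0 else 1.0)
    sd = out.std(ddof=1)
    return (out - out.mean()) / (sd if sd > 0 else 1.0)


def lasso_select(
    table: pd.DataFrame,
    y,
    seed: int = 0,
    n_alphas: int = 100,
) -> tuple[float, list[str]]:
    """L1 path + leave-one-out CV; returns (lambda_star, retained columns).

    Predictors are standardised internally (within each training fold, so
    selection is invariant to affine rescaling of any column); the path
    runs over ``n_alphas`` log-spaced penalties from the smallest penalty
    that zeroes every coefficient down three decades.  ``lambda_star``
    minimises the LOOCV mean squared error (the minimising penalty, not the
    1-SE rule); retained columns are those with non-zero coefficients at
    that penalty in the full-sample fit.  The procedure is deterministic;
    ``seed`` is accepted for interface uniformity.
    """
    if len(table) < 10:
        raise ValueError("need n >= 10 participants for LOOCV selection")
    X = table.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        import warnings

        warnings.warn("design is rank-deficient after screening", UserWarning)

    def zscore(A, mu, sd):
        return (A - mu) / np.where(sd > 0, sd, 1.0)

    # shared penalty path: from the smallest penalty zeroing all coefficients
    # down three decades, 100 log-spaced values
    Xz_full = zscore(X, X.mean(axis=0), X.std(axis=0))
    alpha_max = np.max(np.abs(Xz_full.T @ (y - y.mean()))) / n
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_alphas)

    # leave-one-out CV with per-training-fold standardization
    sq_err = np.zeros(n_alphas)
    for i in range(n):
        tr = np.arange(n) != i
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        _, coefs, _ = lasso_path(
            zscore(X[tr], mu, sd), y[tr], alphas=alphas, max_iter=50_000
        )
        intercept = y[tr].mean()  # predictors are centred within the fold
        pred = zscore(X[i], mu, sd) @ coefs + intercept
        sq_err += (pred - y[i]) ** 2
    lambda_star = float(alphas[np.argmin(sq_err)])

    final = Lasso(alpha=lambda_star, max_iter=50_000)
    final.fit(Xz_full, y)
    retained = [c for c, b in zip(table.columns, final.coef_) if b != 0.0]
    return lambda_star, retained


@dataclass(frozen=True)
class OlsReport:
    """Unpenalised least-squares report on the retained predictors."""

    terms: pd.DataFrame  # index: const + retained; columns: coef, t, p
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    cohens_f2: float
    df_model: int
    df_resid: int


def ols_report(table: pd.DataFrame, retained: list[str], y) -> OlsReport:
    """OLS on the retained predictors with effect-size summary."""
    if not retained:
        raise ValueError("retained predictor set is empty")
    y = np.asarray(y, dtype=float)
    if len(y) <= len(retained) + 1:
        raise ValueError("need n > p + 1 observations for the OLS report")
    X = table[retained].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
    if rank < len(retained) + 1:
        corr = pd.DataFrame(X, columns=retained).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise np.linalg.LinAlgError(
            f"singular design: {retained[i]} and {retained[j]} are collinear"
        )
    fit = sm.OLS(y, sm.add_constant(pd.DataFrame(X, columns=retained))).fit()
    r2 = float(fit.rsquared)
    terms = pd.DataFrame(
        {"coef": fit.params, "t": fit.tvalues, "p": fit.pvalues}
    )
    return OlsReport(
        terms=terms,
        r_squared=r2,
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        cohens_f2=r2 / (1.0 - r2) if r2 < 1.0 else np.inf,
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )


class ArmErrorPredictorSelector(BaseEstimator):
    """Screen + LOOCV-Lasso + OLS pipeline as a scikit-learn estimator.

    Parameters
    ----------
    seed : int, default 0
        Random state of the coordinate-descent path (the LOOCV split order
        is deterministic).
    n_alphas : int, default 100
        Penalty-path resolution.

    Attributes
    ----------
    excluded_ : list of str
        Columns dropped by the zero-variance screen.
    lambda_ : float
        LOOCV-optimal L1 penalty.
    retained_ : list of str
        Predictors with non-zero Lasso coefficients at ``lambda_``.
    ols_ : OlsReport or None
        Report on the retained set (None when nothing was retained).
    """

    def __init__(self, seed: int = 0, n_alphas: int = 100):
        self.seed = seed
        self.n_alphas = n_alphas

    def fit(self, X: pd.DataFrame, y) -> "ArmErrorPredictorSelector":
        reduced, self.excluded_ = screen_predictors(X)
        self.lambda_, self.retained_ = lasso_select(
            reduced, y, seed=self.seed, n_alphas=self.n_alphas
        )
        self.ols_ = ols_report(reduced, self.retained_, y) if self.retained_ else None
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict the response from the retained-OLS model."""
        check_is_fitted(self, "retained_")
        if self.ols_ is None:
            raise ValueError("no predictors retained; nothing to predict with")
        coefs = self.ols_.terms["coef"]
        out = np.full(len(X), coefs["const"])
        for name in self.retained_:
            out = out + coefs[name] * X[name].to_numpy(dtype=float)
        return out
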