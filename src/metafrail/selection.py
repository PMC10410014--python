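"""LASSO selection of biomarkers independently associated with the FI.

Solves min (1/2n) ||y - X b - C g||^2 + lambda ||b||_1, where X is the
standardized biomarker panel (penalized) and C holds mandatory adjustment
covariates (age, sex; unpenalized). Because C is unpenalized, the problem
is solved exactly by Frisch-Waugh-Lovell residualization: project y and X
off C, run coordinate descent on the residuals, then recover g by OLS of
the remaining response on C.

The regularization parameter is tuned by seeded k-fold cross-validation and
the 1-SE rule: lambda_1se is the LARGEST lambda whose CV mean squared error
is within one standard error of the minimum (maximal sparsity). Biomarkers
with nonzero coefficients at lambda_1se are "selected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from ._utils import derive_rng

__all__ = ["LassoResult", "lasso_select"]


@dataclass
class LassoResult:
    lambda_path: np.ndarray  # decreasing
    cv_mse: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    coefficients: dict[str, float] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambda_path, "cv_mse": self.cv_mse, "cv_se": self.cv_se}
        )


def _residualize(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Project y and X off the column space of C (C includes an intercept)."""
    coefs, *_ = np.linalg.lstsq(C, np.column_stack([y, X]), rcond=None)
    resid = np.column_stack([y, X]) - C @ coefs
    return resid[:, 0], resid[:, 1:]


def _fit_at_lambdas(y, X, C, lambdas):
    """Penalized coefficients at each lambda (FWL on the given sample)."""
    y_r, X_r = _residualize(y, X, C)
    _, coefs, _ = lasso_path(X_r, y_r, alphas=lambdas)
    return coefs  # shape (p, n_lambdas)


def lasso_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    mandatory: pd.DataFrame | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> LassoResult:
    """Cross-validated LASSO with unpenalized mandatory covariates.

    ``X`` is expected standardized (mean 0, SD 1); if not, it is
    standardized internally with a warning. ``y`` is the raw FI (%).
    Fold assignment is a seeded shuffle, deterministic given ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n <= n_folds:
        raise ValueError("need more observations than folds")

    mu, sd = Xa.mean(axis=0), Xa.std(axis=0, ddof=1)
    if np.max(np.abs(mu)) > 1e-6 or np.max(np.abs(sd - 1)) > 1e-3:
        warnings.warn(
            "biomarker matrix not standardized; standardizing internally",
            stacklevel=2,
        )
        Xa = (Xa - mu) / sd

    if mandatory is not None and mandatory.shape[1] > 0:
        C = np.column_stack([np.ones(n), mandatory.to_numpy(dtype=float)])
        mand_names = ["intercept", *mandatory.columns]
    else:
        C = np.ones((n, 1))
        mand_names = ["intercept"]

    # lambda grid from the full residualized data (glmnet-style)
    y_r, X_r = _residualize(ya, Xa, C)
    lambda_max = np.max(np.abs(X_r.T @ y_r)) / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambdas)

    rng = derive_rng(seed, "lasso-folds")
    fold_id = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(fold_id)

    fold_mse = np.empty((n_folds, n_lambdas))
    for k in range(n_folds):
        test = fold_id == k
        train = ~test
        coefs = _fit_at_lambdas(ya[train], Xa[train], C[train], lambdas)
        # unpenalized covariate fit on training residual response
        resp = ya[train][:, None] - Xa[train] @ coefs
        g, *_ = np.linalg.lstsq(C[train], resp, rcond=None)
        pred = Xa[test] @ coefs + C[test] @ g
        fold_mse[k] = np.mean((ya[test][:, None] - pred) ** 2, axis=0)

    cv_mse = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(np.argmin(cv_mse))
    bound = cv_mse[i_min] + cv_se[i_min]
    # largest lambda meeting the 1-SE bound (lambdas are decreasing)
    i_1se = int(np.flatnonzero(cv_mse <= bound)[0])

    coefs_full = _fit_at_lambdas(ya, Xa, C, lambdas)
    beta = coefs_full[:, i_1se]
    g, *_ = np.linalg.lstsq(C, ya - Xa @ beta, rcond=None)

    coefficients = {nm: float(b) for nm, b in zip(names, beta)}
    coefficients.update({nm: float(v) for nm, v in zip(mand_names, g)})
    selected = [nm for nm, b in zip(names, beta) if b != 0.0]
    return LassoResult(
        lambda_path=lambdas,
        cv_mse=cv_mse,
        cv_se=cv_se,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        coefficients=coefficients,
        selected=selected,
    )
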