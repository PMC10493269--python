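"""SVD-based ridge (L2) regression with an efficient penalty path.

The estimator minimizes ``||X b - y||^2 + lambda ||b||^2`` on the
standardized design (intercept handled by centering, never penalized).
One singular-value decomposition of X serves the whole penalty path:
``b(lambda) = V diag(d / (d^2 + lambda)) U' y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .preprocess import DesignMatrix

_RCOND = 1e-12  # relative singular-value cutoff for the unpenalized limit


@dataclass
class RidgeFit:
    """One fitted ridge model.

    ``coef`` is on the original predictor scale (score units per raw
    predictor unit); ``coef_std`` is the penalized, standardized-scale
    solution it was back-transformed from.
    """

    lambda_: float
    intercept: float
    coef: pd.Series
    coef_std: pd.Series
    r2_train: float

    @property
    def columns(self) -> list[str]:
        return list(self.coef.index)


def _svd(design: DesignMatrix):
    X = design.X.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(design.y)):
        raise ValidationError("non-finite entries in design matrix or outcome")
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    return U, d, Vt


def _path_coefs(U, d, Vt, y, lambdas: np.ndarray) -> np.ndarray:
    """Standardized-scale coefficients, one column per penalty value."""
    uty = U.T @ y
    d2 = d**2
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = d[:, None] / (d2[:, None] + lambdas[None, :])
    # (numerically) zero singular values: pseudo-inverse limit at lambda = 0,
    # and d/(d^2+lambda) ~ 0 anyway for lambda > 0
    tiny = d <= _RCOND * (d.max() if d.size else 0.0)
    factors[tiny, :] = 0.0
    return Vt.T @ (factors * uty[:, None])


def _finalize(design: DesignMatrix, lam: float, beta_std: np.ndarray) -> RidgeFit:
    cols = design.columns
    scale = design.meta["scale"].to_numpy(dtype=float)
    center = design.meta["center"].to_numpy(dtype=float)
    coef = beta_std / scale
    intercept = design.y_center - float(coef @ center)
    resid = design.y - design.X.to_numpy() @ beta_std
    sst = float(np.sum(design.y**2))  # y is centered
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    return RidgeFit(
        lambda_=float(lam),
        intercept=float(intercept),
        coef=pd.Series(coef, index=cols),
        coef_std=pd.Series(beta_std, index=cols),
        r2_train=r2,
    )


def fit_ridge(design: DesignMatrix, lam: float) -> RidgeFit:
    """Fit ridge at one penalty value on a standardized design."""
    if lam < 0:
        raise ValidationError(f"penalty must be non-negative, got {lam}")
    if not design.standardized:
        raise ValidationError("fit_ridge requires a standardized design")
    if design.n < 2:
        raise ValidationError("need at least 2 rows")
    U, d, Vt = _svd(design)
    beta = _path_coefs(U, d, Vt, design.y, np.asarray([float(lam)]))[:, 0]
    return _finalize(design, lam, beta)


def ridge_path(design: DesignMatrix, lambdas) -> list[RidgeFit]:
    """Fit the whole penalty grid with a single shared SVD."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValidationError("empty penalty grid")
    if np.any(lambdas < 0):
        raise ValidationError("penalties must be non-negative")
    if not design.standardized:
        raise ValidationError("ridge_path requires a standardized design")
    U, d, Vt = _svd(design)
    betas = _path_coefs(U, d, Vt, design.y, lambdas)
    return [_finalize(design, lam, betas[:, j]) for j, lam in enumerate(lambdas)]


def predict(fit: RidgeFit, design: DesignMatrix) -> np.ndarray:
    """Predicted outcomes for a design matrix (standardized or raw)."""
    if list(design.X.columns) != fit.columns:
        raise ValidationError("design columns do not match fitted model")
    if design.standardized:
        X = design.X.to_numpy() * design.meta["scale"].to_numpy() + design.meta[
            "center"
        ].to_numpy()
    else:
        X = design.X.to_numpy(dtype=float)
    return fit.intercept + X @ fit.coef.to_numpy()


def r_squared(fit: RidgeFit, design: DesignMatrix) -> float:
    """Coefficient of determination of ``fit`` on ``design``'s outcome.

    Computed as 1 - SS_res/SS_tot around the evaluated sample's own mean;
    may be negative on held-out data.
    """
    y = design.y + (design.y_center if design.standardized else 0.0)
    yhat = predict(fit, design)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValidationError("outcome has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst
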