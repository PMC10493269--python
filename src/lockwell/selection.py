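"""Penalty selection by k-fold cross-validation maximizing held-out R^2.

Default protocol: k = 20 folds (each fold a 5% test set, the remaining 95%
the training set), a 100-value log-spaced penalty grid, and out-of-fold
predictions pooled over all rows to give one R^2 per penalty.  The penalty
with the highest held-out R^2 wins (ties toward the stronger penalty) and
the final model is refit on all rows at that value.  Standardization
constants are computed on each training split only, so no information leaks
into the held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .preprocess import DesignMatrix, standardize
from .ridge import RidgeFit, _path_coefs, _svd, fit_ridge


def make_folds(n: int, k: int, seed) -> np.ndarray:
    """Random partition of ``n`` rows into ``k`` folds of near-equal size.

    Returns an integer array of fold indices in 0..k-1; fold sizes differ by
    at most one (the first ``n % k`` folds get the extra row).
    """
    if not 2 <= k <= n:
        raise ValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    assignment = np.repeat(np.arange(k), sizes)
    return assignment[rng.permutation(n)]


def lambda_grid(
    design: DesignMatrix,
    n_lambda: int = 100,
    eps_scale: float = 1e-3,
    decades: float = 4.0,
) -> np.ndarray:
    """Descending log-spaced penalty grid anchored at the data scale.

    The top of the grid is ``max_j |x_j' y| / (n * eps_scale)`` — the largest
    absolute predictor-outcome inner product, inflated so the strongest
    penalty shrinks essentially everything — and the grid descends
    ``decades`` orders of magnitude from there.
    """
    if n_lambda < 1:
        raise ValidationError("n_lambda must be >= 1")
    if not design.standardized:
        raise ValidationError("lambda_grid requires a standardized design")
    xty = design.X.to_numpy().T @ design.y
    m = float(np.max(np.abs(xty)))
    if m == 0:
        raise ValidationError("degenerate design: all predictor-outcome "
                              "inner products are zero")
    lam_max = m / (design.n * eps_scale)
    if n_lambda == 1:
        return np.asarray([lam_max])
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambda)


@dataclass
class CVResult:
    """Cross-validation trace: grid, held-out R^2 curve, winner, final refit."""

    lambda_grid: np.ndarray
    r2: np.ndarray
    best_lambda: float
    folds: np.ndarray
    k: int
    fit: RidgeFit


def _lenient_constants(X: np.ndarray, time_mask: np.ndarray):
    centers = X.mean(axis=0)
    sds = X.std(axis=0)
    scales = np.where((sds == 0) | time_mask, 1.0, sds)
    return centers, scales


def cv_select_lambda(
    design: DesignMatrix,
    grid,
    k: int = 20,
    seed=0,
    pooled: bool = True,
) -> CVResult:
    """Select the ridge penalty by k-fold cross-validation.

    ``design`` must be unstandardized: each training split is standardized
    with its own constants and the held-out rows are transformed with those
    same constants before prediction.  With ``pooled`` (default) all
    out-of-fold predictions are pooled into a single R^2 per penalty;
    otherwise per-fold R^2 values are averaged.
    """
    if design.standardized:
        raise ValidationError(
            "cv_select_lambda needs the unstandardized design (per-split scaling)"
        )
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0 or np.any(grid < 0):
        raise ValidationError("invalid penalty grid")
    n = design.n
    folds = make_folds(n, k, seed)
    X = design.X.to_numpy(dtype=float)
    y = design.y.astype(float)
    time_mask = (design.meta["role"] == "time").to_numpy()
    oof = np.empty((n, grid.size))
    for f in range(k):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        centers, scales = _lenient_constants(Xtr, time_mask)
        Xtr_s = (Xtr - centers) / scales
        ytr_c = ytr - ytr.mean()
        U, d, Vt = np.linalg.svd(Xtr_s, full_matrices=False)
        betas = _path_coefs(U, d, Vt, ytr_c, grid)
        Xte_s = (X[test] - centers) / scales
        oof[test] = ytr.mean() + Xte_s @ betas
    if pooled:
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - np.sum((y[:, None] - oof) ** 2, axis=0) / sst
    else:
        r2 = np.zeros(grid.size)
        for f in range(k):
            test = folds == f
            yt = y[test]
            sst = float(np.sum((yt - yt.mean()) ** 2))
            if sst == 0:
                continue  # degenerate fold contributes nothing to the average
            r2 += (1.0 - np.sum((yt[:, None] - oof[test]) ** 2, axis=0) / sst) / k
    best_idx = int(np.argmax(r2))  # grid is descending: first max = largest lambda
    best_lambda = float(grid[best_idx])
    final = fit_ridge(standardize(design), best_lambda)
    return CVResult(
        lambda_grid=grid, r2=r2, best_lambda=best_lambda, folds=folds, k=k, fit=final
    )
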