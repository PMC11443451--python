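"""Multiple monotone imputation based on linear regression.

Missingness in the cell-means matrix is concentrated in the closest
distance bin (too few voxels near a vein); each incomplete column is
regressed on the complete columns of the same (area, compartment) cell
plus a group indicator, coefficients are drawn from their sampling
distribution, and residual noise is added per draw.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import CellMeansMatrix

__all__ = ["monotone_impute"]


def _predictor_columns(cells: CellMeansMatrix, col: int, complete: np.ndarray):
    """Complete columns sharing all within-factor levels except the bin."""
    cond = cells.conditions
    names = list(cond.names)
    target = cond[col]
    sel = []
    for j in range(len(cond)):
        if j == col or not complete[j]:
            continue
        same = all(
            cond[j][k] == target[k]
            for k, name in enumerate(names)
            if name != "distance_bin"
        )
        if same:
            sel.append(j)
    return sel


def monotone_impute(
    cells: CellMeansMatrix, m: int = 5, seed: int = 0
) -> list[CellMeansMatrix]:
    """Return ``m`` completed copies of the cell matrix (seeded).

    With no missing values this returns m identical copies.  When fewer
    complete cases than predictors + 2 are available, the regression
    falls back to intercept + group with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    Y = cells.data
    col_missing = np.isnan(Y).any(axis=0)
    complete_cols = ~col_missing
    group_levels = list(pd.unique(cells.groups))
    gdum = np.column_stack(
        [(cells.groups == lv).astype(float) for lv in group_levels[1:]]
    )

    # monotone order: least missing first
    order = sorted(np.flatnonzero(col_missing), key=lambda c: np.isnan(Y[:, c]).sum())

    out = []
    for imp in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, imp]))
        filled = np.array(Y, copy=True)
        for col in order:
            obs = ~np.isnan(Y[:, col])
            mis = ~obs
            preds = _predictor_columns(cells, col, complete_cols)
            X = np.column_stack(
                [np.ones(len(Y))] + [Y[:, j] for j in preds] + [gdum]
            )
            n_obs = int(obs.sum())
            if n_obs < X.shape[1] + 2:
                warnings.warn(
                    f"column {col}: only {n_obs} complete cases; falling back "
                    "to intercept + group regression"
                )
                X = np.column_stack([np.ones(len(Y)), gdum])
            Xo, yo = X[obs], Y[obs, col]
            XtX = Xo.T @ Xo
            XtX_pinv = np.linalg.pinv(XtX)
            beta = XtX_pinv @ (Xo.T @ yo)
            resid = yo - Xo @ beta
            k = int(np.linalg.matrix_rank(Xo))
            dof = max(n_obs - k, 1)
            sigma2 = float(resid @ resid) / dof
            # draw residual variance, then coefficients, then noise
            sigma2_star = sigma2 * dof / rng.chisquare(dof)
            cov = sigma2_star * XtX_pinv
            beta_star = rng.multivariate_normal(beta, cov, method="svd")
            noise = rng.normal(0.0, np.sqrt(sigma2_star), size=int(mis.sum()))
            filled[mis, col] = X[mis] @ beta_star + noise
        out.append(cells.copy_with(filled))
    return out
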