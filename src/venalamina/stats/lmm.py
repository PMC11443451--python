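"""Random-intercept linear mixed models by ML profile likelihood, and
likelihood-ratio comparisons of nested fixed-effect designs.

For a fixed variance ratio lambda = sigma_b^2 / sigma^2 the GLS estimates
of beta and sigma^2 are closed-form under the per-participant compound
symmetry covariance V_i = I + lambda J; lambda is then maximized by a 1D
bounded search on the log scale (with the lambda = 0 boundary checked
explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = ["LmmFit", "fit_random_intercept", "lrt_compare", "build_distance_design"]


@dataclass
class LmmFit:
    beta: np.ndarray
    sigma_b2: float
    sigma2: float
    lam: float
    loglik: float
    n_fixed: int
    n_obs: int
    formula: str = ""
    boundary: bool = False


def _profile_loglik(lam: float, X, y, blocks):
    """Profile log-likelihood and GLS estimates at fixed lambda."""
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet = 0.0
    for idx in blocks:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        w = lam / (1.0 + lam * ni)
        # V_i^{-1} = I - w J
        XtVX = Xi.T @ Xi - w * np.outer(Xi.sum(0), Xi.sum(0))
        XtVy = Xi.T @ yi - w * Xi.sum(0) * yi.sum()
        A += XtVX
        b += XtVy
        logdet += np.log1p(lam * ni)
    beta = np.linalg.solve(A, b)
    rss = 0.0
    for idx in blocks:
        ri = y[idx] - X[idx] @ beta
        ni = len(idx)
        w = lam / (1.0 + lam * ni)
        rss += ri @ ri - w * ri.sum() ** 2
    n = len(y)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return ll, beta, sigma2


def fit_random_intercept(y, X, participant_ids, formula: str = "") -> LmmFit:
    """ML fit of y = X beta + u_participant + eps with u ~ N(0, sigma_b^2)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = np.asarray(participant_ids)
    if X.shape[0] != y.size or ids.size != y.size:
        raise ValueError("design, response and participant ids must align")
    uniq, inv = np.unique(ids, return_inverse=True)
    blocks = [np.flatnonzero(inv == k) for k in range(len(uniq))]
    if min(len(b) for b in blocks) < 2:
        raise ValueError("need >= 2 observations per participant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")

    def neg(u):
        return -_profile_loglik(np.exp(u), X, y, blocks)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-10},
    )
    ll_hat = -res.fun
    lam_hat = float(np.exp(res.x))
    ll0, beta0, s0 = _profile_loglik(0.0, X, y, blocks)
    boundary = False
    if ll0 >= ll_hat - 1e-10:
        lam_hat, ll_hat = 0.0, ll0
        boundary = True
    ll, beta, sigma2 = _profile_loglik(lam_hat, X, y, blocks)
    return LmmFit(
        beta=beta,
        sigma_b2=float(lam_hat * sigma2),
        sigma2=float(sigma2),
        lam=lam_hat,
        loglik=float(ll),
        n_fixed=X.shape[1],
        n_obs=len(y),
        formula=formula,
        boundary=boundary,
    )


def lrt_compare(fit_big: LmmFit, fit_small: LmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect designs (same rows)."""
    if fit_big.n_obs != fit_small.n_obs:
        raise ValueError("models fitted on different rows are not comparable")
    df = fit_big.n_fixed - fit_small.n_fixed
    if df <= 0:
        raise ValueError("fit_big must have more fixed-effect parameters")
    chi2 = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    return chi2, df, float(sps.chi2.sf(chi2, df))


def build_distance_design(
    bins: np.ndarray, risk: np.ndarray | None = None, interaction: bool = False
) -> np.ndarray:
    """Design matrix: intercept + distance-bin dummies [+ risk [+ bin:risk]].

    ``bins`` is a vector of bin labels (5 levels gives 4 dummies); the
    interaction adds one column per bin level (risk within each bin),
    matching the 5-parameter gap between the interaction model and the
    null model.
    """
    bins = np.asarray(bins)
    levels = list(pd.unique(bins))
    cols = [np.ones(len(bins))]
    for lv in levels[1:]:
        cols.append((bins == lv).astype(float))
    if risk is not None:
        risk = np.asarray(risk, dtype=float)
        cols.append(risk)
        if interaction:
            for lv in levels[1:]:
                cols.append((bins == lv).astype(float) * risk)
    return np.column_stack(cols)
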