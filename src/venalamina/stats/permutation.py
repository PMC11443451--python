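"""Monte-Carlo permutation Welch two-sample t-test."""

from __future__ import annotations

import numpy as np

__all__ = ["permutation_welch"]


def _welch_stat(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    va = a.var(ddof=1, axis=axis)
    vb = b.var(ddof=1, axis=axis)
    na = a.shape[axis]
    nb = b.shape[axis]
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=axis) - b.mean(axis=axis)) / se


def permutation_welch(a, b, B: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo p-value of the Welch statistic under group relabelling.

    p = (1 + #{|t*| >= |t_obs|}) / (1 + B): the add-one estimator is valid
    (never anti-conservative) for any B.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 observations per group")
    if B < 1000:
        raise ValueError("B must be >= 1000")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("combined sample is constant")
    t_obs = _welch_stat(a, b)

    rng = np.random.default_rng(seed)
    na = a.size
    # one permuted relabelling per row
    perm = rng.permuted(np.broadcast_to(pooled, (B, pooled.size)), axis=1)
    t_star = _welch_stat(perm[:, :na], perm[:, na:], axis=1)
    t_star = np.nan_to_num(t_star, nan=np.inf)  # constant halves: extreme
    # count ties despite permutation-order roundoff (keeps the p valid)
    tol = 1e-9 * max(1.0, abs(t_obs))
    exceed = np.count_nonzero(np.abs(t_star) >= abs(t_obs) - tol)
    return float((1 + exceed) / (1 + B))
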