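"""Post hoc tests: paired and Welch t-tests, Hedges-corrected Cohen's d
with percentile-bootstrap CIs, Holm-Bonferroni adjustment, and Pearson
correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t",
    "welch_t",
    "hedges_d",
    "holm_bonferroni",
    "pearson_corr",
]


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    d: float | None = None
    d_ci: tuple[float, float] | None = None
    p_holm: float | None = None
    n: tuple[int, ...] = ()


def _hedges_j(df: float) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def paired_t(x, y) -> TestResult:
    """Two-tailed paired-samples t-test on equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired test needs equal-length samples of size >= 3")
    diff = x - y
    sd = diff.std(ddof=1)
    n = diff.size
    if sd == 0:
        if np.allclose(diff, 0):
            return TestResult(t=0.0, df=n - 1, p=1.0, n=(n,))
        raise ValueError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    return TestResult(t=float(t), df=float(df),
                      p=float(2 * sps.t.sf(abs(t), df)), n=(n,))


def welch_t(a, b) -> TestResult:
    """Two-tailed independent-samples Welch t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("Welch test needs >= 3 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return TestResult(t=0.0, df=na + nb - 2, p=1.0, n=(na, nb))
        raise ValueError("zero variance in both groups")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return TestResult(t=float(t), df=float(df),
                      p=float(2 * sps.t.sf(abs(t), df)), n=(na, nb))


def hedges_d(
    x, y=None, *, paired: bool = False, B_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Hedges-corrected Cohen's d with a percentile bootstrap CI.

    Paired: d = mean(x - y) / sd(x - y) * J with J = 1 - 3/(4 df - 1),
    df = n - 1.  Independent: d = (mean_a - mean_b) / s_pooled * J,
    df = n_a + n_b - 2.  Pairs are resampled jointly; groups within group.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)

    if paired:
        y = np.asarray(y, dtype=float)
        diff = x - y

        def stat(d):
            sd = d.std(ddof=1)
            if sd == 0:
                raise ValueError("zero sd of paired differences")
            return d.mean() / sd * _hedges_j(d.size - 1)

        d_hat = stat(diff)
        n = diff.size
        boots = np.empty(B_boot)
        for b in range(B_boot):
            idx = rng.integers(0, n, n)
            rs = diff[idx]
            sd = rs.std(ddof=1)
            boots[b] = rs.mean() / sd * _hedges_j(n - 1) if sd > 0 else 0.0
    else:
        y = np.asarray(y, dtype=float)

        def stat2(a, b):
            na, nb = a.size, b.size
            sp = np.sqrt(
                ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                / (na + nb - 2)
            )
            if sp == 0:
                raise ValueError("zero pooled sd")
            return (a.mean() - b.mean()) / sp * _hedges_j(na + nb - 2)

        d_hat = stat2(x, y)
        boots = np.empty(B_boot)
        for b in range(B_boot):
            ra = x[rng.integers(0, x.size, x.size)]
            rb = y[rng.integers(0, y.size, y.size)]
            try:
                boots[b] = stat2(ra, rb)
            except ValueError:
                boots[b] = 0.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(d_hat), (float(lo), float(hi))


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order.

    adjusted_(i) = min(1, max_{j <= i} p_(j) * (m - j + 1)) over ascending
    ranks; monotone non-decreasing in rank and >= the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, p[idx] * (m - rank))
        adj[idx] = min(1.0, running)
    return adj


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length samples of size >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance")
    r = float((xc * yc).sum() / denom)
    n = x.size
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * sps.t.sf(abs(t), n - 2))
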