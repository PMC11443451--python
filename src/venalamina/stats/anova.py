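"""Mixed-design ANOVA: univariate split-plot path with Greenhouse-Geisser
correction and multivariate (Wilks/Hotelling) path, generalized
eta-squared, and D2 pooling across imputations.

One between-subject factor crossed with any number of within-subject
factors.  The univariate path decomposes the total sum of squares into
orthogonal strata via orthonormal within-factor contrasts (each within
effect keeps its own interaction-with-subjects error term), so the SS
ledger conserves total variance exactly.  The multivariate path tests
each within effect (and its interaction with the between factor) on the
contrast scores with an exact F when the hypothesis has rank one, which
reproduces DFd = N - g - p + 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CellMeansMatrix

__all__ = [
    "AnovaResult",
    "mixed_anova",
    "gg_epsilon",
    "generalized_eta_squared",
    "pool_imputed_anova",
]


@dataclass
class AnovaResult:
    """Per-effect statistics plus the sum-of-squares ledger."""

    table: pd.DataFrame
    ss_total: float
    ss_subjects: float
    ss_error_total: float
    marginal_means: pd.DataFrame | None = None

    def ledger_residual(self) -> float:
        """Relative gap between total SS and the sum of all SS entries."""
        acc = self.ss_subjects + float(self.table["SS"].sum()) + self.ss_error_total
        return abs(acc - self.ss_total) / max(self.ss_total, 1e-300)


def orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the space orthogonal to the constant."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    # Helmert-style, then orthonormalized (deterministic)
    raw = np.zeros((k, k - 1))
    for j in range(k - 1):
        raw[: j + 1, j] = 1.0
        raw[j + 1, j] = -(j + 1.0)
    q, _ = np.linalg.qr(raw)
    return q


def _contrast_matrix(levels: dict[str, int], subset: tuple[str, ...]) -> np.ndarray:
    """Kronecker contrast matrix for a within-effect subset.

    ``levels`` must be in the condition-index order (last factor varying
    fastest), matching numpy's kron convention.
    """
    parts = []
    for name, k in levels.items():
        if name in subset:
            parts.append(orthonormal_contrasts(k))
        else:
            parts.append(np.full((k, 1), 1.0 / np.sqrt(k)))
    C = parts[0]
    for p in parts[1:]:
        C = np.kron(C, p)
    return C


def gg_epsilon(contrast_covariance: np.ndarray, k: int) -> float:
    """Greenhouse-Geisser epsilon from the contrast-score covariance.

    epsilon = (tr S)^2 / ((k - 1) tr(S^2)), clipped to [1/(k-1), 1].
    """
    S = np.asarray(contrast_covariance, dtype=float)
    S = np.atleast_2d(S)
    tr = float(np.trace(S))
    if tr <= 0:
        raise ValueError("zero-trace contrast covariance")
    p = k - 1
    eps = tr**2 / (p * float(np.trace(S @ S)))
    return float(np.clip(eps, 1.0 / p, 1.0))


def generalized_eta_squared(
    ss_effect: float, ss_subjects: float, ss_error_total: float
) -> float:
    """eta^2_G = SS_effect / (SS_effect + SS_subjects + sum of error SS)."""
    if min(ss_effect, ss_subjects, ss_error_total) < -1e-12:
        raise ValueError("negative sum of squares")
    denom = ss_effect + ss_subjects + ss_error_total
    return float(ss_effect / denom) if denom > 0 else 0.0


def _wilks_f(H: np.ndarray, E: np.ndarray, q: int, df_e: int) -> tuple[float, float, float, float]:
    """Rao's F for Wilks lambda; exact when min(p, q) <= 2.

    Returns (F, df1, df2, p_value).
    """
    p = H.shape[0]
    if df_e < p:
        # too few subjects for the multivariate test on p contrast scores
        return float("nan"), float(p * q), float("nan"), float("nan")
    sH, ldH = np.linalg.slogdet(E)
    sHE, ldHE = np.linalg.slogdet(E + H)
    if sH <= 0 or sHE <= 0:
        return float("nan"), float(p * q), float("nan"), float("nan")
    lam = np.exp(ldH - ldHE)
    pq = p * q
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    df2 = t * (df_e - (p - q + 1) / 2.0) - (pq - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t <= 0:
        return float("inf"), pq, df2, 0.0
    F = (1.0 - lam_t) / lam_t * df2 / pq
    return float(F), float(pq), float(df2), float(sps.f.sf(F, pq, df2))


def mixed_anova(
    cells: CellMeansMatrix,
    between: str = "group",
    within: list[str] | None = None,
) -> AnovaResult:
    """Mixed ANOVA with both the univariate-GG and multivariate paths.

    The returned table has one row per effect with: DFn/DFd/F/p of the
    univariate path, GG epsilon and corrected p, DFn/DFd/F/p of the
    multivariate path, SS, error SS, and eta^2_G.
    """
    Y = cells.data
    if np.isnan(Y).any():
        bad = [s for s, r in zip(cells.subjects, np.isnan(Y).any(axis=1)) if r]
        raise ValueError(
            f"missing cells for subjects {bad}; impute or drop before the ANOVA"
        )
    within = within or cells.within_factors
    if list(cells.within_factors) != list(within):
        raise ValueError("within factors must match the condition index order")

    group_levels = list(pd.unique(cells.groups))
    g = len(group_levels)
    N, K = Y.shape
    if g < 2 or min(np.sum(cells.groups == lv) for lv in group_levels) < 2:
        raise ValueError("need >= 2 subjects in each of >= 2 groups")
    group_rows = [np.flatnonzero(cells.groups == lv) for lv in group_levels]
    n_g = np.array([len(r) for r in group_rows])

    levels = {f: len(cells.conditions.get_level_values(f).unique()) for f in within}

    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    # between-subject stratum on subject means
    s = Y.mean(axis=1)
    s_g = np.array([s[r].mean() for r in group_rows])
    s_bar = s.mean()
    ss_between = float(K * np.sum(n_g * (s_g - s_bar) ** 2))
    ss_subjects = float(K * sum(((s[r] - m) ** 2).sum() for r, m in zip(group_rows, s_g)))
    if ss_subjects <= 0:
        raise ValueError("degenerate data: zero subject variability")
    F_b = (ss_between / (g - 1)) / (ss_subjects / (N - g))
    rows = [
        {
            "effect": between,
            "DFn": g - 1,
            "DFd": N - g,
            "F": F_b,
            "p": float(sps.f.sf(F_b, g - 1, N - g)),
            "eps_GG": np.nan,
            "p_GG": np.nan,
            "F_multi": F_b,
            "DFn_multi": g - 1,
            "DFd_multi": N - g,
            "p_multi": float(sps.f.sf(F_b, g - 1, N - g)),
            "SS": ss_between,
            "SS_error": ss_subjects,
        }
    ]

    subsets = []
    for r in range(1, len(within) + 1):
        subsets.extend(itertools.combinations(within, r))

    ss_error_total = 0.0
    for subset in subsets:
        C = _contrast_matrix(levels, subset)
        p = C.shape[1]
        Z = Y @ C
        zbar = Z.mean(axis=0)
        zbar_g = np.vstack([Z[r].mean(axis=0) for r in group_rows])

        ss_w = float(N * (zbar**2).sum())
        ss_wg = float(np.sum(n_g[:, None] * zbar_g**2) - N * (zbar**2).sum())
        resid = [Z[r] - m for r, m in zip(group_rows, zbar_g)]
        E = sum(rz.T @ rz for rz in resid)
        E = np.atleast_2d(E)
        ss_err = float(np.trace(E))
        if ss_err <= 0 and (ss_w > 0 or ss_wg > 0):
            raise ValueError(f"degenerate data: zero error SS for {subset}")
        ss_error_total += ss_err
        df_e = N - g

        degenerate = max(np.abs(Z).max(initial=0.0), 0.0) < 1e-12
        S = E / df_e
        eps = 1.0 if degenerate else gg_epsilon(S, p + 1)

        for name, ss_eff, q, H_src in (
            (" × ".join(subset), ss_w, 1, np.sqrt(N) * zbar[:, None]),
            (
                f"{between} × " + " × ".join(subset),
                ss_wg,
                g - 1,
                (np.sqrt(n_g)[:, None] * (zbar_g - zbar)).T,
            ),
        ):
            dfn_u = p * q
            dfd_u = p * (N - g)
            if degenerate:
                rows.append(
                    {
                        "effect": name, "DFn": dfn_u, "DFd": dfd_u, "F": 0.0,
                        "p": 1.0, "eps_GG": eps, "p_GG": 1.0, "F_multi": 0.0,
                        "DFn_multi": p * q, "DFd_multi": df_e - p + 1,
                        "p_multi": 1.0, "SS": 0.0, "SS_error": ss_err,
                    }
                )
                continue
            F_u = (ss_eff / dfn_u) / (ss_err / dfd_u)
            p_u = float(sps.f.sf(F_u, dfn_u, dfd_u))
            p_gg = float(sps.f.sf(F_u, eps * dfn_u, eps * dfd_u))
            H = H_src @ H_src.T
            F_m, dfn_m, dfd_m, p_m = _wilks_f(H, E, q, df_e)
            rows.append(
                {
                    "effect": name, "DFn": dfn_u, "DFd": dfd_u, "F": F_u,
                    "p": p_u, "eps_GG": eps, "p_GG": p_gg, "F_multi": F_m,
                    "DFn_multi": dfn_m, "DFd_multi": dfd_m, "p_multi": p_m,
                    "SS": ss_eff, "SS_error": ss_err,
                }
            )

    table = pd.DataFrame(rows)
    table["eta_G"] = [
        generalized_eta_squared(ss, ss_subjects, ss_error_total)
        for ss in table["SS"]
    ]

    means = _marginal_means(cells, within)
    return AnovaResult(
        table=table,
        ss_total=ss_total,
        ss_subjects=ss_subjects,
        ss_error_total=ss_error_total,
        marginal_means=means,
    )


def _marginal_means(cells: CellMeansMatrix, within: list[str]) -> pd.DataFrame:
    """Condition means and SEMs per within-factor level (subjects as units)."""
    recs = []
    df = pd.DataFrame(cells.data, columns=cells.conditions)
    for factor in within:
        lv = cells.conditions.get_level_values(factor)
        for level in pd.unique(lv):
            per_subject = df.loc[:, np.asarray(lv == level)].mean(axis=1)
            recs.append(
                {
                    "factor": factor,
                    "level": level,
                    "mean": float(per_subject.mean()),
                    "sem": float(per_subject.std(ddof=1) / np.sqrt(len(per_subject))),
                }
            )
    return pd.DataFrame(recs)


def pool_imputed_anova(results: list[AnovaResult]) -> pd.DataFrame:
    """Combine per-imputation ANOVA tables with the D2 procedure.

    For each effect and each path, per-imputation F statistics are turned
    into chi-square statistics d_i = k F_i and combined (Li, Meng,
    Raghunathan & Rubin); the per-imputation F range is retained.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 imputations to pool")
    effects = list(results[0].table["effect"])
    for r in results[1:]:
        if list(r.table["effect"]) != effects:
            raise ValueError("mismatched effect lists across imputations")

    m = len(results)
    out = []
    for i, effect in enumerate(effects):
        rec = {"effect": effect}
        for path, fcol, dfncol, dfdcol in (
            ("uni", "F", "DFn", "DFd"),
            ("multi", "F_multi", "DFn_multi", "DFd_multi"),
        ):
            Fs = np.array([r.table.loc[i, fcol] for r in results], dtype=float)
            k = float(results[0].table.loc[i, dfncol])
            d = k * Fs
            dbar = d.mean()
            r2 = (1.0 + 1.0 / m) * np.var(np.sqrt(d), ddof=1)
            if r2 < 1e-12:
                D2 = dbar / k
                nu = 1e8
            else:
                D2 = (dbar / k - (m + 1.0) / (m - 1.0) * r2) / (1.0 + r2)
                nu = k ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r2) ** 2
            D2 = max(D2, 0.0)
            rec[f"F_pooled_{path}"] = D2
            rec[f"DFn_{path}"] = k
            rec[f"DFd_{path}"] = nu
            rec[f"p_pooled_{path}"] = float(sps.f.sf(D2, k, nu))
            rec[f"F_min_{path}"] = float(Fs.min())
            rec[f"F_max_{path}"] = float(Fs.max())
        out.append(rec)
    return pd.DataFrame(out)
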