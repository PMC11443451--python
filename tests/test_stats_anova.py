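import numpy as np
import pandas as pd
import pytest

from venalamina.stats import (
    CellMeansMatrix,
    gg_epsilon,
    generalized_eta_squared,
    mixed_anova,
    pool_imputed_anova,
)


def make_cells(data, groups, factors):
    """Build a CellMeansMatrix from an array and factor level dict."""
    cond = pd.MultiIndex.from_product(list(factors.values()), names=list(factors))
    subjects = [f"s{i}" for i in range(len(data))]
    return CellMeansMatrix(np.asarray(data, float), cond, subjects, np.asarray(groups))


def enumeration_ss(Y, groups):
    """Oracle: classical balanced split-plot SS by direct cell-mean sums
    (one between group, one within factor)."""
    Y = np.asarray(Y, float)
    N, K = Y.shape
    glev = list(dict.fromkeys(groups))
    rows = {g: [i for i, x in enumerate(groups) if x == g] for g in glev}
    grand = Y.mean()
    subj = Y.mean(axis=1)
    gmean = {g: Y[rows[g]].mean() for g in glev}
    cmean = Y.mean(axis=0)
    cellg = {g: Y[rows[g]].mean(axis=0) for g in glev}

    ss_total = ((Y - grand) ** 2).sum()
    ss_group = K * sum(len(rows[g]) * (gmean[g] - grand) ** 2 for g in glev)
    ss_subj = K * sum(
        ((subj[rows[g]] - gmean[g]) ** 2).sum() for g in glev
    )
    ss_cond = N * ((cmean - grand) ** 2).sum()
    ss_int = sum(
        len(rows[g]) * ((cellg[g] - gmean[g] - cmean + grand) ** 2).sum()
        for g in glev
    )
    ss_err = sum(
        (
            (Y[rows[g]] - subj[rows[g]][:, None] - cellg[g][None, :]
             + gmean[g]) ** 2
        ).sum()
        for g in glev
    )
    return dict(total=ss_total, group=ss_group, subj=ss_subj, cond=ss_cond,
                inter=ss_int, err=ss_err)


# hand-built 2 (group) x 2 (condition) toy: balanced, 2 subjects per group
TOY = np.array([[3.0, 5.0], [4.0, 8.0], [7.0, 6.0], [9.0, 10.0]])
TOY_GROUPS = ["a", "a", "b", "b"]


class TestUnivariatePath:
    def test_toy_matches_enumeration_oracle(self):
        cells = make_cells(TOY, TOY_GROUPS, {"cond": ["c1", "c2"]})
        res = mixed_anova(cells)
        oracle = enumeration_ss(TOY, TOY_GROUPS)
        t = res.table.set_index("effect")
        assert t.loc["group", "SS"] == pytest.approx(oracle["group"], abs=1e-10)
        assert res.ss_subjects == pytest.approx(oracle["subj"], abs=1e-10)
        assert t.loc["cond", "SS"] == pytest.approx(oracle["cond"], abs=1e-10)
        assert t.loc["group × cond", "SS"] == pytest.approx(oracle["inter"], abs=1e-10)
        assert t.loc["cond", "SS_error"] == pytest.approx(oracle["err"], abs=1e-10)
        # F ratios rebuilt from the oracle ledger
        F_cond = oracle["cond"] / (oracle["err"] / 2)
        assert t.loc["cond", "F"] == pytest.approx(F_cond, abs=1e-10)

    def test_ledger_conserves_total_ss(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(9, 2 * 3 * 4))
        cells = make_cells(
            data, ["a"] * 5 + ["b"] * 4,
            {"f1": ["x", "y"], "f2": list("pqr"), "f3": list("klmn")},
        )
        res = mixed_anova(cells)
        assert res.ledger_residual() < 1e-8

    def test_missing_cells_fatal_with_subject_list(self):
        data = TOY.copy()
        data[1, 0] = np.nan
        cells = make_cells(data, TOY_GROUPS, {"cond": ["c1", "c2"]})
        with pytest.raises(ValueError, match="s1"):
            mixed_anova(cells)

    def test_null_within_effect_degenerate(self):
        # identical values in all conditions per subject: F = 0, p = 1
        base = np.array([[1.0], [2.0], [3.0], [4.0], [2.5], [3.5]])
        data = np.repeat(base, 5, axis=1)
        cells = make_cells(data, ["a", "a", "a", "b", "b", "b"],
                           {"distance": list("vwxyz")})
        t = mixed_anova(cells).table.set_index("effect")
        assert t.loc["distance", "F"] == 0.0
        assert t.loc["distance", "p"] == 1.0
        assert t.loc["distance", "F_multi"] == 0.0
        assert t.loc["distance", "p_multi"] == 1.0

    def test_single_group_rejected(self):
        cells = make_cells(TOY, ["a"] * 4, {"cond": ["c1", "c2"]})
        with pytest.raises(ValueError, match="group"):
            mixed_anova(cells)


@pytest.fixture(scope="module")
def paper_sized():
    rng = np.random.default_rng(42)
    data = rng.normal(size=(35, 2 * 4 * 5))
    return mixed_anova(
        make_cells(
            data, ["young"] * 18 + ["old"] * 17,
            {"area": ["M1", "S1"], "compartment": list("SOID"),
             "distance_bin": ["0-2", "2-4", "4-6", "6-8", "8-10"]},
        )
    ).table.set_index("effect")


class TestMultivariatePath:

    def test_distance_df_4_30(self, paper_sized):
        assert paper_sized.loc["distance_bin", "DFn_multi"] == 4
        assert paper_sized.loc["distance_bin", "DFd_multi"] == 30

    def test_depth_df_3_31(self, paper_sized):
        assert paper_sized.loc["compartment", "DFn_multi"] == 3
        assert paper_sized.loc["compartment", "DFd_multi"] == 31

    def test_age_df_1_33(self, paper_sized):
        assert paper_sized.loc["group", "DFn_multi"] == 1
        assert paper_sized.loc["group", "DFd_multi"] == 33

    def test_three_way_interaction_df_4_30(self, paper_sized):
        row = paper_sized.loc["group × area × distance_bin"]
        assert row["DFn_multi"] == 4
        assert row["DFd_multi"] == 30

    def test_interaction_df_matches_main(self, paper_sized):
        assert (
            paper_sized.loc["group × distance_bin", "DFd_multi"]
            == paper_sized.loc["distance_bin", "DFd_multi"]
        )

    def test_multivariate_nan_when_too_few_subjects(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 20))
        t = mixed_anova(
            make_cells(data, ["a"] * 4 + ["b"] * 4,
                       {"f1": list("abcd"), "f2": list("vwxyz")})
        ).table.set_index("effect")
        assert np.isnan(t.loc["f1 × f2", "F_multi"])  # p = 12 > N - g = 6
        assert np.isfinite(t.loc["f1 × f2", "F"])  # univariate still valid


class TestGGEpsilon:
    def test_spherical_identity(self):
        assert gg_epsilon(np.eye(4), k=5) == pytest.approx(1.0)

    def test_maximal_violation_lower_bound(self):
        S = np.diag([1.0, 0.0, 0.0, 0.0])
        assert gg_epsilon(S, k=5) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_spd_matches_formula_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 4))
        S = A @ A.T
        eps = gg_epsilon(S, k=5)
        direct = np.trace(S) ** 2 / (4 * np.trace(S @ S))
        assert eps == pytest.approx(np.clip(direct, 0.25, 1.0))
        assert 0.25 <= eps <= 1.0

    def test_zero_trace_fatal(self):
        with pytest.raises(ValueError, match="trace"):
            gg_epsilon(np.zeros((3, 3)), k=4)


class TestGeneralizedEtaSquared:
    def test_single_within_specialization(self):
        assert generalized_eta_squared(10.0, 30.0, 60.0) == pytest.approx(0.1)

    def test_all_variance_in_effect(self):
        assert generalized_eta_squared(5.0, 0.0, 0.0) == 1.0

    def test_toy_hand_computation(self):
        cells = make_cells(TOY, TOY_GROUPS, {"cond": ["c1", "c2"]})
        res = mixed_anova(cells)
        oracle = enumeration_ss(TOY, TOY_GROUPS)
        t = res.table.set_index("effect")
        expect = oracle["cond"] / (oracle["cond"] + oracle["subj"] + oracle["err"])
        assert t.loc["cond", "eta_G"] == pytest.approx(expect, abs=1e-10)

    def test_negative_ss_fatal(self):
        with pytest.raises(ValueError):
            generalized_eta_squared(-1.0, 1.0, 1.0)


class TestPooling:
    def _result(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(10, 5))
        return mixed_anova(
            make_cells(data, ["a"] * 5 + ["b"] * 5, {"bin": list("vwxyz")})
        )

    def test_identical_tables_pool_to_common_f(self):
        res = self._result(0)
        pooled = pool_imputed_anova([res, res, res])
        merged = pooled.merge(res.table, on="effect")
        np.testing.assert_allclose(merged["F_pooled_uni"], merged["F"], rtol=1e-9)

    def test_pooled_f_bounded_by_max(self):
        results = [self._result(s) for s in range(5)]
        pooled = pool_imputed_anova(results)
        assert (pooled["F_pooled_uni"] <= pooled["F_max_uni"] + 1e-9).all()
        assert (pooled["p_pooled_uni"].between(0, 1)).all()

    def test_null_rejection_rate_nominal(self):
        # D2-pooled p-values under the null reject at roughly 5%
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            data = rng.normal(size=(12, 4))
            cells = make_cells(data, ["a"] * 6 + ["b"] * 6, {"bin": list("wxyz")})
            res = [
                mixed_anova(cells.copy_with(
                    cells.data + rng.normal(0, 1e-9, cells.data.shape)))
                for _ in range(3)
            ]
            pooled = pool_imputed_anova(res).set_index("effect")
            if pooled.loc["bin", "p_pooled_uni"] <= 0.05:
                rejections += 1
        se = np.sqrt(n_rep * 0.05 * 0.95)
        assert abs(rejections - 0.05 * n_rep) <= 3 * se

    def test_mismatched_effects_fatal(self):
        a = self._result(0)
        b = self._result(1)
        b.table.loc[0, "effect"] = "renamed"
        with pytest.raises(ValueError, match="mismatch"):
            pool_imputed_anova([a, b])

    def test_single_table_rejected(self):
        with pytest.raises(ValueError):
            pool_imputed_anova([self._result(0)])
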