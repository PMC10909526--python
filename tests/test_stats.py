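"""Inference battery vs brute-force oracles and an independent implementation."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sst

import trackshift as ts

# ---------------------------------------------------------------------------
# brute-force oracles


def ols_ss(y, X):
    """Residual sum of squares of an OLS fit (independent route via lstsq)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def rm1_oracle(table):
    """One-way RM-ANOVA through nested OLS models (subject vs subject+condition)."""
    n, k = table.shape
    y = table.ravel()
    subj = np.repeat(np.eye(n), k, axis=0)
    cond = np.tile(np.eye(k), (n, 1))
    ss_red = ols_ss(y, subj)
    ss_full = ols_ss(y, np.column_stack([subj, cond[:, 1:]]))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = ((ss_red - ss_full) / df1) / (ss_full / df2)
    return F, df1, df2, (ss_red - ss_full) / ss_red


def exact_corr_data(R, n=64):
    """A dataset whose sample correlation matrix equals ``R`` exactly."""
    p = R.shape[0]
    rng = np.random.default_rng(0)
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(axis=0)
    # orthonormalize columns, then color with the Cholesky factor
    Q, _ = np.linalg.qr(Z)
    L = np.linalg.cholesky(R)
    X = Q[:, :p] @ L.T
    return X


def r2_from_data(X, y_idx, pred_idx):
    if not pred_idx:
        return 0.0
    y = X[:, y_idx]
    D = np.column_stack([np.ones(X.shape[0]), X[:, pred_idx]])
    ss_res = ols_ss(y, D)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------


class TestRmAnova1Way:
    def test_identical_columns_give_f0_p1(self):
        x = np.tile(np.arange(4.0)[:, None], (1, 3))
        res = ts.rm_anova_1way(x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_ols_oracle_and_pingouin(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 3)) + np.array([0.0, 0.4, 0.9])
        res = ts.rm_anova_1way(x)
        F, df1, df2, eta = rm1_oracle(x)
        assert abs(res.statistic - F) <= 1e-10
        assert (res.df1, res.df2) == (df1, df2)
        assert abs(res.effect_size - eta) <= 1e-10
        long = pd.DataFrame({
            "y": x.ravel(),
            "subj": np.repeat(np.arange(5), 3),
            "cond": np.tile(np.arange(3), 5),
        })
        pr = pg.rm_anova(data=long, dv="y", within="cond", subject="subj", correction=True)
        assert abs(res.statistic - pr["F"].iloc[0]) <= 1e-8
        assert abs(res.p - pr["p_unc"].iloc[0]) <= 1e-8
        assert abs(res.eps_gg - pr["eps"].iloc[0]) <= 1e-8
        assert abs(res.p_gg - pr["p_GG_corr"].iloc[0]) <= 1e-8

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejects = sum(
            ts.rm_anova_1way(rng.standard_normal((8, 3))).p_gg < 0.05
            for _ in range(400)
        )
        assert 0.03 <= rejects / 400 <= 0.075

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            ts.rm_anova_1way(x)


class TestRmAnova2Way:
    def test_matches_pingouin_two_way(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((6, 2, 3)) + np.arange(3) * 0.5
        res = ts.rm_anova_2way(y, factor_names=("A", "B"))
        long = pd.DataFrame({
            "y": y.ravel(),
            "subj": np.repeat(np.arange(6), 6),
            "A": np.tile(np.repeat(np.arange(2), 3), 6),
            "B": np.tile(np.arange(3), 12),
        })
        pr = pg.rm_anova(data=long, dv="y", within=["A", "B"], subject="subj")
        for name, row in zip(["A", "B", "A x B"], range(3)):
            assert abs(res[name].statistic - pr["F"].iloc[row]) <= 1e-8
            assert abs(res[name].p - pr["p_unc"].iloc[row]) <= 1e-8

    def test_2x2_hand_table_matches_cell_means_decomposition(self):
        # subjects x A x B, small enough to verify sums of squares directly
        y = np.array([
            [[3.0, 5.0], [4.0, 8.0]],
            [[2.0, 4.5], [5.0, 9.0]],
            [[4.0, 6.0], [3.5, 7.0]],
            [[3.0, 5.5], [4.0, 8.5]],
        ])
        res = ts.rm_anova_2way(y)
        n = 4
        mA = y.mean(axis=(0, 2)); mB = y.mean(axis=(0, 1)); g = y.mean()
        ss_a = n * 2 * ((mA - g) ** 2).sum()
        ss_b = n * 2 * ((mB - g) ** 2).sum()
        msa = y.mean(axis=2); msb = y.mean(axis=1); ms = y.mean(axis=(1, 2))
        ss_sa = 2 * ((msa - ms[:, None] - mA[None, :] + g) ** 2).sum()
        ss_sb = 2 * ((msb - ms[:, None] - mB[None, :] + g) ** 2).sum()
        assert abs(res["A"].statistic - (ss_a / 1) / (ss_sa / 3)) <= 1e-10
        assert abs(res["B"].statistic - (ss_b / 1) / (ss_sb / 3)) <= 1e-10

    def test_null_interaction_rejection_near_alpha(self):
        rng = np.random.default_rng(17)
        rejects = 0
        for _ in range(300):
            y = rng.standard_normal((8, 2, 3))
            y += np.arange(3) * 0.5  # additive B effect only
            rejects += ts.rm_anova_2way(y)["A x B"].p < 0.05
        assert 0.02 <= rejects / 300 <= 0.10

    def test_unbalanced_rejected(self):
        y = np.ones((4, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            ts.rm_anova_2way(y)


class TestPosthoc:
    def test_identical_pair_t0_p1(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = ts.pairwise_posthoc(x)
        assert res[0].statistic == 0.0 and res[0].p == 1.0

    def test_bh_adjustment_formula(self):
        np.testing.assert_allclose(ts.fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(ts.fdr_bh([0.01, 0.04]), [0.02, 0.04])

    def test_zero_variance_differences_direct_to_wilcoxon(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0) + 1.0])
        with pytest.raises(ValueError, match="wilcoxon"):
            ts.pairwise_posthoc(x, method="paired_t")

    def test_wilcoxon_pairwise_matches_exact_enumeration(self):
        d = np.array([1.2, -0.4, 2.1, 0.6, -1.5, 0.9])
        x = np.column_stack([d, np.zeros(6)])
        res = ts.pairwise_posthoc(x, method="wilcoxon")[0]
        ranks = sst.rankdata(np.abs(d))
        wplus_obs = ranks[d > 0].sum()
        mu = 6 * 7 / 4.0
        count = sum(
            abs(sum(r for r, s in zip(ranks, signs) if s) - mu) >= abs(wplus_obs - mu) - 1e-12
            for signs in np.ndindex(*(2,) * 6)
        )
        assert abs(res.p - count / 2**6) <= 1e-10


class TestWilcoxonVsConstant:
    def test_all_above_constant_minimal_p(self):
        v = np.arange(1.0, 11.0)
        res = ts.wilcoxon_vs_constant(v, 0.0)
        assert abs(res.p - 2.0 / 2**10) <= 1e-12  # most extreme ranking, n=10
        assert res.statistic > 0

    def test_all_equal_is_degenerate(self):
        res = ts.wilcoxon_vs_constant(np.full(6, 2.0), 2.0)
        assert res.p == 1.0

    def test_symmetric_null_rejection_near_alpha(self):
        rng = np.random.default_rng(23)
        rejects = sum(
            ts.wilcoxon_vs_constant(rng.standard_normal(15), 0.0).p < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejects / 400 <= 0.08


class TestMannWhitney:
    def test_complete_separation_maximal_u(self):
        res = ts.mann_whitney([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert res.statistic == 25.0
        assert res.effect_size == 1.0

    def test_matches_exact_enumeration_4v4(self):
        a = np.array([1.1, 3.4, 2.2, 5.0])
        b = np.array([2.9, 0.7, 4.1, 1.8])
        res = ts.mann_whitney(a, b)
        ranks = sst.rankdata(np.concatenate([a, b]))
        u_obs = ranks[:4].sum() - 4 * 5 / 2.0
        us = []
        for idx in combinations(range(8), 4):
            us.append(ranks[list(idx)].sum() - 4 * 5 / 2.0)
        us = np.array(us)
        p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
        assert abs(res.p - min(p, 1.0)) <= 1e-10

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(29)
        ps = [ts.mann_whitney(rng.standard_normal(12), rng.standard_normal(12)).p
              for _ in range(300)]
        assert 0.02 <= np.mean(np.array(ps) < 0.05) <= 0.10


class TestClusterPermutation:
    def test_identical_conditions_yield_no_significant_cluster(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((8, 1, 40))
        data = np.tile(base, (1, 3, 1))
        res = ts.cluster_perm_F(data, n_perm=200, seed=1)
        assert all(c[2] == 1.0 for c in res.clusters) or res.clusters == []

    def test_injected_span_recovered(self):
        hits = 0
        for run in range(10):
            rng = np.random.default_rng(50 + run)
            x = rng.standard_normal((12, 3, 100))
            x[:, 2, 8:29] += 2.0
            res = ts.cluster_perm_F(x, n_perm=300, seed=run)
            covered = 0
            for members, _, p in res.clusters:
                if p < 0.05:
                    covered = max(covered, np.intersect1d(members, np.arange(8, 29)).size)
            hits += covered >= 0.8 * 21
        assert hits >= 9

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            ts.cluster_perm_F(rng.standard_normal((4, 2, 10)), n_perm=50, seed=0)

    def test_p_never_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 3, 30))
        x[:, 0, 5:15] += 3.0
        res = ts.cluster_perm_F(x, n_perm=200, seed=2)
        assert all(c[2] >= 1.0 / 201 for c in res.clusters)


class TestRmcorr:
    def test_exact_linear_relation_gives_unit_r(self):
        x = np.tile(np.arange(4.0), 3)
        subj = np.repeat(["a", "b", "c"], 4)
        y = x + np.repeat([0.0, 5.0, -2.0], 4)
        r, df, p = ts.rmcorr(x, y, subj)
        assert abs(r - 1.0) <= 1e-12

    def test_negative_slope_negative_r(self):
        rng = np.random.default_rng(7)
        x = np.tile(np.arange(5.0), 4)
        subj = np.repeat(list("abcd"), 5)
        y = -2.0 * x + np.repeat(rng.standard_normal(4), 5) + 0.01 * rng.standard_normal(20)
        r, _, _ = ts.rmcorr(x, y, subj)
        assert r < -0.99

    def test_matches_ancova_oracle_and_pingouin(self):
        rng = np.random.default_rng(13)
        subj = np.repeat(list("abc"), 3)
        x = rng.standard_normal(9)
        y = 0.8 * x + np.repeat(rng.standard_normal(3), 3) + 0.3 * rng.standard_normal(9)
        r, df, p = ts.rmcorr(x, y, subj)
        # ANCOVA oracle: nested OLS with subject dummies, slope from the full model
        dummies = (subj[:, None] == np.array(list("abc"))[None, :]).astype(float)
        ss_red = ols_ss(y, dummies)
        ss_full = ols_ss(y, np.column_stack([dummies, x]))
        f_stat = (ss_red - ss_full) / (ss_full / (9 - 3 - 1))
        r_oracle = np.sqrt(f_stat / (f_stat + 9 - 3 - 1))
        assert abs(abs(r) - r_oracle) <= 1e-10
        assert df == 9 - 3 - 1
        pgres = pg.rm_corr(data=pd.DataFrame({"x": x, "y": y, "s": subj}),
                           x="x", y="y", subject="s")
        assert abs(r - pgres["r"].iloc[0]) <= 1e-6
        assert abs(p - pgres["pval"].iloc[0]) <= 1e-6

    def test_single_observation_subjects_dropped(self):
        x = np.array([1.0, 2, 3, 4, 1, 2, 3, 4, 5.0])
        y = x.copy()
        subj = np.array(["a"] * 4 + ["b"] * 4 + ["c"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ts.rmcorr(x, y, subj)


class TestDominance:
    def test_single_predictor_is_squared_correlation(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        dom, full = ts.dominance(R, outcome=1)
        assert abs(dom["x0"] - 0.36) <= 1e-12
        assert abs(full - 0.36) <= 1e-12

    def test_orthogonal_predictors_partition_exactly(self):
        R = np.eye(3)
        R[0, 2] = R[2, 0] = 0.5
        R[1, 2] = R[2, 1] = 0.3
        dom, full = ts.dominance(R, outcome=2)
        assert abs(dom["x0"] - 0.25) <= 1e-12
        assert abs(dom["x1"] - 0.09) <= 1e-12

    def test_matches_all_orderings_oracle_on_random_pd_matrix(self):
        rng = np.random.default_rng(31)
        A = rng.standard_normal((8, 5))
        S = A.T @ A + 0.5 * np.eye(5)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        dom, full = ts.dominance(R, outcome=4)
        X = exact_corr_data(R)
        incs = {i: [] for i in range(4)}
        for order in permutations(range(4)):
            for pos, i in enumerate(order):
                before = list(order[:pos])
                incs[i].append(
                    r2_from_data(X, 4, before + [i]) - r2_from_data(X, 4, before)
                )
        for i in range(4):
            assert abs(dom[f"x{i}"] - np.mean(incs[i])) <= 1e-10
        assert abs(sum(dom.values()) - full) <= 1e-10
        assert abs(full - r2_from_data(X, 4, [0, 1, 2, 3])) <= 1e-10

    def test_singular_subset_named(self):
        R = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            ts.dominance(R, outcome=2)
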