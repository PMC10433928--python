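import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydrotrait import multitrait


def _ols_r2(y, x):
    """Independent centred R^2 via lstsq on an explicit design."""
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)


class TestPCA:
    def test_perfectly_correlated_pair_is_rank_one(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = multitrait.pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_match_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame(rng.normal(size=(20, 6)),
                          columns=list("abcdef"))
        res = multitrait.pca(df)
        z = (df - df.mean()) / df.std(ddof=1)
        _, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        for k in range(6):
            v = vt[k]
            w = res.loadings[:, k]
            assert (np.allclose(v, w, atol=1e-8)
                    or np.allclose(v, -w, atol=1e-8))
        assert np.allclose(res.variance_fraction,
                           s ** 2 / np.sum(s ** 2), atol=1e-10)

    def test_reconstruction_of_standardized_matrix(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.normal(size=(15, 4)),
                          columns=list("abcd"))
        res = multitrait.pca(df)
        z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        assert np.allclose(res.scores @ res.loadings.T, z, atol=1e-8)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame(rng.normal(size=(12, 5)))
        res = multitrait.pca(df)
        assert res.variance_fraction.sum() == pytest.approx(1.0,
                                                            abs=1e-10)

    def test_constant_trait_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0] * 3})
        with pytest.raises(ValueError, match="flat"):
            multitrait.pca(df)


class TestRegressOnPCs:
    def test_response_equal_to_pc1(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(rng.normal(size=(20, 4)))
        res = multitrait.pca(df)
        fit = multitrait.regress_on_pcs(res.scores[:, 0], res, k=2)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.params[2] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_response_no_fit(self):
        rng = np.random.default_rng(24)
        df = pd.DataFrame(rng.normal(size=(30, 3)))
        res = multitrait.pca(df)
        y = rng.normal(size=30)
        y = y - res.scores[:, :2] @ np.linalg.lstsq(
            res.scores[:, :2], y, rcond=None)[0]
        fit = multitrait.regress_on_pcs(y, res, k=2)
        assert fit.r2 == pytest.approx(0.0, abs=1e-10)

    def test_k_validation(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        res = multitrait.pca(df)
        with pytest.raises(ValueError):
            multitrait.regress_on_pcs(np.ones(10), res, k=0)
        with pytest.raises(ValueError):
            multitrait.regress_on_pcs(np.ones(10), res, k=5)


class TestLMG:
    def test_matches_brute_force_permutation_oracle(self):
        """p = 3 correlated design: shares equal an explicit average of
        incremental R^2 over all 6 orderings, computed with independent
        OLS machinery."""
        rng = np.random.default_rng(25)
        n = 40
        base = rng.normal(size=n)
        x = np.column_stack([base + rng.normal(0, 0.5, n),
                             base + rng.normal(0, 1.0, n),
                             rng.normal(size=n)])
        y = x @ [1.0, 0.5, -0.8] + rng.normal(0, 1, n)
        res = multitrait.lmg(y, x)
        shares = np.zeros(3)
        for perm in itertools.permutations(range(3)):
            prev: list = []
            for j in perm:
                r_with = _ols_r2(y, x[:, prev + [j]])
                r_without = _ols_r2(y, x[:, prev]) if prev else 0.0
                shares[j] += r_with - r_without
                prev.append(j)
        shares /= 6
        assert np.allclose(res.shares, shares, atol=1e-12)

    def test_shares_sum_to_total_r2_random_designs(self):
        rng = np.random.default_rng(26)
        for _ in range(25):
            n, p = 20, rng.integers(2, 5)
            x = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            res = multitrait.lmg(y, x)
            assert res.shares.sum() == pytest.approx(res.total_r2,
                                                     abs=1e-10)
            assert np.all(res.shares >= -1e-12)

    def test_orthogonal_regressors_get_marginal_r2(self):
        n = 32
        t = np.arange(n)
        x = np.column_stack([np.cos(2 * np.pi * t / n),
                             np.sin(2 * np.pi * t / n)])
        rng = np.random.default_rng(27)
        y = 2 * x[:, 0] - x[:, 1] + rng.normal(0, 0.5, n)
        res = multitrait.lmg(y, x)
        assert res.shares[0] == pytest.approx(_ols_r2(y, x[:, [0]]),
                                              abs=1e-10)
        assert res.shares[1] == pytest.approx(_ols_r2(y, x[:, [1]]),
                                              abs=1e-10)

    def test_equals_direct_shapley_formula(self):
        """Shapley weights k!(p-1-k)!/p! over subsets — the independent
        formulation of the same attribution."""
        rng = np.random.default_rng(28)
        n, p = 25, 4
        x = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
        y = x @ rng.normal(size=p) + rng.normal(0, 1, n)
        res = multitrait.lmg(y, x)
        for j in range(p):
            share = 0.0
            others = [i for i in range(p) if i != j]
            for k in range(p):
                for subset in itertools.combinations(others, k):
                    w = (math.factorial(k) * math.factorial(p - 1 - k)
                         / math.factorial(p))
                    r_with = _ols_r2(y, x[:, list(subset) + [j]])
                    r_without = (_ols_r2(y, x[:, list(subset)])
                                 if subset else 0.0)
                    share += w * (r_with - r_without)
            assert res.shares[j] == pytest.approx(share, abs=1e-10)

    def test_collinear_design_rejected(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            multitrait.lmg(np.random.default_rng(0).normal(size=10), x)


class TestLMGBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=(25, 2))
        y = x[:, 0] + rng.normal(0, 0.5, 25)
        a = multitrait.lmg_bootstrap(y, x, n_boot=200, seed=4)
        b = multitrait.lmg_bootstrap(y, x, n_boot=200, seed=4)
        assert np.array_equal(a.ci_lower, b.ci_lower)
        assert np.array_equal(a.ci_upper, b.ci_upper)

    def test_noise_free_share_degenerate_at_one(self):
        x = np.random.default_rng(30).normal(size=(20, 1))
        y = 2.0 * x[:, 0]
        res = multitrait.lmg_bootstrap(y, x, n_boot=100, seed=0)
        assert res.ci_lower[0] == pytest.approx(1.0, abs=1e-10)
        assert res.ci_upper[0] == pytest.approx(1.0, abs=1e-10)

    def test_ci_bounds_ordered_and_cover_point(self):
        rng = np.random.default_rng(31)
        base = rng.normal(size=30)
        x = np.column_stack([base + rng.normal(0, 0.7, 30),
                             base + rng.normal(0, 0.7, 30)])
        y = x[:, 0] + 0.5 * x[:, 1] + rng.normal(0, 1, 30)
        res = multitrait.lmg_bootstrap(y, x, n_boot=300, seed=1)
        assert np.all(res.ci_lower <= res.ci_upper)

    def test_minimum_runs_enforced(self):
        with pytest.raises(ValueError):
            multitrait.lmg_bootstrap(np.ones(10), np.arange(10.0), 50)


class TestTukey:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(32)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        comp = multitrait.tukey_compare(np.concatenate([a, b]),
                                        ["a"] * 8 + ["b"] * 8)
        t_p = stats.ttest_ind(a, b).pvalue
        assert comp.pairwise["p_adj"].iloc[0] == pytest.approx(t_p,
                                                               abs=1e-6)

    def test_identical_groups_share_letters(self):
        rng = np.random.default_rng(33)
        vals = rng.normal(0, 1, 20)
        labels = np.repeat(list("abcde"), 4)
        comp = multitrait.tukey_compare(vals, labels)
        assert len(set(comp.letters.values())) == 1

    def test_shifted_group_gets_own_letter(self):
        rng = np.random.default_rng(34)
        vals = np.concatenate([rng.normal(0, 0.3, 12),
                               rng.normal(10, 0.3, 4)])
        labels = np.repeat(list("abcd"), 4)
        comp = multitrait.tukey_compare(vals, labels)
        assert comp.letters["d"] not in {comp.letters[g]
                                         for g in "abc"}

    def test_transform_recorded_and_applied(self):
        vals = np.exp(np.random.default_rng(35).normal(0, 1, 12))
        comp = multitrait.tukey_compare(vals, np.repeat(list("abc"), 4),
                                        transform="log")
        assert comp.transform == "log"
        assert np.allclose(sorted(comp.means),
                           sorted(np.log(vals).reshape(3, 4).mean(1)))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            multitrait.tukey_compare([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_adjusted_p_matches_monte_carlo_range_null(self):
        """Tukey p for the observed q equals the Monte-Carlo tail
        probability of the studentized range under the null."""
        rng = np.random.default_rng(36)
        k, n = 5, 4
        vals = rng.normal(0, 1, k * n)
        labels = np.repeat([f"g{i}" for i in range(k)], n)
        comp = multitrait.tukey_compare(vals, labels)
        q_obs = comp.pairwise["q"].max()
        draws = rng.normal(size=(20000, k, n))
        means = draws.mean(axis=2)
        mse = draws.var(axis=2, ddof=1).mean(axis=1)
        q_null = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(
            mse / n)
        p_mc = (q_null >= q_obs).mean()
        p_pkg = comp.pairwise["p_adj"].min()
        se = math.sqrt(p_mc * (1 - p_mc) / 20000)
        assert abs(p_pkg - p_mc) < 4 * se + 1e-3


class TestFitR2Model:
    def test_pure_hv_response_attributes_all_to_hv(self):
        rng = np.random.default_rng(37)
        hv = rng.uniform(1e-3, 4e-3, 20)
        kp = rng.uniform(1.0, 5.0, 20)
        # orthogonalize so the sample correlation with hv is exactly 0
        design = np.column_stack([np.ones(20), hv])
        kp = kp - design @ np.linalg.lstsq(design, kp, rcond=None)[0]
        kp = kp + 3.0
        y = 100.0 * hv
        res = multitrait.fit_r2_model(y, hv, kp, n_boot=100, seed=0)
        assert res.relimp.shares[0] == pytest.approx(res.r2, abs=1e-6)
        assert res.relimp.shares[1] == pytest.approx(0.0, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_shares_sum_to_model_r2(self):
        rng = np.random.default_rng(38)
        hv = rng.uniform(1e-3, 4e-3, 20)
        kp = 1000.0 * hv + rng.normal(0, 0.5, 20)
        y = 100.0 * hv + 0.1 * kp + rng.normal(0, 0.1, 20)
        res = multitrait.fit_r2_model(y, hv, kp, n_boot=100, seed=0)
        assert res.relimp.shares.sum() == pytest.approx(res.r2,
                                                        abs=1e-10)

    def test_diagnostics_present(self):
        rng = np.random.default_rng(39)
        hv = rng.uniform(1e-3, 4e-3, 20)
        kp = rng.uniform(1.0, 5.0, 20)
        y = 50.0 * hv + rng.normal(0, 0.05, 20)
        res = multitrait.fit_r2_model(y, hv, kp, n_boot=100, seed=0)
        for key in ("shapiro_p", "breusch_pagan_p", "condition_number"):
            assert np.isfinite(res.diagnostics[key])

    def test_too_few_trees_rejected(self):
        with pytest.raises(ValueError):
            multitrait.fit_r2_model([0.5] * 5, [1e-3] * 5, [1.0] * 5)
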