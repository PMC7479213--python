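import numpy as np
import pytest
from scipy import stats as sps

from ratssm.stats import (mann_whitney, mixed_ancova,
                          score_behavior_regression, shapiro_wilk_gate,
                          u_from_mean_rank)


class TestMannWhitney:
    def test_complete_separation_small_samples_exact_p(self):
        # {1,2,3} vs {4,5,6}: U = 0; of the C(6,3)=20 equally likely rank
        # assignments only the two extremes are as extreme: p = 2/20 = 0.1
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_give_half_of_n_squared(self):
        res = mann_whitney([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.u == pytest.approx(4.5)  # n^2/2
        assert res.p_value == 1.0

    def test_swapping_samples_leaves_u_and_p_unchanged(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.u == r2.u and r1.p_value == r2.p_value

    def test_mean_rank_identity_aggregate(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=10)
        res = mann_whitney(a, b)
        total = res.mean_rank_a * res.n_a + res.mean_rank_b * res.n_b
        n = res.n_a + res.n_b
        assert total == pytest.approx(n * (n + 1) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_u_from_mean_rank_agrees_with_direct_computation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 11))
        b = rng.normal(0.8, 1, rng.integers(3, 11))
        res = mann_whitney(a, b)
        assert u_from_mean_rank(res.mean_rank_a, res.n_a, res.n_b) == res.u

    def test_exact_type_one_error_at_nominal_level(self):
        # null n = 10 + 10: rejection rate at alpha = 0.05 must be <= 0.055
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 10_000
        for _ in range(n_sim):
            a, b = rng.normal(size=10), rng.normal(size=10)
            if mann_whitney(a, b).p_value <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.055


class TestUFromMeanRank:
    def test_minimal_mean_rank_gives_zero(self):
        assert u_from_mean_rank(5.5, 10, 10) == 0.0

    def test_unattainable_rank_sum_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            u_from_mean_rank(6.83, 10, 10)
        with pytest.raises(ValueError, match="attainable"):
            u_from_mean_rank(2.0, 10, 10)


def split_plot_oracle(y, g, c):
    """Independent GLM route: sequential sums of squares on the full
    stacked design (intercept, covariate, group, subject dummies, day,
    day x covariate, day x group), error strata read off the increments."""
    n, d = y.shape
    resp = y.ravel()
    subj = np.repeat(np.arange(n), d)
    day = np.tile(np.arange(d), n)

    def cols(kind):
        if kind == "1":
            return np.ones((n * d, 1))
        if kind == "cov":
            return c[subj][:, None]
        if kind == "group":
            return g[subj][:, None]
        if kind == "subject":
            return np.eye(n)[subj]
        if kind == "day":
            return np.eye(d)[day]
        if kind == "day:cov":
            return np.eye(d)[day] * c[subj][:, None]
        if kind == "day:group":
            return np.eye(d)[day] * g[subj][:, None]
        raise KeyError(kind)

    order = ["1", "cov", "group", "subject", "day", "day:cov", "day:group"]
    X = np.empty((n * d, 0))
    rss_prev = float(resp @ resp)
    ss, dfs = {}, {}
    rank_prev = 0
    for kind in order:
        X = np.column_stack([X, cols(kind)])
        beta, _, rank, _ = np.linalg.lstsq(X, resp, rcond=None)
        rss = float(((resp - X @ beta) ** 2).sum())
        ss[kind] = rss_prev - rss
        dfs[kind] = rank - rank_prev
        rss_prev, rank_prev = rss, rank
    ss["resid"] = rss_prev
    dfs["resid"] = n * d - rank_prev
    f_group = (ss["group"] / dfs["group"]) / (ss["subject"] / dfs["subject"])
    f_day = (ss["day"] / dfs["day"]) / (ss["resid"] / dfs["resid"])
    f_int = (ss["day:group"] / dfs["day:group"]) / (ss["resid"] / dfs["resid"])
    return f_group, f_day, f_int, dfs


class TestMixedAncova:
    def _fixture(self, seed=0, n=20, d=4):
        rng = np.random.default_rng(seed)
        g = np.array([0.0] * (n // 2) + [1.0] * (n - n // 2))
        c = rng.normal(2.0, 0.5, n)
        subject = rng.normal(0, 1.0, n)
        day_effect = -np.arange(d) * 2.0
        y = (10 + 3 * g + 1.5 * c)[:, None] + subject[:, None] \
            + day_effect[None, :] + rng.normal(0, 0.8, (n, d))
        return y, g, c

    def test_twenty_subject_design_df_structure(self):
        y, g, c = self._fixture()
        res = mixed_ancova(y, g, c)
        assert res.df_group == (1, 17)
        assert res.df_day == (3, 51)
        assert res.df_interaction == (3, 51)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_sequential_glm_oracle(self, seed):
        y, g, c = self._fixture(seed=seed)
        res = mixed_ancova(y, g, c)
        f_group, f_day, f_int, dfs = split_plot_oracle(y, g, c)
        assert dfs["subject"] == 17 and dfs["resid"] == 51
        assert res.f_group == pytest.approx(f_group, abs=1e-8)
        assert res.f_day == pytest.approx(f_day, abs=1e-8)
        assert res.f_interaction == pytest.approx(f_int, abs=1e-8)

    def test_group_p_uniform_under_null_permutations(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(500):
            y = rng.normal(0, 1, (20, 4))
            g = rng.permutation([0.0] * 10 + [1.0] * 10)
            c = rng.normal(0, 1, 20)
            pvals.append(mixed_ancova(y, g, c).p_group)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_invariance_to_response_shift_and_covariate_rescale(self):
        y, g, c = self._fixture(seed=5)
        base = mixed_ancova(y, g, c)
        shifted = mixed_ancova(y + 123.4, g, c * 0.01 + 7.0)
        for attr in ("f_group", "f_day", "f_interaction"):
            assert getattr(shifted, attr) == pytest.approx(
                getattr(base, attr), rel=1e-8)

    def test_zero_variance_covariate_falls_back_to_anova(self):
        y, g, _ = self._fixture()
        with pytest.warns(UserWarning, match="mixed ANOVA"):
            res = mixed_ancova(y, g, np.ones(20))
        assert res.df_group == (1, 18)
        assert res.df_day == (3, 54)
        assert not res.covariate_used


class TestScoreBehaviorRegression:
    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        res = score_behavior_regression(x, 3.0 - 2.0 * x)
        assert res.r == pytest.approx(-1.0)

    def test_f_r2_identity_on_arbitrary_fixture(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = score_behavior_regression(x, y)
        expected = res.r_squared * 13 / (1 - res.r_squared)
        assert res.f_statistic == pytest.approx(expected, rel=1e-12)
        assert res.df == (1, 13)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            score_behavior_regression(np.ones(6), np.arange(6.0))


class TestShapiroGate:
    def test_exact_normal_quantiles_score_high_w(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.375) / 20.25)
        gate = shapiro_wilk_gate(q)
        assert gate.w >= 0.98 and gate.passed

    def test_heavily_skewed_samples_fail_the_gate(self):
        import warnings
        rng = np.random.default_rng(0)
        failures = 0
        for _ in range(100):
            sample = np.exp(rng.normal(0, 1.5, 20))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gate = shapiro_wilk_gate(sample)
            if not gate.passed:
                failures += 1
        assert failures >= 90

    def test_affine_invariance_of_w(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        w1 = shapiro_wilk_gate(x).w
        w2 = shapiro_wilk_gate(-3.5 * x + 100).w
        assert w2 == pytest.approx(w1, rel=1e-9)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk_gate(np.full(10, 2.0))
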