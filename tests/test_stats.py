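"""ICC, Bland-Altman, Friedman, and exact Wilcoxon tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import friedmanchisquare, mannwhitneyu, wilcoxon

from natriq.stats import (
    MUSCLES,
    bland_altman,
    friedman_test,
    icc_twoway,
    pairwise_signed_rank,
    round_half_away,
    session_mean_by_muscle,
    subject_session_matrix,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from natriq.tables import tsc_table


@pytest.fixture(scope="module")
def healthy():
    t = tsc_table()
    return t[t.group == "healthy"]


class TestICC:
    def test_published_consistency_average_values(self, healthy):
        expected = {"GM": 0.784, "TA": 0.818, "S": 0.807}
        for m, val in expected.items():
            r = icc_twoway(subject_session_matrix(healthy, m), "Ck")
            assert round(r.value, 3) == val

    def test_toy_matrix_matches_hand_anova(self):
        x = np.array([[9.0, 10.0], [6.0, 7.0], [3.0, 5.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand) ** 2).sum() / ((n - 1) * (k - 1))
        hand = {
            "A1": (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)),
            "Ak": (msr - mse) / (msr + (msc - mse) / n),
            "C1": (msr - mse) / (msr + (k - 1) * mse),
            "Ck": 1 - mse / msr,
        }
        for variant, expect in hand.items():
            assert abs(icc_twoway(x, variant).value - expect) < 1e-12

    def test_identical_columns_give_one(self):
        x = np.tile(np.array([[3.0], [7.0], [9.0], [1.0]]), (1, 3))
        for variant in ("A1", "Ak", "C1", "Ck"):
            assert np.isclose(icc_twoway(x, variant).value, 1.0)

    def test_agrees_with_pingouin(self, healthy):
        pg = pytest.importorskip("pingouin")
        sub = healthy[healthy.muscle == "TA"]
        ref = pg.intraclass_corr(data=sub, targets="subject", raters="session",
                                 ratings="tsc").set_index("Type")
        x = subject_session_matrix(healthy, "TA")
        assert abs(icc_twoway(x, "A1").value - ref.loc["ICC(A,1)", "ICC"]) < 1e-9
        assert abs(icc_twoway(x, "Ck").value - ref.loc["ICC(C,k)", "ICC"]) < 1e-9

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            icc_twoway(x)


class TestBlandAltman:
    def test_identical_sessions_zero_limits(self, healthy):
        dup = healthy[healthy.session == "M1"].copy()
        dup2 = dup.copy()
        dup2["session"] = "M2"
        res = bland_altman(pd.concat([dup, dup2]), "GM", ("M1", "M2"))
        assert res.mean_diff == 0.0 and res.loa_high - res.loa_low == 0.0

    def test_limits_converge_to_normal_quantiles(self):
        rng = np.random.default_rng(0)
        n = 10000
        mu, sigma = 0.3, 0.8
        a = rng.normal(5.0, 1.0, n)
        b = a - rng.normal(mu, sigma, n)
        frames = []
        for sess, vals in (("M1", a), ("M2", b)):
            frames.append(pd.DataFrame({
                "subject": np.arange(n), "muscle": "GM", "session": sess,
                "tsc": vals, "group": "healthy",
            }))
        res = bland_altman(pd.concat(frames), "GM", ("M1", "M2"))
        assert abs(res.loa_low - (mu - 1.96 * sigma)) < 0.02 * 4 * sigma
        assert abs(res.loa_high - (mu + 1.96 * sigma)) < 0.02 * 4 * sigma
        assert 0.90 < res.fraction_within < 0.99

    def test_published_sessions_mostly_within_limits(self, healthy):
        within = []
        for m in MUSCLES:
            for pair in (("M1", "M2"), ("M1", "M3"), ("M2", "M3")):
                res = bland_altman(healthy, m, pair)
                within.append(res.fraction_within == 1.0)
        assert np.mean(within) > 0.5

    def test_too_few_subjects_rejected(self, healthy):
        tiny = healthy[healthy.subject <= 2]
        with pytest.raises(ValueError):
            bland_altman(tiny, "GM", ("M1", "M2"))


class TestFriedman:
    def test_identical_values_null(self):
        x = np.tile([5.0, 5.0, 5.0], (6, 1))
        res = friedman_test(x)
        assert res.statistic == 0.0 and res.p_exact == 1.0

    def test_perfect_ordering_statistic(self):
        # rank sums 30/20/10 for n=10, k=3 -> statistic 20
        x = np.tile([3.0, 2.0, 1.0], (10, 1))
        res = friedman_test(x)
        assert np.isclose(res.statistic, 20.0)
        assert res.p_exact < 1e-4

    def test_published_muscle_difference_significant(self):
        wide = session_mean_by_muscle(tsc_table(), "healthy")
        res = friedman_test(wide.to_numpy())
        assert res.p_exact < 0.05 and res.p_asymptotic < 0.05

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(9, 3)) + np.array([0.0, 0.4, 0.9])
        res = friedman_test(x, mode="asymptotic")
        ref = friedmanchisquare(*(x[:, j] for j in range(3)))
        assert np.isclose(res.p_asymptotic, ref.pvalue)

    def test_exact_against_bruteforce_enumeration(self):
        # tiny n: enumerate all 6^n within-subject permutations directly
        import itertools

        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 3))
        res = friedman_test(x)
        from scipy.stats import rankdata

        ranks = np.apply_along_axis(rankdata, 1, x)
        n, k = x.shape

        def stat(r):
            s = r.sum(axis=0)
            return 12.0 / (n * k * (k + 1)) * (s**2).sum() - 3 * n * (k + 1)

        obs = stat(ranks)
        perms = list(itertools.permutations(range(3)))
        count = total = 0
        for combo in itertools.product(perms, repeat=n):
            r = np.stack([ranks[i, list(p)] for i, p in enumerate(combo)])
            total += 1
            if stat(r) >= obs - 1e-12:
                count += 1
        assert np.isclose(res.p_exact, count / total)


class TestSignedRank:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 11.0), np.zeros(10))
        assert np.isclose(res.p_exact, 2.0 / 1024.0)

    def test_bonferroni_multiplies_and_caps(self):
        base = wilcoxon_signed_rank(np.arange(1.0, 11.0), np.zeros(10))
        bonf = wilcoxon_signed_rank(np.arange(1.0, 11.0), np.zeros(10),
                                    m_comparisons=3)
        assert np.isclose(bonf.p_exact, min(1.0, 3 * base.p_exact))
        capped = wilcoxon_signed_rank(np.array([1.0, -1.5]), np.zeros(2),
                                      m_comparisons=50)
        assert capped.p_exact == 1.0

    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank(np.zeros(5), np.zeros(5))
        assert res.p_exact == 1.0

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_exhaustive_agreement_with_scipy(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            d = rng.normal(0, 1, n)
            ours = wilcoxon_signed_rank(d, np.zeros(n))
            ref = wilcoxon(d, method="exact")
            assert abs(ours.p_exact - ref.pvalue) < 1e-12

    def test_exact_close_to_normal_approximation_midrange(self):
        rng = np.random.default_rng(10)
        d = rng.normal(0.4, 1.0, 10)
        res = wilcoxon_signed_rank(d, np.zeros(10))
        if 0.05 < res.p_exact < 0.5:   # mid-range statistic
            assert abs(res.p_exact - res.p_asymptotic) / res.p_exact < 0.2


class TestRankSum:
    def test_complete_separation_10_vs_5(self):
        a = np.arange(20.0, 30.0)
        b = np.arange(1.0, 6.0)
        res = wilcoxon_rank_sum(a, b)
        assert np.isclose(res.p_exact, 2.0 / 3003.0)
        assert round(res.p_exact, 4) == 0.0007

    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = wilcoxon_rank_sum(a, a)
        assert res.p_exact == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (6, 4), (8, 7)])
    def test_exhaustive_agreement_with_scipy(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(25):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            ours = wilcoxon_rank_sum(a, b)
            ref = mannwhitneyu(a, b, method="exact")
            assert abs(ours.p_exact - ref.pvalue) < 1e-12

    def test_matches_permutation_resampling(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.8, 1, 8)
        b = rng.normal(0, 1, 6)
        res = wilcoxon_rank_sum(a, b)
        from scipy.stats import rankdata

        combined = np.concatenate([a, b])
        ranks = rankdata(combined)
        obs = ranks[len(a):].sum()
        mu = len(b) * (len(combined) + 1) / 2.0
        n_perm = 20000
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(ranks)
            hits += abs(perm[len(a):].sum() - mu) >= abs(obs - mu) - 1e-12
        mc = hits / n_perm
        se = np.sqrt(mc * (1 - mc) / n_perm)
        assert abs(res.p_exact - mc) < 4 * se + 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestHelpers:
    def test_pairwise_uses_bonferroni_three(self):
        wide = session_mean_by_muscle(tsc_table(), "healthy")
        res = pairwise_signed_rank(wide)
        assert len(res) == 3
        assert all(v.correction == "bonferroni" for v in res.values())

    def test_round_half_away(self):
        assert round_half_away(0.25, 1) == 0.3
        assert round_half_away(-0.25, 1) == -0.3
        assert round_half_away(12.65, 1) == 12.7
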