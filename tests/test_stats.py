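"""Group-comparison engine: omnibus tests, post hocs, effect sizes, decision tree.

Pairwise p-values for the shared unequal-variance fixture are checked
against values computed independently in R (TukeyHSD / oneway.test /
kruskal.test), frozen below; the Welch and Games-Howell statistics are
additionally rebuilt from their published formulas inside the tests.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import groups_to_frame
from ibrtools.stats import (
    InsufficientDataError,
    assess_normality,
    compare_groups,
    dunn_bonferroni,
    epsilon_squared,
    games_howell,
    homogeneity,
    kruskal_wallis,
    omega_squared,
    one_way_anova,
    transform_cascade,
    tukey_hsd,
    welch_anova,
)

# frozen R oracle for the mixed_variance_fixture (see conftest)
R_TUKEY_P = {
    ("A", "B"): 4.98253507569e-02,
    ("A", "C"): 7.85247901539e-01,
    ("A", "D"): 8.17317471656e-04,
    ("B", "C"): 3.49960179886e-03,
    ("B", "D"): 2.33795598719e-01,
    ("C", "D"): 4.78716778469e-05,
}
R_WELCH = (11.9480833318, 3, 16.3062633582, 0.000218665476477)
R_KRUSKAL = (19.1223209284, 0.000257929700219)


class TestNormality:
    def test_four_normal_groups_pass(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(0, 1, 20) for g in "ABCD"}
        assert assess_normality(groups).passed

    def test_one_lognormal_group_fails_overall(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(0, 1, 20) for g in "ABC"}
        groups["D"] = np.exp(rng.normal(0, 1, 20))
        res = assess_normality(groups)
        assert not res.passed
        assert res.per_group_p["D"] <= 0.05

    def test_constant_group_fails_with_degenerate_flag(self):
        res = assess_normality({"A": [1.0, 1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0, 4.0]})
        assert not res.passed
        assert res.degenerate == ["A"]

    def test_tiny_group_is_untestable_not_failing(self):
        rng = np.random.default_rng(0)
        res = assess_normality({"A": [1.0, 2.0], "B": rng.normal(0, 1, 20)})
        assert res.per_group_p["A"] is None
        assert res.passed


class TestTransformCascade:
    def test_already_normal_data_untouched(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(5, 1, 20) for g in "AB"}
        out, applied, res = transform_cascade(groups)
        assert applied == "none" and res.passed
        np.testing.assert_array_equal(out["A"], groups["A"])

    def test_squared_normal_recovered_by_sqrt(self):
        rng = np.random.default_rng(30)
        groups = {g: rng.normal(10, 1, 20) ** 2 for g in "AB"}
        out, applied, res = transform_cascade(groups)
        assert applied == "sqrt" and res.passed
        np.testing.assert_allclose(out["A"], np.sqrt(groups["A"]))

    def test_wide_lognormal_requires_ln(self):
        rng = np.random.default_rng(0)
        groups = {g: np.exp(rng.normal(0, 2.0, 30)) for g in "AB"}
        out, applied, res = transform_cascade(groups)
        assert applied == "ln" and res.passed
        np.testing.assert_allclose(out["A"], np.log(groups["A"]))

    def test_doubly_exponential_data_resists_both_transforms(self):
        rng = np.random.default_rng(0)
        groups = {g: np.exp(np.exp(rng.normal(0, 1.2, 20))) for g in "ABCD"}
        out, applied, res = transform_cascade(groups)
        assert not res.passed
        assert applied == "ln"  # last transform tried; original values returned
        np.testing.assert_array_equal(out["A"], groups["A"])

    def test_negative_values_skip_sqrt_and_ln(self):
        rng = np.random.default_rng(0)
        groups = {g: np.exp(rng.normal(0, 2.0, 30)) - 50 for g in "AB"}
        _, applied, res = transform_cascade(groups)
        assert applied == "untransformable"
        assert not res.passed


class TestHomogeneity:
    def test_equal_spread_groups_pass(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(10, 2, 20) for g in "ABCD"}
        _, p, degenerate = homogeneity(groups)
        assert p > 0.05 and not degenerate

    def test_five_fold_spread_ratio_fails(self):
        rng = np.random.default_rng(3)
        groups = {"A": rng.normal(10, 1, 20), "B": rng.normal(10, 5, 20)}
        _, p, _ = homogeneity(groups)
        assert p < 0.05

    def test_all_constant_groups_degenerate(self):
        _, p, degenerate = homogeneity({"A": [2.0, 2.0], "B": [3.0, 3.0]})
        assert p == 1.0 and degenerate


class TestOneWayAnova:
    def test_hand_sums_of_squares_oracle(self):
        # groups {1,2,3} and {2,3,4}: SSb = 1.5, SSw = 4, F = 1.5/(4/4) = 1.5
        F, df1, df2, p = one_way_anova({"A": [1, 2, 3], "B": [2, 3, 4]})
        assert (df1, df2) == (1, 4)
        assert F == pytest.approx(1.5)

    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        F, _, _, p_f = one_way_anova({"A": a, "B": b})
        t, p_t = sps.ttest_ind(a, b)
        assert F == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_null_f_averages_near_one(self):
        vals = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            F, *_ = one_way_anova({g: rng.normal(0, 1, 10) for g in "ABCD"})
            vals.append(F)
        assert abs(np.mean(vals) - 1.0) < 0.2

    def test_all_constant_groups_undefined(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova({"A": [1, 1], "B": [1, 1]})


class TestWelchAnova:
    def test_matches_r_and_direct_formula(self, mixed_variance_fixture):
        F, df1, df2, p = welch_anova(mixed_variance_fixture)
        assert (F, df1, df2, p) == pytest.approx(R_WELCH, rel=1e-8)
        # direct evaluation of Welch's published formula
        arrays = list(mixed_variance_fixture.values())
        n = np.array([a.size for a in arrays])
        m = np.array([a.mean() for a in arrays])
        v = np.array([a.var(ddof=1) for a in arrays])
        w = n / v
        mw = np.sum(w * m) / np.sum(w)
        k = len(arrays)
        A = np.sum(w * (m - mw) ** 2) / (k - 1)
        tail = np.sum((1 - w / w.sum()) ** 2 / (n - 1))
        B = 1 + 2 * (k - 2) / (k**2 - 1) * tail
        assert F == pytest.approx(A / B)
        assert df2 == pytest.approx((k**2 - 1) / (3 * tail))

    def test_two_groups_equals_welch_t_squared(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 3, 14)
        F, _, df2, p_f = welch_anova({"A": a, "B": b})
        t, p_t = sps.ttest_ind(a, b, equal_var=False)
        assert F == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_near_classical_f_under_equal_variances(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(10, 2, 50) for g in "ABC"}
        Fw, *_ = welch_anova(groups)
        F, *_ = one_way_anova(groups)
        assert abs(Fw - F) < 0.2

    def test_zero_variance_group_rejected(self):
        with pytest.raises(InsufficientDataError, match="B"):
            welch_anova({"A": [1.0, 2.0, 3.0], "B": [4.0, 4.0, 4.0]})


class TestKruskalWallis:
    def test_all_identical_values_degenerate(self):
        H, df, p, n = kruskal_wallis({"A": [2, 2], "B": [2, 2]})
        assert H == 0.0 and p == 1.0 and df == 1

    def test_hand_rank_oracle_without_ties(self):
        # ranks 1..6; mean ranks 1.5, 3.5, 5.5 -> H = 12/42 * 89.5 - 21
        H, df, p, n = kruskal_wallis({"A": [1, 2], "B": [3, 4], "C": [5, 6]})
        assert df == 2 and n == 6
        assert H == pytest.approx(12 / 42 * (2 * 1.5**2 + 2 * 3.5**2 + 2 * 5.5**2) - 3 * 7)

    def test_matches_r_on_shared_fixture(self, mixed_variance_fixture):
        H, df, p, n = kruskal_wallis(mixed_variance_fixture)
        assert (H, p) == pytest.approx(R_KRUSKAL, rel=1e-8)

    def test_group_label_permutation_leaves_null_distribution_invariant(self):
        """H computed on shuffled labels has the same distribution as on the
        original labels when all groups share one distribution."""
        rng = np.random.default_rng(11)
        pooled = rng.normal(0, 1, 30)
        sizes = [10, 10, 10]

        def h_of(perm):
            parts = np.split(pooled[perm], np.cumsum(sizes)[:-1])
            return kruskal_wallis({str(i): p for i, p in enumerate(parts)})[0]

        h_orig = [h_of(rng.permutation(30)) for _ in range(200)]
        # under the null, H ~ chi2(2): compare the permutation mean with df
        assert abs(np.mean(h_orig) - 2.0) < 0.35


class TestTukey:
    def test_identical_groups_give_p_one(self):
        out = tukey_hsd({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        assert out["estimate"].iloc[0] == 0.0
        assert out["p_adjusted"].iloc[0] == pytest.approx(1.0)

    def test_two_balanced_groups_match_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        out = tukey_hsd({"A": a, "B": b})
        _, p_t = sps.ttest_ind(a, b)
        assert out["p_adjusted"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_matches_r_tukeyhsd_on_shared_fixture(self, mixed_variance_fixture):
        out = tukey_hsd(mixed_variance_fixture).set_index(["group_i", "group_j"])
        for pair, expect in R_TUKEY_P.items():
            assert out.loc[pair, "p_adjusted"] == pytest.approx(expect, rel=1e-5, abs=1e-9)

    def test_table_has_all_pairs(self, mixed_variance_fixture):
        assert len(tukey_hsd(mixed_variance_fixture)) == 6


class TestGamesHowell:
    def test_identical_groups_give_p_one(self):
        out = games_howell({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        assert out["estimate"].iloc[0] == pytest.approx(0.0)
        assert out["p_adjusted"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_tukey_when_variances_equal(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(10, 2, 40) for g in "ABC"}
        gh = games_howell(groups).set_index(["group_i", "group_j"])["p_adjusted"]
        tk = tukey_hsd(groups).set_index(["group_i", "group_j"])["p_adjusted"]
        assert np.allclose(gh, tk.loc[gh.index], atol=0.03)

    def test_direct_formula_oracle(self, mixed_variance_fixture):
        """Per-pair q, Welch-Satterthwaite df and studentized-range p rebuilt
        from the published formulas."""
        out = games_howell(mixed_variance_fixture).set_index(["group_i", "group_j"])
        k = len(mixed_variance_fixture)
        for (gi, gj) in itertools.combinations(mixed_variance_fixture, 2):
            a, b = mixed_variance_fixture[gi], mixed_variance_fixture[gj]
            se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
            q = abs(a.mean() - b.mean()) / np.sqrt(se2 / 2)
            df = se2**2 / (
                (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
                + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
            )
            p = sps.studentized_range.sf(q, k, df)
            assert out.loc[(gi, gj), "p_adjusted"] == pytest.approx(p, rel=1e-4, abs=1e-9)


class TestDunnBonferroni:
    def test_identical_groups_z_zero_p_one(self):
        out = dunn_bonferroni({"A": [1.0, 1.0, 2.0, 2.0], "B": [1.0, 2.0, 1.0, 2.0]})
        assert out["estimate"].iloc[0] == pytest.approx(0.0)
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_hand_rank_oracle_without_ties(self):
        groups = {"A": [1.0, 2.0], "B": [3.0, 4.0], "C": [5.0, 6.0]}
        out = dunn_bonferroni(groups).set_index(["group_i", "group_j"])
        # N=6, no ties: var base = 6*7/12 = 3.5; mean ranks 1.5, 3.5, 5.5
        for pair, dr in [(("A", "B"), -2.0), (("A", "C"), -4.0), (("B", "C"), -2.0)]:
            z = dr / np.sqrt(3.5 * (0.5 + 0.5))
            assert out.loc[pair, "estimate"] == pytest.approx(z)
            assert out.loc[pair, "p_adjusted"] == pytest.approx(min(1.0, 3 * 2 * sps.norm.sf(abs(z))))

    def test_adjusted_p_never_exceeds_one(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = dunn_bonferroni({g: rng.normal(0, 1, 6) for g in "ABCD"})
            assert (out["p_adjusted"] <= 1.0).all()
            assert (out["p_adjusted"] >= 0.0).all()


class TestEffectSizes:
    def test_omega_squared_zero_at_f_one(self):
        assert omega_squared(1.0, 3, 40) == 0.0

    @pytest.mark.parametrize(
        "F, df1, df2, expect",
        [
            (13.5, 3, 75, 0.322),   # glucose energy
            (10.8, 3, 71, 0.282),   # GST
            (3.87, 3, 72, 0.102),   # energy consumed
            (0.114, 3, 76, -0.034), # lipid energy (F < 1 -> negative)
            (0.496, 3, 71, -0.021), # CEA
        ],
    )
    def test_omega_squared_reproduces_reported_values(self, F, df1, df2, expect):
        assert omega_squared(F, df1, df2) == pytest.approx(expect, abs=5e-4)

    def test_omega_squared_matches_sums_of_squares_definition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(0, 2), 1, rng.integers(5, 15)) for _ in range(4)]
            allv = np.concatenate(groups)
            grand = allv.mean()
            ssb = sum(a.size * (a.mean() - grand) ** 2 for a in groups)
            ssw = sum(((a - a.mean()) ** 2).sum() for a in groups)
            sst = ssb + ssw
            df1, df2 = 3, allv.size - 4
            msw = ssw / df2
            F = (ssb / df1) / msw
            direct = (ssb - df1 * msw) / (sst + msw)
            assert omega_squared(F, df1, df2) == pytest.approx(direct, abs=1e-12)

    def test_epsilon_squared_formula(self):
        assert epsilon_squared(0.0, 10) == 0.0
        assert epsilon_squared(14.6, 76) == pytest.approx(0.195, abs=5e-4)

    def test_epsilon_squared_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        groups = {g: rng.uniform(1, 5, 12) for g in "ABC"}
        H1, _, _, n1 = kruskal_wallis(groups)
        H2, _, _, n2 = kruskal_wallis({g: np.exp(v) for g, v in groups.items()})
        assert epsilon_squared(H1, n1) == pytest.approx(epsilon_squared(H2, n2))

    def test_epsilon_squared_needs_two_observations(self):
        with pytest.raises(ValueError):
            epsilon_squared(1.0, 1)


class TestCompareGroups:
    def test_normal_homoscedastic_fixture_takes_anova_branch(self):
        rng = np.random.default_rng(0)
        df = groups_to_frame({g: rng.normal(10, 1, 20) for g in "ABCD"})
        r = compare_groups(df, "y")
        assert r.trail.branch == "anova_tukey"
        assert r.statistic_kind == "F" and r.effect_size_kind == "omega2"
        assert len(r.posthoc) == 6

    def test_heteroscedastic_fixture_takes_welch_branch(self):
        rng = np.random.default_rng(0)
        df = groups_to_frame({k: rng.normal(20, s, 20) for k, s in zip("ABCD", [1, 1, 1, 4])})
        r = compare_groups(df, "y")
        assert r.trail.branch == "welch_gameshowell"
        assert r.statistic_kind == "F_welch" and r.effect_size_approx

    def test_stubbornly_skewed_fixture_takes_kruskal_branch(self):
        rng = np.random.default_rng(0)
        df = groups_to_frame({g: np.exp(np.exp(rng.normal(0, 1.2, 20))) for g in "ABCD"})
        r = compare_groups(df, "y")
        assert r.trail.branch == "kruskal_dunn"
        assert r.effect_size_kind == "epsilon2" and r.df2 is None

    def test_branch_choice_is_deterministic(self):
        rng = np.random.default_rng(4)
        df = groups_to_frame({g: rng.normal(10, 1, 15) for g in "ABC"})
        r1, r2 = compare_groups(df, "y"), compare_groups(df, "y")
        assert r1.trail == r2.trail
        assert r1.p == r2.p

    def test_posthoc_p_values_are_probabilities(self):
        rng = np.random.default_rng(6)
        df = groups_to_frame({g: np.exp(rng.normal(0, 1, 15)) for g in "ABCD"})
        r = compare_groups(df, "y")
        assert ((r.posthoc["p_adjusted"] >= 0) & (r.posthoc["p_adjusted"] <= 1)).all()
        assert 0 <= r.p <= 1

    def test_posthoc_gating_and_suppression(self):
        rng = np.random.default_rng(0)
        df = groups_to_frame({g: rng.normal(10, 1, 20) for g in "ABCD"})  # null: p large
        gated = compare_groups(df, "y", posthoc="gated")
        never = compare_groups(df, "y", posthoc="never")
        assert len(never.posthoc) == 0
        if gated.p >= 0.05:
            assert len(gated.posthoc) == 0

    def test_insufficient_data_raises_skip_signal(self):
        df = pd.DataFrame({"group": ["A", "A", "B"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            compare_groups(df, "y")
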