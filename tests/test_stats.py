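"""ANOVA, the variance gate, LSD, Dunnett's T3 and the t-test."""

import math

import numpy as np
import pytest

import charvoid as cv
from charvoid.errors import DegenerateDataError, ValidationError
from charvoid.stats import GroupData, PairwiseResult, compare_groups


def brute_force_anova(groups):
    """Independent textbook computation of one-way ANOVA."""
    from scipy.stats import f as fdist

    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, fdist.sf(F, dfb, dfw)


def brute_force_pooled_t(a, b):
    """Closed-form pooled two-sample t-test."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sp2 = (sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)) / (
        na + nb - 2
    )
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * tdist.sf(abs(t), na + nb - 2)


FIXTURE = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]


def as_groups(lists):
    return [GroupData(str(i), np.array(v)) for i, v in enumerate(lists)]


class TestAnova:
    def test_matches_brute_force_fixture(self):
        f, df, p = cv.oneway_anova(as_groups(FIXTURE))
        f_ref, p_ref = brute_force_anova(FIXTURE)
        assert f == pytest.approx(f_ref)
        assert p == pytest.approx(p_ref)
        assert df == (2, 6)

    def test_two_groups_f_is_t_squared(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 4.0, 5.0, 5.5]
        f, _, p_f = cv.oneway_anova(as_groups([a, b]))
        t, p_t = brute_force_pooled_t(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_identical_groups_give_zero_f(self):
        f, _, p = cv.oneway_anova(as_groups([[1, 2, 3]] * 3))
        assert f == 0.0
        assert p == 1.0

    def test_zero_within_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cv.oneway_anova(as_groups([[1.0, 1.0], [2.0, 2.0]]))

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            cv.oneway_anova(as_groups([[1.0, 2.0]]))


class TestVarianceGate:
    def test_identical_groups_select_lsd(self):
        assert cv.variance_gate(as_groups(FIXTURE)) == "LSD"

    def test_wildly_unequal_variances_select_t3(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1, 20)
        g2 = rng.normal(0, 10, 20)
        assert cv.variance_gate(as_groups([g1, g2])) == "DunnettT3"

    def test_type_one_rate_of_gate(self):
        # equal-variance normal groups (n=7): LSD selected ~95% of reps
        rng = np.random.default_rng(7)
        picks = sum(
            cv.variance_gate(as_groups(rng.normal(0, 1, (3, 7)))) == "LSD"
            for _ in range(1000)
        )
        assert 0.92 <= picks / 1000 <= 0.98


class TestFisherLSD:
    def test_two_groups_reduce_to_pooled_t(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        (res,) = cv.fisher_lsd(as_groups([a, b]))
        t_ref, p_ref = brute_force_pooled_t(a, b)
        assert res.statistic == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)

    def test_matches_pooled_t_oracle_three_groups(self):
        groups = as_groups(FIXTURE)
        results = cv.fisher_lsd(groups)
        assert len(results) == 3
        # oracle: pairwise t on the pooled MSW with N-k df
        from scipy.stats import t as tdist

        ssw = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
        msw, dfw = ssw / 6, 6
        for r in results:
            ga = groups[int(r.group_a)].values
            gb = groups[int(r.group_b)].values
            se = math.sqrt(msw * (1 / len(ga) + 1 / len(gb)))
            t_ref = (ga.mean() - gb.mean()) / se
            assert r.statistic == pytest.approx(t_ref)
            assert r.p == pytest.approx(2 * tdist.sf(abs(t_ref), dfw))

    def test_symmetric_in_group_order(self):
        groups = as_groups(FIXTURE)
        ps = {frozenset((r.group_a, r.group_b)): r.p
              for r in cv.fisher_lsd(groups)}
        ps_rev = {frozenset((r.group_a, r.group_b)): r.p
                  for r in cv.fisher_lsd(groups[::-1])}
        for k, v in ps.items():
            assert ps_rev[k] == pytest.approx(v)


class TestDunnettT3:
    def test_two_groups_at_least_welch_p(self):
        from scipy.stats import ttest_ind

        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 2.5, 3.0, 9.0, 12.0]
        (res,) = cv.dunnett_t3(as_groups([a, b]), mc_draws=50_000)
        welch_p = ttest_ind(a, b, equal_var=False).pvalue
        assert res.p >= welch_p - 0.01

    def test_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 7)
        other = rng.normal(0, 2, 7)
        ps = []
        for shift in (0.0, 1.0, 2.5, 5.0):
            groups = as_groups([base, other - other.mean() + shift])
            (res,) = cv.dunnett_t3(groups, mc_draws=50_000)
            ps.append(res.p)
        assert all(p1 >= p2 - 0.01 for p1, p2 in zip(ps, ps[1:]))

    def test_undersized_group_rejected(self):
        with pytest.raises(ValidationError):
            GroupData("a", [1.0])  # < 2 values
        with pytest.raises(ValidationError):
            cv.dunnett_t3([GroupData("a", [1.0, 2.0])])

    def test_welch_statistic_and_df(self):
        # the per-pair statistic is Welch's t with Welch-Satterthwaite df
        from scipy.stats import ttest_ind

        a = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        b = np.array([2.0, 9.0, 4.0, 5.5, 13.0])
        (res,) = cv.dunnett_t3(as_groups([a, b]), mc_draws=10_000)
        ref = ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.df == pytest.approx(ref.df)


class TestTTest:
    def test_identical_samples_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, p = cv.t_test_two_tailed(a, a)
        assert t == 0.0
        assert p == 1.0

    def test_symmetric(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        _, p_ab = cv.t_test_two_tailed(a, b)
        _, p_ba = cv.t_test_two_tailed(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t, p = cv.t_test_two_tailed(a, b)
        t_ref, p_ref = brute_force_pooled_t(a, b)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_degenerate_constant_samples(self):
        with pytest.raises(DegenerateDataError):
            cv.t_test_two_tailed([2.0, 2.0], [2.0, 2.0])


class TestCompareGroups:
    def test_report_complete_and_consistent(self):
        comp = compare_groups(as_groups(FIXTURE), mc_draws=5000)
        assert comp.posthoc_method in ("LSD", "DunnettT3")
        assert len(comp.pairwise) == 3
        assert len(comp.pairwise_lsd) == 3
        assert len(comp.pairwise_t3) == 3
        assert 0 <= comp.p_anova <= 1
        d = comp.to_dict()
        assert set(d) >= {"F", "df", "p_anova", "posthoc_method", "pairwise"}
        for r in comp.pairwise:
            assert isinstance(r, PairwiseResult)
            assert r.ci_low <= r.mean_diff <= r.ci_high
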