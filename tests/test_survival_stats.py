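import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from metabalance.exceptions import ValidationError
from metabalance.survival_stats import (
    SurvivalData,
    chisq_2x2,
    collinearity_filter,
    cox_fit,
    intersect_candidates,
    km_estimate,
    logrank_test,
    median_split,
    prognostic_index,
    ttest_by_group,
    univariable_screen,
)


def _surv(time, event, idx=None):
    idx = idx or [f"s{i}" for i in range(len(time))]
    return SurvivalData(pd.Series(time, index=idx, dtype=float),
                        pd.Series(event, index=idx))


def _sim_surv(rng, x, beta, h0=0.05, window=40.0):
    t = rng.exponential(1.0 / (h0 * np.exp(beta * x)))
    c = rng.uniform(0, window, size=len(x))
    return np.minimum(t, c), (t <= c).astype(int)


class TestSurvivalData:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            _surv([1.0, -1.0], [1, 0])
        with pytest.raises(ValidationError):
            _surv([1.0, 2.0], [1, 2])

    def test_n_events(self):
        assert _surv([1, 2, 3], [1, 0, 1]).n_events == 2


class TestCoxFit:
    def test_bruteforce_1d_oracle(self):
        """6-subject toy, no ties: beta equals 1-D maximization of the
        hand-written partial likelihood."""
        time = [2.0, 4.0, 5.0, 7.0, 9.0, 12.0]
        event = [1, 1, 0, 1, 1, 0]
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        sd = _surv(time, event)
        fit = cox_fit(pd.DataFrame({"x": x}, index=sd.time.index), sd)

        def neg_pl(b):
            order = np.argsort(time)
            ll = 0.0
            for i in order:
                if event[i]:
                    risk = [j for j in range(6) if time[j] >= time[i]]
                    ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return -ll

        opt = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.coef["x"] == pytest.approx(opt.x, abs=1e-6)

    def test_duplicating_subjects_leaves_beta_unchanged(self, rng):
        x = rng.standard_normal(40)
        time, event = _sim_surv(rng, x, 0.5)
        idx = [f"s{i}" for i in range(40)]
        sd = _surv(time, event, idx)
        # Breslow: the duplicated-cohort partial likelihood is the square of
        # the original up to a constant, so the argmax is exactly preserved.
        # (Efron's within-tie adjustment breaks exact proportionality.)
        fit1 = cox_fit(pd.DataFrame({"x": x}, index=idx), sd, ties="breslow")
        idx2 = idx + [f"d{i}" for i in range(40)]
        sd2 = _surv(list(time) * 2, list(event) * 2, idx2)
        fit2 = cox_fit(pd.DataFrame({"x": list(x) * 2, }, index=idx2), sd2,
                       ties="breslow")
        assert fit2.coef["x"] == pytest.approx(fit1.coef["x"], abs=1e-6)

    def test_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        x = rng.standard_normal((150, 2))
        time, event = _sim_surv(rng, x[:, 0] - 0.5 * x[:, 1], 0.4)
        time = np.round(time, 0) + 0.5  # force heavy ties
        idx = [f"s{i}" for i in range(150)]
        sd = _surv(time, event, idx)
        fit = cox_fit(pd.DataFrame(x, index=idx, columns=["a", "b"]), sd)
        df = pd.DataFrame({"T": time, "E": event, "a": x[:, 0], "b": x[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.coef["a"] == pytest.approx(cph.params_["a"], abs=1e-4)
        assert fit.coef["b"] == pytest.approx(cph.params_["b"], abs=1e-4)
        assert fit.se["a"] == pytest.approx(cph.standard_errors_["a"], abs=1e-4)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_breslow_differs_from_efron_under_ties(self, rng):
        x = rng.standard_normal(80)
        time, event = _sim_surv(rng, x, 0.6)
        time = np.round(time, 0) + 0.5
        idx = [f"s{i}" for i in range(80)]
        sd = _surv(time, event, idx)
        X = pd.DataFrame({"x": x}, index=idx)
        be = cox_fit(X, sd, ties="efron").coef["x"]
        bb = cox_fit(X, sd, ties="breslow").coef["x"]
        assert be != bb

    def test_hr_ci_p_relations(self, rng):
        x = rng.standard_normal(60)
        time, event = _sim_surv(rng, x, 0.5)
        idx = [f"s{i}" for i in range(60)]
        fit = cox_fit(pd.DataFrame({"x": x}, index=idx), _surv(time, event, idx))
        assert fit.hr["x"] == pytest.approx(np.exp(fit.coef["x"]))
        assert fit.ci_lower["x"] < fit.hr["x"] < fit.ci_upper["x"]
        z = fit.coef["x"] / fit.se["x"]
        assert fit.p["x"] == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_constant_covariate_named(self):
        sd = _surv([1, 2, 3, 4], [1, 1, 1, 0])
        X = pd.DataFrame({"flat": [1.0] * 4}, index=sd.time.index)
        with pytest.raises(ValidationError, match="flat"):
            cox_fit(X, sd)

    def test_too_few_events(self):
        sd = _surv([1, 2, 3], [1, 0, 0])
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=sd.time.index)
        with pytest.raises(ValidationError, match="events"):
            cox_fit(X, sd)


class TestUnivariableScreen:
    def test_planted_gene_retained(self):
        kept = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            expr = pd.DataFrame(rng.standard_normal((11, n)),
                                index=["PLANTED"] + [f"null{i}" for i in range(10)],
                                columns=[f"s{i}" for i in range(n)])
            time, event = _sim_surv(rng, expr.loc["PLANTED"].to_numpy(), 0.5)
            sd = _surv(time, event, list(expr.columns))
            res = univariable_screen(expr, sd, alpha=0.1)
            kept += "PLANTED" in res.retained
        assert kept >= 9

    def test_alpha_zero_empty(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 50)),
                            columns=[f"s{i}" for i in range(50)],
                            index=list("abc"))
        time, event = _sim_surv(rng, np.zeros(50), 0.0)
        sd = _surv(time, event, list(expr.columns))
        res = univariable_screen(expr, sd, alpha=1e-300)
        assert res.retained == []

    def test_ordered_by_p(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 100)),
                            columns=[f"s{i}" for i in range(100)],
                            index=list("abcde"))
        time, event = _sim_surv(rng, expr.loc["a"].to_numpy(), 0.8)
        sd = _surv(time, event, list(expr.columns))
        res = univariable_screen(expr, sd, alpha=1.0 - 1e-12)
        assert res.table["p"].is_monotonic_increasing

    def test_constant_gene_skipped_not_fatal(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 50)),
                            columns=[f"s{i}" for i in range(50)], index=["a", "b"])
        expr.loc["b"] = 1.0
        time, event = _sim_surv(rng, expr.loc["a"].to_numpy(), 0.5)
        sd = _surv(time, event, list(expr.columns))
        res = univariable_screen(expr, sd)
        assert [g for g, _ in res.skipped] == ["b"]


class TestIntersect:
    def test_published_table_lists(self):
        dfs = ["PFKFB4", "ALDOA", "EGLN3", "CYP4A22", "PCK1", "ACADL",
               "CYP4A11", "EHHADH", "GAPDH", "HMGCS2", "ENO2"]
        os_ = ["PFKFB4", "EGLN3", "ALDOA", "GAPDH", "HK2", "ENO2", "PFKFB3",
               "HIF1A", "HMGCS2", "EHHADH", "ECI1", "LDHB"]
        got = intersect_candidates(dfs, os_)
        assert got == ["PFKFB4", "ALDOA", "EGLN3", "EHHADH", "GAPDH",
                       "HMGCS2", "ENO2"]
        assert len(got) == 7

    def test_disjoint(self):
        assert intersect_candidates(["a"], ["b"]) == []

    def test_idempotent(self):
        assert intersect_candidates(["a", "b"], ["a", "b"]) == ["a", "b"]


class TestCollinearity:
    def test_high_r_pair_drops_second(self, rng):
        base = rng.standard_normal(100)
        expr = pd.DataFrame({"keep": base, "drop": base + 0.01 * rng.standard_normal(100),
                             "indep": rng.standard_normal(100)}).T
        kept, exclusions = collinearity_filter(expr, ["keep", "drop", "indep"])
        assert kept == ["keep", "indep"]
        assert exclusions[0]["gene"] == "drop"
        assert exclusions[0]["partner"] == "keep"

    def test_cutoff_above_one_keeps_all(self, rng):
        base = rng.standard_normal(50)
        expr = pd.DataFrame({"a": base, "b": base}).T
        kept, exclusions = collinearity_filter(expr, ["a", "b"], r_cutoff=1.01)
        assert kept == ["a", "b"] and exclusions == []

    def test_matches_bruteforce_greedy(self, rng):
        n, g = 80, 12
        block = rng.standard_normal(n)
        expr = {}
        for i in range(g):
            if i % 3 == 0:
                expr[f"g{i}"] = block + 0.3 * rng.standard_normal(n)
            else:
                expr[f"g{i}"] = rng.standard_normal(n)
        expr = pd.DataFrame(expr).T
        order = [f"g{i}" for i in range(g)]
        kept, exclusions = collinearity_filter(expr, order, r_cutoff=0.6)

        bf_kept = []
        bf_excl = []
        for gene in order:
            clash = None
            for k in bf_kept:
                r = np.corrcoef(expr.loc[gene], expr.loc[k])[0, 1]
                if abs(r) >= 0.6:
                    clash = k
                    break
            if clash is None:
                bf_kept.append(gene)
            else:
                bf_excl.append(gene)
        assert kept == bf_kept
        assert [e["gene"] for e in exclusions] == bf_excl

    def test_missing_candidate_errors(self, rng):
        expr = pd.DataFrame({"a": rng.standard_normal(10)}).T
        with pytest.raises(ValidationError, match="zz"):
            collinearity_filter(expr, ["a", "zz"])


class TestPrognosticIndex:
    def _fit(self, rng, genes=("a", "b")):
        n = 80
        expr = pd.DataFrame(rng.standard_normal((len(genes), n)), index=list(genes),
                            columns=[f"s{i}" for i in range(n)])
        time, event = _sim_surv(rng, expr.iloc[0].to_numpy(), 0.5)
        sd = _surv(time, event, list(expr.columns))
        return cox_fit(expr.T, sd), expr

    def test_single_gene_beta_one_scales_expression(self, rng):
        fit, expr = self._fit(rng, genes=("a",))
        fit.coef["a"] = 1.0
        pi = prognostic_index(fit, expr)
        assert np.allclose(pi, expr.loc["a"])

    def test_zero_beta_gives_zero(self, rng):
        fit, expr = self._fit(rng)
        fit.coef[:] = 0.0
        assert np.allclose(prognostic_index(fit, expr), 0.0)

    def test_matches_matrix_product(self, rng):
        fit, expr = self._fit(rng, genes=("a", "b", "c"))
        pi = prognostic_index(fit, expr)
        expected = fit.coef.to_numpy() @ expr.loc[["a", "b", "c"]].to_numpy()
        assert np.allclose(pi.to_numpy(), expected)

    def test_missing_gene_errors(self, rng):
        fit, expr = self._fit(rng)
        with pytest.raises(ValidationError, match="a"):
            prognostic_index(fit, expr.drop(index="a"))


class TestMedianSplit:
    def test_tie_goes_high(self):
        rg = median_split(pd.Series([-1.0, 0.0, 1.0]))
        assert rg.labels.tolist() == ["low", "high", "high"]
        assert rg.threshold == 0.0 and rg.rule == "pi_median"

    def test_all_equal_all_high(self):
        rg = median_split(pd.Series([2.0, 2.0]))
        assert (rg.labels == "high").all()

    def test_matches_bruteforce(self, rng):
        pi = pd.Series(rng.standard_normal(31))
        rg = median_split(pi)
        med = float(np.sort(pi)[15])
        for i in pi.index:
            assert rg.labels[i] == ("high" if pi[i] >= med else "low")


class TestKm:
    def test_all_censored_flat(self):
        sd = _surv([1, 2, 3], [0, 0, 0])
        curve = km_estimate(sd)["all"]
        assert len(curve.times) == 0
        assert curve.survival_at(10.0) == 1.0

    def test_hand_computed_product_limit(self):
        # events at t=1 and t=3, censor at t=2, extra subjects at 4, 5
        sd = _surv([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
        curve = km_estimate(sd)["all"]
        assert curve.survival_at(1) == pytest.approx(4 / 5)
        assert curve.survival_at(2.5) == pytest.approx(4 / 5)
        assert curve.survival_at(3) == pytest.approx(4 / 5 * (1 - 1 / 3))

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        time = np.round(rng.exponential(10, 100), 1) + 0.1
        event = rng.integers(0, 2, 100)
        sd = _surv(time, event)
        curve = km_estimate(sd)["all"]
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        expected = kmf.survival_function_.loc[curve.times, "KM_estimate"].to_numpy()
        assert np.allclose(curve.survival, expected, atol=1e-12)

    def test_no_censoring_equals_empirical(self, rng):
        time = rng.exponential(5, 60)
        sd = _surv(time, [1] * 60)
        curve = km_estimate(sd)["all"]
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx((time > t).mean())

    def test_non_increasing(self, rng):
        time = rng.exponential(5, 80)
        event = rng.integers(0, 2, 80)
        curve = km_estimate(_surv(time, event))["all"]
        assert (np.diff(curve.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_zero(self):
        # both groups are the exact same subjects: O-E vanishes
        time = [1.0, 2.0, 3.0, 4.0] * 2
        event = [1, 0, 1, 1] * 2
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=[f"s{i}" for i in range(8)])
        stat, p = logrank_test(_surv(time, event), groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_closed_form(self):
        time = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        event = [1] * 10
        groups = pd.Series(["a", "b"] * 5, index=[f"s{i}" for i in range(10)])
        stat, p = logrank_test(_surv(time, event), groups)
        o_minus_e = 0.0
        var = 0.0
        for i, t in enumerate(time):
            at_risk = [j for j in range(10) if time[j] >= t]
            n = len(at_risk)
            n1 = sum(1 for j in at_risk if j % 2 == 0)
            o_minus_e += (1 if i % 2 == 0 else 0) - n1 / n
            if n > 1:
                var += (n1 / n) * (1 - n1 / n)
        assert stat == pytest.approx(o_minus_e ** 2 / var, abs=1e-12)

    def test_power_with_separated_hazards(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.repeat([0.0, 1.0], 100)
            time, event = _sim_surv(rng, x, np.log(3.0))
            groups = pd.Series(np.where(x > 0, "hi", "lo"),
                               index=[f"s{i}" for i in range(200)])
            _, p = logrank_test(_surv(time, event), groups)
            hits += p < 0.001
        assert hits >= 9

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        time = np.round(rng.exponential(10, 120), 0) + 0.5
        event = rng.integers(0, 2, 120)
        g = rng.integers(0, 2, 120)
        groups = pd.Series(np.where(g > 0, "a", "b"),
                           index=[f"s{i}" for i in range(120)])
        stat, p = logrank_test(_surv(time, event), groups)
        r = ll_logrank(time[g > 0], time[g == 0], event[g > 0], event[g == 0])
        assert stat == pytest.approx(r.test_statistic, abs=1e-9)
        assert p == pytest.approx(r.p_value, abs=1e-12)

    def test_single_group_errors(self):
        groups = pd.Series(["a"] * 4, index=[f"s{i}" for i in range(4)])
        with pytest.raises(ValidationError):
            logrank_test(_surv([1, 2, 3, 4], [1, 1, 0, 0]), groups)


class TestTtest:
    def test_identical_groups(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        t, p = ttest_by_group(v, g)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_welch_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        v = pd.Series(np.concatenate([a, b]))
        g = pd.Series(["x"] * 4 + ["y"] * 4)
        t, p = ttest_by_group(v, g, welch=True)
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        expected_t = (a.mean() - b.mean()) / se
        assert t == pytest.approx(expected_t)
        df = (a.var(ddof=1) / 4 + b.var(ddof=1) / 4) ** 2 / (
            (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 4) ** 2 / 3)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), df))

    def test_power(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            v = pd.Series(np.concatenate([rng.normal(0, 1, 50),
                                          rng.normal(1, 1, 50)]))
            g = pd.Series(["a"] * 50 + ["b"] * 50)
            _, p = ttest_by_group(v, g)
            hits += p < 0.001
        assert hits >= 9

    def test_degenerate_group_errors(self):
        v = pd.Series([1.0, 2.0, 3.0])
        g = pd.Series(["a", "b", "b"])
        with pytest.raises(ValidationError):
            ttest_by_group(v, g)


class TestChisq:
    def test_balanced_table_zero(self):
        stat, p = chisq_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_without_yates(self):
        stat, _ = chisq_2x2([[30, 10], [10, 30]], yates=False)
        # n(ad-bc)^2 / (r1 r2 c1 c2) = 80*800^2/40^4
        assert stat == pytest.approx(80 * 800 ** 2 / 40 ** 4)
        assert stat == pytest.approx(20.0)

    def test_yates_shrinks_statistic(self):
        plain, _ = chisq_2x2([[12, 5], [7, 14]], yates=False)
        corr, _ = chisq_2x2([[12, 5], [7, 14]], yates=True)
        assert corr < plain

    def test_yates_p_closer_to_fisher(self):
        table = [[12, 5], [7, 14]]
        _, p_plain = chisq_2x2(table, yates=False)
        _, p_yates = chisq_2x2(table, yates=True)
        _, p_fisher = stats.fisher_exact(table)
        assert abs(p_yates - p_fisher) < abs(p_plain - p_fisher)

    def test_zero_margin_errors(self):
        with pytest.raises(ValidationError):
            chisq_2x2([[0, 0], [5, 5]])
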