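"""Group tests, logistic fits, BIC stepwise selection, summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import apdscreen as a
from apdscreen.models import null_bic

from test_rules import params as make_params


def mwu_exact_oracle(x, y):
    """Two-sided exact MWU p by full enumeration of rank assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n = len(pooled)
    ranks_all = range(n)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    vals = sorted(pooled)
    for idx in itertools.combinations(ranks_all, len(x)):
        xs = [vals[i] for i in idx]
        ys = [vals[i] for i in ranks_all if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def fisher_oracle(table):
    """Two-sided Fisher p: sum over tables (fixed margins) with pmf <= observed."""
    (a11, a12), (a21, a22) = table
    r1, c1, n = a11 + a12, a11 + a21, a11 + a12 + a21 + a22
    rv = stats.hypergeom(n, c1, r1)
    p_obs = rv.pmf(a11)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    return float(sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9)))


class TestMwu:
    def test_null_identical_groups(self):
        _, p = a.mwu_test([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_separated_small_sample_exact(self):
        u, p = a.mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = list(np.round(rng.normal(0, 10, size=4), 3))
        y = list(np.round(rng.normal(5, 10, size=5), 3))
        _, p = a.mwu_test(x, y)
        assert p == pytest.approx(mwu_exact_oracle(x, y))

    def test_alarms_discriminate_on_default_cohort(self, small_params):
        cases = [p.total_alarms for p in small_params if p.group == a.CASE]
        controls = [p.total_alarms for p in small_params if p.group == a.CONTROL]
        _, p = a.mwu_test(cases, controls)
        assert p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            a.mwu_test([], [1.0])


class TestFisher:
    def test_homogeneous_table(self):
        assert a.fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[10, 0], [0, 10]], [[7, 3], [2, 8]], [[1, 9], [5, 5]], [[0, 4], [4, 0]]],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert a.fisher_exact(table) == pytest.approx(fisher_oracle(table), rel=1e-6)

    def test_transpose_symmetry(self):
        t = [[7, 3], [2, 8]]
        tt = [list(r) for r in zip(*t)]
        assert a.fisher_exact(t) == pytest.approx(a.fisher_exact(tt))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            a.fisher_exact([[1.5, 2], [3, 4]])


class TestLogisticSimple:
    def test_two_by_two_closed_form_odds_ratio(self):
        # binary covariate: cases 8 exposed / 4 unexposed, controls 3 / 9
        x = [1] * 8 + [0] * 4 + [1] * 3 + [0] * 9
        y = [1] * 12 + [0] * 12
        fit = a.logistic_simple(x, y, name="exposure")
        assert fit.ok
        orr = fit.or_per_unit["exposure"][0]
        assert orr == pytest.approx((8 * 9) / (4 * 3), rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            a.logistic_simple([2.0] * 10, [1] * 5 + [0] * 5)

    def test_separation_flagged_not_garbage(self):
        x = [0, 1, 2, 3, 10, 11, 12, 13]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        fit = a.logistic_simple(x, y)
        assert fit.separation or not fit.converged
        assert not fit.ok

    def test_parameter_recovery_beta_026(self, rng):
        """On a constructed linear-logit design the MLE recovers the true
        slope 0.261 within 3 standard errors (n = 2,000)."""
        beta0, beta1, n = -2.0, 0.261, 2000
        x = rng.normal(10, 6, size=n)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = rng.binomial(1, p)
        fit = a.logistic_simple(x, y, name="x")
        assert fit.ok
        bhat = fit.beta["x"]
        lo, hi = fit.or_per_unit["x"][1:]
        se = (math.log(hi) - math.log(lo)) / (2 * 1.959964)
        assert abs(bhat - beta1) < 3 * se

    def test_or_equals_exp_beta_and_ci_brackets(self, small_params):
        x = np.array([p.total_alarms for p in small_params], dtype=float)
        y = np.array([1 if p.group == a.CASE else 0 for p in small_params])
        fit = a.logistic_simple(x, y, name="alarms")
        if fit.ok:
            orr, lo, hi = fit.or_per_unit["alarms"]
            assert orr == pytest.approx(math.exp(fit.beta["alarms"]))
            assert lo <= orr <= hi


def all_subsets_bic(candidates, y):
    """Exhaustive BIC search over every candidate subset (oracle)."""
    from apdscreen.models import _fit_logit

    best = ((), null_bic(y))
    names = list(candidates)
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            X = np.column_stack([candidates[nm] for nm in subset])
            fit = _fit_logit(X, np.asarray(y), subset)
            if fit.ok and fit.bic < best[1]:
                best = (subset, fit.bic)
    return best


class TestStepwiseBic:
    def _signal_design(self, rng, n=500):
        x1 = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.0 + 2.0 * x1)))
        y = rng.binomial(1, p)
        cands = {"signal": x1}
        for i in range(3):
            cands[f"noise{i}"] = rng.normal(size=n)
        return cands, y

    def test_selects_exactly_the_signal_covariate(self, rng):
        cands, y = self._signal_design(rng)
        res = a.stepwise_bic(cands, y)
        assert res.selected == ("signal",)
        assert res.status["noise0"] == "NC"

    def test_matches_all_subsets_search(self, rng):
        cands, y = self._signal_design(rng, n=300)
        res = a.stepwise_bic(cands, y)
        best_subset, best_bic = all_subsets_bic(cands, y)
        assert set(res.selected) == set(best_subset)
        assert res.bic == pytest.approx(best_bic)

    def test_final_model_is_one_move_optimal(self, small_params):
        from apdscreen.models import complete_cases
        from apdscreen.pipeline import MODEL_PARAMETERS

        x, y, _ = complete_cases(small_params, MODEL_PARAMETERS)
        res = a.stepwise_bic(x, y)
        _, exhaustive_bic = all_subsets_bic(x, y)
        # greedy result can be no better than the global optimum
        assert res.bic >= exhaustive_bic - 1e-9

    def test_duplicated_covariate_enters_once(self, rng):
        x = rng.normal(size=200)
        p = 1 / (1 + np.exp(-1.5 * x))
        y = rng.binomial(1, p)
        res = a.stepwise_bic({"a": x, "b": x.copy()}, y)
        assert sorted(res.status.values()) == ["NC", "selected"]

    def test_pure_noise_keeps_null_model(self, rng):
        y = rng.binomial(1, 0.4, size=300)
        cands = {f"n{i}": rng.normal(size=300) for i in range(3)}
        res = a.stepwise_bic(cands, y)
        assert res.selected == ()
        assert res.bic == pytest.approx(null_bic(y))

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            a.stepwise_bic({"only": np.arange(6.0)}, [0, 0, 0, 1, 1, 1])


class TestOddsMultiplier:
    def test_printed_worked_examples(self):
        assert a.odds_multiplier(0.994, -200) == pytest.approx(3.332, abs=0.001)
        assert a.odds_multiplier(1.0, 57) == 1.0
        assert a.odds_multiplier(1.298, 14) == pytest.approx(38.5, abs=0.1)

    def test_additivity_in_delta(self):
        orr = 1.298
        assert a.odds_multiplier(orr, 5 + 9) == pytest.approx(
            a.odds_multiplier(orr, 5) * a.odds_multiplier(orr, 9)
        )

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            a.odds_multiplier(0.0, 1.0)


class TestSummarizeCohort:
    def test_quartile_convention(self):
        rows = [make_params(f"p{i}", a.CASE, alarms=i) for i in (1, 2, 3, 4)]
        df = a.summarize_cohort(rows, parameters=["total_alarms"])
        r = df.iloc[0]
        assert r["median"] == 2.5
        assert r["iqr"] == pytest.approx(1.5)

    def test_identical_weeks_have_zero_spread(self):
        rows = [make_params(f"p{i}", a.CASE) for i in range(5)]
        df = a.summarize_cohort(rows, parameters=["total_alarms", "mean_netUF_lastfill"])
        assert (df["sd"] == 0).all()
        assert (df["iqr"] == 0).all()

    def test_absent_values_excluded_pairwise(self):
        rows = [make_params("p1", a.CONTROL, absent_lastfill=True)] + [
            make_params(f"p{i}", a.CONTROL) for i in (2, 3)
        ]
        df = a.summarize_cohort(rows, parameters=["mean_netUF_lastfill", "total_alarms"])
        by_param = df.set_index("parameter")["n"]
        assert by_param["mean_netUF_lastfill"] == 2
        assert by_param["total_alarms"] == 3

    def test_case_mean_alarms_near_printed_value(self, default_config):
        import dataclasses

        big = dataclasses.replace(default_config, n_cases=4000, n_controls=1, seed=3)
        params_list = a.derive_cohort(a.sample_cohort(big))
        df = a.summarize_cohort(params_list, parameters=["total_alarms"])
        case_mean = df[df["group"] == a.CASE]["mean"].iloc[0]
        assert case_mean == pytest.approx(19.3, abs=3 * 16.5 / math.sqrt(4000) + 0.5)
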