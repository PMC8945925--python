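"""Diagnostic metrics, group tests, survival machinery and cutoff search."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metpet import (
    TwoByTwo,
    chi_square,
    confusion_metrics,
    cox_fit,
    disease_control_rate,
    km_fit,
    log_rank,
    logistic_fit,
    mann_whitney,
    odds_ratio,
    optimal_cutoff,
    roc_cutoff,
    spearman,
)

STUDY_TABLE = TwoByTwo(tp=20, fn=4, fp=1, tn=5)  # MR vs nPD classification counts


class TestConfusionMetrics:
    def test_study_table_reproduces_published_percentages(self):
        m = confusion_metrics(STUDY_TABLE)
        assert m["sensitivity"] == pytest.approx(100 * 20 / 24)
        assert m["specificity"] == pytest.approx(100 * 5 / 6)
        assert m["ppv"] == pytest.approx(100 * 20 / 21)
        assert m["npv"] == pytest.approx(100 * 5 / 9)
        assert m["accuracy"] == pytest.approx(100 * 25 / 30)
        # whole-percent rounding: 83/83/95/56/83
        assert [round(m[k]) for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")] \
            == [83, 83, 95, 56, 83]

    def test_perfect_classifier_is_all_100(self):
        m = confusion_metrics(TwoByTwo(7, 0, 0, 3))
        assert all(v == 100.0 for v in m.values())

    def test_empty_margin_reported_as_undefined(self):
        m = confusion_metrics(TwoByTwo(0, 0, 1, 1))
        assert m["sensitivity"] is None
        assert m["specificity"] is not None

    def test_agrees_with_direct_enumeration_from_labels(self):
        rng = np.random.default_rng(1)
        test = rng.uniform(size=40) < 0.5
        cond = rng.uniform(size=40) < 0.6
        t = TwoByTwo.from_labels(test, cond)
        m = confusion_metrics(t)
        assert m["accuracy"] == pytest.approx(100 * np.mean(test == cond))


class TestOddsRatio:
    def test_study_table_or_and_woolf_ci(self):
        r = odds_ratio(STUDY_TABLE)
        assert r["or"] == pytest.approx(25.0)
        assert r["ci_low"] == pytest.approx(2.27, abs=0.01)
        assert r["ci_high"] == pytest.approx(276, rel=0.005)

    def test_uniform_table_is_one(self):
        assert odds_ratio(TwoByTwo(1, 1, 1, 1))["or"] == pytest.approx(1.0)

    def test_label_swap_inverts(self):
        direct = odds_ratio(STUDY_TABLE)["or"]
        swapped = odds_ratio(TwoByTwo(1, 5, 20, 4))["or"]
        assert swapped == pytest.approx(1 / direct)

    def test_zero_cell_requires_haldane(self):
        t = TwoByTwo(5, 0, 2, 3)
        with pytest.raises(ValueError):
            odds_ratio(t)
        assert odds_ratio(t, haldane=True)["or"] > 1


class TestDiseaseControlRate:
    def test_study_value(self):
        labels = ["nPD"] * 24 + ["PD"] * 6
        assert disease_control_rate(labels) == pytest.approx(80.0)

    @pytest.mark.parametrize("labels,expected", [(["nPD"] * 4, 100.0), (["PD"] * 3, 0.0)])
    def test_degenerate_cohorts(self, labels, expected):
        assert disease_control_rate(labels) == expected


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r["U"] == 0.0

    def test_identical_groups_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["p"] == pytest.approx(1.0)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            mann_whitney(rng.normal(size=50), rng.normal(size=50))["p"] < 0.05
            for _ in range(400)
        )
        # binomial(400, 0.05): 3 sigma band around 20
        assert abs(rejections - 20) <= 3 * math.sqrt(400 * 0.05 * 0.95)


class TestChiSquare:
    def test_proportional_table_is_null(self):
        r = chi_square(TwoByTwo(10, 10, 20, 20))
        assert r["method"] == "chi2"
        assert r["statistic"] == pytest.approx(0.0)
        assert r["p"] == pytest.approx(1.0)

    def test_small_expected_counts_switch_to_fisher(self):
        r = chi_square(STUDY_TABLE)
        assert r["method"] == "fisher"

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        r = chi_square(STUDY_TABLE)
        # enumerate all tables with the same margins; two-sided Fisher p sums
        # the probabilities of tables no more likely than the observed one
        a, b, c, d = 20, 4, 1, 5
        row1, col1, n = a + b, a + c, a + b + c + d
        probs = {
            x: sps.hypergeom.pmf(x, n, row1, col1)
            for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        }
        p_obs = probs[a]
        p_exact = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert r["p"] == pytest.approx(p_exact, rel=1e-6)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)["rho"] == pytest.approx(1.0)
        assert spearman(x, -x)["rho"] == pytest.approx(-1.0)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        times = np.arange(1.0, 11.0)
        fit = km_fit(times, np.ones(10, bool))
        assert fit.median_months == pytest.approx(5.0)
        for t, s in [(1, 0.9), (5, 0.5), (9, 0.1)]:
            assert fit.survival_at(t) == pytest.approx(s)

    def test_all_censored_median_undefined(self):
        fit = km_fit([3.0, 5.0, 8.0], [False, False, False])
        assert math.isinf(fit.median_months)

    def test_exponential_median_recovered(self):
        rng = np.random.default_rng(3)
        lam = math.log(2) / 12.0
        times = rng.exponential(1 / lam, 1000)
        fit = km_fit(times, np.ones(1000, bool))
        assert fit.median_months == pytest.approx(12.0, rel=0.1)
        assert fit.median_ci[0] < 12.0 < fit.median_ci[1]


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.arange(1.0, 21.0)
        e = np.ones(20, bool)
        r = log_rank(t, e, t, e)
        assert r["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert r["p"] == pytest.approx(1.0)

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(5)
        a = rng.exponential(20.0, 100)
        b = rng.exponential(4.0, 100)
        e = np.ones(100, bool)
        assert log_rank(a, e, b, e)["p"] < 1e-6

    def test_matches_independent_implementation(self):
        # cross-check against scikit-survival's log-rank
        from sksurv.compare import compare_survival

        rng = np.random.default_rng(11)
        t = np.concatenate([rng.exponential(10, 40), rng.exponential(6, 40)])
        e = rng.uniform(size=80) < 0.8
        grp = np.repeat([0, 1], 40)
        ours = log_rank(t[:40], e[:40], t[40:], e[40:])
        y = np.array(list(zip(e, t)), dtype=[("event", bool), ("time", float)])
        chi2, p = compare_survival(y, grp)
        assert ours["statistic"] == pytest.approx(chi2, rel=1e-6)
        assert ours["p"] == pytest.approx(p, rel=1e-6)


def exhaustive_cutoff(values, times, events, min_group_fraction=0.15):
    """Independent oracle: evaluate every distinct observed value meeting the
    group floor and return (cutoff, p) minimizing p, ties to the candidate
    closest to the median."""
    v = np.asarray(values, float)
    med = np.median(v)
    best = None
    for c in np.unique(v):
        low = v < c
        if low.sum() < min_group_fraction * v.size or (~low).sum() < min_group_fraction * v.size:
            continue
        p = log_rank(np.asarray(times)[low], np.asarray(events)[low],
                     np.asarray(times)[~low], np.asarray(events)[~low])["p"]
        key = (p, abs(c - med))
        if best is None or key < best[0]:
            best = (key, c, p)
    assert best is not None
    return best[1], best[2]


class TestOptimalCutoff:
    def _cohort(self, seed, n=60):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 12, n)
        lam = math.log(2) / 15.0 * np.where(vals >= 6.0, 5.0, 1.0)
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 33, n)
        return vals, np.minimum(t_event, t_cens), t_event <= t_cens

    def test_two_distinct_values_single_candidate(self):
        v = [1.0] * 10 + [2.0] * 10
        t = np.arange(1.0, 21.0)
        res = optimal_cutoff(v, t, np.ones(20, bool))
        assert res.cutoff == 2.0
        assert res.n_low == 10 and res.n_high == 10

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_search(self, seed):
        v, t, e = self._cohort(seed)
        res = optimal_cutoff(v, t, e)
        c, p = exhaustive_cutoff(v, t, e)
        assert res.cutoff == pytest.approx(c)
        assert res.p == pytest.approx(p)

    def test_recovers_planted_change_point(self):
        v, t, e = self._cohort(123, n=200)
        res = optimal_cutoff(v, t, e)
        assert abs(res.cutoff - 6.0) < 1.0

    def test_group_floor_violation_raises(self):
        v = [1.0] * 19 + [2.0]
        t = np.arange(1.0, 21.0)
        with pytest.raises(ValueError):
            optimal_cutoff(v, t, np.ones(20, bool), min_group_fraction=0.15)

    def test_trace_covers_all_distinct_values(self):
        v, t, e = self._cohort(2)
        res = optimal_cutoff(v, t, e)
        assert len(res.trace) == np.unique(v).size


class TestCoxFit:
    def test_single_binary_covariate_recovery(self):
        rng = np.random.default_rng(21)
        n, beta = 500, math.log(4.85)
        x = rng.uniform(size=n) < 0.5
        lam = math.log(2) / 15.0 * np.exp(beta * x)
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 33, n)
        df = pd.DataFrame({"x": x.astype(float)})
        fit = cox_fit(df, np.minimum(t_event, t_cens), t_event <= t_cens)
        assert abs(fit.loc["x", "coef"] - beta) < 3 * fit.loc["x", "se"]

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"x": np.ones(20)})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, np.arange(1.0, 21.0), np.ones(20, bool))

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0) % 2, "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, np.arange(1.0, 11.0), [True] + [False] * 9)


class TestLogisticFit:
    def test_reproduces_crude_or_on_study_table(self):
        # single binary covariate: MR status; outcome: nPD at 3 months
        x = np.array([1.0] * 21 + [0.0] * 9)
        y = np.array([True] * 20 + [False] * 1 + [True] * 4 + [False] * 5)
        fit = logistic_fit(pd.DataFrame({"mr": x}), y)
        assert fit.loc["mr", "or"] == pytest.approx(25.0, rel=1e-4)
        assert fit.loc["mr", "ci_low"] == pytest.approx(2.27, abs=0.01)
        assert fit.loc["mr", "ci_high"] == pytest.approx(276, rel=0.005)

    def test_perfect_separation_is_an_error(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = x > 0.5
        with pytest.raises(RuntimeError):
            logistic_fit(pd.DataFrame({"x": x}), y)


class TestRocCutoff:
    def test_perfect_separation_auc_one(self):
        s = np.concatenate([np.zeros(10), np.ones(10)])
        r = roc_cutoff(s, s > 0.5)
        assert r["auc"] == 1.0

    def test_independent_scores_auc_half(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(size=4000)
        y = rng.uniform(size=4000) < 0.5
        assert roc_cutoff(s, y)["auc"] == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_u_statistic_identity(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=60)
        y = rng.uniform(size=60) < 0.4
        auc = roc_cutoff(s, y)["auc"]
        u = sps.mannwhitneyu(s[y], s[~y], alternative="two-sided").statistic
        assert auc == pytest.approx(u / (y.sum() * (~y).sum()))
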