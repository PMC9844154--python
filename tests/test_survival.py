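"""Kaplan-Meier, log-rank, Cox regression, and rank/count statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radtiles.survival import (
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    rank_and_count_stats,
    response_comparison,
)


def frame(times, events, group=None):
    d = {"time_months": times, "event": events}
    if group is not None:
        d["g"] = group
    return pd.DataFrame(d)


def km_direct(times, events):
    """Independent product-limit computation by direct counting."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    out = {}
    s = 1.0
    for t in sorted(set(times)):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        if d:
            s *= 1 - d / at_risk
        out[t] = s
    return out


def logrank_direct(df, group_col):
    """Independent two-group log-rank by direct O-E counting."""
    times = df["time_months"].to_numpy()
    events = df["event"].to_numpy()
    g = (df[group_col] == sorted(df[group_col].unique())[1]).to_numpy()
    O_minus_E, V = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & g).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V if V > 0 else 0.0


class TestKM:
    def test_product_limit_by_hand(self):
        fit = km_estimate(frame([1, 2, 3, 4], [1, 1, 1, 1]))
        g = fit.groups["all"]
        assert g.survival.loc[2.0, "estimate"] == pytest.approx(0.5)
        assert g.median == pytest.approx(2.0)

    def test_no_censoring_equals_empirical(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 40).round(2)
        fit = km_estimate(frame(t, np.ones(40, int)))
        direct = km_direct(t, np.ones(40, int))
        surv = fit.groups["all"].survival
        for tt, s in direct.items():
            assert surv.loc[tt, "estimate"] == pytest.approx(s)

    def test_all_censored_not_reached(self):
        fit = km_estimate(frame([1, 2, 3], [0, 0, 0]))
        g = fit.groups["all"]
        assert (g.survival["estimate"] == 1.0).all()
        assert not g.median_reached

    def test_km_nonincreasing_starts_at_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        surv = km_estimate(frame(t, e)).groups["all"].survival["estimate"]
        assert surv.iloc[0] == 1.0
        assert (np.diff(surv.to_numpy()) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        df = frame(t + t, e + e, group=[0] * 4 + [1] * 4)
        stat, p = logrank_test(df, "g")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_counting_on_exhaustive_small_sets(self):
        # all event/censor patterns for 6 subjects, 3 per arm, distinct times
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        group = [0, 1, 0, 1, 0, 1]
        for pattern in itertools.product([0, 1], repeat=6):
            if sum(pattern) == 0:
                continue
            df = frame(times, list(pattern), group)
            stat, _ = logrank_test(df, "g")
            assert stat == pytest.approx(logrank_direct(df, "g"), abs=1e-8)

    def test_power_against_true_hazard_ratio(self):
        rng = np.random.default_rng(2)
        rejected = 0
        reps = 20
        for _ in range(reps):
            n = 500
            g = np.repeat([0, 1], n)
            t = rng.exponential(1 / (0.2 * np.exp(np.log(2.0) * g)))
            df = frame(t, np.ones(2 * n, int), g)
            if logrank_test(df, "g")[1] < 0.05:
                rejected += 1
        assert rejected >= int(0.95 * reps)


class TestCox:
    def test_score_test_equals_logrank_no_ties(self):
        rng = np.random.default_rng(3)
        n = 60
        g = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.3 * np.exp(-0.5 * g)))  # continuous: no ties
        df = frame(t, np.ones(n, int), g)
        stat, _ = logrank_test(df, "g")
        assert cox_score_test(df, "g") == pytest.approx(stat, abs=1e-8)

    def test_breslow_matches_efron_without_ties(self):
        rng = np.random.default_rng(4)
        n = 120
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.3 * np.exp(-0.6 * g)))
        df = frame(t, np.ones(n, int), g)
        efron = cox_fit(df, ["g"]).cox_table["coef"].iloc[0]
        breslow = cox_fit(df, ["g"], ties="breslow").cox_table["coef"].iloc[0]
        assert breslow == pytest.approx(efron, abs=1e-6)

    def test_consistency_at_known_log_hazard(self):
        rng = np.random.default_rng(5)
        n = 1000
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.25 * np.exp(-0.4 * g)))
        c = rng.exponential(40, n)
        df = frame(np.minimum(t, c), (t <= c).astype(int), g)
        coef = cox_fit(df, ["g"]).cox_table["coef"].iloc[0]
        assert coef == pytest.approx(-0.4, abs=0.15)

    def test_univariate_entry_rule_strict(self):
        rng = np.random.default_rng(6)
        n = 300
        strong = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=n)
        t = rng.exponential(1 / (0.3 * np.exp(-0.8 * strong)))
        df = frame(t, np.ones(n, int))
        df["strong"] = strong
        df["noise"] = noise
        fit = cox_fit(df, ["strong", "noise"], mode="multivariate")
        tab = fit.cox_table
        uni = tab[tab["mode"] == "univariate"]
        entered = tab.attrs["entered_multivariate"]
        for cov in ["strong", "noise"]:
            assert (cov in entered) == (uni.loc[cov, "p"] < 0.05)
        # the noise covariate should essentially never enter
        assert "strong" in entered

    def test_too_few_events_raises(self):
        df = frame([1.0, 2.0, 3.0], [0, 0, 0])
        df["x"] = [0.0, 1.0, 2.0]
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])

    def test_categorical_covariate_one_hot(self):
        rng = np.random.default_rng(7)
        n = 200
        smoke = rng.choice(["never", "former", "current"], n)
        t = rng.exponential(4, n)
        df = frame(t, np.ones(n, int))
        df["smoking"] = smoke
        tab = cox_fit(df, ["smoking"]).cox_table
        assert set(tab.index) == {"smoking[former]", "smoking[never]"}


class TestRankAndCount:
    def test_spearman_identity(self):
        x = np.arange(20.0)
        out = rank_and_count_stats(x=x, y=x)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_spearman_constant_flagged(self):
        out = rank_and_count_stats(x=np.ones(10), y=np.arange(10.0))
        assert np.isnan(out["spearman_rho"])
        assert "constant" in out["spearman_flag"]

    def test_fisher_diagonal_table(self):
        from math import comb

        out = rank_and_count_stats(table=np.array([[10, 0], [0, 10]]))
        assert out["fisher_p"] == pytest.approx(2 / comb(20, 10))
        assert np.isinf(out["odds_ratio_sample"])
        assert "zero cell" in out["odds_ratio_flag"]

    def test_fisher_or_consistency(self):
        out = rank_and_count_stats(table=np.array([[12, 5], [6, 14]]))
        assert out["odds_ratio_sample"] == pytest.approx(12 * 14 / (5 * 6))
        assert out["odds_ratio_cmle"] > 1

    def test_wilcoxon_identical_groups(self):
        x = np.arange(30.0)
        out = rank_and_count_stats(x=x, y=x.copy())
        assert out["wilcoxon_p"] > 0.95

    def test_fisher_rejects_bad_table(self):
        with pytest.raises(ValueError):
            rank_and_count_stats(table=np.array([[1.5, 2], [3, 4]]))


class TestResponseComparison:
    def _scores(self, shift):
        rng = np.random.default_rng(8)
        cats = ["responder"] * 20 + ["stable"] * 20 + ["progressive"] * 20
        vals = np.concatenate(
            [rng.normal(shift, 1, 20), rng.normal(shift / 2, 1, 20), rng.normal(0, 1, 20)]
        )
        return pd.Series(vals), pd.Series(cats)

    def test_exactly_two_comparisons(self):
        s, c = self._scores(0.0)
        out = response_comparison(s, c)
        assert set(out) == {"responder_vs_progressive", "stable_vs_progressive"}

    def test_shifted_scores_significant(self):
        s, c = self._scores(3.0)
        out = response_comparison(s, c)
        assert out["responder_vs_progressive"] < 0.001

    def test_empty_category_skipped(self):
        s = pd.Series(np.arange(10.0))
        c = pd.Series(["responder"] * 5 + ["progressive"] * 5)
        out = response_comparison(s, c)
        assert out["stable_vs_progressive"] is None


def test_permutation_p_values_uniform_under_null():
    """Permuting group labels yields a uniform log-rank p distribution."""
    rng = np.random.default_rng(9)
    n = 60
    t = rng.exponential(5, n)
    e = np.ones(n, int)
    ps = []
    for _ in range(200):
        g = rng.permutation(np.repeat([0, 1], n // 2))
        ps.append(logrank_test(frame(t, e, g), "g")[1])
    from scipy import stats as sps

    assert sps.kstest(ps, "uniform").pvalue > 0.01
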