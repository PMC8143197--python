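"""Survival and seeding statistics against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from tautrace import (
    anova_line_by_dose,
    auc_trapezoid,
    cox_fit,
    cox_score_test,
    cumulative_onset,
    km_estimate,
    log_rank,
)
from tautrace.detect import SeedCountSeries
from tautrace.survival import (
    aggregate_fraction_at,
    early_aggregator_groups,
    onset_expression_correlation,
    post_onset_records,
    seeding_slope,
)


def hand_product_limit(times, events):
    """Independent product-limit: explicit risk-set loop."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in np.unique(times[events]):
        n = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1 - d / n
        out[t] = s
    return out


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = km_estimate([5, 6, 7], [False, False, False])
        assert np.allclose(km.survival, 1.0)

    def test_hand_product_limit_four_records(self):
        # events at t=1 (n=4) and t=3 (n=2), censor at t=2
        km = km_estimate([1, 2, 3, 4], [True, False, True, False])
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(3) == pytest.approx(0.375)

    def test_uncensored_km_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 200).round(1)
        km = km_estimate(t, np.ones(200, bool))
        for q in km.times:
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_hand_loop_on_random_censored_data(self, rng):
        t = rng.integers(1, 15, 30).astype(float)
        e = rng.random(30) < 0.7
        km = km_estimate(t, e)
        for q, s in hand_product_limit(t, e).items():
            assert km.survival_at(q) == pytest.approx(s)

    def test_band_brackets_estimate(self, rng):
        t = rng.exponential(10, 50)
        km = km_estimate(t, np.ones(50, bool))
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.ci_upper >= km.survival - 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        res = log_rank(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computed_o_minus_e_table(self):
        # 10 records; O-E and V computed by explicit risk-table arithmetic
        ta, ea = [1, 3, 5, 7, 9], [True, True, False, True, True]
        tb, eb = [2, 4, 6, 8, 10], [True, False, True, True, False]
        time = np.r_[ta, tb].astype(float)
        event = np.r_[ea, eb]
        group = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        o_minus_e = v = 0.0
        for t in np.unique(time[event]):
            n = (time >= t).sum()
            n1 = (time[group] >= t).sum()
            d = ((time == t) & event).sum()
            d1 = ((time == t) & event & group).sum()
            o_minus_e += d1 - d * n1 / n
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / max(n - 1, 1)
        expected = o_minus_e**2 / v
        res = log_rank(ta, ea, tb, eb)
        assert res.chi_square == pytest.approx(expected)

    def test_agrees_with_lifelines(self, rng):
        ta = rng.exponential(8, 25)
        tb = rng.exponential(14, 30)
        ea = rng.random(25) < 0.8
        eb = rng.random(30) < 0.8
        ours = log_rank(ta, ea, tb, eb)
        theirs = logrank_test(ta, tb, ea, eb)
        assert ours.chi_square == pytest.approx(theirs.test_statistic)
        assert ours.p == pytest.approx(theirs.p_value)

    def test_permutation_p_close_to_asymptotic(self, rng):
        ta = rng.exponential(8, 16)
        tb = rng.exponential(13, 18)
        res = log_rank(
            ta, np.ones(16, bool), tb, np.ones(18, bool),
            permutations=4000, rng=2,
        )
        assert abs(res.p - res.p_permutation) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([], [], [1.0], [True])


class TestCox:
    def _two_group(self, rng, hr=2.5, n=150, censor_scale=None):
        t1 = rng.exponential(1.0, n)
        t2 = rng.exponential(1.0 / hr, n)
        t = np.r_[t1, t2]
        g = np.r_[np.zeros(n), np.ones(n)]
        if censor_scale:
            c = rng.exponential(censor_scale, 2 * n)
            return pd.DataFrame(
                dict(time_h=np.minimum(t, c), event=(t <= c).astype(int), grp=g)
            )
        return pd.DataFrame(dict(time_h=t, event=1, grp=g))

    def test_null_covariate_ci_covers_zero(self, rng):
        df = self._two_group(rng, hr=1.0, n=200)
        res = cox_fit(df, covariates=["grp"])
        assert res.summary.loc["grp", "ci_lower"] < 0 < res.summary.loc[
            "grp", "ci_upper"
        ]

    def test_recovers_known_hazard_ratio(self, rng):
        logs = [
            cox_fit(self._two_group(rng, hr=2.5, n=300), covariates=["grp"]).coef("grp")
            for _ in range(5)
        ]
        assert np.mean(logs) == pytest.approx(np.log(2.5), abs=0.15)

    def test_hazard_ratio_is_exp_of_coefficient(self, rng):
        res = cox_fit(self._two_group(rng, n=100), covariates=["grp"])
        assert res.hazard_ratio("grp") == pytest.approx(
            np.exp(res.coef("grp"))
        )

    def test_score_test_equals_log_rank_without_ties(self, rng):
        df = self._two_group(rng, hr=1.8, n=60, censor_scale=2.0)
        chi2, p = cox_score_test(df["time_h"], df["event"] == 1, df["grp"] == 1)
        a = df[df["grp"] == 1]
        b = df[df["grp"] == 0]
        lr = log_rank(a["time_h"], a["event"] == 1, b["time_h"], b["event"] == 1)
        assert chi2 == pytest.approx(lr.chi_square, rel=1e-10)

    def test_breslow_flag_not_available(self, rng):
        with pytest.raises(NotImplementedError):
            cox_fit(self._two_group(rng), ties_method="breslow")


class TestOnsetCurves:
    def _df(self, onset, time, event, line="control"):
        return pd.DataFrame(
            dict(onset_h=onset, time_h=time, event=event, line=line)
        )

    def test_no_onsets_flat_zero(self):
        df = self._df([np.nan] * 3, [10.0, 20.0, 30.0], [True, False, True])
        curve = cumulative_onset(df)
        assert (curve["cumulative_incidence"] == 0).all()

    def test_synchronous_onset_steps_to_one(self):
        df = self._df([10.0] * 4, [30.0] * 4, [False] * 4)
        curve = cumulative_onset(df)
        assert curve["cumulative_incidence"].iloc[-1] == pytest.approx(1.0)

    def test_post_onset_clock_durations(self):
        df = self._df([10.0, np.nan], [30.0, 40.0], [True, False])
        rec = post_onset_records(df)
        assert len(rec) == 1 and rec["time_h"].iloc[0] == 20.0

    def test_early_aggregator_split_respects_observability(self):
        df = self._df(
            [20.0, 60.0, np.nan, np.nan],
            [100.0, 100.0, 30.0, 100.0],
            [True, False, False, False],
        )
        early, others = early_aggregator_groups(df, cutoff_h=48.0)
        assert len(early) == 1  # onset at 20 h
        assert len(others) == 2  # late onset + survivor; censored-at-30 dropped


class TestAggregateFraction:
    def test_zero_onset_hazard_gives_zero_fractions(self):
        df = pd.DataFrame(
            dict(
                onset_h=[np.nan] * 8,
                time_h=[168.0] * 8,
                event=[False] * 8,
                line=["control"] * 4 + ["mutant"] * 4,
                replicate=[0, 0, 1, 1] * 2,
            )
        )
        fracs, tests = aggregate_fraction_at(df, (48.0, 168.0))
        assert (fracs["fraction"] == 0).all()

    def test_known_fractions_recovered(self):
        rows = []
        for rep in range(2):
            for i in range(10):
                rows.append(
                    dict(
                        onset_h=24.0 if i < 3 else np.nan, time_h=168.0,
                        event=False, line="control", replicate=rep,
                    )
                )
        fracs, _ = aggregate_fraction_at(pd.DataFrame(rows), (48.0,))
        assert np.allclose(fracs["fraction"], 0.3)


class TestSeedingAnalytics:
    def _series(self, counts, times=None, **kw):
        times = times if times is not None else np.arange(len(counts)) * 2.0
        return SeedCountSeries("w", times, counts, **kw)

    def test_auc_zero_series(self):
        assert auc_trapezoid(self._series([0.0, 0.0, 0.0])) == 0.0

    def test_auc_rectangle(self):
        s = self._series([2.0] * 6, times=np.linspace(0, 10, 6))
        assert auc_trapezoid(s) == pytest.approx(20.0)

    def test_auc_hand_trapezoid(self):
        s = self._series([0.0, 4.0, 8.0], times=[0.0, 2.0, 4.0])
        assert auc_trapezoid(s) == pytest.approx(16.0)

    def test_auc_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid(self._series([1.0, 2.0], times=[4.0, 2.0]))

    def test_anova_matches_hand_sum_of_squares(self, rng):
        # balanced 2x3 design with 3 obs/cell: compare to direct SS sums
        rows = []
        for li, line in enumerate(("control", "mutant")):
            for di, dose in enumerate((1.0, 5.0, 10.0)):
                for r in range(3):
                    rows.append(
                        dict(line=line, dose_ug=dose,
                             auc=10 * di + 2 * li + rng.normal(0, 1.0))
                    )
        df = pd.DataFrame(rows)
        res = anova_line_by_dose(df)
        y = df["auc"].to_numpy()
        grand = y.mean()
        ss_line = sum(
            len(g) * (g["auc"].mean() - grand) ** 2
            for _, g in df.groupby("line")
        )
        ss_dose = sum(
            len(g) * (g["auc"].mean() - grand) ** 2
            for _, g in df.groupby("dose_ug")
        )
        ss_cells = sum(
            len(g) * (g["auc"].mean() - grand) ** 2
            for _, g in df.groupby(["line", "dose_ug"])
        )
        ss_int = ss_cells - ss_line - ss_dose
        ss_err = sum(
            ((g["auc"] - g["auc"].mean()) ** 2).sum()
            for _, g in df.groupby(["line", "dose_ug"])
        )
        f_line = (ss_line / 1) / (ss_err / 12)
        f_dose = (ss_dose / 2) / (ss_err / 12)
        f_int = (ss_int / 2) / (ss_err / 12)
        assert res.f("line") == pytest.approx(f_line)
        assert res.f("dose") == pytest.approx(f_dose)
        assert res.f("interaction") == pytest.approx(f_int)

    def test_anova_requires_replication(self):
        df = pd.DataFrame(
            dict(line=["control", "mutant"], dose_ug=[1.0, 1.0], auc=[1.0, 2.0])
        )
        with pytest.raises(ValueError):
            anova_line_by_dose(df)

    def test_constant_series_zero_slope(self):
        s = self._series([3.0] * 30, times=np.arange(30) * 2.0)
        s.line = "control"
        slopes, _ = seeding_slope([s])
        assert slopes["slope_per_h"].iloc[0] == pytest.approx(0.0)

    def test_linear_series_recovers_slope(self):
        t = np.arange(30) * 2.0
        s = self._series(3.0 * t, times=t)
        s.line = "control"
        slopes, _ = seeding_slope([s])
        assert slopes["slope_per_h"].iloc[0] == pytest.approx(3.0)


class TestExpressionCorrelation:
    def test_affine_relation_gives_r_one(self):
        df = pd.DataFrame(
            dict(
                t0_intensity_norm=np.linspace(0.5, 1.5, 20),
                onset_h=10 + 30 * np.linspace(0.5, 1.5, 20),
            )
        )
        out = onset_expression_correlation(df)
        assert out["r"] == pytest.approx(1.0)

    def test_ten_pair_fixture_matches_hand_formula(self, rng):
        x = rng.normal(1, 0.2, 10)
        y = rng.normal(50, 10, 10)
        df = pd.DataFrame(dict(t0_intensity_norm=x, onset_h=y))
        out = onset_expression_correlation(df)
        hand = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum())
            * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert out["r"] == pytest.approx(hand)
        assert out["r_squared"] == pytest.approx(hand**2)
        assert out["adjusted_r_squared"] == pytest.approx(
            1 - (1 - hand**2) * 9 / 8
        )

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(
            dict(t0_intensity_norm=[1.0] * 5, onset_h=[1, 2, 3, 4, 5.0])
        )
        with pytest.raises(ValueError):
            onset_expression_correlation(df)
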