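"""Speed bins, fits, contrasts, phase labelling and welfare states."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import finlogger as fl
from finlogger.errors import ChannelMissing


class TestAggregateSpeedBins:
    def test_hourly_steps_at_ten_minute_cadence_give_six_records_per_speed(self):
        times = np.arange(0, 300, 10.0)  # 5 one-hour steps
        records = pd.DataFrame({"time_min": times, "value": 0.0})
        schedule = fl.SpeedSchedule()
        out = fl.aggregate_speed_bins(records, schedule)
        counts = out.groupby("speed_mps")["value"].count()
        assert set(counts.index) == set(schedule.speeds)
        assert (counts == 6).all()
        # flush + acclimation minutes excluded from respirometry alignment
        per_speed = out.groupby("speed_mps")["in_respiro_window"].sum()
        assert (per_speed == 4).all()

    def test_empty_records_give_empty_bins(self):
        out = fl.aggregate_speed_bins(pd.DataFrame({"time_min": []}),
                                      fl.SpeedSchedule())
        assert len(out) == 0

    def test_out_of_schedule_records_are_unassigned(self):
        records = pd.DataFrame({"time_min": [-5.0, 100.0, 400.0]})
        out = fl.aggregate_speed_bins(records, fl.SpeedSchedule())
        assert list(out["assigned"]) == [False, True, False]

    def test_assignment_matches_constructed_truth(self, rng):
        schedule = fl.SpeedSchedule()
        truth_idx = rng.integers(0, 5, 40)
        times = truth_idx * 60 + rng.uniform(0, 60, 40)
        out = fl.aggregate_speed_bins(pd.DataFrame({"time_min": times}),
                                      schedule)
        expected = np.asarray(schedule.speeds)[truth_idx]
        assert np.allclose(out["speed_mps"], expected)


class TestFitSpeedResponse:
    def test_exact_exponential_recovered(self):
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        y = 12.0 * np.exp(1.8 * x)
        fit = fl.fit_speed_response(x, y, model="exponential")
        assert np.allclose(fit.coeffs, [12.0, 1.8], atol=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_channel_has_no_trend(self, rng):
        x = np.repeat([0.2, 0.4, 0.6, 0.8, 1.0], 4)
        y = 5.0 + rng.normal(0, 1e-9, x.size)
        fit = fl.fit_speed_response(x, y, model="polynomial", degree=1)
        assert abs(fit.coeffs[0]) < 1e-6
        assert abs(fit.r_squared) < 0.5

    def test_rise_above_uopt_is_monotone_at_high_speeds(self, rng):
        # channel flat below 0.74 m/s and rising above, as HR behaves
        x = np.repeat([0.2, 0.4, 0.6, 0.8, 1.0], 6)
        y = 62 + 40 * np.clip(x - 0.74, 0, None) ** 2 + rng.normal(0, 0.5,
                                                                   x.size)
        fit = fl.fit_speed_response(x, y, model="exponential")
        grid = np.linspace(0.8, 1.0, 20)
        curve = fit.coeffs[0] * np.exp(fit.coeffs[1] * grid)
        assert np.all(np.diff(curve) > 0)
        assert fit.r_squared > 0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            fl.fit_speed_response([1, 2, 3], [1, 2, 3], model="spline")


class TestCorrelationMatrix:
    def test_identity_and_anticorrelation(self):
        x = np.linspace(0, 1, 20)
        cm = fl.correlation_matrix(pd.DataFrame({"a": x, "b": x, "c": -x}))
        assert cm.r.loc["a", "b"] == pytest.approx(1.0)
        assert cm.r.loc["a", "c"] == pytest.approx(-1.0)
        assert cm.r2_signed.loc["a", "c"] == pytest.approx(-1.0)

    def test_symmetry_and_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        cm = fl.correlation_matrix(df)
        assert np.allclose(cm.r.values, cm.r.values.T)
        assert np.allclose(np.diag(cm.r.values), 1.0)

    def test_constant_column_flagged_undefined(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.full(10, 3.0)})
        cm = fl.correlation_matrix(df)
        assert "b" in cm.constant_columns
        assert np.isnan(cm.r.loc["a", "b"])
        assert not cm.significant.loc["a", "b"]

    def test_simulation_calibration_rho_075(self):
        rs = []
        for rep in range(300):
            rng = np.random.default_rng(rep)
            x = rng.multivariate_normal([0, 0], [[1, 0.75], [0.75, 1]], 60)
            cm = fl.correlation_matrix(pd.DataFrame(x, columns=["a", "b"]))
            rs.append(cm.r.loc["a", "b"])
        assert np.mean(rs) == pytest.approx(0.75, abs=0.03)


class TestPairwiseContrasts:
    def test_fixed_effects_path_matches_classical_tukey(self, rng):
        y = rng.normal(0, 1, 30) + np.repeat([0.0, 0.8, 1.6], 10)
        g = np.repeat(["a", "b", "c"], 10)
        ind = [f"i{k}" for k in range(30)]  # one obs per individual
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fl.pairwise_contrasts(y, g, ind)
        assert res.model_kind == "fixed"
        oracle = pairwise_tukeyhsd(y, g)
        assert np.allclose(np.sort(res.table["p_adj"]),
                           np.sort(oracle.pvalues), atol=1e-9)

    def test_repeated_measures_use_the_mixed_path(self, rng):
        n_ind = 8
        rows = []
        for i in range(n_ind):
            b = rng.normal(0, 2)
            for g, shift in (("a", 0.0), ("b", 3.0)):
                rows.append((b + shift + rng.normal(0, 0.5), g, f"i{i}"))
        y, g, ind = map(np.array, zip(*rows))
        res = fl.pairwise_contrasts(y, g, ind)
        assert res.model_kind == "mixed"
        assert res.table["p_adj"].iloc[0] < 0.01

    def test_single_individual_falls_back_with_warning(self, rng):
        y = rng.normal(0, 1, 12)
        g = np.repeat(["a", "b", "c"], 4)
        with pytest.warns(UserWarning, match="fixed effects"):
            res = fl.pairwise_contrasts(y, g, ["only_fish"] * 12)
        assert res.model_kind == "fixed"

    def test_detects_large_within_individual_shift(self, rng):
        rows = []
        for i in range(10):
            b = rng.normal(0, 1)
            rows.append((b + rng.normal(0, 1), "a", f"i{i}"))
            rows.append((b + 10 + rng.normal(0, 1), "b", f"i{i}"))
        y, g, ind = map(np.array, zip(*rows))
        res = fl.pairwise_contrasts(y, g, ind)
        assert res.table["p_adj"].iloc[0] < 1e-4


class TestCompactLetters:
    def test_all_equal_groups_share_a_letter(self):
        p = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        letters = fl.compact_letters(p)
        assert len(set(letters.values())) == 1

    def test_separated_group_gets_its_own_letter(self):
        groups = list("abc")
        p = pd.DataFrame(np.ones((3, 3)), index=groups, columns=groups)
        p.loc["a", "c"] = p.loc["c", "a"] = 0.001
        letters = fl.compact_letters(p)
        assert set(letters["a"]) != set(letters["c"])
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])


class TestPhaseLabelling:
    def test_measurement_on_the_hour_is_its_stress_phase(self):
        schedule = fl.CrowdingSchedule()
        labels = fl.label_crowding_phases([11 * 60.0], schedule)
        assert labels[0] == "stress_2"

    def test_ten_minute_cadence_gives_five_recovery_points_per_event(self):
        schedule = fl.CrowdingSchedule()
        times = np.arange(9 * 60.0, 17 * 60.0 + 1, 10.0)
        labels = list(fl.label_crowding_phases(times, schedule))
        for k in range(1, 5):
            assert labels.count(f"stress_{k}") == 1
            assert labels.count(f"recovery_{k}") == 5

    def test_empty_schedule_labels_everything_basal(self):
        labels = fl.label_crowding_phases([0.0, 500.0, 900.0], None)
        assert set(labels) == {"basal"}

    def test_gap_after_last_event_is_uncategorized(self):
        schedule = fl.CrowdingSchedule()
        labels = fl.label_crowding_phases([14 * 60.0 + 10], schedule)
        assert labels[0] == "uncategorized"

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=24 * 60.0,
                     allow_nan=False))
    def test_every_time_gets_exactly_one_label(self, t):
        schedule = fl.CrowdingSchedule()
        label = fl.label_crowding_phases([t], schedule)[0]
        valid = {"basal", "final_rec", "uncategorized"} | \
            {f"stress_{k}" for k in range(1, 5)} | \
            {f"recovery_{k}" for k in range(1, 5)}
        assert label in valid


@pytest.fixture(scope="module")
def session_summaries():
    session, truth = fl.generate_crowding_session(seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summaries = fl.phase_summaries(session.records, session.schedule)
    return session, truth, summaries


class TestPhaseSummaries:

    def test_stress_heart_rate_is_monotone_increasing(self, session_summaries):
        _, _, summaries = session_summaries
        hr = summaries["hr_bpm"].set_index("phase")["mean"]
        stress = [hr[f"stress_{k}"] for k in range(1, 5)]
        assert all(a < b for a, b in zip(stress, stress[1:]))

    def test_acc_freezing_pattern_at_fourth_stressor(self, session_summaries):
        _, _, summaries = session_summaries
        acc = summaries["acc_mg"].set_index("phase")["mean"]
        assert all(acc["stress_4"] < acc[f"stress_{k}"] for k in (1, 2, 3))

    def test_recovery_acc_returns_to_basal(self, session_summaries):
        _, _, summaries = session_summaries
        acc = summaries["acc_mg"].set_index("phase")
        basal_m, basal_se = acc.loc["basal", "mean"], acc.loc["basal", "se"]
        for k in range(1, 5):
            m = acc.loc[f"recovery_{k}", "mean"]
            se = acc.loc[f"recovery_{k}", "se"]
            assert abs(m - basal_m) < 2 * np.hypot(se, basal_se)

    def test_heart_rate_stays_elevated_after_the_challenge(self,
                                                           session_summaries):
        _, _, summaries = session_summaries
        hr = summaries["hr_bpm"].set_index("phase")
        assert hr.loc["final_rec", "mean"] > hr.loc["basal", "mean"]
        assert hr.loc["final_rec", "letters"] != hr.loc["basal", "letters"]

    def test_constant_channels_share_one_letter_group(self):
        times = np.arange(9 * 60.0, 17 * 60.0 + 1, 10.0)
        rows = []
        for ind in range(4):
            for t in times:
                rows.append((t, f"i{ind}", "hr_bpm", 60.0 + 0.01 * ind))
        records = pd.DataFrame(rows, columns=["time_min", "individual",
                                              "channel", "value"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summaries = fl.phase_summaries(records, fl.CrowdingSchedule())
        assert summaries["hr_bpm"]["letters"].nunique() == 1


class TestWelfareClassifier:
    @pytest.mark.parametrize("hr, acc, amp, expected", [
        (0.0, 1.0, 1.0, fl.WelfareState.RESTING),
        (0.0, 3.0, 1.0, fl.WelfareState.REGULAR_ACTIVITY),
        (3.0, 1.0, 1.0, fl.WelfareState.REACTIVE_RESPONSE),
        (3.0, 3.0, 3.0, fl.WelfareState.PROACTIVE_RESPONSE),
    ])
    def test_canonical_corners(self, hr, acc, amp, expected):
        assert fl.classify_welfare_state(hr, acc, amp).state == expected

    def test_missing_channel_names_it(self):
        with pytest.raises(ChannelMissing, match="acc_rel"):
            fl.classify_welfare_state(0.0, np.nan, 1.0)

    def test_timeline_requires_all_channels(self):
        with pytest.raises(ChannelMissing, match="amp_rel"):
            fl.classify_welfare_timeline(pd.DataFrame({"hr_rel": [0.0],
                                                       "acc_rel": [1.0]}))

    @settings(deadline=None, max_examples=200)
    @given(st.floats(-5, 5, allow_nan=False),
           st.floats(-5, 5, allow_nan=False),
           st.floats(-5, 5, allow_nan=False))
    def test_total_and_deterministic_with_scores_in_range(self, hr, acc, amp):
        c1 = fl.classify_welfare_state(hr, acc, amp)
        c2 = fl.classify_welfare_state(hr, acc, amp)
        assert c1.state == c2.state
        assert 0.0 < c1.score <= 1.0

    def test_order_invariance_of_timeline(self, rng):
        df = pd.DataFrame({"hr_rel": rng.uniform(-3, 5, 30),
                           "acc_rel": rng.uniform(0, 5, 30),
                           "amp_rel": rng.uniform(0, 5, 30)})
        fwd = fl.classify_welfare_timeline(df)
        perm = rng.permutation(30)
        rev = fl.classify_welfare_timeline(df.iloc[perm]).sort_index()
        assert list(fwd["state"]) == list(rev["state"])
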