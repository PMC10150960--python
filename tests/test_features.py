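"""Event-representation oracles: hand-computable examples, moment-statistic
brute-force agreement, missingness contracts, and the no-look-ahead property."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypocause.diary import (
    CarbIntake,
    Category,
    Diary,
    GlucoseReading,
    HypoEpisode,
    InsulinDose,
    InsulinKind,
    QuizAnswer,
    AdvisorRecord,
    SubjectProfile,
)
from hypocause.features import (
    EXTRA_FEATURES,
    FEATURE_REGISTRY,
    WindowConfig,
    advisor_features,
    compute_baselines,
    featurize_cohort,
    interp_bg_features,
    intake_context_features,
    longterm_signal_stats,
    neighbor_bg_features,
    quiz_engagement_features,
    represent_event,
    temporal_features,
)

T0 = datetime(2019, 6, 14, 18, 0)  # a Friday, 18:00


def _diary(**kwargs) -> Diary:
    profile = SubjectProfile("S000", age=45.0, gender=0, years_with_diabetes=20.0)
    d = Diary(profile=profile, **kwargs)
    return d.sort()


def _episode(ts=T0, value=3.2) -> HypoEpisode:
    return HypoEpisode(ts, "S000", value, "x", 5, Category.ACTIVITY)


def _with_morning_readings(days=120, wake_minutes=7 * 60):
    """Readings at a fixed wake time each day plus one on the episode day."""
    readings = []
    start = T0 - timedelta(days=days)
    for k in range(days + 1):
        day = start + timedelta(days=k)
        readings.append(
            GlucoseReading(day.replace(hour=wake_minutes // 60, minute=wake_minutes % 60), 6.0)
        )
    return readings


class TestTemporal:
    def test_tod_anchors(self):
        d = _diary(readings=_with_morning_readings())
        b = compute_baselines(d, T0)
        out = temporal_features(_episode(T0), d, b)
        assert out["tod"] == pytest.approx(0.75)  # 18:00 -> 18/24
        assert out["cos_tod"] == pytest.approx(6.0)  # |18 - 12|
        assert out["sin_tod"] == pytest.approx(6.0)  # min(18, 24-18)

    def test_offsets_at_noon_and_midnight(self):
        d = _diary(readings=_with_morning_readings())
        noon = T0.replace(hour=12, minute=0)
        mid = T0.replace(hour=0, minute=5)
        b = compute_baselines(d, noon)
        assert temporal_features(_episode(noon), d, b)["cos_tod"] == pytest.approx(0.0)
        out = temporal_features(HypoEpisode(mid, "S000", 3.0, "x", 5, Category.FOOD), d, b)
        assert out["sin_tod"] == pytest.approx(5 / 60)  # near-midnight boundary

    def test_business_day_flag(self):
        d = _diary(readings=_with_morning_readings())
        sat = datetime(2019, 6, 15, 12, 0)
        b = compute_baselines(d, sat)
        assert temporal_features(_episode(sat), d, b)["is_bday"] == 0.0
        assert temporal_features(_episode(T0), d, compute_baselines(d, T0))["is_bday"] == 1.0

    def test_wake_up_offset_against_median(self):
        # usual first reading 07:00; episode day's first reading 08:30
        readings = _with_morning_readings()
        readings = [r for r in readings if r.timestamp.date() != T0.date()]
        readings.append(GlucoseReading(T0.replace(hour=8, minute=30), 6.0))
        d = _diary(readings=readings)
        b = compute_baselines(d, T0)
        out = temporal_features(_episode(T0), d, b)
        assert out["wake_up_offset"] == pytest.approx(1.5)

    def test_wake_up_offset_missing_without_same_day_reading(self):
        readings = [r for r in _with_morning_readings() if r.timestamp.date() != T0.date()]
        d = _diary(readings=readings)
        b = compute_baselines(d, T0)
        assert np.isnan(temporal_features(_episode(T0), d, b)["wake_up_offset"])


class TestInterpolatedBg:
    def test_constant_window(self):
        readings = [
            GlucoseReading(T0 + timedelta(hours=h), 5.0) for h in (-2.0, -1.0, 0.0, 1.0)
        ]
        d = _diary(readings=readings)
        out = interp_bg_features(_episode(T0, 5.0 - 1.5), d)  # episode value irrelevant here
        assert out["bgi_mean"] == pytest.approx(5.0)
        assert out["bgi_std"] == pytest.approx(0.0)
        assert out["bgi_range"] == pytest.approx(0.0)
        assert out["bgi_slope"] == pytest.approx(0.0)

    def test_knots_reproduced(self):
        vals = [8.0, 3.2, 6.5, 7.0]
        readings = [
            GlucoseReading(T0 + timedelta(hours=h), v)
            for h, v in zip((-2.5, 0.0, 1.0, 2.5), vals)
        ]
        d = _diary(readings=readings)
        out = interp_bg_features(_episode(T0), d)
        assert out["bgi_max"] <= max(vals) + 1e-9  # monotone interpolant: no overshoot
        assert out["bgi_min"] >= min(vals) - 1e-9
        assert out["bgi_min"] == pytest.approx(3.2)  # knot values are attained
        assert out["bgi_max"] == pytest.approx(8.0)

    def test_collinear_slope(self):
        # 8.0 -> 4.0 over 3 h: slope -4/3 mmol/L/h; PCHIP reproduces a line
        readings = [
            GlucoseReading(T0 - timedelta(hours=1.5), 8.0),
            GlucoseReading(T0, 6.0),
            GlucoseReading(T0 + timedelta(hours=1.5), 4.0),
        ]
        d = _diary(readings=readings)
        out = interp_bg_features(_episode(T0), d)
        assert out["bgi_slope"] == pytest.approx(-4.0 / 3.0, abs=1e-6)
        assert out["bgi_std"] > 0

    def test_single_knot_degrades_to_constant(self):
        d = _diary(readings=[GlucoseReading(T0, 3.2)])
        out = interp_bg_features(_episode(T0), d)
        assert out["bgi_mean"] == pytest.approx(3.2)
        assert out["bgi_std"] == 0.0 and out["bgi_slope"] == 0.0
        assert np.isnan(out["bgi_skew"]) and np.isnan(out["bgi_kurt"])

    def test_empty_window_all_missing(self):
        d = _diary(readings=[GlucoseReading(T0 - timedelta(hours=10), 6.0)])
        out = interp_bg_features(_episode(T0), d)
        assert all(np.isnan(v) for v in out.values())


class TestNeighborReadings:
    def test_nearest_prior_rule(self):
        readings = [
            GlucoseReading(T0 - timedelta(hours=2.0), 5.2),
            GlucoseReading(T0 - timedelta(hours=0.5), 6.0),
            GlucoseReading(T0, 3.2),
        ]
        d = _diary(readings=readings)
        out = neighbor_bg_features(_episode(T0), d)
        assert out["pre_g_val"] == pytest.approx(6.0)
        assert out["pre_g_offset"] == pytest.approx(0.5)

    def test_threshold_classes_forward(self):
        readings = [
            GlucoseReading(T0, 3.2),
            GlucoseReading(T0 + timedelta(hours=1.5), 9.8),
            GlucoseReading(T0 + timedelta(hours=4.0), 11.2),
        ]
        d = _diary(readings=readings)
        out = neighbor_bg_features(_episode(T0), d)
        assert out["post_g_val"] == pytest.approx(9.8)
        assert out["post_g_offset"] == pytest.approx(1.5)
        assert out["post_H_offset"] == pytest.approx(4.0)  # first reading > 10
        assert out["post_t_offset"] == pytest.approx(1.5)  # 9.8 in [4, 10]
        assert np.isnan(out["post_h_offset"])  # no later hypo reading

    def test_episode_reading_excluded(self):
        d = _diary(readings=[GlucoseReading(T0, 3.2)])
        out = neighbor_bg_features(_episode(T0), d)
        assert np.isnan(out["pre_g_val"]) and np.isnan(out["post_g_val"])

    def test_no_prior_hypo_missing(self):
        readings = [GlucoseReading(T0 - timedelta(hours=3), 7.0), GlucoseReading(T0, 3.2)]
        d = _diary(readings=readings)
        assert np.isnan(neighbor_bg_features(_episode(T0), d)["pre_h_offset"])


class TestIntakeContext:
    def _doses(self, mean=6.0, n=90):
        """Daily QA doses of `mean` units over the 90 days before T0."""
        return [
            InsulinDose(T0 - timedelta(days=k, hours=5), mean, InsulinKind.QA)
            for k in range(1, n + 1)
        ]

    def test_subject_centering_worked_example(self):
        # last QA dose 8 U at t-1.25 h, subject mean 6 U -> +2.0, offset 1.25
        doses = self._doses(6.0) + [InsulinDose(T0 - timedelta(hours=1.25), 8.0, InsulinKind.QA)]
        d = _diary(qa_doses=doses)
        b = compute_baselines(d, T0)
        out = intake_context_features(_episode(T0), d, b)
        # brute-force 90-day mean: daily doses k=1..89 are inside the window
        # (k=90 falls 5 h outside) plus the 8 U dose itself
        expected_mean = (89 * 6.0 + 8.0) / 90
        assert b.qa_mean == pytest.approx(expected_mean)
        assert out["pre_ins_dosage"] == pytest.approx(8.0 - expected_mean)
        assert out["pre_ins_offset"] == pytest.approx(1.25)

    def test_carb_centering_after_event(self):
        carbs = [CarbIntake(T0 - timedelta(days=k), 45.0) for k in range(1, 60)] + [
            CarbIntake(T0 + timedelta(hours=0.5), 60.0)
        ]
        d = _diary(carbs=carbs)
        b = compute_baselines(d, T0)
        out = intake_context_features(_episode(T0), d, b)
        assert out["post_car_dosage"] == pytest.approx(15.0)  # 60 - 45
        assert out["post_car_offset"] == pytest.approx(0.5)

    def test_absent_post_basal_missing(self):
        d = _diary(basal_doses=[InsulinDose(T0 - timedelta(days=1), 24.0, InsulinKind.BASAL)])
        b = compute_baselines(d, T0)
        out = intake_context_features(_episode(T0), d, b)
        assert np.isnan(out["post_bas_dosage"]) and np.isnan(out["post_bas_offset"])


class TestAdvisor:
    def test_difference_and_tag(self):
        rec = AdvisorRecord(
            timestamp=T0 - timedelta(hours=2),
            food_ins=4.0, corr_ins=1.0, total_ins=5.0, logged_intake=4.0,
            exercise_tag=True,
        )
        d = _diary(advisor_records=[rec])
        out = advisor_features(_episode(T0), d)
        assert out["ba_diff"] == pytest.approx(1.0)
        assert out["ba_has_excercise"] == 1.0

    def test_no_record_in_lookback_all_missing(self):
        rec = AdvisorRecord(timestamp=T0 - timedelta(hours=10), total_ins=5.0)
        d = _diary(advisor_records=[rec])
        out = advisor_features(_episode(T0), d)
        assert all(np.isnan(v) for v in out.values())


class TestLongTermStats:
    def test_mean_crossing_rate(self):
        t = np.arange(6.0)
        v = np.array([4.0, 6.0, 4.0, 6.0, 4.0, 6.0])
        out = longterm_signal_stats(t, v, t_event_h=10.0, prefix="glu")
        assert out["glu_mean"] == pytest.approx(5.0)
        assert out["glu_mean_x"] == pytest.approx(5 / 6)

    def test_slope_means_two_segments(self):
        t = np.array([0.0, 2.0, 3.0])
        v = np.array([10.0, 6.0, 8.0])
        out = longterm_signal_stats(t, v, t_event_h=10.0, prefix="glu", with_slopes=True)
        assert out["neg_slopes_mean"] == pytest.approx(-2.0)
        assert out["pos_slopes_mean"] == pytest.approx(2.0)

    def test_overnight_gaps_excluded_from_slopes(self):
        t = np.array([0.0, 2.0, 12.0])  # 10 h gap: excluded
        v = np.array([10.0, 6.0, 16.0])
        out = longterm_signal_stats(t, v, t_event_h=20.0, prefix="glu", with_slopes=True)
        assert np.isnan(out["pos_slopes_mean"])
        assert out["neg_slopes_mean"] == pytest.approx(-2.0)

    def test_symmetric_sample_zero_skew(self):
        t = np.arange(5.0)
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = longterm_signal_stats(t, v, t_event_h=10.0, prefix="car")
        assert out["car_skew"] == pytest.approx(0.0, abs=1e-12)

    def test_window_excludes_event_time(self):
        t = np.array([0.0, 5.0, 10.0])
        v = np.array([1.0, 2.0, 99.0])
        out = longterm_signal_stats(t, v, t_event_h=10.0, prefix="glu")
        assert out["glu_max"] == pytest.approx(2.0)  # reading at t_event excluded

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.5, max_value=30.0), min_size=3, max_size=40),
    )
    def test_moment_stats_match_textbook_brute_force(self, values):
        x = np.asarray(values)
        t = np.arange(len(x), dtype=float)
        out = longterm_signal_stats(t, x, t_event_h=len(x) + 1.0, prefix="glu")
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        assert out["glu_std"] == pytest.approx(np.sqrt(m2), abs=1e-9)
        if m2 > 0:
            g1 = ((x - m) ** 3).mean() / m2**1.5
            g2 = ((x - m) ** 4).mean() / m2**2 - 3
            assert out["glu_skew"] == pytest.approx(g1, abs=1e-9)
            assert out["glu_kurt"] == pytest.approx(g2, abs=1e-9)
        assert out["glu_range"] == pytest.approx(x.max() - x.min())


class TestQuiz:
    def test_session_arithmetic(self):
        answers = [
            QuizAnswer(T0 - timedelta(days=3, minutes=m), 2, "a") for m in range(4)
        ] + [QuizAnswer(T0 - timedelta(days=1, minutes=m), 2, "b") for m in range(6)]
        d = _diary(quiz_answers=answers)
        out = quiz_engagement_features(d, T0)
        assert out["cnc_ansnum"] == 10
        assert out["cnc_daysnum"] == 2
        assert out["cnc_dist_avg"] == pytest.approx(5.0)  # sessions of 4 and 6
        assert out["cnc_points_avg"] == pytest.approx(2.0)
        assert out["cnc_points_std"] == pytest.approx(0.0)

    def test_no_activity(self):
        d = _diary()
        out = quiz_engagement_features(d, T0)
        assert out["cnc_ansnum"] == 0.0 and out["cnc_daysnum"] == 0.0
        assert np.isnan(out["cnc_points_avg"])


class TestAssembly:
    def test_exactly_83_canonical_slots(self, default_cohort):
        diaries, _ = default_cohort
        diary = next(iter(diaries.values()))
        episode = diary.episodes[0]
        vec = represent_event(episode, diary)
        assert len(FEATURE_REGISTRY) == 83
        canonical = {k: v for k, v in vec.items() if k in FEATURE_REGISTRY}
        assert list(canonical) == FEATURE_REGISTRY
        assert set(vec) - set(FEATURE_REGISTRY) == set(EXTRA_FEATURES)

    def test_determinism(self, default_cohort):
        diaries, _ = default_cohort
        diary = next(iter(diaries.values()))
        episode = diary.episodes[0]
        v1 = represent_event(episode, diary)
        v2 = represent_event(episode, diary)
        assert all(
            (np.isnan(v1[k]) and np.isnan(v2[k])) or v1[k] == v2[k] for k in v1
        )

    def test_offset_features_nonnegative(self, default_features):
        offset_cols = [c for c in FEATURE_REGISTRY if c.endswith("_offset") and c != "wake_up_offset"]
        vals = default_features[offset_cols].to_numpy(float)
        assert np.nanmin(vals) >= 0.0
        assert default_features["cos_tod"].between(0, 12).all()
        assert default_features["sin_tod"].between(0, 12).all()
        assert default_features["tod"].between(0, 1).all()

    def test_range_is_max_minus_min(self, default_features):
        for p in ("glu", "ins", "bas", "car"):
            df = default_features[[f"{p}_range", f"{p}_max", f"{p}_min"]].dropna()
            assert np.allclose(df[f"{p}_range"], df[f"{p}_max"] - df[f"{p}_min"])

    def test_no_lookahead_in_longterm_features(self, default_cohort):
        """Truncating the diary just after the episode must not change any
        long-horizon or baseline feature."""
        diaries, _ = default_cohort
        diary = next(d for d in diaries.values() if len(d.episodes) >= 3)
        episode = diary.episodes[len(diary.episodes) // 2]
        full = represent_event(episode, diary)
        cut = episode.timestamp + timedelta(minutes=1)
        truncated = Diary(
            profile=diary.profile,
            readings=[r for r in diary.readings if r.timestamp <= cut],
            qa_doses=[r for r in diary.qa_doses if r.timestamp <= cut],
            basal_doses=[r for r in diary.basal_doses if r.timestamp <= cut],
            carbs=[r for r in diary.carbs if r.timestamp <= cut],
            advisor_records=[r for r in diary.advisor_records if r.timestamp <= cut],
            quiz_answers=[r for r in diary.quiz_answers if r.timestamp <= cut],
            episodes=[e for e in diary.episodes if e.timestamp <= cut],
        )
        trunc = represent_event(episode, truncated)
        past_only = [
            c for c in FEATURE_REGISTRY
            if c.split("_")[0] in ("glu", "ins", "bas", "car", "cnc", "ba")
            or c in ("neg_slopes_mean", "pos_slopes_mean", "wake_up_offset",
                     "pre_ins_dosage", "pre_bas_dosage", "pre_car_dosage")
        ]
        for c in past_only:
            assert (np.isnan(full[c]) and np.isnan(trunc[c])) or full[c] == pytest.approx(trunc[c]), c

    def test_missing_advisor_keeps_length(self, default_features):
        no_adv = default_features[default_features["ba_total_ins"].isna()]
        assert len(no_adv) > 0
        assert no_adv[
            ["ba_food_ins", "ba_corr_ins", "ba_diff", "ba_meal_rise", "ba_has_excercise"]
        ].isna().all().all()

    def test_featurize_shape(self, default_features):
        assert list(default_features.columns[:3]) == ["episode_id", "subject_id", "category"]
        assert default_features.columns[3:].tolist() == FEATURE_REGISTRY + EXTRA_FEATURES
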