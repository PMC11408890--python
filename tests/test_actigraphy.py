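"""Epoch processing: cutpoints, non-wear, bouts, daily and weekly summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actiqol import (
    Bout,
    CountStream,
    DailyActivitySummary,
    NonWearRule,
    classify_intensity,
    detect_bouts,
    detect_nonwear,
    is_valid_participant,
    summarize_day,
    summarize_week,
    weekly_met_minutes,
)
from actiqol.actigraphy import (
    LIGHT,
    MODERATE,
    NON_WEAR,
    SEDENTARY,
    VIGOROUS,
    NoValidDaysError,
    nonwear_mask,
)

from oracles import bouts_oracle, nonwear_mask_oracle


def day_stream(cpm_row, pid="p"):
    return CountStream(participant_id=pid, cpm=np.asarray(cpm_row)[None, :])


def wear_day(*segments, fill=500, length=1440):
    """A day of `fill` CPM with (start, values) segments painted over it."""
    day = np.full(length, fill, dtype=np.int64)
    for start, values in segments:
        day[start : start + len(values)] = values
    return day


class TestClassifyIntensity:
    @pytest.mark.parametrize(
        "cpm,label",
        [
            (0, "sedentary"),
            (50, "sedentary"),
            (99, "sedentary"),
            (100, "light"),
            (1999, "light"),
            (2000, "moderate"),
            (5998, "moderate"),
            (5999, "vigorous"),
            (20000, "vigorous"),
        ],
    )
    def test_cutpoint_boundaries(self, cpm, label):
        assert classify_intensity(cpm) == label

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(-1)

    def test_vectorized_matches_scalar(self, rng):
        cpm = rng.integers(0, 8000, 200)
        labels = classify_intensity(cpm)
        assert all(labels[i] == classify_intensity(int(c)) for i, c in enumerate(cpm))


class TestNonWear:
    def test_sixty_zero_minutes_is_nonwear(self):
        stream = day_stream(wear_day((600, np.zeros(60, int))))
        assert detect_nonwear(stream) == {0: [(600, 659)]}

    def test_fiftynine_zero_minutes_is_wear(self):
        stream = day_stream(wear_day((600, np.zeros(59, int))))
        assert detect_nonwear(stream) == {0: []}

    def test_one_minute_sub100_interruption_absorbed(self):
        seg = np.zeros(81, int)
        seg[40] = 80
        stream = day_stream(wear_day((600, seg)))
        assert detect_nonwear(stream) == {0: [(600, 680)]}

    def test_two_minute_sub100_interruption_breaks_window(self):
        seg = np.zeros(82, int)
        seg[40:42] = 80
        stream = day_stream(wear_day((600, seg)))
        assert detect_nonwear(stream) == {0: []}

    def test_cpm_at_or_above_100_breaks_window(self):
        seg = np.zeros(121, int)
        seg[60] = 100
        stream = day_stream(wear_day((600, seg)))
        assert detect_nonwear(stream) == {0: [(600, 659), (661, 720)]}

    def test_strict_greater_than_rule(self):
        rule = NonWearRule(strict_gt=True)
        sixty = day_stream(wear_day((600, np.zeros(60, int))))
        sixty_one = day_stream(wear_day((600, np.zeros(61, int))))
        assert detect_nonwear(sixty, rule) == {0: []}
        assert detect_nonwear(sixty_one, rule) == {0: [(600, 660)]}

    def test_empty_stream(self):
        stream = CountStream("p", np.zeros((0, 1440), int))
        assert detect_nonwear(stream) == {}

    @given(st.data())
    @settings(max_examples=250, deadline=None)
    def test_matches_bruteforce_oracle(self, data):
        n = data.draw(st.integers(1, 1440))
        seed = data.draw(st.integers(0, 2**31 - 1))
        r = np.random.default_rng(seed)
        # zero-heavy mixture so qualifying windows actually occur
        cpm = r.choice(
            [0, 1, 50, 99, 100, 500, 3000], size=n, p=[0.5, 0.1, 0.1, 0.1, 0.08, 0.07, 0.05]
        )
        day = np.full(1440, 500, dtype=np.int64)  # wear padding
        day[:n] = cpm
        mask = nonwear_mask(day_stream(day))[0, :n]
        assert mask.tolist() == nonwear_mask_oracle(cpm.tolist())


class TestBouts:
    def test_twelve_moderate_minutes_is_one_bout(self):
        labels = np.full(12, MODERATE)
        (bout,) = detect_bouts(labels)
        assert (bout.start_minute, bout.end_minute) == (0, 11)
        assert bout.moderate_minutes == 12 and bout.interruption_minutes == 0

    def test_nine_minutes_is_no_bout(self):
        assert detect_bouts(np.full(9, MODERATE)) == []

    def test_one_minute_interruption_merges(self):
        labels = np.array([MODERATE] * 6 + [LIGHT] + [MODERATE] * 5)
        (bout,) = detect_bouts(labels)
        assert bout.span == 12
        assert bout.moderate_minutes == 11
        assert bout.interruption_minutes == 1

    def test_two_minute_interruption_breaks(self):
        labels = np.array([MODERATE] * 6 + [LIGHT] * 2 + [MODERATE] * 5)
        assert detect_bouts(labels) == []

    def test_nonwear_breaks_even_single_minute(self):
        labels = np.array([MODERATE] * 6 + [NON_WEAR] + [MODERATE] * 5)
        assert detect_bouts(labels) == []

    def test_mixed_intensities_counted(self):
        labels = np.array([MODERATE] * 5 + [VIGOROUS] * 5 + [SEDENTARY] + [VIGOROUS] * 2)
        (bout,) = detect_bouts(labels)
        assert bout.moderate_minutes == 5
        assert bout.vigorous_minutes == 7
        assert bout.interruption_minutes == 1

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, data):
        n = data.draw(st.integers(1, 200))
        seed = data.draw(st.integers(0, 2**31 - 1))
        r = np.random.default_rng(seed)
        labels = r.choice(
            [SEDENTARY, LIGHT, MODERATE, VIGOROUS, NON_WEAR],
            size=n,
            p=[0.15, 0.2, 0.35, 0.15, 0.15],
        )
        got = [
            (b.start_minute, b.end_minute, b.moderate_minutes,
             b.vigorous_minutes, b.interruption_minutes)
            for b in detect_bouts(labels)
        ]
        assert got == bouts_oracle(labels.tolist())


class TestSummarizeDay:
    def test_all_sedentary_valid_day(self):
        stream = CountStream.from_epochs(
            "p", [0] * 720, list(range(720)), [50] * 720
        )
        s = summarize_day(stream, 0)
        assert s.sedentary_minutes == 720
        assert s.wear_minutes == 720
        assert s.is_valid_day

    def test_599_wear_minutes_invalid(self):
        stream = CountStream.from_epochs(
            "p", [0] * 599, list(range(599)), [50] * 599
        )
        assert not summarize_day(stream, 0).is_valid_day

    def test_mixed_intensity_counts(self):
        cpm = [50] * 600 + [500] * 30 + [3000] * 15 + [7000] * 5
        stream = CountStream.from_epochs(
            "p", [0] * 650, list(range(650)), cpm
        )
        s = summarize_day(stream, 0)
        assert (
            s.sedentary_minutes,
            s.light_minutes,
            s.moderate_minutes,
            s.vigorous_minutes,
        ) == (600, 30, 15, 5)
        assert s.wear_minutes == 650
        assert s.is_valid_day

    def test_absent_day_yields_empty_summary(self):
        stream = day_stream(wear_day())
        s = summarize_day(stream, 5)
        assert s.wear_minutes == 0 and not s.is_valid_day and s.bouts == []

    def test_nonwear_excluded_from_wear_and_intensity(self):
        stream = day_stream(wear_day((600, np.zeros(120, int))))
        s = summarize_day(stream, 0)
        assert s.wear_minutes == 1440 - 120
        assert s.sedentary_minutes == 0  # zeros were all non-wear
        assert s.light_minutes == 1320

    def test_conservation_property(self, rng):
        for _ in range(20):
            cpm = rng.choice([0, 50, 500, 3000, 7000], size=1440)
            s = summarize_day(day_stream(cpm), 0)
            assert (
                s.sedentary_minutes
                + s.light_minutes
                + s.moderate_minutes
                + s.vigorous_minutes
                == s.wear_minutes
            )


def _summary(day, mod=0, vig=0, bout_mod=0, bout_vig=0, wear=840, valid=True):
    bouts = []
    if bout_mod or bout_vig:
        span = bout_mod + bout_vig
        bouts = [
            Bout(
                day_index=day,
                start_minute=0,
                end_minute=span - 1,
                moderate_minutes=bout_mod,
                vigorous_minutes=bout_vig,
                interruption_minutes=0,
            )
        ]
    return DailyActivitySummary(
        day_index=day,
        wear_minutes=wear,
        sedentary_minutes=wear - mod - vig,
        light_minutes=0,
        moderate_minutes=mod,
        vigorous_minutes=vig,
        bouts=bouts,
        is_valid_day=valid,
    )


class TestWeeklyMetMinutes:
    def test_single_active_day_normalized_to_600(self):
        summaries = [_summary(0, mod=100, vig=25, bout_mod=100, bout_vig=25)] + [
            _summary(d) for d in range(1, 7)
        ]
        w = weekly_met_minutes(summaries)
        assert w.met_minutes_ab == pytest.approx(600.0)
        assert w.meets_ab

    def test_all_zero_activity(self):
        w = weekly_met_minutes([_summary(d) for d in range(7)])
        assert w.met_minutes_at == 0 and not w.meets_at and not w.meets_ab

    def test_vigorous_counts_double(self):
        vig_only = [_summary(0, vig=75)] + [_summary(d) for d in range(1, 7)]
        mod_only = [_summary(0, mod=150)] + [_summary(d) for d in range(1, 7)]
        assert (
            weekly_met_minutes(vig_only).met_minutes_at
            == weekly_met_minutes(mod_only).met_minutes_at
            == pytest.approx(600.0)
        )

    def test_bout_minutes_are_subset_of_total(self, rng):
        for _ in range(30):
            summaries = [
                _summary(
                    d,
                    mod=int(rng.integers(0, 60)) + 20,
                    vig=int(rng.integers(0, 20)) + 10,
                    bout_mod=int(rng.integers(0, 20)),
                    bout_vig=int(rng.integers(0, 10)),
                )
                for d in range(7)
            ]
            w = weekly_met_minutes(summaries)
            assert w.met_minutes_ab <= w.met_minutes_at

    def test_invalid_days_excluded(self):
        summaries = [_summary(0, mod=150, bout_mod=150)] + [
            _summary(d, mod=500, bout_mod=500, wear=300, valid=False)
            for d in range(1, 7)
        ]
        w = weekly_met_minutes(summaries)
        assert w.valid_days == 1
        # only the single valid day counts: mean daily 600 scaled to 7 days
        assert w.met_minutes_at == pytest.approx(7 * 600.0)

    def test_sum_normalization(self):
        summaries = [_summary(d, mod=30) for d in range(4)]
        w = weekly_met_minutes(summaries, normalization="sum")
        assert w.met_minutes_at == pytest.approx(4 * 120.0)

    def test_zero_valid_days_raises(self):
        with pytest.raises(NoValidDaysError):
            weekly_met_minutes([_summary(0, wear=100, valid=False)])


class TestValidity:
    @pytest.mark.parametrize("n_valid,expected", [(4, True), (3, False), (7, True)])
    def test_valid_day_threshold(self, n_valid, expected):
        summaries = [
            _summary(d, wear=600 if d < n_valid else 300, valid=d < n_valid)
            for d in range(7)
        ]
        assert is_valid_participant(summaries) is expected

    def test_boundary_wear_days_from_streams(self):
        # 7 days of exactly 600 recorded wear minutes each
        stream = CountStream.from_epochs(
            "p",
            np.repeat(np.arange(7), 600),
            np.tile(np.arange(600), 7),
            [500] * 4200,
        )
        summaries = summarize_week(stream)
        assert all(s.wear_minutes == 600 and s.is_valid_day for s in summaries)
        assert is_valid_participant(summaries)


class TestDeterminism:
    def test_identical_streams_identical_summaries(self, rng):
        cpm = rng.choice([0, 50, 500, 3000], size=(7, 1440))
        a = summarize_week(CountStream("p", cpm))
        b = summarize_week(CountStream("p", cpm.copy()))
        assert a == b
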