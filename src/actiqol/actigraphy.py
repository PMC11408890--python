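"""Minute-epoch actigraphy processing.

Turns counts-per-minute (CPM) streams into wear time, intensity minutes,
bout-qualified moderate-to-vigorous physical activity (MVPA), and weekly
MET-minute exposures:

* :func:`classify_intensity` - CPM cutpoint classification.
* :func:`detect_nonwear` - zero-run device-off detection with the sub-100 CPM
  interruption tolerance.
* :func:`detect_bouts` - sustained-MVPA bout detection (>= 10-minute span,
  tolerating interior sub-MVPA runs of at most one minute).
* :func:`summarize_day` / :func:`summarize_week` - per-day aggregation.
* :func:`weekly_met_minutes` - MET-minutes/week under the total (AT) and
  bout-qualified (AB) definitions, with the 600 MET-minutes/week flag.
* :class:`AccelerometerSummarizer` - a scikit-learn style transformer mapping
  a list of :class:`CountStream` to a weekly exposure DataFrame.

Minute epochs are 0-based and day-partitioned; bouts and non-wear windows do
not cross midnight.  Intervals are closed ``[start, end]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import (
    MAX_DAYS,
    MINUTES_PER_DAY,
    BoutRule,
    IntensityThresholds,
    METWeights,
    NonWearRule,
    ValidityRule,
)

# Intensity codes used in labeled minute arrays.
SEDENTARY, LIGHT, MODERATE, VIGOROUS = 0, 1, 2, 3
NON_WEAR = -1  # wear-excluded minute (device off)
ABSENT = -2  # minute not recorded at all

INTENSITY_LABELS = ("sedentary", "light", "moderate", "vigorous")


class NoValidDaysError(ValueError):
    """Weekly exposure requested for a participant with zero valid days."""


@dataclass
class CountStream:
    """One participant's minute-epoch CPM series over the wearing week.

    ``cpm`` is an ``(n_days, 1440)`` integer array; ``present`` marks minutes
    actually recorded (``None`` means fully present).  Day span is at most 7.
    """

    participant_id: str
    cpm: np.ndarray
    present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cpm = np.asarray(self.cpm)
        if self.cpm.ndim != 2 or self.cpm.shape[1] != MINUTES_PER_DAY:
            raise ValueError("cpm must have shape (n_days, 1440)")
        if self.cpm.shape[0] > MAX_DAYS:
            raise ValueError(f"day span exceeds {MAX_DAYS} days")
        if self.present is not None:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape != self.cpm.shape:
                raise ValueError("present mask must match cpm shape")
        if self.present is None:
            negative = self.cpm.size and self.cpm.min() < 0
        else:
            negative = bool(np.any((self.cpm < 0) & self.present))
        if negative:
            raise ValueError("cpm must be non-negative")

    @property
    def n_days(self) -> int:
        return self.cpm.shape[0]

    def present_mask(self) -> np.ndarray:
        if self.present is None:
            return np.ones_like(self.cpm, dtype=bool)
        return self.present

    @classmethod
    def from_epochs(
        cls,
        participant_id: str,
        day_index: Sequence[int],
        minute_of_day: Sequence[int],
        cpm: Sequence[int],
        n_days: int | None = None,
    ) -> "CountStream":
        """Build a stream from long-form epoch records.

        Epochs must be unique per ``(day_index, minute_of_day)``; minutes not
        listed are marked absent.
        """
        day = np.asarray(day_index, dtype=np.int64)
        minute = np.asarray(minute_of_day, dtype=np.int64)
        counts = np.asarray(cpm, dtype=np.int64)
        if day.size and (day.min() < 0):
            raise ValueError("day_index must be >= 0")
        if minute.size and (minute.min() < 0 or minute.max() >= MINUTES_PER_DAY):
            raise ValueError("minute_of_day must be in 0..1439")
        nd = int(n_days if n_days is not None else (day.max() + 1 if day.size else 0))
        key = day * MINUTES_PER_DAY + minute
        if np.unique(key).size != key.size:
            raise ValueError("duplicate (day, minute) epochs")
        grid = np.zeros((nd, MINUTES_PER_DAY), dtype=np.int64)
        present = np.zeros((nd, MINUTES_PER_DAY), dtype=bool)
        grid[day, minute] = counts
        present[day, minute] = True
        return cls(participant_id=participant_id, cpm=grid, present=present)

    def to_epochs_frame(self) -> pd.DataFrame:
        """Long-form epoch table (only minutes that are present)."""
        mask = self.present_mask()
        day, minute = np.nonzero(mask)
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "day_index": day,
                "minute_of_day": minute,
                "cpm": self.cpm[mask],
            }
        )


@dataclass(frozen=True)
class Bout:
    """A sustained run of MVPA minutes (closed interval within one day)."""

    day_index: int
    start_minute: int
    end_minute: int
    moderate_minutes: int
    vigorous_minutes: int
    interruption_minutes: int

    @property
    def span(self) -> int:
        return self.end_minute - self.start_minute + 1


@dataclass
class DailyActivitySummary:
    """Wear and intensity minutes plus detected bouts for one day."""

    day_index: int
    wear_minutes: int
    sedentary_minutes: int
    light_minutes: int
    moderate_minutes: int
    vigorous_minutes: int
    bouts: list[Bout] = field(default_factory=list)
    is_valid_day: bool = False

    @property
    def bout_moderate_minutes(self) -> int:
        return sum(b.moderate_minutes for b in self.bouts)

    @property
    def bout_vigorous_minutes(self) -> int:
        return sum(b.vigorous_minutes for b in self.bouts)


@dataclass(frozen=True)
class WeeklyActivity:
    """Weekly MET-minute exposures under the total (AT) and bout (AB)
    definitions, with the 600 MET-minutes/week guideline flags."""

    valid_days: int
    met_minutes_at: float
    met_minutes_ab: float
    meets_at: bool
    meets_ab: bool


def intensity_codes(
    cpm: np.ndarray, thresholds: IntensityThresholds | None = None
) -> np.ndarray:
    """Vectorized cutpoint classification to integer codes 0..3."""
    thresholds = thresholds or IntensityThresholds()
    arr = np.asarray(cpm)
    if arr.size and arr.min() < 0:
        raise ValueError("cpm must be non-negative")
    edges = np.array(
        [thresholds.sedentary_below, thresholds.moderate_low, thresholds.vigorous_low]
    )
    return np.searchsorted(edges, arr, side="right")


def classify_intensity(cpm, thresholds: IntensityThresholds | None = None):
    """Classify CPM into {sedentary, light, moderate, vigorous}.

    Scalar input returns a label string; array input returns an array of
    label strings.  Negative counts raise ``ValueError``.
    """
    codes = intensity_codes(np.asarray(cpm), thresholds)
    if np.ndim(cpm) == 0:
        return INTENSITY_LABELS[int(codes)]
    return np.take(INTENSITY_LABELS, codes)


def _runs(values: np.ndarray):
    """Run-length encode: yields (start, end_exclusive, value)."""
    n = len(values)
    if n == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0, int)
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return starts, ends, values[starts]


def _merged_windows(
    cat: np.ndarray, core: int, tolerated: int, max_interruption: int
):
    """Maximal windows of ``core`` runs merged across interior ``tolerated``
    runs shorter than ``max_interruption`` minutes.

    Returns (window_start, last_core_end_exclusive) pairs: windows begin and
    end with core minutes; any other category, or a tolerated run of
    >= ``max_interruption`` minutes, terminates the window.
    """
    starts, ends, vals = _runs(cat)
    windows: list[tuple[int, int]] = []
    win_start = -1
    core_end = -1
    # iterate python ints: run counts can reach the array length
    for s, e, v in zip(starts.tolist(), ends.tolist(), vals.tolist()):
        if v == core:
            if win_start < 0:
                win_start = int(s)
            core_end = int(e)
        elif v == tolerated and (e - s) < max_interruption and win_start >= 0:
            continue
        else:
            if win_start >= 0:
                windows.append((win_start, core_end))
            win_start = -1
    if win_start >= 0:
        windows.append((win_start, core_end))
    return windows


def _nonwear_intervals_1d(
    cpm: np.ndarray, present: np.ndarray, rule: NonWearRule
) -> list[tuple[int, int]]:
    """Non-wear intervals [start, end] within one day's minute array."""
    # categories: 0 = zero count, 1 = tolerated sub-threshold, 2 = wear/absent
    cat = np.full(cpm.shape, 2, dtype=np.int8)
    zero = present & (cpm == 0)
    sub = present & (cpm > 0) & (cpm < rule.tolerance_cpm_below)
    cat[sub] = 1
    cat[zero] = 0
    out = []
    for start, end in _merged_windows(cat, 0, 1, rule.tolerance_max_run):
        span = end - start
        if span > rule.min_zero_run or (
            not rule.strict_gt and span == rule.min_zero_run
        ):
            out.append((start, end - 1))
    return out


def detect_nonwear(
    stream: CountStream, rule: NonWearRule | None = None
) -> dict[int, list[tuple[int, int]]]:
    """Per-day non-wear intervals (closed ``[start, end]`` minute ranges).

    A minute is non-wear iff it lies in a maximal window of zero-count
    minutes spanning at least ``rule.min_zero_run`` minutes, where interior
    runs of sub-threshold (CPM < 100) minutes shorter than 2 minutes are
    tolerated and absorbed into the window.
    """
    rule = rule or NonWearRule()
    present = stream.present_mask()
    return {
        d: _nonwear_intervals_1d(stream.cpm[d], present[d], rule)
        for d in range(stream.n_days)
    }


def nonwear_mask(
    stream: CountStream, rule: NonWearRule | None = None
) -> np.ndarray:
    """Boolean (n_days, 1440) mask of non-wear minutes."""
    mask = np.zeros_like(stream.cpm, dtype=bool)
    for day, intervals in detect_nonwear(stream, rule).items():
        for start, end in intervals:
            mask[day, start : end + 1] = True
    return mask


def detect_bouts(
    labels: np.ndarray,
    day_index: int = 0,
    rule: BoutRule | None = None,
) -> list[Bout]:
    """Detect qualifying MVPA bouts in one day's labeled minute array.

    ``labels`` uses the intensity codes of this module, with ``NON_WEAR`` /
    ``ABSENT`` for wear-excluded minutes.  A bout is a maximal run of
    MVPA-labeled minutes, merged across interior sub-MVPA runs of at most
    one minute, whose total span is at least ``rule.min_span``.  Interruption
    minutes count toward the span but contribute no MVPA time.
    """
    rule = rule or BoutRule()
    labels = np.asarray(labels)
    # categories: 0 = MVPA, 1 = tolerated sub-MVPA wear minute, 2 = break
    cat = np.full(labels.shape, 2, dtype=np.int8)
    cat[(labels == SEDENTARY) | (labels == LIGHT)] = 1
    cat[(labels == MODERATE) | (labels == VIGOROUS)] = 0
    bouts = []
    for start, end in _merged_windows(cat, 0, 1, rule.max_interruption):
        span = end - start
        if span < rule.min_span:
            continue
        window = labels[start:end]
        mod = int(np.count_nonzero(window == MODERATE))
        vig = int(np.count_nonzero(window == VIGOROUS))
        bouts.append(
            Bout(
                day_index=day_index,
                start_minute=start,
                end_minute=end - 1,
                moderate_minutes=mod,
                vigorous_minutes=vig,
                interruption_minutes=span - mod - vig,
            )
        )
    return bouts


def label_day(
    stream: CountStream,
    day: int,
    nonwear: dict[int, list[tuple[int, int]]] | None = None,
    thresholds: IntensityThresholds | None = None,
    nonwear_rule: NonWearRule | None = None,
) -> np.ndarray:
    """Labeled minute array for one day: intensity codes on wear minutes,
    ``NON_WEAR`` on device-off minutes, ``ABSENT`` on unrecorded minutes."""
    if day < 0 or day >= stream.n_days:
        return np.full(MINUTES_PER_DAY, ABSENT, dtype=np.int8)
    if nonwear is None:
        nonwear = detect_nonwear(stream, nonwear_rule)
    labels = intensity_codes(stream.cpm[day], thresholds).astype(np.int8)
    labels[~stream.present_mask()[day]] = ABSENT
    for start, end in nonwear.get(day, []):
        labels[start : end + 1] = NON_WEAR
    return labels


def summarize_day(
    stream: CountStream,
    day: int,
    nonwear: dict[int, list[tuple[int, int]]] | None = None,
    thresholds: IntensityThresholds | None = None,
    validity: ValidityRule | None = None,
    bout_rule: BoutRule | None = None,
    nonwear_rule: NonWearRule | None = None,
) -> DailyActivitySummary:
    """Aggregate one day: wear minutes, intensity minutes, bouts, validity.

    Intensity minutes are computed over wear epochs only (recorded minutes
    minus non-wear); a day absent from the stream yields an empty summary.
    """
    validity = validity or ValidityRule()
    labels = label_day(stream, day, nonwear, thresholds, nonwear_rule)
    counts = {
        code: int(np.count_nonzero(labels == code))
        for code in (SEDENTARY, LIGHT, MODERATE, VIGOROUS)
    }
    wear = sum(counts.values())
    return DailyActivitySummary(
        day_index=day,
        wear_minutes=wear,
        sedentary_minutes=counts[SEDENTARY],
        light_minutes=counts[LIGHT],
        moderate_minutes=counts[MODERATE],
        vigorous_minutes=counts[VIGOROUS],
        bouts=detect_bouts(labels, day, bout_rule),
        is_valid_day=wear >= validity.min_wear_minutes_per_day,
    )


def summarize_week(
    stream: CountStream,
    thresholds: IntensityThresholds | None = None,
    nonwear_rule: NonWearRule | None = None,
    validity: ValidityRule | None = None,
    bout_rule: BoutRule | None = None,
) -> list[DailyActivitySummary]:
    """Per-day summaries for every day of the stream."""
    nonwear = detect_nonwear(stream, nonwear_rule)
    return [
        summarize_day(stream, d, nonwear, thresholds, validity, bout_rule)
        for d in range(stream.n_days)
    ]


def is_valid_participant(
    summaries: Iterable[DailyActivitySummary], validity: ValidityRule | None = None
) -> bool:
    """True iff the number of valid days reaches ``validity.min_valid_days``."""
    validity = validity or ValidityRule()
    return sum(s.is_valid_day for s in summaries) >= validity.min_valid_days


def weekly_met_minutes(
    summaries: Sequence[DailyActivitySummary],
    mode: str | None = None,
    met: METWeights | None = None,
    normalization: str = "mean7",
) -> WeeklyActivity:
    """Weekly MET-minute exposures over the valid days of one participant.

    AT counts every moderate/vigorous wear minute; AB counts only minutes
    inside qualifying bouts (interruption minutes contribute zero).  With the
    default ``mean7`` normalization the weekly value is the mean daily
    MET-minutes over valid days scaled to 7 days; ``sum`` uses the raw sum.
    ``mode`` is accepted for symmetry with the two exposure definitions but
    both are always computed.
    """
    if mode is not None and mode.upper() not in ("AT", "AB"):
        raise ValueError("mode must be 'AT' or 'AB'")
    met = met or METWeights()
    valid = [s for s in summaries if s.is_valid_day]
    if not valid:
        raise NoValidDaysError("no valid wear days: weekly exposure undefined")
    at_daily = [
        met.moderate * s.moderate_minutes + met.vigorous * s.vigorous_minutes
        for s in valid
    ]
    ab_daily = [
        met.moderate * s.bout_moderate_minutes + met.vigorous * s.bout_vigorous_minutes
        for s in valid
    ]
    if normalization == "mean7":
        at = float(np.mean(at_daily) * 7)
        ab = float(np.mean(ab_daily) * 7)
    elif normalization == "sum":
        at = float(np.sum(at_daily))
        ab = float(np.sum(ab_daily))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return WeeklyActivity(
        valid_days=len(valid),
        met_minutes_at=at,
        met_minutes_ab=ab,
        meets_at=at >= met.guideline_met_minutes,
        meets_ab=ab >= met.guideline_met_minutes,
    )


class AccelerometerSummarizer(BaseEstimator, TransformerMixin):
    """Transform CPM count streams into a weekly exposure table.

    A stateless scikit-learn transformer: ``transform`` maps a list of
    :class:`CountStream` to one row per participant with wear statistics,
    MVPA-AT and MVPA-AB MET-minutes/week, guideline flags, and the
    wear-validity flag.  Participants with zero valid days get NaN exposures
    and ``valid_participant == False``.
    """

    def __init__(
        self,
        thresholds: IntensityThresholds | None = None,
        nonwear_rule: NonWearRule | None = None,
        validity: ValidityRule | None = None,
        bout_rule: BoutRule | None = None,
        met: METWeights | None = None,
        normalization: str = "mean7",
    ):
        self.thresholds = thresholds
        self.nonwear_rule = nonwear_rule
        self.validity = validity
        self.bout_rule = bout_rule
        self.met = met
        self.normalization = normalization

    def fit(self, X: Sequence[CountStream], y=None) -> "AccelerometerSummarizer":
        return self

    def transform(self, X: Sequence[CountStream]) -> pd.DataFrame:
        validity = self.validity or ValidityRule()
        rows = []
        for stream in X:
            summaries = summarize_week(
                stream,
                self.thresholds,
                self.nonwear_rule,
                validity,
                self.bout_rule,
            )
            valid_days = sum(s.is_valid_day for s in summaries)
            row = {
                "participant_id": stream.participant_id,
                "n_days": stream.n_days,
                "valid_days": valid_days,
                "wear_minutes_week": sum(s.wear_minutes for s in summaries),
                "sedentary_minutes_week": sum(s.sedentary_minutes for s in summaries),
                "valid_participant": valid_days >= validity.min_valid_days,
            }
            try:
                weekly = weekly_met_minutes(
                    summaries, met=self.met, normalization=self.normalization
                )
                row.update(
                    met_at=weekly.met_minutes_at,
                    met_ab=weekly.met_minutes_ab,
                    meets_at=weekly.meets_at,
                    meets_ab=weekly.meets_ab,
                )
            except NoValidDaysError:
                row.update(
                    met_at=np.nan, met_ab=np.nan, meets_at=False, meets_ab=False
                )
            rows.append(row)
        columns = [
            "participant_id",
            "n_days",
            "valid_days",
            "wear_minutes_week",
            "sedentary_minutes_week",
            "valid_participant",
            "met_at",
            "met_ab",
            "meets_at",
            "meets_ab",
        ]
        return pd.DataFrame(rows, columns=columns)

    def daily_frame(self, X: Sequence[CountStream]) -> pd.DataFrame:
        """Per-(participant, day) summary table."""
        rows = []
        for stream in X:
            for s in summarize_week(
                stream,
                self.thresholds,
                self.nonwear_rule,
                self.validity,
                self.bout_rule,
            ):
                rows.append(
                    {
                        "participant_id": stream.participant_id,
                        "day_index": s.day_index,
                        "wear_minutes": s.wear_minutes,
                        "sedentary_minutes": s.sedentary_minutes,
                        "light_minutes": s.light_minutes,
                        "moderate_minutes": s.moderate_minutes,
                        "vigorous_minutes": s.vigorous_minutes,
                        "n_bouts": len(s.bouts),
                        "bout_moderate_minutes": s.bout_moderate_minutes,
                        "bout_vigorous_minutes": s.bout_vigorous_minutes,
                        "is_valid_day": s.is_valid_day,
                    }
                )
        return pd.DataFrame(rows)
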