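"""Analysis constants and YAML-backed configuration.

All defaults are the hip-worn ActiGraph minute-epoch conventions used by the
study this package implements: Troiano-style counts-per-minute (CPM) intensity
cutpoints, the 60-minute zero-count non-wear rule with a <2-minute sub-100 CPM
tolerance, the 10 hours/day x 4 days/week wear-validity rule, 10-minute MVPA
bouts with <2-minute interruptions, and the 600 MET-minutes/week guideline with
moderate activity at 4 METs and vigorous at 8 METs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

MINUTES_PER_DAY = 1440
MAX_DAYS = 7


class ConfigError(ValueError):
    """A configuration object violates one or more of its invariants.

    ``fields`` lists the offending field names.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = list(fields or [])


@dataclass(frozen=True)
class IntensityThresholds:
    """CPM cutpoints for sedentary / light / moderate / vigorous minutes.

    Sedentary is CPM < ``sedentary_below``; moderate is
    ``moderate_low`` <= CPM <= ``moderate_high``; vigorous is
    CPM >= ``vigorous_low``.  The unnamed 100-1999 CPM band is light.
    """

    sedentary_below: int = 100
    moderate_low: int = 2000
    moderate_high: int = 5998
    vigorous_low: int = 5999

    def __post_init__(self) -> None:
        bad = []
        if not self.sedentary_below < self.moderate_low <= self.moderate_high:
            bad += ["sedentary_below", "moderate_low", "moderate_high"]
        if self.vigorous_low != self.moderate_high + 1:
            bad += ["vigorous_low"]
        if bad:
            raise ConfigError(
                "cutpoints must satisfy sedentary_below < moderate_low <= "
                "moderate_high and vigorous_low == moderate_high + 1",
                fields=bad,
            )


@dataclass(frozen=True)
class NonWearRule:
    """Zero-count run rule for device-off detection.

    A maximal window of zero-CPM minutes of length >= ``min_zero_run``
    (strictly greater if ``strict_gt``) is non-wear; runs of minutes with
    0 < CPM < ``tolerance_cpm_below`` shorter than ``tolerance_max_run``
    (an exclusive bound, i.e. at most one whole minute) inside the window
    are tolerated and absorbed into it.
    """

    min_zero_run: int = 60
    tolerance_cpm_below: int = 100
    tolerance_max_run: int = 2
    strict_gt: bool = False

    def __post_init__(self) -> None:
        bad = [
            f
            for f in ("min_zero_run", "tolerance_cpm_below", "tolerance_max_run")
            if getattr(self, f) <= 0
        ]
        if bad:
            raise ConfigError("non-wear rule fields must be positive", fields=bad)


@dataclass(frozen=True)
class ValidityRule:
    """Minimum wear time for a valid day and minimum valid days per week."""

    min_wear_minutes_per_day: int = 600
    min_valid_days: int = 4

    def __post_init__(self) -> None:
        bad = []
        if not 0 < self.min_wear_minutes_per_day <= MINUTES_PER_DAY:
            bad.append("min_wear_minutes_per_day")
        if not 1 <= self.min_valid_days <= MAX_DAYS:
            bad.append("min_valid_days")
        if bad:
            raise ConfigError("invalid wear-validity rule", fields=bad)


@dataclass(frozen=True)
class BoutRule:
    """Sustained-MVPA bout rule: span >= ``min_span`` minutes, tolerating
    interior sub-MVPA runs shorter than ``max_interruption`` minutes
    (exclusive bound)."""

    min_span: int = 10
    max_interruption: int = 2

    def __post_init__(self) -> None:
        bad = [f for f in ("min_span", "max_interruption") if getattr(self, f) <= 0]
        if bad:
            raise ConfigError("bout rule fields must be positive", fields=bad)


@dataclass(frozen=True)
class METWeights:
    """MET weighting of intensity minutes and the weekly guideline threshold.

    One vigorous minute counts as two moderate minutes (8 vs 4 METs); the
    guideline is met at >= 600 MET-minutes/week.
    """

    moderate: float = 4.0
    vigorous: float = 8.0
    guideline_met_minutes: float = 600.0

    def __post_init__(self) -> None:
        bad = [
            f
            for f in ("moderate", "vigorous", "guideline_met_minutes")
            if getattr(self, f) <= 0
        ]
        if bad:
            raise ConfigError("MET weights must be positive", fields=bad)


@dataclass(frozen=True)
class EQ5DOptions:
    """Scoring conventions for the EQ-5D-3L index.

    ``literal_formula`` subtracts the tariff constant unconditionally (so
    perfect health scores 1 - constant); the default applies it only when at
    least one dimension exceeds level 1, the standard valuation convention
    under which 11111 scores exactly 1.0.  ``tie_to_high`` sends an index
    exactly equal to the cohort mean to the high-QoL group.
    """

    literal_formula: bool = False
    tie_to_high: bool = True


# "mean7": weekly MET-minutes = mean over valid days x 7 (default);
# "sum": raw sum over valid days.
WEEKLY_NORMALIZATIONS = ("mean7", "sum")


@dataclass
class AnalysisConfig:
    """Bundle of every tunable rule of the analysis, YAML round-trippable."""

    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)
    nonwear: NonWearRule = field(default_factory=NonWearRule)
    validity: ValidityRule = field(default_factory=ValidityRule)
    bout: BoutRule = field(default_factory=BoutRule)
    met: METWeights = field(default_factory=METWeights)
    eq5d: EQ5DOptions = field(default_factory=EQ5DOptions)
    weekly_normalization: str = "mean7"

    def __post_init__(self) -> None:
        if self.weekly_normalization not in WEEKLY_NORMALIZATIONS:
            raise ConfigError(
                f"weekly_normalization must be one of {WEEKLY_NORMALIZATIONS}",
                fields=["weekly_normalization"],
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "thresholds": IntensityThresholds,
            "nonwear": NonWearRule,
            "validity": ValidityRule,
            "bout": BoutRule,
            "met": METWeights,
            "eq5d": EQ5DOptions,
        }
        for name, klass in sections.items():
            if name in d:
                kwargs[name] = klass(**d[name])
        if "weekly_normalization" in d:
            kwargs["weekly_normalization"] = d["weekly_normalization"]
        return cls(**kwargs)


def default_config() -> AnalysisConfig:
    """The study's published constants."""
    return AnalysisConfig()


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file (missing sections
    fall back to the published defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return AnalysisConfig.from_dict(data)


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
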