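"""End-to-end analysis orchestration.

Applies the enrollment exclusion cascade, builds the analysis-ready
participant table (accelerometer exposures, GPAQ exposure, EQ-5D index and
mean-split QoL label), and produces the three study tables:

* Table 1 - baseline characteristics by QoL group with t / chi-square
  p-values;
* Table 2 - guideline compliance counts by QoL group with chi-square
  p-values;
* Table 3 - crude, socioeconomic-adjusted (Model 1) and mental-health-
  adjusted (Model 2) odds ratios of high QoL per exposure definition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .actigraphy import AccelerometerSummarizer, CountStream
from .config import AnalysisConfig, default_config
from .eq5d import RESPONSE_COLUMNS, EQ5DIndexScorer, MeanSplitBinarizer
from .gpaq import GPAQScorer
from .inference import (
    MODEL1_COVARIATES,
    MODEL2_COVARIATES,
    ContingencyTable2x2,
    LogisticModelSpec,
    chi_square_independence,
    fit_logistic,
    odds_ratio,
    two_sample_t,
)

#: Exclusion cascade steps in enrollment order; a participant is attributed
#: to the first step it matches.
EXCLUSION_STEPS = (
    "device_lost",
    "nonwearer",
    "mechanical_error",
    "insufficient_wear",
    "missing_eq5d",
    "pregnancy",
    "cancer_treatment",
    "arthritis",
)


@dataclass
class ExclusionReport:
    """Counts removed at each cascade step, conserving the total."""

    initial_n: int
    steps: list[tuple[str, int]]
    final_n: int

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.steps)
        if self.initial_n - removed != self.final_n:
            raise ValueError("exclusion counts do not conserve the total")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "enrolled", "removed": 0, "remaining": self.initial_n}]
        remaining = self.initial_n
        for step, n in self.steps:
            remaining -= n
            rows.append({"step": step, "removed": n, "remaining": remaining})
        return pd.DataFrame(rows)


def apply_exclusions(
    participants: pd.DataFrame,
    wear_valid: Mapping[str, bool] | pd.Series,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the enrollment exclusion cascade, in order.

    ``wear_valid`` maps participant id to the wear-validity flag (at least
    10 hours on at least 4 days); ids absent from the mapping are treated as
    wear-invalid.  Each participant is counted at the first step it matches.
    Returns the analytic subset and the step-by-step report.
    """
    df = participants.reset_index(drop=True)
    if isinstance(wear_valid, pd.Series):
        wear_valid = wear_valid.to_dict()
    valid = df["participant_id"].map(lambda i: bool(wear_valid.get(i, False)))
    eq5d_missing = df[list(RESPONSE_COLUMNS)].isna().any(axis=1)
    status = df.get(
        "accelerometer_status", pd.Series("ok", index=df.index)
    )
    conditions = {
        "device_lost": (status == "lost"),
        "nonwearer": (status == "nonwearer"),
        "mechanical_error": (status == "mechanical_error"),
        "insufficient_wear": ~valid,
        "missing_eq5d": eq5d_missing,
        "pregnancy": df.get("pregnancy", False),
        "cancer_treatment": df.get("cancer_treatment", False),
        "arthritis": df.get("arthritis", False),
    }
    excluded = np.zeros(len(df), dtype=bool)
    steps = []
    for step in EXCLUSION_STEPS:
        cond = np.asarray(conditions[step], dtype=bool) & ~excluded
        steps.append((step, int(cond.sum())))
        excluded |= cond
    analytic = df.loc[~excluded].reset_index(drop=True)
    report = ExclusionReport(
        initial_n=len(df), steps=steps, final_n=len(analytic)
    )
    return analytic, report


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: (variable, kind, ordered categories or None) rows of Table 1.
TABLE1_VARIABLES: list[tuple[str, str, tuple[str, ...] | None]] = [
    ("age", "continuous", None),
    ("sex", "categorical", ("male", "female")),
    ("marital_status", "categorical", ("single", "married", "separated_divorced_widowed")),
    ("education", "categorical", ("middle_school_or_less", "high_school", "college_or_more")),
    ("employment", "categorical", ("white_collar", "blue_collar", "unemployed")),
    ("income", "categorical", ("low", "high")),
    ("residence", "categorical", ("urban", "rural")),
    ("smoking", "categorical", ("nonsmoker", "past_smoker", "smoker")),
    ("alcohol", "categorical", ("abstainer", "adequate_drinker", "heavy_drinker")),
    ("sleep_hours", "continuous", None),
    ("stress", "categorical", ("little_stressful", "stressful")),
    ("subjective_health", "categorical", ("poor", "normal", "good")),
    ("cardiovascular_disease", "categorical", ("no", "yes")),
    ("diabetes", "categorical", ("no", "yes")),
    ("depression", "categorical", ("no", "yes")),
    ("sedentary_minutes_week", "continuous", None),
]

EXPOSURES = (
    ("meets_ab", "MVPA-AB (10 min bouts)"),
    ("meets_at", "MVPA-AT (total)"),
    ("meets_s", "MVPA-S (self-reported)"),
)


def _group_split(df: pd.DataFrame, label_col: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    low = df[df[label_col] == "low"]
    high = df[df[label_col] == "high"]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both QoL groups must be non-empty")
    return low, high


def build_table1(
    df: pd.DataFrame,
    label_col: str = "qol_label",
    variables: Sequence[tuple[str, str, tuple[str, ...] | None]] | None = None,
) -> pd.DataFrame:
    """Baseline characteristics by QoL group.

    Continuous variables report mean (SD) per group with a two-sample t
    p-value; categorical variables report n (%) per category with a
    chi-square p-value.
    """
    low, high = _group_split(df, label_col)
    variables = variables or [
        v for v in TABLE1_VARIABLES if v[0] in df.columns
    ]
    rows = []
    for name, kind, categories in variables:
        if kind == "continuous":
            t, _, p = two_sample_t(low[name], high[name])
            rows.append(
                {
                    "variable": name,
                    "category": "",
                    "low_stat": f"{low[name].mean():.2f} ({low[name].std(ddof=1):.2f})",
                    "high_stat": f"{high[name].mean():.2f} ({high[name].std(ddof=1):.2f})",
                    "low_value": float(low[name].mean()),
                    "high_value": float(high[name].mean()),
                    "p_value": p,
                }
            )
        else:
            counts = np.array(
                [
                    [int((g[name] == c).sum()) for c in categories]
                    for g in (low, high)
                ]
            )
            _, _, p = chi_square_independence(counts)
            for j, c in enumerate(categories):
                rows.append(
                    {
                        "variable": name,
                        "category": c,
                        "low_stat": f"{counts[0, j]} ({100 * counts[0, j] / len(low):.2f})",
                        "high_stat": f"{counts[1, j]} ({100 * counts[1, j] / len(high):.2f})",
                        "low_value": float(100 * counts[0, j] / len(low)),
                        "high_value": float(100 * counts[1, j] / len(high)),
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)


def build_table2(
    df: pd.DataFrame, label_col: str = "qol_label"
) -> pd.DataFrame:
    """Guideline compliance counts n (%) by QoL group per exposure, with
    chi-square p-values."""
    low, high = _group_split(df, label_col)
    rows = []
    for col, name in EXPOSURES:
        if col not in df.columns:
            continue
        table = ContingencyTable2x2.from_labels(
            exposed=df[col], outcome_high=(df[label_col] == "high")
        )
        _, _, p = chi_square_independence(table)
        for flag, tag in ((False, "<600 METs"), (True, ">=600 METs")):
            nl = int((low[col] == flag).sum())
            nh = int((high[col] == flag).sum())
            rows.append(
                {
                    "exposure": name,
                    "stratum": tag,
                    "low_n": nl,
                    "low_pct": 100 * nl / len(low),
                    "high_n": nh,
                    "high_pct": 100 * nh / len(high),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def build_table3(
    df: pd.DataFrame,
    label_col: str = "qol_label",
    model1_covariates: Sequence[str] = tuple(MODEL1_COVARIATES),
    model2_covariates: Sequence[str] = tuple(MODEL2_COVARIATES),
) -> pd.DataFrame:
    """Odds-ratio table: crude, Model 1, Model 2 per exposure definition.

    The outcome is high QoL; crude cells equal the 2x2 odds ratio of the
    corresponding compliance table, and the adjusted cells come from the
    maximum-likelihood logistic fits.
    """
    rows = []
    for col, name in EXPOSURES:
        if col not in df.columns:
            continue
        exposed = df[col].astype(bool)
        if exposed.all() or (~exposed).all():
            raise ValueError(f"empty exposure stratum for {col}")
        crude = odds_ratio(
            ContingencyTable2x2.from_labels(
                exposed=exposed, outcome_high=(df[label_col] == "high")
            )
        )
        fits = {}
        for model, covs in (("model1", model1_covariates), ("model2", model2_covariates)):
            spec = LogisticModelSpec(
                outcome=label_col, exposure=col, covariates=list(covs)
            )
            fits[model] = fit_logistic(spec, df).exposure_or()
        rows.append(
            {
                "exposure": name,
                "n_unexposed": int((~exposed).sum()),
                "n_exposed": int(exposed.sum()),
                "crude_or": crude.odds_ratio,
                "crude_ci_low": crude.ci_low,
                "crude_ci_high": crude.ci_high,
                "model1_or": fits["model1"][0],
                "model1_ci_low": fits["model1"][1],
                "model1_ci_high": fits["model1"][2],
                "model2_or": fits["model2"][0],
                "model2_ci_low": fits["model2"][1],
                "model2_ci_high": fits["model2"][2],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """Everything the end-to-end analysis produces."""

    weekly: pd.DataFrame
    analytic: pd.DataFrame
    exclusion_report: ExclusionReport
    mean_index: float
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def run_study(
    participants: pd.DataFrame,
    streams: Sequence[CountStream],
    config: AnalysisConfig | None = None,
    build_tables: bool = True,
) -> StudyResult:
    """Run the full analysis on a participant table and its epoch streams.

    Processes the streams to weekly exposures, applies the exclusion
    cascade, scores GPAQ and the EQ-5D index, dichotomizes the index at the
    analytic-sample mean, and (optionally) builds Tables 1-3.
    """
    cfg = config or default_config()
    summarizer = AccelerometerSummarizer(
        thresholds=cfg.thresholds,
        nonwear_rule=cfg.nonwear,
        validity=cfg.validity,
        bout_rule=cfg.bout,
        met=cfg.met,
        normalization=cfg.weekly_normalization,
    )
    weekly = summarizer.transform(streams)
    analytic, report = apply_exclusions(
        participants,
        weekly.set_index("participant_id")["valid_participant"],
    )
    analytic = analytic.merge(
        weekly.drop(columns=["valid_participant"]), on="participant_id", how="left"
    )
    analytic = GPAQScorer(met=cfg.met).transform(analytic)
    scorer = EQ5DIndexScorer(literal_formula=cfg.eq5d.literal_formula)
    analytic["eq5d_index"] = scorer.transform(analytic)
    binarizer = MeanSplitBinarizer(tie_to_high=cfg.eq5d.tie_to_high).fit(
        analytic["eq5d_index"]
    )
    analytic["qol_label"] = binarizer.transform(analytic["eq5d_index"])
    result = StudyResult(
        weekly=weekly,
        analytic=analytic,
        exclusion_report=report,
        mean_index=binarizer.mean_,
        table1=pd.DataFrame(),
        table2=pd.DataFrame(),
        table3=pd.DataFrame(),
    )
    if build_tables:
        result.table1 = build_table1(analytic)
        result.table2 = build_table2(analytic)
        result.table3 = build_table3(analytic)
    return result


def parameter_recovery(
    n_replicates: int,
    seed: int,
    n_participants: int = 1298,
    covariates: Sequence[str] = tuple(MODEL2_COVARIATES),
    **config_kwargs,
) -> dict:
    """Simulation study of exposure-OR recovery through the full pipeline.

    For each replicate, generates a synthetic cohort whose true conditional
    odds ratio of high QoL for bout-qualified compliance is the generator
    default (1.55), runs the complete epoch-to-tables pipeline, fits the
    adjusted logistic model, and records whether the Wald 95% CI covers the
    generating value.  Returns the observed coverage, the mean recovered OR,
    and the per-replicate estimates.
    """
    from .simulate import CohortConfig, simulate_cohort

    ors = []
    hits = 0
    true_or = None
    for r in range(n_replicates):
        cfg = CohortConfig(
            n_participants=n_participants, seed=int(seed) + r, **config_kwargs
        )
        true_or = math.exp(cfg.true_exposure_log_or)
        cohort = simulate_cohort(cfg)
        result = run_study(
            cohort.participants, cohort.streams, build_tables=False
        )
        spec = LogisticModelSpec(
            outcome="qol_label", exposure="meets_ab", covariates=list(covariates)
        )
        est, lo, hi = fit_logistic(spec, result.analytic).exposure_or()
        ors.append(est)
        hits += int(lo <= true_or <= hi)
    return {
        "true_or": true_or,
        "coverage": hits / n_replicates,
        "mean_or": float(np.mean(ors)),
        "ors": ors,
    }
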