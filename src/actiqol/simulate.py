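"""Synthetic cohort generation.

Generates cohorts with the statistical structure the analysis assumes:
minute-epoch CPM streams with a diurnal wear window, device-off gaps,
sustained MVPA bouts, and short fragmented MVPA spells; EQ-5D-3L responses
causally linked to bout-qualified guideline compliance; GPAQ self-report with
noisy, over-report-biased recall; and the socio-demographic covariates of the
descriptive table.  Every stage of the pipeline is therefore testable without
any external data.

The generative model, per participant:

1. Covariates are drawn from the marginal distributions of the high-QoL
   column of the descriptive table.
2. A latent *active* class (base prevalence ~0.226, the compliance prevalence
   of the study sample) receives enough qualifying bouts per week to exceed
   600 MET-minutes; the inactive class gets a sparse Poisson trickle of bouts.
   Everyone gets fragmented 1-9 minute MVPA spells, calibrated so that the
   total-MVPA (AT) compliance prevalence lands near the study's ~0.59.
3. High QoL is Bernoulli with logit = alpha + log(1.55) x meets_AB +
   covariate effects; alpha is solved so the cohort prevalence of high QoL
   matches the study's 1005/1298.  Because compliance flags are computed from
   the *planned* bout arithmetic (which the epoch painter reproduces
   exactly), the generating exposure effect is recoverable downstream.
4. EQ-5D responses are drawn so that the two latent classes are separated by
   the mean-split: high-QoL states are perfect or carry a single mild
   level-2 complaint, low-QoL states carry at least one level-3 dimension.
5. GPAQ MET-minutes are the participant's true total-MVPA MET-minutes plus a
   floor, scaled by a heavy-tailed log-normal reporting multiplier, then
   split across the occupation / commuting / leisure domains.

Streams are painted so that the wear/non-wear and bout structure recovered by
the actigraphy module equals the planned ground truth exactly: planned gaps
are flanked by forced light minutes so zero-runs cannot leak across wear
boundaries, and MVPA events are separated by at least two sub-MVPA minutes so
they never merge.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .actigraphy import CountStream
from .config import MINUTES_PER_DAY, ConfigError

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Default covariate effects (log-odds of high QoL) mirroring the direction
#: and rough magnitude of the group differences in the descriptive table.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_per_year": -0.012,
    "sex_female": -0.35,
    "marital_separated": -0.55,
    "education_college": 0.20,
    "income_high": 0.25,
    "stress_stressful": -0.90,
    "health_poor": -1.50,
    "health_good": 0.80,
    "depression": -1.20,
}

_EFFECT_TERMS = set(DEFAULT_COVARIATE_EFFECTS)

#: Covariate marginals: the high-QoL column of the descriptive table.
_MARGINALS = {
    "sex": (("male", "female"), (0.4060, 0.5940)),
    "marital_status": (
        ("single", "married", "separated_divorced_widowed"),
        (0.2151, 0.7371, 0.0478),
    ),
    "education": (
        ("middle_school_or_less", "high_school", "college_or_more"),
        (0.1383, 0.4080, 0.4537),
    ),
    "employment": (
        ("white_collar", "blue_collar", "unemployed"),
        (0.3380, 0.3599, 0.3021),
    ),
    "income": (("low", "high"), (0.2951, 0.7049)),
    "residence": (("urban", "rural"), (0.8279, 0.1721)),
    "smoking": (
        ("nonsmoker", "past_smoker", "smoker"),
        (0.6985, 0.1502, 0.1513),
    ),
    "alcohol": (
        ("abstainer", "adequate_drinker", "heavy_drinker"),
        (0.2328, 0.6607, 0.1065),
    ),
    "stress": (("little_stressful", "stressful"), (0.7841, 0.2159)),
    "subjective_health": (("poor", "normal", "good"), (0.0786, 0.5423, 0.3791)),
    "cardiovascular_disease": (("no", "yes"), (0.9891, 0.0109)),
    "diabetes": (("no", "yes"), (0.9632, 0.0368)),
    "depression": (("no", "yes"), (0.9741, 0.0259)),
}

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "marital_status",
    "education",
    "employment",
    "income",
    "residence",
    "smoking",
    "alcohol",
    "sleep_hours",
    "stress",
    "subjective_health",
    "cardiovascular_disease",
    "diabetes",
    "depression",
    "pregnancy",
    "cancer_treatment",
    "arthritis",
    "accelerometer_status",
    "mo",
    "sc",
    "ua",
    "pd",
    "ad",
    "gpaq_occ_mod",
    "gpaq_occ_vig",
    "gpaq_commute",
    "gpaq_leis_mod",
    "gpaq_leis_vig",
]

GROUND_TRUTH_COLUMNS = [
    "participant_id",
    "active",
    "met_ab_true",
    "met_at_true",
    "met_at_raw",
    "meets_ab_true",
    "meets_at_true",
    "valid_days_true",
    "p_high_qol",
    "high_qol_true",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions: n = 1298 analyzable adults, 7
    recording days, ~14 h/day of wear, bout-compliance prevalence ~0.226,
    total-MVPA compliance ~0.59, high-QoL prevalence 1005/1298, and a true
    conditional exposure odds ratio of 1.55 for bout compliance.
    """

    n_participants: int = 1298
    seed: int = 0
    days: int = 7
    # wear schedule (minutes)
    wear_start_mean: float = 420.0
    wear_start_sd: float = 60.0
    wear_length_mean: float = 840.0
    wear_length_sd: float = 90.0
    short_wear_length_mean: float = 480.0
    short_wear_length_sd: float = 90.0
    nonwear_gap_rate: float = 0.3  # >=60-min device-off gaps per day
    nonwear_gap_min: int = 60
    nonwear_gap_max: int = 120
    # activity structure
    p_active: float = 0.2257
    active_weekly_met_min: float = 700.0
    active_weekly_met_max: float = 2000.0
    inactive_bout_rate: float = 0.7  # qualifying bouts per week
    bout_len_min: int = 10
    bout_len_max: int = 40
    bout_vig_alpha: float = 1.0
    bout_vig_beta: float = 6.0
    bout_interruption_prob: float = 0.3
    spell_rate_per_day: float = 3.65  # fragmented 1-9 min MVPA spells
    spell_len_min: int = 1
    spell_len_max: int = 9
    background_sedentary_prob: float = 0.57
    sedentary_zero_prob: float = 0.30
    # outcome model
    true_exposure_log_or: float = math.log(1.55)
    target_high_prevalence: float = 1005 / 1298
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    exposure_confounding: dict[str, float] = field(default_factory=dict)
    # EQ-5D response model
    p_minor_complaint_high: float = 0.20
    # GPAQ self-report model
    gpaq_base_met: float = 80.0
    gpaq_log_bias: float = -0.20
    gpaq_log_sd: float = 0.8
    # enrollment emulation (exclusion-cascade structure); all off by default,
    # i.e. the cohort emulates the analyzable sample directly
    emulate_enrollment: bool = False
    p_device_lost: float = 9 / 1827
    p_nonwearer: float = 47 / 1827
    p_mechanical_error: float = 3 / 1827
    p_poor_wear: float = 342 / 1768
    p_eq5d_missing: float = 8 / 1426
    p_pregnancy: float = 2 / 1418
    p_cancer_treatment: float = 24 / 1416
    p_arthritis: float = 94 / 1392

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_participants < 0:
            bad.append("n_participants")
        if not 1 <= self.days <= 7:
            bad.append("days")
        for f in (
            "wear_start_sd",
            "wear_length_sd",
            "short_wear_length_sd",
            "gpaq_log_sd",
        ):
            if getattr(self, f) <= 0:
                bad.append(f)
        for f in (
            "nonwear_gap_rate",
            "inactive_bout_rate",
            "spell_rate_per_day",
            "gpaq_base_met",
        ):
            if getattr(self, f) < 0:
                bad.append(f)
        for f in (
            "p_active",
            "p_minor_complaint_high",
            "target_high_prevalence",
            "background_sedentary_prob",
            "sedentary_zero_prob",
            "p_device_lost",
            "p_nonwearer",
            "p_mechanical_error",
            "p_poor_wear",
            "p_eq5d_missing",
            "p_pregnancy",
            "p_cancer_treatment",
            "p_arthritis",
        ):
            if not 0 <= getattr(self, f) <= 1:
                bad.append(f)
        if not 10 <= self.bout_len_min <= self.bout_len_max:
            bad.append("bout_len_min")
        if not 1 <= self.spell_len_min <= self.spell_len_max <= 9:
            bad.append("spell_len_min")
        if not 60 <= self.nonwear_gap_min <= self.nonwear_gap_max:
            bad.append("nonwear_gap_min")
        if self.active_weekly_met_min > self.active_weekly_met_max:
            bad.append("active_weekly_met_min")
        for key in list(self.covariate_effects) + list(self.exposure_confounding):
            if key not in _EFFECT_TERMS:
                bad.append(f"covariate_effects[{key}]")
        if bad:
            raise ConfigError(
                f"invalid cohort configuration: {', '.join(sorted(set(bad)))}",
                fields=sorted(set(bad)),
            )


@dataclass
class Cohort:
    """A simulated cohort: participant table, epoch streams, ground truth."""

    participants: pd.DataFrame
    streams: list[CountStream]
    ground_truth: pd.DataFrame
    config: CohortConfig
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Week planning
# ---------------------------------------------------------------------------


@dataclass
class _BoutPlan:
    start: int
    length: int
    n_interruption: int
    vig_minutes: int

    @property
    def mvpa_minutes(self) -> int:
        return self.length - self.n_interruption

    @property
    def mod_minutes(self) -> int:
        return self.mvpa_minutes - self.vig_minutes

    @property
    def met(self) -> float:
        return 4.0 * self.mod_minutes + 8.0 * self.vig_minutes


@dataclass
class _DayPlan:
    wear_start: int
    wear_end: int  # exclusive
    gaps: list[tuple[int, int]] = field(default_factory=list)  # (start, length)
    bouts: list[_BoutPlan] = field(default_factory=list)
    spells: list[tuple[int, int]] = field(default_factory=list)

    @property
    def wear_minutes(self) -> int:
        return self.wear_end - self.wear_start - sum(g[1] for g in self.gaps)

    @property
    def met_ab(self) -> float:
        return sum(b.met for b in self.bouts)

    @property
    def met_at(self) -> float:
        return self.met_ab + 4.0 * sum(s[1] for s in self.spells)


def _overlaps(s: int, e: int, occupied: list[tuple[int, int, int]]) -> bool:
    return any(not (e < os - sep or s > oe + sep) for os, oe, sep in occupied)


def _try_place(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    length: int,
    occupied: list[tuple[int, int, int]],
    sep: int,
    tries: int = 20,
) -> int | None:
    """Place an interval of ``length`` minutes within [lo, hi) keeping at
    least ``sep`` minutes from every occupied interval; returns the start or
    None."""
    top = hi - length
    if top < lo:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, top + 1))
        if not _overlaps(s, s + length - 1, occupied):
            occupied.append((s, s + length - 1, sep))
            return s
    return None


def _plan_week(
    rng: np.random.Generator, active: bool, poor_wear: bool, cfg: CohortConfig
) -> list[_DayPlan]:
    days: list[_DayPlan] = []
    occupied: list[list[tuple[int, int, int]]] = []
    for _ in range(cfg.days):
        start = int(np.clip(rng.normal(cfg.wear_start_mean, cfg.wear_start_sd), 60, 600))
        mean_len = cfg.short_wear_length_mean if poor_wear else cfg.wear_length_mean
        sd_len = cfg.short_wear_length_sd if poor_wear else cfg.wear_length_sd
        length = int(
            np.clip(rng.normal(mean_len, sd_len), 180, MINUTES_PER_DAY - 60 - start)
        )
        plan = _DayPlan(wear_start=start, wear_end=start + length)
        occ: list[tuple[int, int, int]] = []
        n_gaps = int(rng.poisson(cfg.nonwear_gap_rate))
        for _ in range(n_gaps):
            glen = int(rng.integers(cfg.nonwear_gap_min, cfg.nonwear_gap_max + 1))
            s = _try_place(
                rng, start + 3, plan.wear_end - 3, glen, occ, sep=5
            )
            if s is not None:
                plan.gaps.append((s, glen))
        days.append(plan)
        occupied.append(occ)

    def place_bout(length: int, n_int: int, vig: int) -> bool:
        d = int(rng.integers(0, cfg.days))
        plan = days[d]
        s = _try_place(
            rng,
            plan.wear_start + 2,
            plan.wear_end - 2,
            length,
            occupied[d],
            sep=2,
        )
        if s is None:
            return False
        plan.bouts.append(
            _BoutPlan(start=s, length=length, n_interruption=n_int, vig_minutes=vig)
        )
        return True

    def draw_bout() -> tuple[int, int, int]:
        length = int(rng.integers(cfg.bout_len_min, cfg.bout_len_max + 1))
        n_int = int(
            length >= 12 and rng.random() < cfg.bout_interruption_prob
        )
        mvpa = length - n_int
        vig = int(round(rng.beta(cfg.bout_vig_alpha, cfg.bout_vig_beta) * mvpa))
        return length, n_int, vig

    if active:
        target = rng.uniform(cfg.active_weekly_met_min, cfg.active_weekly_met_max)
        total = 0.0
        for _ in range(60):
            if total >= target:
                break
            length, n_int, vig = draw_bout()
            if place_bout(length, n_int, vig):
                total += 4.0 * (length - n_int - vig) + 8.0 * vig
    else:
        for _ in range(int(rng.poisson(cfg.inactive_bout_rate))):
            length, n_int, vig = draw_bout()
            place_bout(length, n_int, vig)

    for d, plan in enumerate(days):
        for _ in range(int(rng.poisson(cfg.spell_rate_per_day))):
            slen = int(rng.integers(cfg.spell_len_min, cfg.spell_len_max + 1))
            s = _try_place(
                rng,
                plan.wear_start + 2,
                plan.wear_end - 2,
                slen,
                occupied[d],
                sep=2,
            )
            if s is not None:
                plan.spells.append((s, slen))
    return days


def _weekly_truth(
    days: list[_DayPlan], min_wear: int = 600, min_valid: int = 4
) -> dict:
    valid = [d for d in days if d.wear_minutes >= min_wear]
    raw_at = sum(d.met_at for d in days)
    if valid:
        met_ab = float(np.mean([d.met_ab for d in valid]) * 7)
        met_at = float(np.mean([d.met_at for d in valid]) * 7)
    else:
        met_ab = met_at = float("nan")
    return {
        "met_ab_true": met_ab,
        "met_at_true": met_at,
        "met_at_raw": float(raw_at),
        "meets_ab_true": bool(met_ab >= 600) if valid else False,
        "meets_at_true": bool(met_at >= 600) if valid else False,
        "valid_days_true": len(valid),
    }


# ---------------------------------------------------------------------------
# Epoch painting
# ---------------------------------------------------------------------------


def _band(
    rng: np.random.Generator, size: int, lo: int, hi: int, spread: float = 0.5
) -> np.ndarray:
    """Discretized log-normal CPM draws clipped to [lo, hi]."""
    if size == 0:
        return np.empty(0, dtype=np.int64)
    mu = math.log(lo + 0.3 * (hi - lo + 1))
    return np.clip(
        np.round(np.exp(rng.normal(mu, spread, size))), lo, hi
    ).astype(np.int64)


def _paint_stream(
    rng: np.random.Generator,
    participant_id: str,
    days: list[_DayPlan],
    cfg: CohortConfig,
    all_zero: bool = False,
) -> CountStream:
    mat = np.zeros((cfg.days, MINUTES_PER_DAY), dtype=np.int64)
    if all_zero:
        return CountStream(participant_id=participant_id, cpm=mat)
    for d, plan in enumerate(days):
        start, end = plan.wear_start, plan.wear_end
        m = end - start
        # background sedentary/light mixture over the wear window
        u = rng.random(m)
        sed = u < cfg.background_sedentary_prob
        vals = np.empty(m, dtype=np.int64)
        n_sed = int(sed.sum())
        sed_vals = np.where(
            rng.random(n_sed) < cfg.sedentary_zero_prob,
            0,
            rng.integers(1, 100, n_sed),
        )
        vals[sed] = sed_vals
        vals[~sed] = _band(rng, m - n_sed, 100, 1999)
        mat[d, start:end] = vals
        # forced light minutes at the wear-window edges and gap flanks keep
        # detected non-wear identical to the planned gaps
        forced = [start, start + 1, end - 2, end - 1]
        for gs, glen in plan.gaps:
            mat[d, gs : gs + glen] = 0
            forced += [gs - 2, gs - 1, gs + glen, gs + glen + 1]
        forced_idx = np.array(sorted(set(forced)), dtype=int)
        mat[d, forced_idx] = _band(rng, len(forced_idx), 100, 1999)
        # MVPA events
        for b in plan.bouts:
            idx = np.arange(b.start, b.start + b.length)
            if b.n_interruption:
                interrupt = b.start + b.length // 2
                mat[d, interrupt] = int(_band(rng, 1, 100, 1999)[0])
                idx = idx[idx != interrupt]
            vig_idx = rng.choice(idx, size=b.vig_minutes, replace=False)
            mod_idx = np.setdiff1d(idx, vig_idx)
            mat[d, mod_idx] = _band(rng, len(mod_idx), 2000, 5998)
            mat[d, vig_idx] = _band(rng, len(vig_idx), 5999, 15000)
        for s, slen in plan.spells:
            mat[d, s : s + slen] = _band(rng, slen, 2000, 5998)
    return CountStream(participant_id=participant_id, cpm=mat)


# ---------------------------------------------------------------------------
# Covariates and outcome
# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    data: dict[str, np.ndarray] = {}
    data["age"] = np.round(np.clip(rng.normal(43.18, 12.34, n), 19, 64))
    data["sleep_hours"] = np.round(np.clip(rng.normal(6.86, 1.18, n), 3, 12), 1)
    for name, (values, probs) in _MARGINALS.items():
        data[name] = rng.choice(values, size=n, p=probs)
    return pd.DataFrame(data)


def _effect_design(cov: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age_per_year": cov["age"].to_numpy(float) - 43.0,
        "sex_female": (cov["sex"] == "female").to_numpy(float),
        "marital_separated": (
            cov["marital_status"] == "separated_divorced_widowed"
        ).to_numpy(float),
        "education_college": (cov["education"] == "college_or_more").to_numpy(float),
        "income_high": (cov["income"] == "high").to_numpy(float),
        "stress_stressful": (cov["stress"] == "stressful").to_numpy(float),
        "health_poor": (cov["subjective_health"] == "poor").to_numpy(float),
        "health_good": (cov["subjective_health"] == "good").to_numpy(float),
        "depression": (cov["depression"] == "yes").to_numpy(float),
    }


def _linear_predictor(
    cov: pd.DataFrame, effects: dict[str, float]
) -> np.ndarray:
    design = _effect_design(cov)
    lp = np.zeros(len(cov))
    for term, coef in effects.items():
        lp += coef * design[term]
    return lp


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + lp)) == target."""

    def f(a: float) -> float:
        return float(np.mean(expit(a + lp)) - target)

    return float(brentq(f, -25.0, 25.0, xtol=1e-10))


def _draw_eq5d(
    rng: np.random.Generator, high: np.ndarray, p_minor: float
) -> np.ndarray:
    """Levels (n, 5): high-QoL states are perfect or carry one mild level-2
    complaint; low-QoL states carry 1-2 level-3 dimensions plus optional
    level-2 complaints, keeping the two groups separated by the mean split."""
    n = len(high)
    levels = np.ones((n, 5), dtype=np.int64)
    mild_dims = (1, 3, 4)  # self-care, pain/discomfort, anxiety/depression
    for i in range(n):
        if high[i]:
            if rng.random() < p_minor:
                levels[i, mild_dims[int(rng.integers(0, 3))]] = 2
        else:
            n3 = 1 if rng.random() < 0.7 else 2
            severe = rng.choice(5, size=n3, replace=False)
            levels[i, severe] = 3
            for d in range(5):
                if levels[i, d] == 1 and rng.random() < 0.5:
                    levels[i, d] = 2
    return levels


def _draw_gpaq(
    rng: np.random.Generator, met_at_raw: np.ndarray, cfg: CohortConfig
) -> pd.DataFrame:
    n = len(met_at_raw)
    mult = np.exp(rng.normal(cfg.gpaq_log_bias, cfg.gpaq_log_sd, n))
    total = (met_at_raw + cfg.gpaq_base_met) * mult
    vig_frac = rng.beta(1.0, 8.0, n)
    vig_min = total * vig_frac / 8.0
    mod_min = total * (1.0 - vig_frac) / 4.0
    shares = rng.dirichlet((1.0, 1.0, 1.0), n)
    occ_vig_share = rng.random(n)
    cap = 7 * MINUTES_PER_DAY
    out = pd.DataFrame(
        {
            "gpaq_occ_mod": mod_min * shares[:, 0],
            "gpaq_occ_vig": vig_min * occ_vig_share,
            "gpaq_commute": mod_min * shares[:, 1],
            "gpaq_leis_mod": mod_min * shares[:, 2],
            "gpaq_leis_vig": vig_min * (1.0 - occ_vig_share),
        }
    )
    return out.round().clip(0, cap).astype(float)


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a reproducible synthetic cohort.

    Returns a :class:`Cohort` with the participant table (covariates, EQ-5D
    responses, GPAQ minutes, exclusion flags), one :class:`CountStream` per
    participant, and the generating ground truth per participant.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    n = cfg.n_participants
    if n == 0:
        return Cohort(
            participants=pd.DataFrame(columns=PARTICIPANT_COLUMNS),
            streams=[],
            ground_truth=pd.DataFrame(columns=GROUND_TRUTH_COLUMNS),
            config=cfg,
        )

    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(n + 1)
    rng = np.random.default_rng(children[0])
    part_rngs = [np.random.default_rng(c) for c in children[1:]]

    ids = [f"p{i:05d}" for i in range(n)]
    cov = _draw_covariates(rng, n)

    # enrollment structure
    status = np.full(n, "ok", dtype=object)
    poor_wear = np.zeros(n, dtype=bool)
    eq5d_missing = np.zeros(n, dtype=bool)
    pregnancy = np.zeros(n, dtype=bool)
    cancer = np.zeros(n, dtype=bool)
    arthritis = np.zeros(n, dtype=bool)
    if cfg.emulate_enrollment:
        u = rng.random(n)
        status[u < cfg.p_device_lost] = "lost"
        status[(u >= cfg.p_device_lost) & (u < cfg.p_device_lost + cfg.p_nonwearer)] = (
            "nonwearer"
        )
        hi = cfg.p_device_lost + cfg.p_nonwearer + cfg.p_mechanical_error
        status[(u >= cfg.p_device_lost + cfg.p_nonwearer) & (u < hi)] = (
            "mechanical_error"
        )
        poor_wear = rng.random(n) < cfg.p_poor_wear
        eq5d_missing = rng.random(n) < cfg.p_eq5d_missing
        pregnancy = (cov["sex"] == "female").to_numpy() & (
            rng.random(n) < 2 * cfg.p_pregnancy
        )
        cancer = rng.random(n) < cfg.p_cancer_treatment
        arthritis = rng.random(n) < cfg.p_arthritis

    # exposure propensity, optionally confounded by covariates
    lp_active = logit(cfg.p_active) + _linear_predictor(cov, cfg.exposure_confounding)
    active = rng.random(n) < expit(lp_active)

    plans = [
        _plan_week(part_rngs[i], bool(active[i]), bool(poor_wear[i]), cfg)
        for i in range(n)
    ]
    truth_rows = [_weekly_truth(p) for p in plans]
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "participant_id", ids)
    truth.insert(1, "active", active)

    # outcome
    lp = cfg.true_exposure_log_or * truth["meets_ab_true"].to_numpy(
        float
    ) + _linear_predictor(cov, cfg.covariate_effects)
    alpha = _solve_intercept(lp, cfg.target_high_prevalence)
    p_high = expit(alpha + lp)
    high = rng.random(n) < p_high
    truth["p_high_qol"] = p_high
    truth["high_qol_true"] = high

    levels = _draw_eq5d(rng, high, cfg.p_minor_complaint_high).astype(float)
    levels[eq5d_missing] = np.nan

    gpaq = _draw_gpaq(rng, truth["met_at_raw"].to_numpy(float), cfg)

    participants = pd.concat(
        [
            pd.DataFrame({"participant_id": ids}),
            cov,
            pd.DataFrame(
                {
                    "pregnancy": pregnancy,
                    "cancer_treatment": cancer,
                    "arthritis": arthritis,
                    "accelerometer_status": status,
                }
            ),
            pd.DataFrame(levels, columns=["mo", "sc", "ua", "pd", "ad"]),
            gpaq,
        ],
        axis=1,
    )[PARTICIPANT_COLUMNS]

    streams = [
        _paint_stream(
            part_rngs[i],
            ids[i],
            plans[i],
            cfg,
            all_zero=(status[i] == "nonwearer"),
        )
        for i in range(n)
    ]
    return Cohort(
        participants=participants,
        streams=streams,
        ground_truth=truth[GROUND_TRUTH_COLUMNS],
        config=cfg,
        metadata={"alpha": alpha},
    )


# ---------------------------------------------------------------------------
# Edge-case injection
# ---------------------------------------------------------------------------


def _edge_base_day(
    start: int = 300, length: int = 840, cpm: int = 500
) -> np.ndarray:
    day = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    day[start : start + length] = cpm
    return day


def _edge_stream(
    participant_id: str, special: dict[int, Callable[[np.ndarray], None]], days: int = 7
) -> CountStream:
    mat = np.stack([_edge_base_day() for _ in range(days)])
    for d, fn in special.items():
        if d < days:
            fn(mat[d])
    return CountStream(participant_id=participant_id, cpm=mat)


def _edge_participants() -> list[dict]:
    """Hand-built boundary participants with their expected exposures."""

    def zero_run(length):
        def fn(day):
            day[600 : 600 + length] = 0

        return fn

    def zero_run_with_sub100(run1, sub, run2):
        def fn(day):
            day[600 : 600 + run1] = 0
            day[600 + run1 : 600 + run1 + sub] = 80
            day[600 + run1 + sub : 600 + run1 + sub + run2] = 0

        return fn

    def mvpa(length):
        def fn(day):
            day[700 : 700 + length] = 3000

        return fn

    def mvpa_interrupted(first, gap, second):
        def fn(day):
            day[700 : 700 + first] = 3000
            day[700 + first : 700 + first + gap] = 500
            day[700 + first + gap : 700 + first + gap + second] = 3000

        return fn

    def short_wear(day):
        day[:] = 0
        day[300:900] = 500  # exactly 600 wear minutes

    def no_wear(day):
        day[:] = 0

    cases = [
        {
            "id": "edge_4_valid_days",
            "special": {4: no_wear, 5: no_wear, 6: no_wear},
            "base": short_wear,
        },
        {"id": "edge_600_wear_each_day", "base": short_wear, "special": {}},
        {"id": "edge_zero_run_59", "special": {0: zero_run(59)}},
        {"id": "edge_zero_run_60", "special": {0: zero_run(60)}},
        {"id": "edge_zero_run_61", "special": {0: zero_run(61)}},
        {
            "id": "edge_interruption_1min",
            "special": {0: zero_run_with_sub100(40, 1, 40)},
        },
        {
            "id": "edge_interruption_2min",
            "special": {0: zero_run_with_sub100(40, 2, 40)},
        },
        {"id": "edge_bout_9min", "special": {0: mvpa(9)}},
        {"id": "edge_bout_10min", "special": {0: mvpa(10)}},
        {
            "id": "edge_bout_interrupt_1min",
            "special": {0: mvpa_interrupted(6, 1, 5)},
        },
        {
            "id": "edge_bout_interrupt_2min",
            "special": {0: mvpa_interrupted(6, 2, 5)},
        },
        {"id": "edge_eq5d_11111", "special": {}, "eq5d": (1, 1, 1, 1, 1)},
        {"id": "edge_eq5d_33333", "special": {}, "eq5d": (3, 3, 3, 3, 3)},
    ]
    return cases


def inject_edge_cases(cohort: Cohort) -> Cohort:
    """Append hand-built boundary participants to a simulated cohort.

    The appended streams exercise every rule boundary: the 4-valid-day and
    600-wear-minute validity thresholds, 59/60/61-minute zero runs, 1- and
    2-minute sub-100 CPM interruptions, 9- and 10-minute MVPA runs, bouts
    with 1- and 2-minute interruptions, and the extreme EQ-5D states.
    """
    cases = _edge_participants()
    part_rows = []
    truth_rows = []
    streams = list(cohort.streams)
    days = cohort.config.days
    for case in cases:
        base = case.get("base")
        if base is not None:
            mat = np.stack([_edge_base_day() for _ in range(days)])
            for d in range(days):
                base(mat[d])
            for d, fn in case["special"].items():
                if d < days:
                    fn(mat[d])
            stream = CountStream(participant_id=case["id"], cpm=mat)
        else:
            stream = _edge_stream(case["id"], case["special"], days)
        streams.append(stream)
        eq5d = case.get("eq5d", (1, 1, 1, 1, 1))
        row = {c: None for c in PARTICIPANT_COLUMNS}
        row.update(
            participant_id=case["id"],
            age=43.0,
            sex="male",
            marital_status="single",
            education="middle_school_or_less",
            employment="white_collar",
            income="low",
            residence="urban",
            smoking="nonsmoker",
            alcohol="abstainer",
            sleep_hours=7.0,
            stress="little_stressful",
            subjective_health="normal",
            cardiovascular_disease="no",
            diabetes="no",
            depression="no",
            pregnancy=False,
            cancer_treatment=False,
            arthritis=False,
            accelerometer_status="ok",
            mo=float(eq5d[0]),
            sc=float(eq5d[1]),
            ua=float(eq5d[2]),
            pd=float(eq5d[3]),
            ad=float(eq5d[4]),
            gpaq_occ_mod=0.0,
            gpaq_occ_vig=0.0,
            gpaq_commute=0.0,
            gpaq_leis_mod=0.0,
            gpaq_leis_vig=0.0,
        )
        part_rows.append(row)
        truth_rows.append(
            {
                "participant_id": case["id"],
                "active": False,
                "met_ab_true": np.nan,
                "met_at_true": np.nan,
                "met_at_raw": np.nan,
                "meets_ab_true": False,
                "meets_at_true": False,
                "valid_days_true": days,
                "p_high_qol": np.nan,
                "high_qol_true": True,
            }
        )
    new_parts = pd.DataFrame(part_rows)[PARTICIPANT_COLUMNS]
    new_truth = pd.DataFrame(truth_rows)[GROUND_TRUTH_COLUMNS]
    if len(cohort.participants):
        participants = pd.concat(
            [cohort.participants, new_parts], ignore_index=True
        )
        truth = pd.concat([cohort.ground_truth, new_truth], ignore_index=True)
    else:
        participants, truth = new_parts, new_truth
    return Cohort(
        participants=participants,
        streams=streams,
        ground_truth=truth,
        config=cohort.config,
        metadata=dict(cohort.metadata),
    )
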