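"""GPAQ self-reported physical activity scoring.

The Global Physical Activity Questionnaire records weekly minutes of
moderate and vigorous activity in three domains: occupation, commuting
(transport, moderate-weighted by convention), and leisure.  The same MET
weighting and guideline threshold as the accelerometer exposures apply::

    MET-minutes/week = 4 x (moderate + commuting minutes) + 8 x vigorous minutes
    meets guideline  <=> MET-minutes/week >= 600
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import METWeights

#: Participant-table column names, minutes/week per domain.
GPAQ_COLUMNS = (
    "gpaq_occ_mod",
    "gpaq_occ_vig",
    "gpaq_commute",
    "gpaq_leis_mod",
    "gpaq_leis_vig",
)

_MINUTES_CAP = 7 * 1440


class InvalidGPAQError(ValueError):
    """Negative or implausibly large GPAQ minutes."""


@dataclass(frozen=True)
class GPAQRecord:
    """Weekly minutes of self-reported activity per domain."""

    occupation_moderate: float = 0.0
    occupation_vigorous: float = 0.0
    commuting: float = 0.0
    leisure_moderate: float = 0.0
    leisure_vigorous: float = 0.0

    def __post_init__(self) -> None:
        bad = [
            name
            for name, v in vars(self).items()
            if v < 0 or v > _MINUTES_CAP
        ]
        if bad:
            raise InvalidGPAQError(
                f"minutes must be in [0, {_MINUTES_CAP}]: {', '.join(bad)}"
            )


@dataclass(frozen=True)
class GPAQResult:
    met_minutes: float
    meets: bool


def gpaq_met_minutes(
    record: GPAQRecord, met: METWeights | None = None
) -> GPAQResult:
    """Self-reported MET-minutes/week with the guideline compliance flag.

    Commuting minutes are weighted as moderate activity.
    """
    met = met or METWeights()
    moderate = (
        record.occupation_moderate + record.leisure_moderate + record.commuting
    )
    vigorous = record.occupation_vigorous + record.leisure_vigorous
    total = met.moderate * moderate + met.vigorous * vigorous
    return GPAQResult(met_minutes=total, meets=total >= met.guideline_met_minutes)


class GPAQScorer(BaseEstimator, TransformerMixin):
    """Transformer adding ``met_s`` / ``meets_s`` from GPAQ domain columns.

    ``transform`` accepts a DataFrame with the five domain columns (default
    names in :data:`GPAQ_COLUMNS`) and returns a copy with the self-reported
    exposure appended.
    """

    def __init__(
        self,
        columns: Sequence[str] = GPAQ_COLUMNS,
        met: METWeights | None = None,
    ):
        self.columns = columns
        self.met = met

    def fit(self, X, y=None) -> "GPAQScorer":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        met = self.met or METWeights()
        occ_mod, occ_vig, commute, leis_mod, leis_vig = (
            X[c].to_numpy(dtype=float) for c in self.columns
        )
        values = np.column_stack([occ_mod, occ_vig, commute, leis_mod, leis_vig])
        if (values < 0).any() or (values > _MINUTES_CAP).any():
            raise InvalidGPAQError(
                f"GPAQ minutes must be in [0, {_MINUTES_CAP}]"
            )
        total = met.moderate * (occ_mod + leis_mod + commute) + met.vigorous * (
            occ_vig + leis_vig
        )
        out = X.copy()
        out["met_s"] = total
        out["meets_s"] = total >= met.guideline_met_minutes
        return out
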