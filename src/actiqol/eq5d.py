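"""EQ-5D-3L scoring and mean-split dichotomization.

The EQ-5D-3L instrument records five dimensions (mobility, self-care, usual
activity, pain/discomfort, anxiety/depression) at three levels each.  A
national tariff converts a health state to a single utility index::

    index = 1 - (c * I[any level > 1]
                 + sum of level-2/level-3 decrements
                 + n3 * I[any level = 3])

The Korean tariff used here is c = 0.050, n3 = 0.050, with decrements
M2=0.096, M3=0.418, SC2=0.046, SC3=0.136, UA2=0.051, UA3=0.208, PD2=0.037,
PD3=0.151, AD2=0.043, AD3=0.158.  Under the default convention the constant
applies only when some dimension exceeds level 1, so perfect health (11111)
scores exactly 1.0; ``literal_formula=True`` subtracts the constant
unconditionally.

Health-related quality of life is dichotomized at the cohort mean index:
below the mean is low QoL, at or above the mean is high QoL.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activity",
    "pain_discomfort",
    "anxiety_depression",
)

#: Default participant-table column names for the five dimensions, in order.
RESPONSE_COLUMNS = ("mo", "sc", "ua", "pd", "ad")


class InvalidResponseError(ValueError):
    """An EQ-5D dimension level outside {1, 2, 3}."""


@dataclass(frozen=True)
class EQ5DTariff:
    """Decrement coefficients of an EQ-5D-3L value set.

    ``decrements`` maps each dimension to its (level-2, level-3) utility
    decrements; ``constant`` is subtracted for any departure from full
    health and ``n3`` for any dimension at level 3.
    """

    constant: float = 0.050
    n3: float = 0.050
    decrements: Mapping[str, tuple[float, float]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.decrements is None:
            object.__setattr__(self, "decrements", KOREAN_TARIFF.decrements)
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"tariff missing dimension {dim!r}")
            l2, l3 = self.decrements[dim]
            if l2 < 0 or l3 < 0:
                raise ValueError(f"negative decrement for {dim!r}")
            if l3 <= l2:
                raise ValueError(
                    f"level-3 decrement must exceed level-2 for {dim!r}"
                )


KOREAN_TARIFF = EQ5DTariff(
    constant=0.050,
    n3=0.050,
    decrements={
        "mobility": (0.096, 0.418),
        "self_care": (0.046, 0.136),
        "usual_activity": (0.051, 0.208),
        "pain_discomfort": (0.037, 0.151),
        "anxiety_depression": (0.043, 0.158),
    },
)


@dataclass(frozen=True)
class QoLLabel:
    """A scored index with its low/high label relative to the cohort mean."""

    index: float
    label: str


def _validate_levels(levels: np.ndarray) -> None:
    if levels.shape[-1] != 5:
        raise InvalidResponseError("a response has exactly 5 dimensions")
    if not np.isin(levels, (1, 2, 3)).all():
        raise InvalidResponseError("every dimension level must be 1, 2 or 3")


def eq5d_index(
    response: Sequence[int] | Mapping[str, int],
    tariff: EQ5DTariff = KOREAN_TARIFF,
    literal_formula: bool = False,
) -> float:
    """Score a single EQ-5D-3L response to a utility index.

    ``response`` is either the five levels in dimension order or a mapping
    keyed by dimension name.
    """
    if isinstance(response, Mapping):
        levels = np.array([response[d] for d in DIMENSIONS])
    else:
        levels = np.asarray(response)
    _validate_levels(levels)
    return float(
        eq5d_index_array(levels[None, :], tariff, literal_formula)[0]
    )


def eq5d_index_array(
    levels: np.ndarray,
    tariff: EQ5DTariff = KOREAN_TARIFF,
    literal_formula: bool = False,
) -> np.ndarray:
    """Vectorized scoring of an (n, 5) integer level array."""
    levels = np.asarray(levels)
    _validate_levels(levels)
    l2 = np.array([tariff.decrements[d][0] for d in DIMENSIONS])
    l3 = np.array([tariff.decrements[d][1] for d in DIMENSIONS])
    total = (levels == 2) @ l2 + (levels == 3) @ l3
    any3 = (levels == 3).any(axis=-1)
    total = total + tariff.n3 * any3
    if literal_formula:
        total = total + tariff.constant
    else:
        total = total + tariff.constant * (levels > 1).any(axis=-1)
    return 1.0 - total


def all_states() -> np.ndarray:
    """All 243 EQ-5D-3L health states as a (243, 5) level array."""
    return np.array(list(itertools.product((1, 2, 3), repeat=5)))


class EQ5DIndexScorer(BaseEstimator, TransformerMixin):
    """Transformer scoring EQ-5D-3L responses to utility indices.

    ``transform`` accepts an (n, 5) level array or a DataFrame holding the
    five response columns (default names ``mo, sc, ua, pd, ad``) and returns
    the index array; rows with any missing level yield NaN.
    """

    def __init__(
        self,
        tariff: EQ5DTariff = KOREAN_TARIFF,
        literal_formula: bool = False,
        columns: Sequence[str] = RESPONSE_COLUMNS,
    ):
        self.tariff = tariff
        self.literal_formula = literal_formula
        self.columns = columns

    def fit(self, X, y=None) -> "EQ5DIndexScorer":
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            values = X[list(self.columns)].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
        complete = ~np.isnan(values).any(axis=1)
        out = np.full(len(values), np.nan)
        if complete.any():
            out[complete] = eq5d_index_array(
                values[complete].astype(int), self.tariff, self.literal_formula
            )
        return out


class MeanSplitBinarizer(BaseEstimator, TransformerMixin):
    """Dichotomize utility indices at the cohort mean learned in ``fit``.

    Indices below ``mean_`` are labeled ``"low"``; at or above (the tie
    rule, configurable via ``tie_to_high``) are ``"high"``.  NaN input yields
    a missing label.
    """

    def __init__(self, tie_to_high: bool = True):
        self.tie_to_high = tie_to_high

    def fit(self, X, y=None) -> "MeanSplitBinarizer":
        x = np.asarray(X, dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError("cannot dichotomize an empty cohort")
        self.mean_ = float(np.mean(x))
        return self

    def transform(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        out = np.where(x >= self.mean_ if self.tie_to_high else x > self.mean_,
                       "high", "low").astype(object)
        out[np.isnan(x)] = None
        return out


def dichotomize(
    indices: Iterable[float], tie_to_high: bool = True
) -> list[QoLLabel]:
    """Label a cohort of indices low/high relative to their own mean."""
    arr = np.asarray(list(indices), dtype=float)
    binarizer = MeanSplitBinarizer(tie_to_high=tie_to_high).fit(arr)
    labels = binarizer.transform(arr)
    return [QoLLabel(index=float(i), label=lab) for i, lab in zip(arr, labels)]
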