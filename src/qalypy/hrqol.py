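"""Mapping CDC Healthy Days responses plus age to an EQ-5D-like utility.

Surveys that carry the four-item Healthy Days module (self-rated general
health 1-5 and three 30-day counts of physically unhealthy days, mentally
unhealthy days and activity-limitation days) but not a preference-based
instrument need a mapping to put respondents on the 0 (death) to 1 (perfect
health) utility scale before quality-adjusted life years can be computed.

The mapping here is an additive model with a pluggable coefficient table.
The built-in :data:`DEFAULT_COEFFICIENTS` are a documented stand-in, NOT a
published regression fit: they reproduce the qualitative behaviour (utility
1 at the perfect-health anchor, monotone decline in each morbidity field,
mild age gradient) so the pipeline is exercisable end to end.  Users with a
published coefficient set supply it through the ``mapping:`` config block;
the utility floor is configurable because published EQ-5D value sets allow
states worse than death (negative utilities) while the default anchors at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "HealthyDaysResponse",
    "MappingCoefficients",
    "DEFAULT_COEFFICIENTS",
    "map_to_eq5d",
    "HealthyDaysToEQ5D",
]


@dataclass(frozen=True)
class HealthyDaysResponse:
    """One respondent's Healthy Days answers.

    general_health: 1 (excellent) .. 5 (poor); the three day counts are
    each in 0..30 and refer to the past 30 days.
    """

    general_health: int
    phys_unhealthy_days: int
    ment_unhealthy_days: int
    limitation_days: int

    def __post_init__(self) -> None:
        if not 1 <= self.general_health <= 5:
            raise InputError(
                f"general_health must be in 1..5, got {self.general_health}"
            )
        for name in ("phys_unhealthy_days", "ment_unhealthy_days", "limitation_days"):
            v = getattr(self, name)
            if not 0 <= v <= 30:
                raise InputError(f"{name} must be in 0..30, got {v}")


@dataclass(frozen=True)
class MappingCoefficients:
    """Additive mapping: utility = intercept + Σ coefficient · predictor.

    Day counts enter as fractions of 30; general health as (rank − 1); age
    centred at ``age_center``.  Values are clipped to
    [utility_floor, utility_ceiling].
    """

    intercept: float = 1.0
    general_health: float = -0.07  # per rank step above "excellent"
    phys_days: float = -0.20  # per 30/30 physically unhealthy days
    ment_days: float = -0.15
    limitation_days: float = -0.25
    age: float = -0.001  # per year above age_center
    age_center: float = 65.0
    utility_floor: float = 0.0
    utility_ceiling: float = 1.0
    label: str = field(default="built-in stand-in (not a published set)")

    def __post_init__(self) -> None:
        if not self.utility_floor < self.utility_ceiling <= 1.0:
            raise InputError(
                "require utility_floor < utility_ceiling <= 1, got "
                f"({self.utility_floor}, {self.utility_ceiling})"
            )


DEFAULT_COEFFICIENTS = MappingCoefficients()


def map_to_eq5d(
    response: HealthyDaysResponse,
    age: float,
    coeffs: MappingCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Map one Healthy Days response (plus age) to a clipped utility value."""
    if age < 0:
        raise InputError(f"age must be nonnegative, got {age}")
    u = (
        coeffs.intercept
        + coeffs.general_health * (response.general_health - 1)
        + coeffs.phys_days * (response.phys_unhealthy_days / 30.0)
        + coeffs.ment_days * (response.ment_unhealthy_days / 30.0)
        + coeffs.limitation_days * (response.limitation_days / 30.0)
        + coeffs.age * (age - coeffs.age_center)
    )
    return float(np.clip(u, coeffs.utility_floor, coeffs.utility_ceiling))


class HealthyDaysToEQ5D(TransformerMixin, BaseEstimator):
    """Vectorised transformer: cohort table -> EQ-5D-like utility column.

    Expects columns ``genhlth``, ``physdays``, ``mentdays``, ``actdays`` and
    ``age``.  If the table already carries an ``eq5d`` column the mapping is
    bypassed and that column is returned unchanged (the synthetic generator
    uses this path by default).

    Parameters
    ----------
    coeffs : MappingCoefficients
        Coefficient table; defaults to the documented stand-in set.
    """

    def __init__(self, coeffs: MappingCoefficients = DEFAULT_COEFFICIENTS):
        self.coeffs = coeffs

    def fit(self, X: pd.DataFrame, y=None) -> "HealthyDaysToEQ5D":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if "eq5d" in X.columns and X["eq5d"].notna().all():
            return X["eq5d"].to_numpy(dtype=float)
        logger.info("mapping=healthy_days_to_eq5d coeffs=%r", self.coeffs.label)
        required = ["genhlth", "physdays", "mentdays", "actdays", "age"]
        missing = [c for c in required if c not in X.columns]
        if missing:
            raise InputError(f"Healthy Days mapping requires columns {missing}")
        gh = X["genhlth"].to_numpy(dtype=float)
        if np.nanmin(gh) < 1 or np.nanmax(gh) > 5:
            raise InputError("genhlth values must be in 1..5")
        days = X[["physdays", "mentdays", "actdays"]].to_numpy(dtype=float)
        if np.nanmin(days) < 0 or np.nanmax(days) > 30:
            raise InputError("day-count values must be in 0..30")
        c = self.coeffs
        u = (
            c.intercept
            + c.general_health * (gh - 1)
            + c.phys_days * (days[:, 0] / 30.0)
            + c.ment_days * (days[:, 1] / 30.0)
            + c.limitation_days * (days[:, 2] / 30.0)
            + c.age * (X["age"].to_numpy(dtype=float) - c.age_center)
        )
        return np.clip(u, c.utility_floor, c.utility_ceiling)
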