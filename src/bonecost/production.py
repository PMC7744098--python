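"""The productivity-loss calculus.

Daily loss at age x is the difference in *adjusted* hunting production —
average age-specific production multiplied by the probability of still
hunting — between two covariate profiles (e.g. without vs. with vertebral
fracture). Expected cumulative future loss from age x onward discounts
each future year's daily loss by the survivorship ratio l(a)/l(x),
structurally mirroring Fisher's reproductive value with fertility replaced
by caloric production. Return rates are assumed identical across profiles,
so losses arise entirely from cessation.

Sign convention: profile_a is the better-off group, so daily and future
losses are non-negative whenever the cessation model orders the profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptives import round_half_away
from .synthetic import AgeSchedule, SurvivalSchedule

__all__ = [
    "CovariateProfile",
    "LossProfile",
    "KCAL_PER_G_PROTEIN",
    "KCAL_PER_G_FAT",
    "DAYS_PER_YEAR",
    "adjusted_production",
    "daily_loss",
    "expected_future_production",
    "expected_future_loss",
    "loss_profile",
    "kcal_to_grams",
    "pct_of_reference",
]

KCAL_PER_G_PROTEIN = 4.0
KCAL_PER_G_FAT = 9.0
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class CovariateProfile:
    """A fracture/BMD profile at which production is evaluated.

    ``bmd_offset_sd`` is the standardized BMD offset from the cohort mean
    (+1, 0, -1 SD, ...), interpreted on the SD scale stored in the fit.
    """

    fracture: bool = False
    bmd_offset_sd: float = 0.0
    sex: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.bmd_offset_sd):
            raise ValueError("bmd_offset_sd must be finite")

    def label(self) -> str:
        parts = ["fracture" if self.fracture else "no_fracture"]
        if self.bmd_offset_sd:
            parts.append(f"bmd{self.bmd_offset_sd:+g}sd")
        return "_".join(parts)


def adjusted_production(schedule: AgeSchedule, fit, age: float,
                        profile: CovariateProfile,
                        production_column: str = "hunting_kcal_day") -> float:
    """Age-specific production multiplied by the still-performing probability.

    ``fit`` is any cessation model exposing ``p_still(age, fracture,
    bmd_sd, sex)`` — a fitted logistic model or a fixed probability table.
    """
    production = schedule.value_at(age, production_column)
    p = fit.p_still(age, profile.fracture, bmd_sd=profile.bmd_offset_sd,
                    sex=profile.sex)
    return production * p


def daily_loss(schedule: AgeSchedule, fit, age: float,
               profile_a: CovariateProfile, profile_b: CovariateProfile,
               production_column: str = "hunting_kcal_day") -> float:
    """kcal/day lost by profile_b relative to profile_a at one age."""
    return (adjusted_production(schedule, fit, age, profile_a, production_column)
            - adjusted_production(schedule, fit, age, profile_b, production_column))


def _aligned_survivorship(schedule: AgeSchedule, survival: SurvivalSchedule,
                          start_age: float) -> tuple[np.ndarray, np.ndarray, float]:
    i = schedule.index_of(start_age)
    ages = schedule.ages[i:]
    l = np.array([survival.l_at(a) for a in ages])
    l_start = l[0]
    if l_start <= 0:
        raise ValueError(f"survivorship at start age {start_age} must be positive")
    return ages, l, l_start


def expected_future_production(schedule: AgeSchedule, survival: SurvivalSchedule,
                               fit, start_age: float, profile: CovariateProfile,
                               days_per_year: float = DAYS_PER_YEAR,
                               production_column: str = "hunting_kcal_day") -> float:
    """Expected cumulative production (kcal) from start_age onward.

    Sum over ages a >= start_age of l(a)/l(start_age) x adjusted daily
    production x days per year, conditional on being alive at start_age and
    truncated at the last schedule age.
    """
    ages, l, l_start = _aligned_survivorship(schedule, survival, start_age)
    total = 0.0
    for a, la in zip(ages, l):
        total += (la / l_start) * adjusted_production(
            schedule, fit, a, profile, production_column) * days_per_year
    return total


def expected_future_loss(schedule: AgeSchedule, survival: SurvivalSchedule,
                         fit, start_age: float,
                         profile_a: CovariateProfile, profile_b: CovariateProfile,
                         days_per_year: float = DAYS_PER_YEAR,
                         production_column: str = "hunting_kcal_day") -> float:
    """Mortality-discounted cumulative kcal lost by profile_b vs profile_a."""
    return (expected_future_production(schedule, survival, fit, start_age,
                                       profile_a, days_per_year, production_column)
            - expected_future_production(schedule, survival, fit, start_age,
                                         profile_b, days_per_year, production_column))


@dataclass(frozen=True)
class LossProfile:
    """Per-age daily and expected cumulative future losses between profiles."""

    ages: np.ndarray
    adjusted_production_a: np.ndarray
    adjusted_production_b: np.ndarray
    daily_loss: np.ndarray
    future_production_a: np.ndarray
    future_production_b: np.ndarray
    future_loss: np.ndarray
    profile_a: CovariateProfile
    profile_b: CovariateProfile
    days_per_year: float

    @property
    def peak_daily_loss_age(self) -> float:
        return float(self.ages[int(np.argmax(self.daily_loss))])

    @property
    def peak_daily_loss(self) -> float:
        return float(np.max(self.daily_loss))

    @property
    def peak_future_loss_age(self) -> float:
        return float(self.ages[int(np.argmax(self.future_loss))])

    @property
    def peak_future_loss(self) -> float:
        return float(np.max(self.future_loss))


def loss_profile(schedule: AgeSchedule, survival: SurvivalSchedule, fit,
                 profile_a: CovariateProfile, profile_b: CovariateProfile,
                 days_per_year: float = DAYS_PER_YEAR,
                 production_column: str = "hunting_kcal_day") -> LossProfile:
    """Compute the full age profile of daily and future losses.

    Future values use a reverse cumulative sum of survivorship-weighted
    adjusted production, so the whole profile costs one pass over the grid.
    """
    ages = schedule.ages
    l = np.array([survival.l_at(a) for a in ages])
    if np.any(l <= 0):
        keep = l > 0
        ages, l = ages[keep], l[keep]
    adj_a = np.array([adjusted_production(schedule, fit, a, profile_a,
                                          production_column) for a in ages])
    adj_b = np.array([adjusted_production(schedule, fit, a, profile_b,
                                          production_column) for a in ages])
    weighted_a = np.cumsum((l * adj_a)[::-1])[::-1] * days_per_year / l
    weighted_b = np.cumsum((l * adj_b)[::-1])[::-1] * days_per_year / l
    return LossProfile(
        ages=ages,
        adjusted_production_a=adj_a, adjusted_production_b=adj_b,
        daily_loss=adj_a - adj_b,
        future_production_a=weighted_a, future_production_b=weighted_b,
        future_loss=weighted_a - weighted_b,
        profile_a=profile_a, profile_b=profile_b, days_per_year=days_per_year)


def kcal_to_grams(kcal: float, nutrient: str) -> int:
    """Convert kcal to grams of protein (4 kcal/g) or fat (9 kcal/g),
    rounded half away from zero."""
    if kcal < 0:
        raise ValueError("kcal must be non-negative")
    if nutrient == "protein":
        return round_half_away(kcal / KCAL_PER_G_PROTEIN)
    if nutrient == "fat":
        return round_half_away(kcal / KCAL_PER_G_FAT)
    raise ValueError(f"unknown nutrient {nutrient!r}")


def pct_of_reference(value: float, reference: float) -> int:
    """100 x value / reference, rounded to the nearest integer percent."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round_half_away(100.0 * value / reference)
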