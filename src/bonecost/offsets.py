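"""Fishing-offset calculators.

How much extra fishing — at observed return rates and time allocation —
would wholly replace hunting calories lost to cessation: additional
minutes per day for a daily loss, or additional hours and day-equivalents
for a mortality-discounted cumulative loss.
"""

from __future__ import annotations

from dataclasses import dataclass

from .descriptives import round_half_away

__all__ = ["OffsetResult", "CumulativeOffsetResult", "offset_minutes",
           "cumulative_offset"]


@dataclass(frozen=True)
class OffsetResult:
    age: float
    daily_loss: float          # kcal/day
    return_rate: float         # kcal/hr
    additional_min_day: float  # minutes/day
    expected_min_day: float    # observed + additional
    observed_min_day: float
    pct_increase: int          # integer percent

    def to_dict(self) -> dict:
        return {"age": self.age, "daily_loss": self.daily_loss,
                "return_rate": self.return_rate,
                "additional_min_day": self.additional_min_day,
                "expected_min_day": self.expected_min_day,
                "observed_min_day": self.observed_min_day,
                "pct_increase": self.pct_increase}


def offset_minutes(daily_loss: float, return_rate: float,
                   observed_min_day: float, age: float = float("nan")) -> OffsetResult:
    """Additional fishing minutes/day needed to replace a daily kcal loss.

    additional = 60 x loss / return rate; the percent increase compares
    expected (observed + additional) with observed minutes.
    """
    if return_rate <= 0:
        raise ValueError("return_rate must be positive")
    if observed_min_day < 0:
        raise ValueError("observed_min_day must be non-negative")
    additional = 60.0 * daily_loss / return_rate
    expected = observed_min_day + additional
    if observed_min_day > 0:
        pct = round_half_away(100.0 * (expected / observed_min_day - 1.0))
    else:
        # no observed fishing: a percent increase is undefined unless the
        # loss is also zero
        pct = 0 if additional == 0 else None
    return OffsetResult(age=age, daily_loss=daily_loss, return_rate=return_rate,
                        additional_min_day=additional, expected_min_day=expected,
                        observed_min_day=observed_min_day,
                        pct_increase=pct)


@dataclass(frozen=True)
class CumulativeOffsetResult:
    start_age: float
    future_loss: float          # kcal
    return_rate: float          # kcal/hr
    additional_hours: float
    additional_days: float      # day-equivalents at the basis-age allocation
    fishing_min_day_at_basis: float
    rate_basis: str             # "max_observed" | "min_observed" | other label

    def to_dict(self) -> dict:
        return {"start_age": self.start_age, "future_loss": self.future_loss,
                "return_rate": self.return_rate,
                "additional_hours": self.additional_hours,
                "additional_days": self.additional_days,
                "fishing_min_day_at_basis": self.fishing_min_day_at_basis,
                "rate_basis": self.rate_basis}


def cumulative_offset(future_loss: float, return_rate: float,
                      fishing_min_day_at_basis: float,
                      start_age: float = float("nan"),
                      rate_basis: str = "max_observed") -> CumulativeOffsetResult:
    """Additional fishing hours and day-equivalents for a cumulative loss.

    hours = loss / return rate; day-equivalents divide by the daily fishing
    hours observed at the rate-basis age — an approximation, since real
    time allocation varies with age.
    """
    if return_rate <= 0 or fishing_min_day_at_basis <= 0:
        raise ValueError("return_rate and fishing_min_day_at_basis must be positive")
    if future_loss < 0:
        raise ValueError("future_loss must be non-negative")
    hours = future_loss / return_rate
    days = hours / (fishing_min_day_at_basis / 60.0)
    return CumulativeOffsetResult(start_age=start_age, future_loss=future_loss,
                                  return_rate=return_rate, additional_hours=hours,
                                  additional_days=days,
                                  fishing_min_day_at_basis=fishing_min_day_at_basis,
                                  rate_basis=rate_basis)
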