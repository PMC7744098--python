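"""Fishing time needed to offset hunting losses.

Converts a daily kcal loss into extra fishing minutes per day at the
age-specific return rate, and a cumulative future loss into additional
fishing hours and day-equivalents at the maximum observed return rate.
"""

import numpy as np

import bonecost as bc

cohort = bc.generate_cohort(bc.CohortParams(n_men=5000, n_women=5, seed=1))
fit = bc.fit_cessation(cohort, "hunting")
schedule, survival = bc.generate_schedules()
lp = bc.loss_profile(schedule, survival, fit,
                     bc.CovariateProfile(False), bc.CovariateProfile(True))

age = lp.peak_daily_loss_age
daily = bc.offset_minutes(lp.peak_daily_loss,
                          schedule.value_at(age, "fishing_return"),
                          schedule.value_at(age, "fishing_min_day"), age=age)
print(f"at age {age:.0f}: loss {daily.daily_loss:.0f} kcal/day at "
      f"{daily.return_rate:.0f} kcal/hr")
print(f"  -> +{daily.additional_min_day:.0f} fishing min/day "
      f"({daily.observed_min_day:.0f} observed to "
      f"{daily.expected_min_day:.0f} expected, +{daily.pct_increase}%)")

i = int(np.argmax(schedule.fishing_return))
cum = bc.cumulative_offset(float(lp.future_loss[0]),
                           float(schedule.fishing_return[i]),
                           float(schedule.fishing_min_day[i]),
                           start_age=float(lp.ages[0]))
print(f"future loss from 40: {cum.future_loss / 1e6:.2f} M kcal at "
      f"{cum.return_rate:.0f} kcal/hr (max observed)")
print(f"  -> +{cum.additional_hours:.0f} fishing hours "
      f"= {cum.additional_days:.0f} day-equivalents")
print()
print("Offsets assume return rates unaffected by fracture: replacing lost")
print("hunting calories would require roughly tripling daily fishing time at")
print("the peak-loss age.")
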