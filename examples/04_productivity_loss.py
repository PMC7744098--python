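"""Daily and mortality-discounted future hunting-productivity losses.

Multiplies the age-specific hunting schedule by the fitted probability of
still hunting, with and without fracture, then discounts future losses by
survivorship — the reproductive-value analogue with calories in place of
fertility.
"""

import bonecost as bc

cohort = bc.generate_cohort(bc.CohortParams(n_men=5000, n_women=5, seed=1))
fit = bc.fit_cessation(cohort, "hunting")
schedule, survival = bc.generate_schedules()

a = bc.CovariateProfile(fracture=False)
b = bc.CovariateProfile(fracture=True)
lp = bc.loss_profile(schedule, survival, fit, a, b)

print(f"daily loss at 40: {lp.daily_loss[0]:6.0f} kcal/day")
print(f"peak daily loss:  {lp.peak_daily_loss:6.0f} kcal/day at age "
      f"{lp.peak_daily_loss_age:.0f}")
print(f"  = {bc.kcal_to_grams(lp.peak_daily_loss, 'protein')} g protein or "
      f"{bc.kcal_to_grams(lp.peak_daily_loss, 'fat')} g fat, "
      f"{bc.pct_of_reference(lp.peak_daily_loss, schedule.value_at(lp.peak_daily_loss_age, 'intake_kcal_day'))}% of daily intake")
print(f"daily loss at 75+: {lp.daily_loss[schedule.index_of(75)]:.0f} "
      f"(hunting returns reach zero)")
print(f"expected future loss from age 40: {lp.future_loss[0] / 1e6:.2f} million kcal")
print(f"  = {bc.pct_of_reference(lp.future_loss[0], lp.future_production_a[0])}% "
      f"of expected future hunting production without fracture")
print()
print("Losses are small at 40 (nearly all men still hunt), peak in the early")
print("60s as cessation diverges by fracture status, and vanish at the")
print("terminal hunting age.")
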