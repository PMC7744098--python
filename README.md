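# bonecost

Economic costs of compromised bone strength in a subsistence population.

In forager-horticulturalist groups, food production depends on physically
demanding tasks — hunting, tree chopping, weaving, walking all day — and a
thoracic vertebral fracture or low vertebral bone mineral density (BMD) can
end participation in them. `bonecost` implements, as a tested and reusable
pipeline, the analysis that links bone strength to task cessation and prices
the consequence in calories: logistic cessation models, a daily and
mortality-discounted cumulative hunting-productivity loss calculus, and
fishing-time offsets. It is aimed at biological anthropologists and
epidemiologists studying functional disability and production over the life
course.

## The model

Task cessation is modelled by binary logistic regression

&nbsp;&nbsp;logit P(cease) = β₀ + β₁·age + β₂·fracture + β₃·BMD/SD (+ β₄·sex),

compared stepwise by AIC (fracture first, then BMD) with false-discovery-rate
q-values across tasks. The still-performing probability
p_still = 1 − P(cease) multiplies average age-specific hunting production
P(x) to give adjusted production; the **daily loss** at age x between
covariate profiles a (better off) and b is

&nbsp;&nbsp;ΔE(x) = P(x)·[p_still,a(x) − p_still,b(x)]  (kcal/day),

and the **expected cumulative future loss** from age x, discounted by
survivorship l(a) as in Fisher's reproductive value with fertility replaced
by caloric production, is

&nbsp;&nbsp;L(x) = Σ_{a≥x} [l(a)/l(x)] · ΔE(a) · 365  (kcal).

Losses convert to protein (4 kcal/g) and fat (9 kcal/g) equivalents, percent
of daily intake, and the extra fishing minutes/day (60·ΔE/return-rate) or
cumulative hours (L/return-rate) needed to offset them at observed fishing
return rates. A seeded synthetic-data module generates cohorts and
population schedules with the assumed structure (fracture prevalence 36% in
men / 19% in women, BMD inversely linked to women's fracture risk, fracture
cessation odds ratios near 7, hunting production peaking mid-life and
reaching zero at 75), so the full pipeline runs without any field data.

## Worked example

```python
import numpy as np
import bonecost as bc

ages = np.arange(40.0, 51.0)
production = np.zeros(11); production[0], production[10] = 2000.0, 1800.0
zeros = np.zeros(11)
schedule = bc.AgeSchedule(ages=ages, hunting_kcal_day=production,
                          fishing_kcal_day=zeros, fishing_return=zeros,
                          fishing_min_day=zeros, intake_kcal_day=zeros,
                          intake_pf_kcal_day=zeros)
model = bc.FixedCessation({(40.0, False): 0.01, (40.0, True): 0.15,
                           (50.0, False): 0.10, (50.0, True): 0.25})
a, b = bc.CovariateProfile(fracture=False), bc.CovariateProfile(fracture=True)
print(bc.adjusted_production(schedule, model, 40, a),
      bc.adjusted_production(schedule, model, 40, b),
      bc.daily_loss(schedule, model, 40, a, b))
print(bc.adjusted_production(schedule, model, 50, a),
      bc.adjusted_production(schedule, model, 50, b),
      bc.daily_loss(schedule, model, 50, a, b))
```

prints

```
1980.0 1700.0 280.0
1620.0 1350.0 270.0
```

A 40-year-old producing 2000 hunting kcal/day who still hunts with
probability 0.99 without fracture (0.85 with) yields adjusted production
1980 vs. 1700 kcal/day — a daily loss of 280 kcal; the 50-year-old analogue
loses 270 kcal/day. On the full calibrated synthetic cohort
(`examples/04_productivity_loss.py`) the fitted models put the peak daily
loss at 623 kcal/day at age 63 (156 g of protein, 24% of daily intake) and
the expected future loss from age 40 at 2.00 million kcal — 15% of expected
future hunting production. `examples/` contains one short script per
capability; a thin CLI (`bonecost simulate|descriptives|fit|loss|offset|report`)
wraps the same functions.

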