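"""Logistic cessation models with stepwise AIC and FDR q-values.

Fits, for each subsistence task, Model 1 (age + fracture, plus sex for
full-day walking) and Model 2 (adds BMD per SD), compares them by AIC, and
adjusts the fracture p-values for multiple testing across tasks.
"""

import bonecost as bc

cohort = bc.generate_cohort(bc.CohortParams(seed=3))

p_values = []
for task in bc.TASKS:
    comp = bc.stepwise_compare(cohort, task)
    m1, m2 = comp.fits
    i = m1.covariates.index("fracture")
    p_values.append(float(m1.p_values[i]))
    lo, hi = m1.ci("fracture")
    print(f"{task:14s} OR_fracture = {m1.odds_ratio('fracture'):5.1f} "
          f"(95% CI {lo:5.1f}-{hi:5.1f})  AIC1 = {m1.aic:6.1f}  "
          f"AIC2 = {m2.aic:6.1f}  preferred = model {comp.preferred + 1}")

qs = bc.qvalues(p_values, method="storey")
for task, p, q in zip(bc.TASKS, qs.p_values, qs.q_values):
    print(f"{task:14s} p = {p:.2e}  FDR q = {q:.2e}")
print()
print("Fracture multiplies cessation odds ~7x for hunting/tree chopping and")
print("~8x for walking; weaving shows the weakest link. q-values control the")
print("false-discovery rate across the four task models.")
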