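"""Logistic cessation models: parameter recovery, AIC stepwise behaviour,
q-values, predicted probabilities, and mediation checks."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import bonecost as bc


def test_fracture_or_recovery_at_large_n(large_men_cohort):
    fit = bc.fit_cessation(large_men_cohort, "hunting",
                           covariates=("age", "fracture", "bmd_sd"))
    assert fit.converged
    assert 6.0 <= fit.odds_ratio("fracture") <= 8.9


def test_null_fracture_ci_coverage():
    """Generator with zero fracture effect: the OR CI should cover 1.0 in
    at least 90% of replicates."""
    coefs = {"hunting": (-14.0, 0.194, 0.0, math.log(0.62))}
    covered = n_fit = 0
    for rep in range(200):
        cohort = bc.generate_cohort(bc.CohortParams(
            n_men=500, n_women=5, cessation_coefs=coefs, seed=5000 + rep))
        fit = bc.fit_cessation(cohort, "hunting",
                               covariates=("age", "fracture", "bmd_sd"))
        if not fit.converged:
            continue
        n_fit += 1
        lo, hi = fit.ci("fracture")
        covered += lo <= 1.0 <= hi
    assert n_fit >= 190
    assert covered / 200 >= 0.90


def test_intercept_only_recovers_bernoulli_mean():
    df = pd.DataFrame({
        "sex": "male", "age": 60.0, "bmd": 150.0, "fracture": False,
        "ceased_hunting": [True] * 25 + [False] * 25})
    fit = bc.fit_cessation(df, "hunting", covariates=())
    assert fit.p_cease(age=60, fracture=False) == pytest.approx(0.5, abs=1e-8)


def test_score_equation_mean_fitted_equals_observed(large_men_cohort):
    fit = bc.fit_cessation(large_men_cohort, "hunting",
                           covariates=("age", "fracture", "bmd_sd"))
    men = large_men_cohort.dropna(subset=["ceased_hunting"])
    z = (men.bmd - men.bmd.mean()) / men.bmd.std(ddof=1)
    fitted = [fit.p_cease(a, f, bmd_sd=zz)
              for a, f, zz in zip(men.age, men.fracture, z)]
    assert np.mean(fitted) == pytest.approx(
        men["ceased_hunting"].astype(float).mean(), abs=1e-6)


def test_binary_design_or_equals_cross_product_ratio():
    rows = []
    for frac, ceased, count in [(True, True, 30), (True, False, 60),
                                (False, True, 20), (False, False, 140)]:
        rows += [{"sex": "male", "age": 60.0, "bmd": 150.0,
                  "fracture": frac, "ceased_hunting": ceased}] * count
    df = pd.DataFrame(rows)
    fit = bc.fit_cessation(df, "hunting", covariates=("fracture",))
    assert fit.odds_ratio("fracture") == pytest.approx(
        (30 * 140) / (60 * 20), rel=1e-6)


def test_complete_separation_is_flagged():
    df = pd.DataFrame({
        "sex": "male", "age": np.r_[np.full(20, 45.0), np.full(20, 70.0)],
        "bmd": 150.0, "fracture": False,
        "ceased_hunting": [False] * 20 + [True] * 20})
    fit = bc.fit_cessation(df, "hunting", covariates=("age",))
    assert fit.separation and not fit.converged


def test_stepwise_aic_penalty_under_null_bmd():
    """When BMD has no effect, AIC(model 1) <= AIC(model 2) + 2 except when
    the chance likelihood-ratio exceeds the parameter penalty (~5%)."""
    coefs = {"hunting": (-14.0, 0.194, math.log(7.3), 0.0)}
    ok = 0
    for rep in range(100):
        cohort = bc.generate_cohort(bc.CohortParams(
            n_men=500, n_women=5, cessation_coefs=coefs, seed=9000 + rep))
        comp = bc.stepwise_compare(cohort, "hunting")
        ok += comp.fits[0].aic <= comp.fits[1].aic + 2 + 1e-9
    assert ok >= 80


def test_stepwise_prefers_bmd_model_under_strong_effect():
    coefs = {"hunting": (-14.0, 0.194, math.log(7.3), -1.0)}
    cohort = bc.generate_cohort(bc.CohortParams(
        n_men=3000, n_women=5, cessation_coefs=coefs, seed=17))
    comp = bc.stepwise_compare(cohort, "hunting")
    assert comp.preferred == 1
    assert comp.delta_aic[comp.preferred] == 0.0
    assert min(comp.delta_aic) == 0.0 and all(d >= 0 for d in comp.delta_aic)


def test_stepwise_is_deterministic(default_cohort):
    a = bc.stepwise_compare(default_cohort, "hunting")
    b = bc.stepwise_compare(default_cohort, "hunting")
    assert a.fits[0].aic == b.fits[0].aic
    assert a.fits[1].aic == b.fits[1].aic


@pytest.mark.parametrize("p, method, expected", [
    ([0.05], "bh", [0.05]),
    ([0.01, 0.02, 0.03, 0.04], "bh", [0.04, 0.04, 0.04, 0.04]),
    ([1.0, 1.0, 1.0], "storey", [1.0, 1.0, 1.0]),
])
def test_qvalue_examples(p, method, expected):
    qs = bc.qvalues(p, method=method)
    np.testing.assert_allclose(qs.q_values, expected, atol=1e-12)


def test_qvalues_bh_matches_statsmodels():
    rng = np.random.default_rng(3)
    p = rng.uniform(0, 1, size=25)
    qs = bc.qvalues(p, method="bh")
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(qs.q_values, q_ref, rtol=1e-12)


def test_qvalues_storey_scales_bh_by_pi0():
    rng = np.random.default_rng(4)
    p = rng.uniform(0, 1, size=40)
    storey = bc.qvalues(p, method="storey", lam=0.5)
    bh = bc.qvalues(p, method="bh")
    assert 0 < storey.pi0 <= 1
    np.testing.assert_allclose(storey.q_values,
                               np.clip(bh.q_values * storey.pi0, 0, 1),
                               rtol=1e-12)


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(5)
    p = rng.uniform(0, 1, size=30)
    qs = bc.qvalues(p, method="storey")
    order = np.argsort(p)
    assert np.all(np.diff(qs.q_values[order]) >= -1e-12)


def test_qvalues_empty_raises():
    with pytest.raises(ValueError):
        bc.qvalues([])


def test_p_still_zero_coefficients_give_half():
    fit = _manual_fit(("intercept",), [0.0])
    assert bc.p_still(fit, age=50, fracture=False) == pytest.approx(0.5)


def test_p_still_matches_stated_worked_probability():
    model = bc.FixedCessation({(40.0, True): 0.15})
    assert model.p_still(40, True) == pytest.approx(0.85)


def test_p_still_monotone_in_fracture():
    fit = _manual_fit(("intercept", "age", "fracture"), [-14.0, 0.194, 2.0])
    assert bc.p_still(fit, 60, True) < bc.p_still(fit, 60, False)


def test_p_still_unknown_covariate_raises():
    fit = _manual_fit(("intercept", "frailty"), [0.0, 1.0])
    with pytest.raises(ValueError):
        bc.p_still(fit, 60, False)


def _manual_fit(covariates, coefficients):
    k = len(covariates)
    return bc.LogisticFit(task="hunting", covariates=tuple(covariates),
                          coefficients=np.asarray(coefficients, dtype=float),
                          ses=np.ones(k), p_values=np.full(k, 0.5),
                          aic=0.0, n=0, bmd_sd_used=1.0,
                          converged=True, separation=False)


def test_mediation_null_change_centred_on_zero():
    changes = []
    for rep in range(200):
        cohort = bc.generate_cohort(bc.CohortParams(
            n_men=500, n_women=5, seed=3000 + rep))
        res = bc.mediation_check(cohort, "hunting")
        if res.base.converged and res.adjusted.converged:
            changes.append(res.log_or_change)
    assert len(changes) >= 180
    assert abs(np.mean(changes)) < 0.05


def test_mediation_attenuates_when_anthropometrics_drive_cessation():
    rng = np.random.default_rng(8)
    n = 4000
    frac = rng.random(n) < 0.35
    ffm = 50.0 - 6.0 * frac + rng.normal(0, 3, n)
    eta = 10.0 - 0.22 * ffm          # cessation driven purely by fat-free mass
    ceased = rng.random(n) < 1 / (1 + np.exp(-eta))
    df = pd.DataFrame({"sex": "male", "age": 60.0, "bmd": rng.normal(150, 30, n),
                       "fracture": frac, "fat_free_mass": ffm,
                       "fat_mass": rng.normal(12, 2, n),
                       "ceased_hunting": ceased})
    res = bc.mediation_check(df, "hunting")
    assert abs(math.log(res.adjusted.odds_ratio("fracture"))) \
        < abs(math.log(res.base.odds_ratio("fracture")))


def test_mediation_constant_column_leaves_or_unchanged(default_cohort):
    men = default_cohort[default_cohort.sex == "male"].copy()
    men["constant_anthro"] = 60.0
    base = bc.fit_cessation(men, "hunting",
                            covariates=("age", "fracture", "bmd_sd"))
    adj = bc.fit_cessation(men, "hunting",
                           covariates=("age", "fracture", "bmd_sd",
                                       "constant_anthro"))
    assert adj.odds_ratio("fracture") == pytest.approx(
        base.odds_ratio("fracture"), rel=1e-8)
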