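"""The loss calculus: worked-example arithmetic, hand-summed discounting
oracles, closed forms, and structural invariants."""

import numpy as np
import pytest

import bonecost as bc
from conftest import random_small_problem

NO_FRACTURE = bc.CovariateProfile(fracture=False)
FRACTURE = bc.CovariateProfile(fracture=True)


@pytest.fixture
def worked_example():
    """Toy inputs: a 40-year-old producing 2000 kcal/day, a 50-year-old
    producing 1800, with stated still-hunting probabilities."""
    ages = np.arange(40.0, 51.0)
    production = np.zeros(11)
    production[0], production[10] = 2000.0, 1800.0
    zeros = np.zeros(11)
    schedule = bc.AgeSchedule(ages=ages, hunting_kcal_day=production,
                              fishing_kcal_day=zeros, fishing_return=zeros,
                              fishing_min_day=zeros, intake_kcal_day=zeros,
                              intake_pf_kcal_day=zeros)
    model = bc.FixedCessation({(40.0, False): 0.01, (40.0, True): 0.15,
                               (50.0, False): 0.10, (50.0, True): 0.25})
    return schedule, model


def test_worked_example_adjusted_production(worked_example):
    schedule, model = worked_example
    assert bc.adjusted_production(schedule, model, 40, NO_FRACTURE) == 1980.0
    assert bc.adjusted_production(schedule, model, 40, FRACTURE) == 1700.0
    assert bc.adjusted_production(schedule, model, 50, NO_FRACTURE) == 1620.0
    assert bc.adjusted_production(schedule, model, 50, FRACTURE) == 1350.0


def test_worked_example_daily_loss(worked_example):
    schedule, model = worked_example
    assert bc.daily_loss(schedule, model, 40, NO_FRACTURE, FRACTURE) == 280.0
    assert bc.daily_loss(schedule, model, 50, NO_FRACTURE, FRACTURE) == 270.0
    assert bc.daily_loss(schedule, model, 40, FRACTURE, FRACTURE) == 0.0


def test_adjusted_production_off_grid_raises(worked_example):
    schedule, model = worked_example
    with pytest.raises(Exception):
        bc.adjusted_production(schedule, model, 39, NO_FRACTURE)


def test_zero_production_at_terminal_age(schedules):
    schedule, _ = schedules
    model = bc.FixedCessation({}, default=0.5)
    assert bc.adjusted_production(schedule, model, 80, FRACTURE) == 0.0


def test_future_production_three_age_hand_sum(toy_schedule):
    schedule, survival = toy_schedule
    always = bc.FixedCessation({}, default=0.0)
    total = bc.expected_future_production(schedule, survival, always, 60,
                                          NO_FRACTURE, days_per_year=1.0)
    assert total == pytest.approx(100 + 0.5 * 50 + 0.25 * 10)  # 127.5


def test_future_loss_linearity_in_p_still(toy_schedule):
    schedule, survival = toy_schedule
    model = bc.FixedCessation(
        {(a, True): 0.5 for a in schedule.ages}, default=0.0)
    loss = bc.expected_future_loss(schedule, survival, model, 60,
                                   NO_FRACTURE, FRACTURE, days_per_year=1.0)
    assert loss == pytest.approx(127.5 / 2)  # 63.75


def test_future_production_zero_mortality_closed_form():
    ages = np.arange(40.0, 46.0)
    production = np.array([100.0, 90, 80, 70, 60, 50])
    zeros = np.zeros(6)
    schedule = bc.AgeSchedule(ages=ages, hunting_kcal_day=production,
                              fishing_kcal_day=zeros, fishing_return=zeros,
                              fishing_min_day=zeros, intake_kcal_day=zeros,
                              intake_pf_kcal_day=zeros)
    survival = bc.SurvivalSchedule.from_mortality(40, np.zeros(5))
    always = bc.FixedCessation({}, default=0.0)
    total = bc.expected_future_production(schedule, survival, always, 40,
                                          NO_FRACTURE, days_per_year=365.0)
    assert total == pytest.approx(365.0 * production.sum(), rel=1e-14)


def test_future_loss_matches_brute_force_on_random_problems():
    rng = np.random.default_rng(42)
    for _ in range(25):
        schedule, survival, model = random_small_problem(rng)
        start = float(schedule.ages[0])
        fast = bc.expected_future_loss(schedule, survival, model, start,
                                       NO_FRACTURE, FRACTURE)
        brute = sum(
            survival.l_at(a) / survival.l_at(start)
            * bc.daily_loss(schedule, model, a, NO_FRACTURE, FRACTURE) * 365.0
            for a in schedule.ages)
        assert fast == pytest.approx(brute, rel=1e-12)


def test_mortality_discounting_never_increases_value():
    rng = np.random.default_rng(7)
    for _ in range(10):
        schedule, survival, model = random_small_problem(rng)
        start = float(schedule.ages[0])
        flat = bc.SurvivalSchedule.from_mortality(
            start, np.zeros(len(schedule.ages) - 1))
        with_mortality = bc.expected_future_production(
            schedule, survival, model, start, NO_FRACTURE)
        without = bc.expected_future_production(
            schedule, flat, model, start, NO_FRACTURE)
        assert with_mortality <= without + 1e-9


def test_loss_scales_linearly_with_production(toy_schedule):
    schedule, survival = toy_schedule
    scaled = bc.AgeSchedule(
        ages=schedule.ages, hunting_kcal_day=3.0 * schedule.hunting_kcal_day,
        fishing_kcal_day=schedule.fishing_kcal_day,
        fishing_return=schedule.fishing_return,
        fishing_min_day=schedule.fishing_min_day,
        intake_kcal_day=schedule.intake_kcal_day,
        intake_pf_kcal_day=schedule.intake_pf_kcal_day)
    model = bc.FixedCessation({(a, True): 0.4 for a in schedule.ages})
    base = bc.expected_future_loss(schedule, survival, model, 60,
                                   NO_FRACTURE, FRACTURE)
    tripled = bc.expected_future_loss(scaled, survival, model, 60,
                                      NO_FRACTURE, FRACTURE)
    assert tripled == pytest.approx(3.0 * base, rel=1e-12)


def test_daily_loss_monotone_in_fracture_coefficient(schedules):
    schedule, _ = schedules
    losses = []
    for b_frac in (0.5, 1.0, 2.0, 3.0):
        fit = bc.LogisticFit(
            task="hunting", covariates=("intercept", "age", "fracture"),
            coefficients=np.array([-14.0, 0.194, b_frac]),
            ses=np.ones(3), p_values=np.full(3, 0.5), aic=0.0, n=0,
            bmd_sd_used=1.0, converged=True, separation=False)
        losses.append([bc.daily_loss(schedule, fit, a, NO_FRACTURE, FRACTURE)
                       for a in schedule.ages])
    losses = np.asarray(losses)
    assert np.all(np.diff(losses, axis=0) >= -1e-12)


def test_loss_profile_matches_scalar_path(schedules, large_men_cohort):
    schedule, survival = schedules
    fit = bc.fit_cessation(large_men_cohort, "hunting")
    lp = bc.loss_profile(schedule, survival, fit, NO_FRACTURE, FRACTURE)
    for i in (0, 10, 25):
        start = float(lp.ages[i])
        assert lp.future_loss[i] == pytest.approx(
            bc.expected_future_loss(schedule, survival, fit, start,
                                    NO_FRACTURE, FRACTURE), rel=1e-10)
        assert lp.daily_loss[i] == pytest.approx(
            bc.daily_loss(schedule, fit, start, NO_FRACTURE, FRACTURE))


def test_future_production_at_dead_start_age_raises(toy_schedule):
    schedule, _ = toy_schedule
    dead = bc.SurvivalSchedule(ages=schedule.ages,
                               survivorship=np.array([1.0, 0.0, 0.0]))
    always = bc.FixedCessation({}, default=0.0)
    with pytest.raises(ValueError):
        bc.expected_future_production(schedule, dead, always, 61, NO_FRACTURE)


@pytest.mark.parametrize("kcal, nutrient, grams", [
    (481, "protein", 120), (481, "fat", 53),
    (650, "protein", 163), (650, "fat", 72),
    (0, "fat", 0),
])
def test_kcal_to_grams(kcal, nutrient, grams):
    assert bc.kcal_to_grams(kcal, nutrient) == grams


def test_kcal_to_grams_rejects_negative():
    with pytest.raises(ValueError):
        bc.kcal_to_grams(-1, "protein")


@pytest.mark.parametrize("value, reference, pct", [
    (481, 2592, 19), (481, 919, 52),
    (1.15, 8.49, 14), (1.88, 8.49, 22),
    (7, 7, 100),
])
def test_pct_of_reference(value, reference, pct):
    assert bc.pct_of_reference(value, reference) == pct


def test_pct_of_reference_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        bc.pct_of_reference(1, 0)
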