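import numpy as np
import pytest

import bonecost as bc


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale cohort (256 men, 237 women) at the default calibration."""
    return bc.generate_cohort(bc.CohortParams(seed=7))


@pytest.fixture(scope="session")
def large_men_cohort():
    """5000 men generated at the calibrated hunting-cessation model."""
    return bc.generate_cohort(bc.CohortParams(n_men=5000, n_women=5, seed=1))


@pytest.fixture(scope="session")
def schedules():
    return bc.generate_schedules()


@pytest.fixture
def toy_schedule():
    """Three-age schedule for hand-summed oracles: production 100/50/10
    kcal/day at ages 60-62, survivorship 1, 0.5, 0.25."""
    ages = np.array([60.0, 61.0, 62.0])
    zeros = np.zeros(3)
    schedule = bc.AgeSchedule(
        ages=ages, hunting_kcal_day=np.array([100.0, 50.0, 10.0]),
        fishing_kcal_day=zeros, fishing_return=zeros, fishing_min_day=zeros,
        intake_kcal_day=zeros, intake_pf_kcal_day=zeros)
    survival = bc.SurvivalSchedule(ages=ages,
                                   survivorship=np.array([1.0, 0.5, 0.25]))
    return schedule, survival


def random_small_problem(rng):
    """A random small schedule + survival + table cessation model, for
    brute-force oracle comparisons."""
    n_ages = int(rng.integers(2, 8))
    first = int(rng.integers(40, 70))
    ages = np.arange(first, first + n_ages, dtype=float)
    production = rng.uniform(0, 2000, size=n_ages)
    q = rng.uniform(0.0, 0.3, size=n_ages - 1)
    survival = bc.SurvivalSchedule.from_mortality(first, q)
    zeros = np.zeros(n_ages)
    schedule = bc.AgeSchedule(
        ages=ages, hunting_kcal_day=production, fishing_kcal_day=zeros,
        fishing_return=zeros, fishing_min_day=zeros, intake_kcal_day=zeros,
        intake_pf_kcal_day=zeros)
    table = {(a, f): rng.uniform(0, 1) for a in ages for f in (False, True)}
    model = bc.FixedCessation(table)
    return schedule, survival, model
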