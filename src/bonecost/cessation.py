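"""Binary logistic models of task cessation, AIC stepwise comparison,
FDR q-values, and predicted still-performing probabilities.

Cessation is modelled on age (years), fracture status (grade >= 1), and
standardized BMD; the full-day walking model additionally adjusts for sex.
The still-performing probability ``p_still = 1 - logistic(eta)`` is the
multiplier the loss calculus applies to age-specific production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .synthetic import task_column

__all__ = [
    "LogisticFit",
    "FixedCessation",
    "ModelComparison",
    "QValueSet",
    "MediationResult",
    "fit_cessation",
    "stepwise_compare",
    "qvalues",
    "p_still",
    "mediation_check",
]

SEPARATION_BOUND = 15.0  # |beta| on the standardized scale flags separation


@dataclass(frozen=True)
class LogisticFit:
    """A fitted cessation model.

    ``covariates`` orders the design columns; coefficients are log-odds.
    ``bmd_sd_used`` records the sample SD (mg/cm^3) behind the per-SD BMD
    coefficient so covariate profiles can be expressed in SD offsets.
    """

    task: str
    covariates: tuple
    coefficients: np.ndarray
    ses: np.ndarray
    p_values: np.ndarray
    aic: float
    n: int
    bmd_sd_used: float
    converged: bool
    separation: bool
    alpha: float = 0.05

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def ci(self, covariate: str) -> tuple[float, float]:
        i = self.covariates.index(covariate)
        z = st.norm.ppf(1.0 - self.alpha / 2.0)
        b, se = self.coefficients[i], self.ses[i]
        return float(math.exp(b - z * se)), float(math.exp(b + z * se))

    def odds_ratio(self, covariate: str) -> float:
        return float(np.exp(self.coefficients[self.covariates.index(covariate)]))

    def se(self, covariate: str) -> float:
        return float(self.ses[self.covariates.index(covariate)])

    def linear_predictor(self, age: float, fracture: bool,
                         bmd_sd: float = 0.0, sex: str | None = None) -> float:
        values = {"intercept": 1.0, "age": float(age),
                  "fracture": float(bool(fracture)), "bmd_sd": float(bmd_sd),
                  "sex_male": float(sex == "male") if sex is not None else 0.0}
        eta = 0.0
        for name, beta in zip(self.covariates, self.coefficients):
            if name not in values:
                raise ValueError(f"no value supplied for covariate {name!r}")
            eta += beta * values[name]
        return eta

    def p_cease(self, age: float, fracture: bool, bmd_sd: float = 0.0,
                sex: str | None = None) -> float:
        return 1.0 / (1.0 + math.exp(-self.linear_predictor(age, fracture, bmd_sd, sex)))

    def p_still(self, age: float, fracture: bool, bmd_sd: float = 0.0,
                sex: str | None = None) -> float:
        return 1.0 - self.p_cease(age, fracture, bmd_sd, sex)

    def to_dict(self) -> dict:
        return {
            "task": self.task, "covariates": list(self.covariates),
            "coefficients": [float(b) for b in self.coefficients],
            "odds_ratios": [float(v) for v in self.odds_ratios],
            "ci": {c: list(self.ci(c)) for c in self.covariates},
            "p_values": [float(p) for p in self.p_values],
            "aic": self.aic, "n": self.n, "bmd_sd_used": self.bmd_sd_used,
            "converged": self.converged, "separation": self.separation,
        }


class FixedCessation:
    """Cessation probabilities given directly as a table.

    Useful for worked examples and toy schedules where the still-performing
    probabilities are stated rather than fitted. Keys are
    (age, fracture_bool); ``default`` is the cessation probability used for
    ages absent from the table.
    """

    def __init__(self, p_cease_by_age_fracture: dict, default: float = 0.0):
        self._table = {(float(a), bool(f)): float(p)
                       for (a, f), p in p_cease_by_age_fracture.items()}
        self._default = float(default)

    def p_cease(self, age, fracture, bmd_sd=0.0, sex=None) -> float:
        return self._table.get((float(age), bool(fracture)), self._default)

    def p_still(self, age, fracture, bmd_sd=0.0, sex=None) -> float:
        return 1.0 - self.p_cease(age, fracture, bmd_sd, sex)


def _design(df: pd.DataFrame, covariates):
    """Build the model matrix; BMD standardized by the sample SD.

    Zero-variance covariates are non-informative alongside the intercept
    (and would make the design singular), so they are dropped.
    """
    cols, names = [np.ones(len(df))], ["intercept"]
    bmd_sd = float("nan")
    for cov in covariates:
        if cov == "bmd_sd":
            bmd = df["bmd"].to_numpy(dtype=float)
            bmd_sd = float(np.std(bmd, ddof=1))
            col = (bmd - bmd.mean()) / bmd_sd
        elif cov == "fracture":
            col = df["fracture"].to_numpy(dtype=float)
        elif cov == "sex_male":
            col = (df["sex"] == "male").to_numpy(dtype=float)
        else:
            col = df[cov].to_numpy(dtype=float)
        if np.std(col) == 0:
            continue
        cols.append(col)
        names.append(cov)
    return np.column_stack(cols), tuple(names), bmd_sd


def fit_cessation(records: pd.DataFrame, task: str,
                  covariates: tuple = ("age", "fracture", "bmd_sd"),
                  alpha: float = 0.05) -> LogisticFit:
    """Maximum-likelihood logistic regression of cessation for one task.

    Records with the task unavailable (other sex) or with missing values
    are dropped. Complete separation is flagged — coefficients diverging
    past ``SEPARATION_BOUND`` on the standardized scale — rather than
    penalized.
    """
    col = task_column(task)
    drop = [col] + [c for c in covariates if c in records.columns]
    if "bmd_sd" in covariates:
        drop.append("bmd")
    df = records.dropna(subset=drop)
    y = df[col].astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"cessation model for {task} needs >=1 event and >=1 non-event")
    X, names, bmd_sd = _design(df, covariates)

    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton", tol=1e-8)
        beta = np.asarray(fit.params)
        # standardized-scale coefficients; the intercept is excluded (its
        # raw magnitude reflects uncentred covariates, not separation)
        sd = np.std(X, axis=0)
        if np.any(np.abs(beta[sd > 0] * sd[sd > 0]) > SEPARATION_BOUND):
            separation = True
        if not np.all(np.isfinite(np.asarray(fit.bse))):
            separation = True
        converged = bool(fit.mle_retvals.get("converged", True)) and not separation
        ses = np.asarray(fit.bse)
        pvals = np.asarray(fit.pvalues)
        aic = float(fit.aic)
    except (np.linalg.LinAlgError,
            sm.tools.sm_exceptions.PerfectSeparationError):
        k = X.shape[1]
        beta = np.full(k, np.inf)
        ses = np.full(k, np.inf)
        pvals = np.full(k, np.nan)
        aic = float("nan")
        separation, converged = True, False

    return LogisticFit(task=task, covariates=names, coefficients=beta, ses=ses,
                       p_values=pvals, aic=aic, n=len(df), bmd_sd_used=bmd_sd,
                       converged=converged, separation=separation, alpha=alpha)


@dataclass(frozen=True)
class ModelComparison:
    fits: tuple
    delta_aic: tuple
    preferred: int

    def to_dict(self) -> dict:
        return {"models": [f.to_dict() for f in self.fits],
                "delta_aic": list(self.delta_aic), "preferred": self.preferred}


def stepwise_compare(records: pd.DataFrame, task: str,
                     include_sex: bool | None = None) -> ModelComparison:
    """Stepwise AIC comparison: fracture first, then add BMD.

    Model 1: age + fracture (+ sex for the sex-shared walking task);
    Model 2: Model 1 + BMD per SD.
    """
    if include_sex is None:
        include_sex = task == "walk_all_day"
    base = ("age", "fracture") + (("sex_male",) if include_sex else ())
    fit1 = fit_cessation(records, task, covariates=base)
    fit2 = fit_cessation(records, task, covariates=base + ("bmd_sd",))
    aics = np.array([fit1.aic, fit2.aic])
    best = float(np.nanmin(aics))
    delta = tuple(float(a - best) for a in aics)
    preferred = int(np.nanargmin(aics))
    return ModelComparison(fits=(fit1, fit2), delta_aic=delta, preferred=preferred)


@dataclass(frozen=True)
class QValueSet:
    p_values: np.ndarray
    q_values: np.ndarray
    method: str   # "storey" | "bh"
    pi0: float

    def to_dict(self) -> dict:
        return {"p_values": [float(p) for p in self.p_values],
                "q_values": [float(q) for q in self.q_values],
                "method": self.method, "pi0": self.pi0}


def qvalues(p_values, method: str = "storey", lam: float = 0.5) -> QValueSet:
    """FDR q-values across a family of tests.

    Storey: pi0 = min(1, #{p > lambda} / ((1 - lambda) m)); q for the
    i-th ordered p is min_{j >= i} pi0 * m * p_(j) / j. BH is the same
    step-up with pi0 = 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "storey":
        if not 0 <= lam < 1:
            raise ValueError("lambda must lie in [0, 1)")
        pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueSet(p_values=p, q_values=q, method=method, pi0=pi0)


def p_still(fit, age: float, fracture: bool, bmd_sd: float = 0.0,
            sex: str | None = None) -> float:
    """Probability of still performing the task at the given covariates."""
    return fit.p_still(age, fracture, bmd_sd=bmd_sd, sex=sex)


@dataclass(frozen=True)
class MediationResult:
    """Fracture-OR change when anthropometrics enter the cessation model.

    Attenuation toward 1 after adjustment is consistent with anthropometric
    status mediating the fracture-cessation association; strengthening
    argues against reverse causality through body condition.
    """

    task: str
    base: LogisticFit
    adjusted: LogisticFit
    or_change: float          # adjusted OR_fracture - base OR_fracture
    log_or_change: float

    def to_dict(self) -> dict:
        return {"task": self.task, "base": self.base.to_dict(),
                "adjusted": self.adjusted.to_dict(),
                "or_change": self.or_change, "log_or_change": self.log_or_change}


def mediation_check(records: pd.DataFrame, task: str,
                    anthropometrics: tuple = ("fat_free_mass", "fat_mass"),
                    include_sex: bool | None = None) -> MediationResult:
    """Refit the cessation model with anthropometric covariates added.

    ``weight`` equals fat mass + fat-free mass, so the default adjustment
    set uses the two components; passing all three would make the design
    singular.
    """
    if include_sex is None:
        include_sex = task == "walk_all_day"
    base_cov = ("age", "fracture") + (("sex_male",) if include_sex else ()) + ("bmd_sd",)
    base = fit_cessation(records, task, covariates=base_cov)
    adjusted = fit_cessation(records, task,
                             covariates=base_cov + tuple(anthropometrics))
    d_log = adjusted.coefficients[adjusted.covariates.index("fracture")] \
        - base.coefficients[base.covariates.index("fracture")]
    return MediationResult(
        task=task, base=base, adjusted=adjusted,
        or_change=adjusted.odds_ratio("fracture") - base.odds_ratio("fracture"),
        log_or_change=float(d_log))
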