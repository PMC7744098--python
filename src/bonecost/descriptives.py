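"""Prevalence estimates, contingency tests, log-binomial fracture-risk
models, and the reverse-causality comparisons.

Conventions: prevalence confidence intervals are Wald on the proportion
scale and reported in integer percent (Wilson available behind a flag);
2x2 tables use chi-square with Yates continuity correction unless any
expected cell is below 5, in which case Fisher's exact test is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .synthetic import task_column

__all__ = [
    "PrevalenceEstimate",
    "ContingencyResult",
    "RRModel",
    "BMDDifference",
    "wald_prevalence_ci",
    "crosstab_test",
    "fit_log_binomial",
    "compare_bmd_by_cessation",
    "reason_frequency_test",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class PrevalenceEstimate:
    p_hat: float            # fraction
    n: int
    ci_low: int             # percent, clipped and integer-rounded
    ci_high: int            # percent
    alpha: float
    method: str = "wald"

    @property
    def percent(self) -> int:
        return round_half_away(100.0 * self.p_hat)

    def to_dict(self) -> dict:
        return {"estimate": self.p_hat, "percent": self.percent,
                "ci": [self.ci_low, self.ci_high], "n": self.n,
                "alpha": self.alpha, "method": self.method}


def wald_prevalence_ci(count: int, n: int, alpha: float = 0.05,
                       method: str = "wald") -> PrevalenceEstimate:
    """Prevalence with a (1-alpha) confidence interval in integer percent.

    Wald: p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), clipped to [0, 1].
    ``method='wilson'`` switches to the Wilson score interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    p = count / n
    if method == "wald":
        z = st.norm.ppf(1.0 - alpha / 2.0)
        half = z * math.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        lo, hi = sm.stats.proportion_confint(count, n, alpha=alpha, method="wilson")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = min(max(lo, 0.0), 1.0)
    hi = min(max(hi, 0.0), 1.0)
    return PrevalenceEstimate(p_hat=p, n=n,
                              ci_low=round_half_away(100.0 * lo),
                              ci_high=round_half_away(100.0 * hi),
                              alpha=alpha, method=method)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple
    statistic: float
    p_value: float
    method: str  # "chi_square" | "fisher_exact"

    def to_dict(self) -> dict:
        return {"table": [list(r) for r in self.table], "statistic": self.statistic,
                "p_value": self.p_value, "method": self.method}


def crosstab_test(table, correction: bool = True) -> ContingencyResult:
    """Two-sided test of association on a 2x2 count table.

    Chi-square with Yates continuity correction when every expected cell is
    at least 5; Fisher's exact test otherwise. Both margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins of the 2x2 table must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    tbl = tuple(tuple(int(v) for v in row) for row in t)
    if expected.min() < 5:
        odds, p = st.fisher_exact(t, alternative="two-sided")
        return ContingencyResult(table=tbl, statistic=float(odds),
                                 p_value=float(p), method="fisher_exact")
    chi2, p, _, _ = st.chi2_contingency(t, correction=correction)
    return ContingencyResult(table=tbl, statistic=float(chi2),
                             p_value=float(p), method="chi_square")


@dataclass(frozen=True)
class RRModel:
    """Log-binomial GLM: coefficients are log relative risks."""

    outcome: str
    covariates: tuple
    coefficients: np.ndarray
    ses: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray          # on the RR scale
    ci_high: np.ndarray
    converged: bool
    n: int
    bmd_sd_used: float
    method: str = "log_binomial"
    boundary: bool = False  # MLE pinned at a fitted probability of 1

    @property
    def relative_risks(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def rr(self, covariate: str) -> float:
        return float(np.exp(self.coefficients[self.covariates.index(covariate)]))

    def rr_ci(self, covariate: str) -> tuple[float, float]:
        i = self.covariates.index(covariate)
        return float(self.ci_low[i]), float(self.ci_high[i])

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "covariates": list(self.covariates),
                "rr": [float(v) for v in self.relative_risks],
                "ci": [[float(l), float(h)] for l, h in zip(self.ci_low, self.ci_high)],
                "p_values": [float(p) for p in self.p_values],
                "converged": self.converged, "n": self.n, "method": self.method}


def fit_log_binomial(records: pd.DataFrame, outcome: str = "fracture",
                     covariates: tuple = ("age", "bmd_per_sd"),
                     alpha: float = 0.05,
                     poisson_fallback: bool = False) -> RRModel:
    """Relative-risk regression via a binomial GLM with log link.

    BMD enters per sample SD when ``bmd_per_sd`` is requested; the SD used
    is stored on the fit. Non-convergence (the log link does not bound
    fitted probabilities below 1, so the MLE may sit on the boundary) is
    flagged, and optionally a Poisson working model with robust (HC1)
    variance can be requested explicitly instead.
    """
    df = records.dropna(subset=[outcome, *(c for c in covariates if c != "bmd_per_sd")])
    y = df[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        X, names, bmd_sd = _rr_design(df, covariates)
        k = X.shape[1]
        nan = np.full(k, np.nan)
        return RRModel(outcome=outcome, covariates=names, coefficients=nan,
                       ses=nan, p_values=nan, ci_low=nan, ci_high=nan,
                       converged=False, n=len(df), bmd_sd_used=bmd_sd)
    X, names, bmd_sd = _rr_design(df, covariates)

    if poisson_fallback:
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC1")
        converged = bool(fit.converged)
        boundary = False
    else:
        start = np.zeros(X.shape[1])
        start[0] = math.log(max(y.mean(), 1e-6))
        import warnings
        with warnings.catch_warnings():
            # statsmodels warns that the log link can leave the binomial
            # domain — that is the point of a log-binomial model, and the
            # boundary check below handles it
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X,
                           family=sm.families.Binomial(link=sm.families.links.Log()))
        try:
            fit = model.fit(start_params=start, maxiter=200)
            mu = fit.predict(X)
            # the MLE may sit exactly on the mu = 1 boundary (risks near 1
            # on the data support); beyond 1 the fit is invalid. A boundary
            # solution attenuates the RR and corrupts Wald SEs — the
            # explicit Poisson-robust option is the consistent estimator
            # there.
            boundary = bool(np.any(mu >= 1.0 - 1e-6))
            converged = bool(fit.converged) and bool(np.all(mu <= 1.0 + 1e-8))
        except (ValueError, sm.tools.sm_exceptions.PerfectSeparationError):
            nan = np.full(X.shape[1], np.nan)
            return RRModel(outcome=outcome, covariates=names, coefficients=nan,
                           ses=nan, p_values=nan, ci_low=nan, ci_high=nan,
                           converged=False, n=len(df), bmd_sd_used=bmd_sd)

    z = st.norm.ppf(1.0 - alpha / 2.0)
    beta, se = np.asarray(fit.params), np.asarray(fit.bse)
    return RRModel(
        outcome=outcome, covariates=names, coefficients=beta, ses=se,
        p_values=np.asarray(fit.pvalues),
        ci_low=np.exp(beta - z * se), ci_high=np.exp(beta + z * se),
        converged=converged, n=len(df), bmd_sd_used=bmd_sd,
        method="poisson_robust" if poisson_fallback else "log_binomial",
        boundary=boundary,
    )


def _rr_design(df: pd.DataFrame, covariates):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    bmd_sd = float("nan")
    for cov in covariates:
        if cov == "bmd_per_sd":
            bmd = df["bmd"].to_numpy(dtype=float)
            bmd_sd = float(np.std(bmd, ddof=1))
            cols.append((bmd - bmd.mean()) / bmd_sd)
        else:
            cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), tuple(names), bmd_sd


@dataclass(frozen=True)
class BMDDifference:
    """Adjusted mean BMD difference (ceased - continuing), mg/cm^3."""

    task: str
    difference: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float
    n_ceased: int
    n_continuing: int
    adjust: tuple

    def to_dict(self) -> dict:
        return {"task": self.task, "difference": self.difference,
                "ci": [self.ci_low, self.ci_high], "p_value": self.p_value,
                "n_ceased": self.n_ceased, "n_continuing": self.n_continuing,
                "adjust": list(self.adjust)}


def compare_bmd_by_cessation(records: pd.DataFrame, task: str,
                             adjust: tuple = ("age", "fat_free_mass"),
                             alpha: float = 0.05) -> BMDDifference:
    """Linear-model comparison of BMD between ceasers and continuers.

    Fits BMD ~ ceased + adjustment covariates by OLS and reports the ceased
    coefficient (ceased - continuing) with a Wald CI.
    """
    col = task_column(task)
    df = records.dropna(subset=[col, "bmd", *adjust])
    ceased = df[col].astype(bool).to_numpy()
    if ceased.all() or not ceased.any():
        raise ValueError(f"both cessation groups must be non-empty for {task}")
    X = np.column_stack([np.ones(len(df)), ceased.astype(float)]
                        + [df[c].to_numpy(dtype=float) for c in adjust])
    fit = sm.OLS(df["bmd"].to_numpy(dtype=float), X).fit()
    z = st.t.ppf(1.0 - alpha / 2.0, df=fit.df_resid)
    b, se = float(fit.params[1]), float(fit.bse[1])
    return BMDDifference(task=task, difference=b,
                         ci_low=b - z * se, ci_high=b + z * se, se=se,
                         p_value=float(fit.pvalues[1]),
                         n_ceased=int(ceased.sum()),
                         n_continuing=int((~ceased).sum()), adjust=tuple(adjust))


def reason_frequency_test(records: pd.DataFrame, task: str,
                          reason: str) -> ContingencyResult:
    """Fracture x reason association among those who ceased the task.

    Builds the 2x2 (fracture status x reports-reason) table restricted to
    ceasers. When the reason shows no variation among ceasers there is no
    association to test and a degenerate result with p = 1 is returned.
    """
    col = task_column(task)
    df = records.dropna(subset=[col])
    df = df[df[col].astype(bool)]
    if df.empty:
        raise ValueError(f"no records ceased {task}")
    has_reason = df["reasons"].map(lambda s: reason in str(s).split(";")).to_numpy()
    frac = df["fracture"].to_numpy(dtype=bool)
    table = np.array([
        [int((frac & has_reason).sum()), int((frac & ~has_reason).sum())],
        [int((~frac & has_reason).sum()), int((~frac & ~has_reason).sum())],
    ])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        tbl = tuple(tuple(int(v) for v in row) for row in table)
        return ContingencyResult(table=tbl, statistic=float("nan"),
                                 p_value=1.0, method="fisher_exact")
    return crosstab_test(table)
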