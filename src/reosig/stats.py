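"""Survival and categorical statistics used throughout the pipeline.

Cox proportional-hazards fits (Efron tie handling, Wald inference),
Kaplan-Meier curves, the log-rank test, Harrell's concordance index,
Benjamini-Hochberg FDR adjustment, the pooled-variance two-sample
t-test and 2x2 / r x c contingency tests.

Model fitting delegates to ``lifelines`` (Cox, Kaplan-Meier, log-rank)
and ``scipy`` / ``statsmodels`` (t-test, exact/chi-square tests, FDR);
this module adds the input validation, error taxonomy and result
containers the pipeline relies on.  The concordance index is computed
here directly so the comparable-pair and tie conventions are explicit:
a pair is comparable iff the times differ and the earlier subject had
an event; it is concordant when the earlier subject has the strictly
higher risk score; tied scores count 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatsError",
    "DegenerateCovariateError",
    "SurvivalData",
    "CoxFit",
    "KMCurve",
    "LogRankResult",
    "ContingencyResult",
    "cox_fit",
    "cox_screen_univariate",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "bh_fdr",
    "two_sample_t_test",
    "fisher_exact_2x2",
    "chi_square_independence",
]

Z_95 = 1.96  # Wald 95% CI multiplier


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


class DegenerateCovariateError(StatsError):
    """A covariate (or gene) carries no usable variation."""


@dataclass
class SurvivalData:
    """Aligned follow-up times (months) and event indicators (1/0)."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise StatsError("times and events must be aligned 1-d arrays")
        if self.times.size == 0:
            raise StatsError("empty survival data")
        if (self.times < 0).any():
            raise StatsError("negative survival time")
        if not np.isin(self.events, (0, 1)).all():
            raise StatsError("events must be 0/1")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, mask) -> "SurvivalData":
        mask = np.asarray(mask)
        return SurvivalData(self.times[mask], self.events[mask])

    @classmethod
    def from_clinical(cls, clinical) -> "SurvivalData":
        df = clinical.data
        return cls(df["rfs_months"].to_numpy(), df["event"].to_numpy())


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit (one row per covariate)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    p_values: np.ndarray
    ci95_lower: np.ndarray
    ci95_upper: np.ndarray
    converged: bool
    n_used: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hazard_ratios,
                "p": self.p_values,
                "ci95_lower": self.ci95_lower,
                "ci95_upper": self.ci95_upper,
            },
            index=self.names,
        )


@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier step function with S(0) = 1."""

    times: np.ndarray       # event times where the curve drops (ascending)
    survival: np.ndarray    # S(t) just after each drop
    at_risk: np.ndarray     # risk-set size just before each drop

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def as_triples(self) -> list[tuple[float, float, int]]:
        return [
            (float(t), float(s), int(r))
            for t, s, r in zip(self.times, self.survival, self.at_risk)
        ]


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class ContingencyResult:
    observed: np.ndarray
    test: str
    p_value: float
    statistic: float | None = None


def _validate_covariates(covariates) -> pd.DataFrame:
    if isinstance(covariates, pd.DataFrame):
        X = covariates.copy()
    else:
        arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        if arr.shape[0] == 1 and arr.shape[1] > 1:
            arr = arr.T
        X = pd.DataFrame(arr, columns=[f"x{i+1}" for i in range(arr.shape[1])])
    X = X.astype(float)
    if not np.isfinite(X.to_numpy()).all():
        raise StatsError("covariates contain non-finite values")
    for name in X.columns:
        if X[name].nunique() <= 1:
            raise DegenerateCovariateError(f"degenerate covariate: {name}")
    return X


def cox_fit(covariates, survival: SurvivalData) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Partial likelihood with Efron tie handling maximised by Newton-type
    iterations (via lifelines); Wald CIs exp(coef +/- 1.96 se).
    Requires n >= p + 2, at least one event, and no constant covariate
    column.  Monotone-likelihood / non-converging fits are returned with
    ``converged=False`` rather than raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    X = _validate_covariates(covariates)
    n, p = X.shape
    if len(survival) != n:
        raise StatsError("covariate rows and survival records misaligned")
    if n < p + 2:
        raise StatsError(f"need n >= p + 2 (n={n}, p={p})")
    if survival.n_events < 1:
        raise StatsError("at least one event required for Cox fitting")

    df = X.reset_index(drop=True)
    df["__T"] = survival.times
    df["__E"] = survival.events
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="__T", event_col="__E")
        except ConvergenceError:
            return CoxFit(
                names=list(X.columns),
                coef=np.full(p, np.nan),
                se=np.full(p, np.nan),
                hazard_ratios=np.full(p, np.nan),
                p_values=np.full(p, np.nan),
                ci95_lower=np.full(p, np.nan),
                ci95_upper=np.full(p, np.nan),
                converged=False,
                n_used=n,
            )
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False

    coef = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    z = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    p_values = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # huge se on flagged non-converged fits
        return CoxFit(
            names=list(X.columns),
            coef=coef,
            se=se,
            hazard_ratios=np.exp(coef),
            p_values=p_values,
            ci95_lower=np.exp(coef - Z_95 * se),
            ci95_upper=np.exp(coef + Z_95 * se),
            converged=converged,
            n_used=n,
        )


def cox_screen_univariate(covariate_set: pd.DataFrame, survival: SurvivalData,
                          alpha: float) -> list[str]:
    """Names of covariates with univariate Cox Wald p strictly below alpha.

    Each covariate is fit on its own complete cases (rows where it is
    non-missing).  Degenerate or non-converging covariates are excluded
    with a logged warning.  Output preserves column order.
    """
    selected: list[str] = []
    for name in covariate_set.columns:
        col = covariate_set[name]
        mask = col.notna().to_numpy()
        if mask.sum() < 3:
            logger.warning("covariate %s: too few complete cases, skipped", name)
            continue
        try:
            fit = cox_fit(col[mask].to_frame(), survival.subset(mask))
        except DegenerateCovariateError:
            logger.warning("covariate %s is degenerate, skipped", name)
            continue
        except StatsError as exc:
            logger.warning("covariate %s: %s, skipped", name, exc)
            continue
        if not fit.converged:
            logger.warning("covariate %s: Cox fit did not converge, skipped", name)
            continue
        if fit.p_values[0] < alpha:
            selected.append(name)
    return selected


def km_estimate(survival: SurvivalData) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimator of the survival function."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(survival.times, event_observed=survival.events)
    table = kmf.event_table
    drops = table[table["observed"] > 0]
    times = drops.index.to_numpy(dtype=float)
    at_risk = drops["at_risk"].to_numpy(dtype=int)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def logrank_test(group_labels, survival: SurvivalData) -> LogRankResult:
    """k-sample log-rank test; chi-square with k - 1 df."""
    from lifelines.statistics import multivariate_logrank_test

    labels = np.asarray(group_labels)
    if labels.shape[0] != len(survival):
        raise StatsError("labels and survival misaligned")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise StatsError("log-rank test needs at least two groups")
    if survival.n_events < 1:
        raise StatsError("log-rank test needs at least one event")
    res = multivariate_logrank_test(survival.times, labels, survival.events)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


def concordance_index(risk_scores, survival: SurvivalData) -> float:
    """Harrell's C for right-censored data.

    Comparable pair: times differ and the earlier subject had an event.
    Concordant: the earlier subject has the strictly higher risk score.
    Tied risk scores contribute 0.5.
    """
    r = np.asarray(risk_scores, dtype=float)
    if r.shape[0] != len(survival):
        raise StatsError("risk scores and survival misaligned")
    t, e = survival.times, survival.events.astype(bool)
    # comparable[i, j]: i strictly earlier than j and i had the event
    comparable = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise StatsError("no comparable pair for concordance index")
    concordant = ((r[:, None] > r[None, :]) & comparable).sum()
    tied = ((r[:, None] == r[None, :]) & comparable).sum()
    return float((concordant + 0.5 * tied) / n_comp)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t_test(x, y) -> tuple[float, float]:
    """Pooled-variance (Student) two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("each group needs at least 2 values")
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
    if pooled <= 0:
        raise DegenerateCovariateError("degenerate gene: zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _as_count_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise StatsError("contingency counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise StatsError("contingency counts must be non-negative")
    return arr


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table (minimum-likelihood convention, relative comparison
    tolerance 1e-7).
    """
    arr = _as_count_table(table)
    if arr.shape != (2, 2):
        raise StatsError("fisher_exact_2x2 requires a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("all margins must be positive")
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return ContingencyResult(observed=arr, test="fisher_exact", p_value=float(p))


def chi_square_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = _as_count_table(table)
    if min(arr.shape) < 2:
        raise StatsError("chi-square requires at least a 2x2 table")
    expected = sps.contingency.expected_freq(arr)
    if (expected <= 0).any():
        raise StatsError("zero expected count in contingency table")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        observed=arr, test="chi_square", p_value=float(p), statistic=float(stat)
    )
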