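"""Cohort statistics for the swallowing sound index.

Implements the analysis layer applied to index-vs-clinical-covariate
cohorts: group comparison (Welch t / chi-square), the two-step factor
analysis (univariate screen at p < 0.05, then one age-adjusted linear
model per selected factor), ROC cutoff selection by Youden's J, and the
two-sample t-test sample-size computation.

Although the study protocol labels the second step "multiple logistic
analysis", the reported per-factor coefficients (e.g. 0.006 index units
per ALSFRS-R point with a 0.003-0.010 CI) are on the scale of a linear
model of the continuous index, so linear regression of the index on
factor + age is the default here; a logistic variant (outcome = index
below a cutoff) is available behind ``family="logistic"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for degenerate or mis-specified statistical inputs."""


#: Factors screened against the index, in cohort-table order.
DEFAULT_FACTORS = (
    "age", "sex", "bmi", "duration_months", "alsfrs_r_total", "alsfrs_r_bulbar",
    "onset_type", "albumin", "pct_vc", "tongue_pressure", "masa_total",
    "masa_pharyngeal",
)


def _numeric_factor(cohort: pd.DataFrame, factor: str) -> np.ndarray:
    """Covariate as a float column; binary categoricals are 0/1-coded."""
    col = cohort[factor]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(col.dropna()))
        if len(levels) > 2:
            raise StatsError(f"factor {factor!r} has {len(levels)} levels; expected 2")
        return (col == levels[-1]).astype(float).to_numpy()
    return col.astype(float).to_numpy()


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(
    values_a: Sequence, values_b: Sequence, kind: Literal["continuous", "categorical"]
) -> tuple[float, float]:
    """Two-sided Welch t-test (continuous) or chi-square test (categorical).

    Returns ``(statistic, p_value)``.
    """
    if kind == "continuous":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise StatsError("need >= 2 observations per group")
        if a.std() == 0 and b.std() == 0:
            raise StatsError("zero variance in both groups")
        res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "categorical":
        a = pd.Series(list(values_a))
        b = pd.Series(list(values_b))
        if a.empty or b.empty:
            raise StatsError("empty group")
        table = pd.crosstab(
            pd.Series(["a"] * len(a) + ["b"] * len(b)), pd.concat([a, b], ignore_index=True)
        )
        chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        return float(chi2), float(p)
    raise StatsError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# two-step factor analysis


def univariate_screen(
    cohort: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-factor simple linear models of the index; select p < alpha plus age.

    Age is always carried into the adjusted step regardless of its own
    p-value.  Returns ``(table, selected)`` where ``table`` has one row per
    factor with its slope and p-value.
    """
    if "index" not in cohort:
        raise StatsError("cohort has no 'index' column")
    rows = []
    selected: list[str] = []
    y = cohort["index"].astype(float).to_numpy()
    for factor in factors:
        x = _numeric_factor(cohort, factor)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise StatsError(f"factor {factor!r}: fewer than 3 complete rows")
        if np.std(x[ok]) == 0:
            raise StatsError(f"factor {factor!r} is constant")
        fit = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
        p = float(fit.pvalues[1])
        rows.append({"factor": factor, "slope": float(fit.params[1]), "univariate_p": p})
        if p < alpha:
            selected.append(factor)
    if "age" in factors and "age" not in selected:
        selected.append("age")
    return pd.DataFrame(rows), selected


@dataclass(frozen=True)
class FactorModelResult:
    factor: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    univariate_p: float | None = None


def adjusted_model(
    cohort: pd.DataFrame,
    factor: str,
    family: Literal["linear", "logistic"] = "linear",
    outcome_cutoff: float | None = None,
) -> FactorModelResult:
    """Age-adjusted model for one factor: index ~ factor + age.

    Linear regression by default (coefficient in index units per factor
    unit, 95% CI).  With ``family="logistic"``, the outcome is the binary
    event index < ``outcome_cutoff`` and the coefficient is a log odds
    ratio.  Factors nearly collinear with age are rejected.
    """
    x = _numeric_factor(cohort, factor)
    age = cohort["age"].astype(float).to_numpy()
    y = cohort["index"].astype(float).to_numpy()
    ok = np.isfinite(x) & np.isfinite(age) & np.isfinite(y)
    x, age, y = x[ok], age[ok], y[ok]
    if x.std() == 0:
        raise StatsError(f"factor {factor!r} is constant")
    if factor != "age":
        r = np.corrcoef(x, age)[0, 1]
        if abs(r) > 0.999:
            raise StatsError(f"factor {factor!r} is collinear with age (|r|={abs(r):.4f})")
        design = sm.add_constant(np.column_stack([x, age]))
    else:
        design = sm.add_constant(x[:, None])
    if np.linalg.cond(design) > 1e10:
        raise StatsError(f"ill-conditioned design for factor {factor!r}")

    if family == "linear":
        fit = sm.OLS(y, design).fit()
    elif family == "logistic":
        if outcome_cutoff is None:
            raise StatsError("logistic family requires outcome_cutoff")
        event = (y < outcome_cutoff).astype(float)
        if event.min() == event.max():
            raise StatsError("logistic outcome is single-class at this cutoff")
        fit = sm.Logit(event, design).fit(disp=0)
    else:
        raise StatsError(f"unknown family {family!r}")
    ci = fit.conf_int()
    ci = np.asarray(ci)
    return FactorModelResult(
        factor=factor,
        coefficient=float(fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        n=int(y.shape[0]),
    )


def two_step_analysis(
    cohort: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate screen then per-factor age-adjusted models.

    One row per factor; adjusted columns are filled only for selected
    factors (age itself is adjusted only when selected on its own merit,
    mirroring the per-factor table layout of the two-step protocol).
    """
    table, selected = univariate_screen(cohort, factors, alpha)
    records = []
    for _, row in table.iterrows():
        rec = dict(row)
        factor = row["factor"]
        if factor in selected and not (factor == "age" and row["univariate_p"] >= alpha):
            res = adjusted_model(cohort, factor)
            rec.update(
                coefficient=res.coefficient, ci_low=res.ci_low,
                ci_high=res.ci_high, adjusted_p=res.p_value,
            )
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: Literal["low", "high"]  # which side of the cutoff predicts impairment
    p_value: float


def roc_cutoff(index: Sequence[float], outcome: Sequence[int]) -> RocResult:
    """Empirical ROC of the index against a binary impairment outcome.

    AUC is the Mann-Whitney concordance probability.  The impaired class
    (outcome 1) is expected to have LOW index; if the data run the other
    way the direction is flipped automatically and reported.  The cutoff
    maximises Youden's J = sensitivity + specificity - 1 over the observed
    index values, ties broken to the lower cutoff (favouring sensitivity
    for the "low" direction).  ``p_value`` is the two-sided Mann-Whitney
    test of group separation.
    """
    idx = np.asarray(index, dtype=float)
    out = np.asarray(outcome).astype(bool)
    if idx.shape != out.shape:
        raise StatsError("index and outcome length mismatch")
    if not out.any() or out.all():
        raise StatsError("both outcome classes required")
    impaired, healthy = idx[out], idx[~out]

    mw = sps.mannwhitneyu(healthy, impaired, alternative="two-sided")
    auc_low = float(mw.statistic) / (healthy.size * impaired.size)  # P(healthy > impaired)
    direction: Literal["low", "high"] = "low"
    if auc_low < 0.5:
        direction = "high"
    auc = auc_low if direction == "low" else 1.0 - auc_low

    best = None
    for c in np.unique(idx):
        if direction == "low":
            pred = idx <= c
        else:
            pred = idx >= c
        sens = float((pred & out).sum() / out.sum())
        spec = float((~pred & ~out).sum() / (~out).sum())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    assert best is not None
    _, cutoff, sens, spec = best
    return RocResult(auc=auc, cutoff=cutoff, sensitivity=sens, specificity=spec,
                     direction=direction, p_value=float(mw.pvalue))


# ---------------------------------------------------------------------------
# sample size


@dataclass(frozen=True)
class PowerSpec:
    """Two-group t-test design: detect ``min_difference`` at residual ``sd``."""

    min_difference: float = 0.08
    sd: float = 0.06
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.min_difference <= 0:
            raise StatsError("min_difference must be positive")
        if self.sd <= 0:
            raise StatsError("sd must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise StatsError("alpha and power must be in (0, 1)")


def power_at(n_per_group: int, spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test at equal group size n."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    ncp = (spec.min_difference / spec.sd) * math.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def sample_size(spec: PowerSpec, max_n_per_group: int = 100_000) -> int:
    """Smallest total n (two equal groups) achieving the target power.

    Solved iteratively with noncentral-t power at t-distribution critical
    values; returns the total across both groups (always even).
    """
    for n in range(2, max_n_per_group + 1):
        if power_at(n, spec) >= spec.power:
            return 2 * n
    raise StatsError("required sample size exceeds the search bound")
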