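"""Statistical outputs: per-state and grand summaries, the aggregate
cross-arm regression, the seven-bin behavioral analysis and covariate-
adjusted clustered arm comparisons.

Conventions follow the source tables: the grand mean is the *unweighted*
mean of the ten per-state means; the proportion non-negative counts values
``U >= 0``; "trade time exhausted" counts tasks ending at ``T = 0``; display
rounding is two decimals for values and one for percentages, with all
internal computation unrounded.  Respondents contribute five values each, so
arm comparisons cluster on respondent: linear models carry a respondent
random intercept (with an OLS + cluster-robust fallback on non-convergence)
and logistic comparisons use GEE with exchangeable working correlation.
p-values are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import DomainError


class EstimationError(RuntimeError):
    """A model could not be estimated on the given data."""


# ---------------------------------------------------------------------------
# Arm summaries
# ---------------------------------------------------------------------------


@dataclass
class StateStat:
    mean: float
    sd: float
    n: int


@dataclass
class ArmSummary:
    per_state: Dict[str, StateStat]
    n_records: int
    n_nonnegative: int
    prop_nonnegative: float
    grand_mean_unweighted: float
    exhaustion_count: int
    exhaustion_fraction: float


def summarize_arm(records: pd.DataFrame) -> ArmSummary:
    """Unadjusted per-state means/SDs, proportion non-negative, unweighted
    grand mean and trade-time exhaustion for one arm's records."""
    if len(records) == 0:
        raise DomainError("no records to summarize")
    if records["arm"].nunique() > 1:
        raise DomainError("summarize_arm expects a single arm")
    per_state: Dict[str, StateStat] = {}
    for state, grp in records.groupby("state"):
        n = len(grp)
        sd = float(grp["U"].std(ddof=1)) if n > 1 else 0.0
        per_state[str(state)] = StateStat(mean=float(grp["U"].mean()), sd=sd, n=n)
    n_records = len(records)
    n_nonneg = int((records["U"] >= 0).sum())
    exhausted = int((records["T"] == 0).sum())
    return ArmSummary(
        per_state=per_state,
        n_records=n_records,
        n_nonnegative=n_nonneg,
        prop_nonnegative=n_nonneg / n_records,
        grand_mean_unweighted=float(
            np.mean([s.mean for s in per_state.values()])
        ),
        exhaustion_count=exhausted,
        exhaustion_fraction=exhausted / n_records,
    )


def grand_mean_from_state_means(means: Sequence[float]) -> float:
    """Unweighted grand mean of per-state means."""
    if len(means) == 0:
        raise DomainError("no state means")
    return float(np.mean(means))


def proportion_from_counts(count: int, total: int) -> float:
    """A table proportion, as a fraction."""
    if total < 1 or not 0 <= count <= total:
        raise DomainError(f"bad counts {count}/{total}")
    return count / total


# ---------------------------------------------------------------------------
# Aggregate cross-arm regression
# ---------------------------------------------------------------------------


@dataclass
class AggregateRegression:
    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    n: int


def aggregate_arm_regression(
    x: Sequence[float], y: Sequence[float]
) -> AggregateRegression:
    """OLS of the standard-arm state means ``y`` on the experimental-arm
    state means ``x``; 95% CIs from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("need at least 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate regressor: x values are all equal")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return AggregateRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Seven value bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValueBin:
    label: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool

    def contains(self, u: float) -> bool:
        above = u >= self.lower if self.lower_closed else u > self.lower
        below = u <= self.upper if self.upper_closed else u < self.upper
        return above and below


#: The seven bins partitioning [-2, 1], with {0} as its own bin.
SEVEN_BINS: Tuple[ValueBin, ...] = (
    ValueBin("-2<=x<-1.5", -2.0, -1.5, True, False),
    ValueBin("-1.5<=x<-1", -1.5, -1.0, True, False),
    ValueBin("-1<=x<-0.5", -1.0, -0.5, True, False),
    ValueBin("-0.5<=x<0", -0.5, 0.0, True, False),
    ValueBin("0", 0.0, 0.0, True, True),
    ValueBin("0<x<=0.5", 0.0, 0.5, False, True),
    ValueBin("0.5<x<=1", 0.5, 1.0, False, True),
)

#: Bins whose values lie within 0.5 of the dead point.
MID_BIN_LABELS = ("-0.5<=x<0", "0", "0<x<=0.5")


def assign_bin(u: float) -> ValueBin:
    if not -2.0 <= u <= 1.0:
        raise DomainError(f"value {u} outside [-2, 1]")
    if u == 0.0:
        return SEVEN_BINS[4]
    for b in SEVEN_BINS:
        if b.label != "0" and b.contains(u):
            return b
    raise DomainError(f"value {u} not matched by any bin")  # pragma: no cover


def bin_records(records: pd.DataFrame) -> Dict[ValueBin, pd.DataFrame]:
    """Partition records over the seven value bins."""
    labels = records["U"].map(lambda u: assign_bin(float(u)).label)
    by_label = {b.label: b for b in SEVEN_BINS}
    out = {b: records.iloc[0:0] for b in SEVEN_BINS}
    for label, grp in records.groupby(labels):
        out[by_label[label]] = grp
    return out


# ---------------------------------------------------------------------------
# Clustered arm comparisons
# ---------------------------------------------------------------------------


@dataclass
class ArmComparison:
    outcome: str
    estimate: float  # adjusted difference (continuous) or odds ratio (binary)
    p_value: float
    model: str
    covariates: Tuple[str, ...] = ()


_CATEGORICAL = {"age_group", "gender", "education", "state"}

DEFAULT_COVARIATES = ("age_group", "gender", "education", "state")


def _formula(outcome: str, covariates: Sequence[str]) -> str:
    terms = ["_arm_ind"]
    for c in covariates:
        terms.append(f"C({c})" if c in _CATEGORICAL else c)
    return f"{outcome} ~ " + " + ".join(terms)


def _prepare(records: pd.DataFrame, outcome: str, covariates: Sequence[str]) -> pd.DataFrame:
    if records["arm"].nunique() != 2:
        raise DomainError("compare_arms needs records from both arms")
    df = records.copy()
    df["_arm_ind"] = (df["arm"] == "experimental").astype(int)
    for c in covariates:
        if c not in df.columns:
            raise DomainError(f"covariate {c!r} missing from records")
        if df[c].nunique() < 2:
            raise EstimationError(
                f"degenerate covariate {c!r}: single level in these records"
            )
    return df


def compare_arms(
    records: pd.DataFrame,
    outcome: str = "U",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    binary: bool = False,
) -> ArmComparison:
    """Covariate-adjusted arm effect with respondent-level clustering.

    Continuous outcomes: linear model with a respondent random intercept
    (REML); on non-convergence, OLS with cluster-robust standard errors.
    Binary outcomes: logistic GEE with exchangeable working correlation;
    the estimate is the adjusted odds ratio.
    """
    df = _prepare(records, outcome, covariates)
    formula = _formula(outcome, covariates)
    groups = df["respondent_id"]
    if binary:
        model = smf.gee(
            formula,
            groups=groups,
            data=df,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        try:
            fit = model.fit()
        except Exception as exc:  # separation and friends
            raise EstimationError(f"logistic GEE failed: {exc}") from exc
        return ArmComparison(
            outcome=outcome,
            estimate=float(np.exp(fit.params["_arm_ind"])),
            p_value=float(fit.pvalues["_arm_ind"]),
            model="logistic_gee_exchangeable",
            covariates=tuple(covariates),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=groups).fit(reml=True)
            converged = bool(fit.converged) and np.isfinite(
                fit.pvalues["_arm_ind"]
            )
        except Exception:
            fit, converged = None, False
    if converged:
        return ArmComparison(
            outcome=outcome,
            estimate=float(fit.params["_arm_ind"]),
            p_value=float(fit.pvalues["_arm_ind"]),
            model="linear_random_intercept",
            covariates=tuple(covariates),
        )
    ols = smf.ols(formula, df).fit(
        cov_type="cluster", cov_kwds={"groups": groups}
    )
    return ArmComparison(
        outcome=outcome,
        estimate=float(ols.params["_arm_ind"]),
        p_value=float(ols.pvalues["_arm_ind"]),
        model="ols_cluster_robust(fallback)",
        covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# Behavior by resultant value bin
# ---------------------------------------------------------------------------

BEHAVIOR_COVARIATES = ("age_group", "gender", "education")


def behavior_by_bin(
    records: pd.DataFrame,
    metrics: Sequence[str] = ("n_questions", "duration_s"),
    covariates: Sequence[str] = BEHAVIOR_COVARIATES,
) -> pd.DataFrame:
    """Per-bin, per-arm mean (SD, n) of the behavior metrics, with a
    clustered covariate-adjusted arm-comparison p-value per bin and metric.

    Shaped like the source behavior table: 7 bins x metrics x 2 arms.
    Empty cells carry n=0 and NaN statistics.
    """
    binned = bin_records(records)
    rows = []
    for b, grp in binned.items():
        for metric in metrics:
            row: Dict[str, object] = {"bin": b.label, "metric": metric}
            for arm in ("standard", "experimental"):
                sub = grp[grp["arm"] == arm] if len(grp) else grp
                row[f"{arm}_n"] = len(sub)
                row[f"{arm}_mean"] = (
                    float(sub[metric].mean()) if len(sub) else float("nan")
                )
                row[f"{arm}_sd"] = (
                    float(sub[metric].std(ddof=1)) if len(sub) > 1 else float("nan")
                )
            try:
                cmp_res = compare_arms(grp, outcome=metric, covariates=covariates)
                row["p_value"] = cmp_res.p_value
                row["model"] = cmp_res.model
            except (DomainError, EstimationError):
                row["p_value"] = float("nan")
                row["model"] = "not_estimable"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Value histogram
# ---------------------------------------------------------------------------


def value_histogram(
    values: Iterable[float],
    bin_width: float = 0.25,
    value_range: Tuple[float, float] = (-2.0, 1.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of values over half-open intervals ``[lo, hi)`` (topmost
    closed).  Returns (counts, edges); counts sum to the number of values."""
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    v = np.asarray(list(values), dtype=float)
    lo, hi = value_range
    if len(v) and (v.min() < lo or v.max() > hi):
        raise DomainError("values outside histogram range")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = hi
    counts, edges = np.histogram(v, bins=edges)
    return counts, edges
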