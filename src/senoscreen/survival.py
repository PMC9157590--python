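"""Lifespan analytics for mouse cohorts.

Kaplan–Meier product-limit curves, mean lifespan of fully observed cohorts,
percent mean-lifespan extension (rounded half-away-from-zero to one
decimal), Wilcoxon rank-sum comparison of durations (exact by enumeration
for small tie-free samples, normal approximation with tie and continuity
correction otherwise) and the Mantel–Cox log-rank test.

A cohort is a tidy table with columns ``subject_id``, ``duration_days``
(> 0), ``event`` (1 = death observed, 0 = right-censored) and ``group``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "km_curve",
    "mean_lifespan",
    "median_lifespan",
    "percent_extension",
    "wilcoxon_rank_sum",
    "logrank_test",
]

COHORT_COLUMNS = ["subject_id", "duration_days", "event", "group"]


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous survival step function.

    ``times`` are the distinct event times in ascending order and
    ``survival`` the Kaplan–Meier estimate just after each; the curve
    starts at S(0) = 1 and is nonincreasing.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def at(self, t: float) -> float:
        """S(t): probability of surviving beyond time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("duration_days", "event") if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (cohort["duration_days"] <= 0).any():
        raise ValueError("durations must be positive")
    return cohort


def km_curve(cohort: pd.DataFrame) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with right censoring.

    With no censoring the curve equals the empirical survivor function.
    Raises if the cohort contains no observed events.
    """
    cohort = _check_cohort(cohort)
    if int(cohort["event"].sum()) == 0:
        raise ValueError("cohort has no observed events (all censored)")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort["duration_days"], event_observed=cohort["event"])
    sf = kmf.survival_function_
    event_times = np.unique(cohort.loc[cohort["event"] == 1, "duration_days"])
    surv = np.array([float(sf.loc[t].iloc[0]) for t in event_times])
    return SurvivalCurve(times=event_times, survival=surv)


def mean_lifespan(cohort: pd.DataFrame) -> float:
    """Arithmetic mean duration of a fully observed cohort (days).

    Raises when censored records are present — a plain mean is biased
    there; use a restricted-mean survival time on the Kaplan–Meier curve
    instead (``lifelines.utils.restricted_mean_survival_time``).
    """
    cohort = _check_cohort(cohort)
    if (cohort["event"] == 0).any():
        raise ValueError(
            "cohort contains censored records; the arithmetic mean is undefined — "
            "use a restricted-mean survival time on the KM curve instead"
        )
    return float(cohort["duration_days"].mean())


def median_lifespan(cohort: pd.DataFrame) -> float:
    """Median duration of a fully observed cohort (days)."""
    cohort = _check_cohort(cohort)
    if (cohort["event"] == 0).any():
        raise ValueError("cohort contains censored records; use the KM median")
    return float(cohort["duration_days"].median())


def percent_extension(control_mean: float, treated_mean: float) -> float:
    """Percent lifespan extension, rounded half-away-from-zero to 1 decimal.

    ``100 * (treated - control) / control``; e.g. 394 -> 479 days is a
    21.6% extension.
    """
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    pct = 100.0 * (float(treated_mean) - float(control_mean)) / float(control_mean)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test on two duration samples.

    Uses exact enumeration when the pooled sample has at most 12
    observations and no ties, otherwise the normal approximation with tie
    and continuity corrections. Returns ``(U, p)`` with U the Mann–Whitney
    statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    exact = (pooled.size <= 12) and (np.unique(pooled).size == pooled.size)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def logrank_test(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> tuple[float, float]:
    """Mantel–Cox log-rank test between two cohorts (1 df).

    Returns ``(chi_square, p)``. Each cohort must contain at least one
    observed event.
    """
    cohort_a = _check_cohort(cohort_a)
    cohort_b = _check_cohort(cohort_b)
    for name, c in (("first", cohort_a), ("second", cohort_b)):
        if int(c["event"].sum()) == 0:
            raise ValueError(f"{name} cohort has no observed events")
    res = _lifelines_logrank(
        cohort_a["duration_days"],
        cohort_b["duration_days"],
        event_observed_A=cohort_a["event"],
        event_observed_B=cohort_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def compare_groups(cohort: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """All lifespan comparisons between two groups of one cohort table.

    Returns a dict with the two means, the percent extension of
    ``group_b`` over ``group_a``, the Wilcoxon rank-sum and log-rank
    results, and medians.
    """
    sub_a = cohort[cohort["group"] == group_a]
    sub_b = cohort[cohort["group"] == group_b]
    if sub_a.empty or sub_b.empty:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    mean_a = mean_lifespan(sub_a)
    mean_b = mean_lifespan(sub_b)
    u, wilcoxon_p = wilcoxon_rank_sum(
        sub_a["duration_days"].to_numpy(), sub_b["duration_days"].to_numpy()
    )
    chi2, logrank_p = logrank_test(sub_a, sub_b)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_a_days": mean_a,
        "mean_b_days": mean_b,
        "median_a_days": median_lifespan(sub_a),
        "median_b_days": median_lifespan(sub_b),
        "percent_extension": percent_extension(mean_a, mean_b),
        "wilcoxon_U": u,
        "wilcoxon_p": wilcoxon_p,
        "logrank_chi2": chi2,
        "logrank_p": logrank_p,
    }
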