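"""Survival and clinical-association statistics.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
``lifelines``; this module wraps them in the small result types the rest
of the pipeline consumes and adds the ROC optimal-cutoff sweep,
fold-change/t-test group associations, the paired t-test, the Pearson
chi-square for ordinal-score contingency tables, and per-subtype
summaries with a Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .data_model import DataModelError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate tabulated at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class AssociationResult:
    group_means: tuple[float, float]  # (numerator group, denominator group)
    fold_change: float
    numerator: str
    denominator: str
    test: TestResult


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator over the distinct event times.

    Samples censored exactly at an event time are counted at risk there.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise DataModelError("km_estimate: empty input")
    if (times < 0).any():
        raise DataModelError("km_estimate: negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    tbl = tbl[tbl["observed"] > 0]
    event_times = tbl.index.to_numpy(float)
    surv = kmf.survival_function_.loc[event_times].to_numpy().ravel()
    return SurvivalCurve(
        event_times=event_times,
        at_risk=tbl["at_risk"].to_numpy(int),
        events=tbl["observed"].to_numpy(int),
        survival=surv,
    )


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> TestResult:
    """Standard two-group log-rank test (chi-square, df=1)."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise DataModelError("logrank_test: both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("logrank_test: no events in either group")
        return TestResult(statistic=0.0, df=1, p_value=1.0, method="log-rank")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return TestResult(
        statistic=float(res.test_statistic), df=1, p_value=float(res.p_value), method="log-rank"
    )


# ---------------------------------------------------------------------------
# ROC optimal cutoff
# ---------------------------------------------------------------------------


def roc_cutoff(values: np.ndarray, binary_labels: np.ndarray) -> CutoffResult:
    """Optimal dichotomization cutoff by Youden's J over all midpoints.

    High values are treated as test-positive.  Candidate cutoffs are the
    midpoints between adjacent sorted distinct values; ties on J break
    first toward the more balanced sensitivity/specificity pair, then
    toward the lower cutoff.
    """
    values = np.asarray(values, float)
    labels = np.asarray(binary_labels, int)
    if set(np.unique(labels)) - {0, 1}:
        raise DataModelError("binary_labels must be 0/1")
    if labels.min() == labels.max():
        raise DataModelError("both label classes must be present")
    distinct = np.unique(values)
    if distinct.size < 3:
        raise DataModelError("need at least 3 distinct values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best: tuple | None = None
    for c in mids:
        pred = values > c
        sens = float((pred & (labels == 1)).sum()) / n_pos
        spec = float((~pred & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        balance = abs(sens - spec)
        key = (-j, balance, c)
        if best is None or key < best[0]:
            best = (key, c, sens, spec)
    _, c, sens, spec = best
    return CutoffResult(cutoff=float(c), sensitivity=sens, specificity=spec)


def logrank_min_p_cutoff(
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    min_group_frac: float = 0.1,
) -> tuple[float, TestResult]:
    """Cutoff minimizing the log-rank p over midpoint splits that leave at
    least ``min_group_frac`` of samples on each side."""
    values = np.asarray(values, float)
    distinct = np.unique(values)
    if distinct.size < 3:
        raise DataModelError("need at least 3 distinct values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(values)
    best: tuple | None = None
    for c in mids:
        high = values > c
        if high.sum() < min_group_frac * n or (~high).sum() < min_group_frac * n:
            continue
        res = logrank_test(times[high], events[high], times[~high], events[~high])
        key = (res.p_value, c)
        if best is None or key < best[0]:
            best = (key, c, res)
    if best is None:
        raise DataModelError("no candidate split satisfies the group-size floor")
    _, c, res = best
    return float(c), res


# ---------------------------------------------------------------------------
# Group associations
# ---------------------------------------------------------------------------


def group_association(
    values: np.ndarray,
    group_labels: np.ndarray,
    numerator_group: str,
    welch: bool = False,
) -> AssociationResult:
    """Fold change of group means plus a two-tailed Student's t-test.

    Exactly two groups are required, each with n >= 2.  The fold change is
    mean(numerator group) / mean(denominator group) on the values as given
    (pass linear-scale expression for interpretable folds).
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels)
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise DataModelError(f"expected exactly 2 groups, got {list(groups)}")
    if numerator_group not in groups:
        raise DataModelError(f"numerator_group {numerator_group!r} not among {list(groups)}")
    denominator_group = [g for g in groups if g != numerator_group][0]
    a = values[group_labels == numerator_group]
    b = values[group_labels == denominator_group]
    if len(a) < 2 or len(b) < 2:
        raise DataModelError("each group needs n >= 2")
    if np.array_equal(np.sort(a), np.sort(b)):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_a / mean_b if mean_b != 0 else float("inf")
    return AssociationResult(
        group_means=(mean_a, mean_b),
        fold_change=float(fold),
        numerator=str(numerator_group),
        denominator=str(denominator_group),
        test=TestResult(
            statistic=float(t),
            df=df,
            p_value=float(p),
            method="Welch t" if welch else "Student t",
        ),
    )


def paired_association(values_a: np.ndarray, values_b: np.ndarray) -> TestResult:
    """Two-tailed paired Student's t-test on the per-pair differences."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataModelError("paired_association expects two equal-length vectors")
    if len(a) < 2:
        raise DataModelError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(statistic=0.0, df=len(d) - 1, p_value=1.0, method="paired t")
        # constant non-zero differences: infinitely strong evidence
        sign = np.sign(d[0])
        return TestResult(
            statistic=float(sign * np.inf), df=len(d) - 1, p_value=0.0, method="paired t (degenerate)"
        )
    t, p = stats.ttest_rel(a, b)
    return TestResult(statistic=float(t), df=len(d) - 1, p_value=float(p), method="paired t")


def chisq_association(contingency: np.ndarray) -> TestResult:
    """Pearson chi-square (no continuity correction) on an RxC count table."""
    table = np.asarray(contingency, float)
    if table.ndim != 2 or (table < 0).any():
        raise DataModelError("contingency must be a 2-d non-negative table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataModelError("chisq_association: zero marginal")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning(
            "chi-square: %d expected counts below 5", int((expected < 5).sum())
        )
    return TestResult(statistic=float(chi2), df=int(df), p_value=float(p), method="chi-square")


def summarize_by_subtype(
    scores: pd.Series, subtype_labels: pd.Series
) -> tuple[pd.DataFrame, TestResult]:
    """Per-subtype n/mean/sd plus a global Kruskal-Wallis test."""
    df = pd.DataFrame({"score": scores, "subtype": subtype_labels}).dropna()
    groups = [g["score"].to_numpy() for _, g in df.groupby("subtype") if len(g) > 0]
    if len(groups) < 2:
        raise DataModelError("need at least 2 subtype groups")
    summary = (
        df.groupby("subtype")["score"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    if df["score"].nunique() == 1:
        test = TestResult(statistic=0.0, df=len(groups) - 1, p_value=1.0, method="Kruskal-Wallis")
    else:
        h, p = stats.kruskal(*groups)
        test = TestResult(
            statistic=float(h), df=len(groups) - 1, p_value=float(p), method="Kruskal-Wallis"
        )
    return summary, test


__all__ = [
    "SurvivalCurve",
    "TestResult",
    "CutoffResult",
    "AssociationResult",
    "km_estimate",
    "logrank_test",
    "roc_cutoff",
    "logrank_min_p_cutoff",
    "group_association",
    "paired_association",
    "chisq_association",
    "summarize_by_subtype",
]
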