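"""Discrimination, calibration and between-category inference.

Everything an external validation of a categorical risk model needs:
incidence-by-category contingency summaries, Pearson chi-square /
exact 2xk association tests, the Mann-Whitney AUC with a DeLong (or
bootstrap) confidence interval, per-category calibration points with
logistic Wald intervals, one-way ANOVA for continuous covariates across
categories, and relative risks between categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import lgamma
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit, logit

from .adjudication import CTRCDCall
from .models import RiskAssignment

__all__ = [
    "ContingencySummary",
    "AssociationResult",
    "DiscriminationResult",
    "CalibrationPoint",
    "incidence_table",
    "association_test",
    "fisher_exact_2xk",
    "auc_with_ci",
    "calibration_points",
    "one_way_anova",
    "relative_risk",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencySummary:
    """Event counts by ordered risk category."""

    categories: list[str]
    n_total: list[int]
    n_events: list[int]

    def __post_init__(self) -> None:
        if not (len(self.categories) == len(self.n_total) == len(self.n_events)):
            raise ValueError("categories, totals and events must align")
        for c, n, e in zip(self.categories, self.n_total, self.n_events):
            if not (0 <= e <= n):
                raise ValueError(f"category {c!r}: events {e} outside [0, {n}]")

    @property
    def proportions(self) -> list[float]:
        return [e / n if n else float("nan") for e, n in zip(self.n_events, self.n_total)]

    @property
    def proportions_pct(self) -> list[float]:
        """Event proportions as percentages rounded to 1 decimal, the
        convention used in published incidence tables."""
        return [round(100 * p, 1) for p in self.proportions]

    @property
    def cohort_size(self) -> int:
        return int(sum(self.n_total))

    def to_rows(self) -> list[dict]:
        return [
            {"category": c, "n_total": n, "n_events": e,
             "proportion_pct": round(100 * e / n, 1) if n else None}
            for c, n, e in zip(self.categories, self.n_total, self.n_events)
        ]


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    df: Optional[int]
    method: str  # chi_square | fisher


@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    method: str = "delong"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("AUC must lie within its confidence interval")


@dataclass(frozen=True)
class CalibrationPoint:
    category: str
    n_total: int
    n_events: int
    predicted_risk: float
    observed_risk: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # 0% or 100% observed; exact fallback interval

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.observed_risk <= self.ci_high):
            raise ValueError("observed risk must lie within its interval")


# ---------------------------------------------------------------------------

def incidence_table(
    assignments: Sequence[RiskAssignment],
    calls: Sequence[CTRCDCall],
    categories: Optional[Sequence[str]] = None,
) -> ContingencySummary:
    """Cross-tabulate risk category against adjudicated CTRCD events.

    Unscorable assignments are excluded.  Scorable patients present in
    only one of the two inputs are an error (ids listed).
    """
    calls_by_pid = {c.patient_id: c for c in calls}
    scorable = [a for a in assignments if a.scorable]
    missing_calls = sorted(a.patient_id for a in scorable if a.patient_id not in calls_by_pid)
    if missing_calls:
        raise ValueError(f"patients without adjudication calls: {missing_calls[:10]}")
    if categories is None:
        seen: list[str] = []
        for a in scorable:
            if a.category not in seen:
                seen.append(a.category)
        categories = seen
    totals = {c: 0 for c in categories}
    events = {c: 0 for c in categories}
    for a in scorable:
        if a.category not in totals:
            raise ValueError(f"unexpected category {a.category!r}")
        totals[a.category] += 1
        events[a.category] += int(calls_by_pid[a.patient_id].event)
    return ContingencySummary(
        categories=list(categories),
        n_total=[totals[c] for c in categories],
        n_events=[events[c] for c in categories],
    )


def _log_multi_hypergeom(first_row: Sequence[int], col_totals: Sequence[int],
                         row1: int, n: int) -> float:
    """Log-probability of a 2xk table with the given first row under
    fixed margins (multivariate hypergeometric)."""
    lp = lgamma(row1 + 1) + lgamma(n - row1 + 1) - lgamma(n + 1)
    for a, c in zip(first_row, col_totals):
        lp += lgamma(c + 1) - lgamma(a + 1) - lgamma(c - a + 1)
    return lp


def fisher_exact_2xk(n_events: Sequence[int], n_total: Sequence[int]) -> float:
    """Exact conditional p-value for a 2xk table by enumerating all
    tables with the observed margins and summing the probabilities of
    those no more probable than the observed table."""
    n_events = [int(e) for e in n_events]
    cols = [int(t) for t in n_total]
    row1 = sum(n_events)
    n = sum(cols)
    obs_lp = _log_multi_hypergeom(n_events, cols, row1, n)
    total = 0.0
    p_sum = 0.0
    stack: list[tuple[int, list[int], int]] = [(0, [], row1)]
    while stack:
        j, prefix, remaining = stack.pop()
        if j == len(cols) - 1:
            if 0 <= remaining <= cols[-1]:
                cells = prefix + [remaining]
                lp = _log_multi_hypergeom(cells, cols, row1, n)
                p = math.exp(lp)
                total += p
                if lp <= obs_lp + 1e-9:
                    p_sum += p
            continue
        rest_cap = sum(cols[j + 1:])
        lo = max(0, remaining - rest_cap)
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            stack.append((j + 1, prefix + [a], remaining - a))
    return min(p_sum / total, 1.0)  # normalization guards rounding


def association_test(
    table: ContingencySummary, method: str = "chi_square"
) -> AssociationResult:
    """Test whether event incidence differs between risk categories.

    ``chi_square`` is the Pearson statistic WITHOUT continuity
    correction, df = k - 1; ``fisher`` is the exact conditional test by
    enumeration; ``auto`` runs Fisher when any expected cell count is
    below 5 and reports which method ran.
    """
    if len(table.categories) < 2:
        raise ValueError("at least 2 categories are required")
    if any(n == 0 for n in table.n_total):
        raise ValueError("categories with n_total == 0 must be dropped upstream")
    obs = np.array([table.n_events,
                    [n - e for n, e in zip(table.n_total, table.n_events)]])
    expected = sps.contingency.expected_freq(obs)
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi_square"
    if method == "chi_square":
        stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
        return AssociationResult(float(stat), float(p), int(df), "chi_square")
    if method == "fisher":
        p = fisher_exact_2xk(table.n_events, table.n_total)
        return AssociationResult(float("nan"), float(p), None, "fisher")
    raise ValueError(f"unknown association method {method!r}")


# ---------------------------------------------------------------------------
# AUC with DeLong or bootstrap confidence interval

def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([cases, controls]))
    n1, n0 = len(cases), len(controls)
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong structural-component variance of the AUC estimator."""
    m, n = len(cases), len(controls)
    all_vals = np.concatenate([cases, controls])
    mid_all = sps.rankdata(all_vals)          # midranks in the pooled sample
    mid_cases = sps.rankdata(cases)
    mid_controls = sps.rankdata(controls)
    v10 = (mid_all[:m] - mid_cases) / n        # per-case placement values
    v01 = 1.0 - (mid_all[m:] - mid_controls) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_with_ci(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> DiscriminationResult:
    """Area under the ROC curve with a 95% confidence interval.

    AUC is the rank (Mann-Whitney) estimator
    ``P(score_case > score_control) + 0.5 P(tie)``; ordinal categories
    enter through their ranks.  The default interval uses the DeLong
    variance; ``method='bootstrap'`` uses a seeded percentile bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must align")
    cases, controls = scores[outcomes], scores[~outcomes]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need at least one case and one control")
    auc = _auc_mann_whitney(cases, controls)
    if method == "delong":
        se = math.sqrt(max(_delong_variance(cases, controls), 0.0))
        lo, hi = auc - Z95 * se, auc + Z95 * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            c = cases[rng.integers(0, len(cases), len(cases))]
            k = controls[rng.integers(0, len(controls), len(controls))]
            reps[b] = _auc_mann_whitney(c, k)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return DiscriminationResult(
        auc=float(auc),
        ci_low=float(min(max(lo, 0.0), auc)),
        ci_high=float(max(min(hi, 1.0), auc)),
        n_cases=int(len(cases)),
        n_controls=int(len(controls)),
        method=method,
    )


# ---------------------------------------------------------------------------
# Calibration

def _wald_logit_interval(e: int, n: int) -> tuple[float, float]:
    """95% Wald interval from an intercept-only logistic model: the MLE of
    the intercept is logit(e/n) with variance 1/(n p (1-p))."""
    p = e / n
    se = math.sqrt(1.0 / (n * p * (1.0 - p)))
    return float(expit(logit(p) - Z95 * se)), float(expit(logit(p) + Z95 * se))


def _clopper_pearson(e: int, n: int) -> tuple[float, float]:
    lo = 0.0 if e == 0 else float(sps.beta.ppf(0.025, e, n - e + 1))
    hi = 1.0 if e == n else float(sps.beta.ppf(0.975, e + 1, n - e))
    return lo, hi


def calibration_points(
    assignments: Sequence[RiskAssignment],
    calls: Sequence[CTRCDCall],
    categories: Optional[Sequence[str]] = None,
) -> list[CalibrationPoint]:
    """Predicted vs observed absolute risk per category.

    Observed risk is the empirical event proportion — identically the
    fitted probability of an intercept-only logistic model — with a 95%
    Wald interval on the logit scale transformed back.  Categories with
    0% or 100% observed risk fall back to an exact Clopper-Pearson
    interval and are flagged ``degenerate``.
    """
    calls_by_pid = {c.patient_id: c for c in calls}
    groups: dict[str, list[RiskAssignment]] = {}
    order: list[str] = list(categories) if categories is not None else []
    for a in assignments:
        if not a.scorable:
            continue
        if a.predicted_risk is None:
            raise ValueError(f"assignment for {a.patient_id} lacks predicted_risk")
        if categories is None and a.category not in order:
            order.append(a.category)
        groups.setdefault(a.category, []).append(a)
    points = []
    for cat in order:
        members = groups.get(cat, [])
        if not members:
            continue
        n = len(members)
        e = sum(int(calls_by_pid[a.patient_id].event) for a in members)
        pred = float(np.mean([a.predicted_risk for a in members]))
        obs = e / n
        degenerate = e in (0, n)
        lo, hi = _clopper_pearson(e, n) if degenerate else _wald_logit_interval(e, n)
        points.append(CalibrationPoint(cat, n, e, pred, obs, lo, hi, degenerate))
    return points


# ---------------------------------------------------------------------------

def one_way_anova(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Classical one-way ANOVA F test across category labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("at least 2 groups are required")
    samples = [values[labels == g] for g in uniq]
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance everywhere")
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def relative_risk(
    table: ContingencySummary, numerator_category: str, denominator_category: str
) -> float:
    """Ratio of event proportions between two categories (display at
    1 decimal is the caller's concern; full precision returned)."""
    idx = {c: i for i, c in enumerate(table.categories)}
    for cat in (numerator_category, denominator_category):
        if cat not in idx:
            raise ValueError(f"unknown category {cat!r}")
    den = table.n_events[idx[denominator_category]] / table.n_total[idx[denominator_category]]
    if den == 0:
        raise ValueError("denominator category has zero events")
    num = table.n_events[idx[numerator_category]] / table.n_total[idx[numerator_category]]
    return num / den
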