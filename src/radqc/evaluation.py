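"""Evaluation harness: detection matching, metrics, agreement and rates.

Implements the statistics used to assess an error-detection system against a
manually annotated reference standard: confusion counts from greedy
span matching, precision / recall / F1 / accuracy with percentile-bootstrap
confidence intervals (report-level resampling, 1,000 resamples by default),
Cohen's κ and Gwet's AC1 inter-rater agreement, two-proportion χ² tests,
stratified error rates, multiple linear regression on monthly rates, and the
Wilcoxon rank-sum test for score comparisons.

Percentage conventions follow the field's reporting style: metrics round
half-up to one decimal (86.4%), error rates below 10% to two decimals
(0.85%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm


class MetricUndefinedError(ZeroDivisionError):
    """A metric's denominator is zero (or agreement is degenerate)."""


# ---------------------------------------------------------------------------
# detection-to-gold matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchCriterion:
    span_policy: str = "overlap"  # "overlap" | "exact"
    require_type_match: bool = False

    def __post_init__(self) -> None:
        if self.span_policy not in {"overlap", "exact"}:
            raise ValueError(f"bad span_policy {self.span_policy!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None  # undefined for error-level scoring

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0 or (self.tn is not None and self.tn < 0):
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        tn = None
        if self.tn is not None and other.tn is not None:
            tn = self.tn + other.tn
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, tn)


def _effective_span(item) -> tuple[int, int]:
    start, end = item.start, item.end
    if start == end:  # zero-width omission spans match their neighbourhood
        return (max(0, start - 1), start + 1)
    return (start, end)


def _matches(pred, gold, criterion: MatchCriterion) -> bool:
    if criterion.require_type_match and pred.error_type != gold.error_type:
        return False
    if criterion.span_policy == "exact":
        return (pred.start, pred.end) == (gold.start, gold.end)
    ps, pe = _effective_span(pred)
    gs, ge = _effective_span(gold)
    return max(ps, gs) < min(pe, ge)


def match_report(predicted: Sequence, gold: Sequence,
                 criterion: MatchCriterion | None = None) -> ConfusionCounts:
    """One-to-one span matching within a single report.

    Candidate pairs are scanned in span order and completed to a maximum
    one-to-one matching (augmenting paths), so tp is the size of the maximum
    bipartite matching between gold and predictions under the criterion.
    """
    criterion = criterion or MatchCriterion()
    preds = sorted(predicted, key=lambda d: (d.start, d.end))
    golds = sorted(gold, key=lambda a: (a.start, a.end))
    compatible = [
        [i for i, p in enumerate(preds) if _matches(p, g, criterion)] for g in golds
    ]
    owner: dict[int, int] = {}  # prediction index -> gold index

    def assign(g: int, seen: set[int]) -> bool:
        for i in compatible[g]:
            if i in seen:
                continue
            seen.add(i)
            if i not in owner or assign(owner[i], seen):
                owner[i] = g
                return True
        return False

    tp = sum(assign(g, set()) for g in range(len(golds)))
    return ConfusionCounts(tp=tp, fp=len(preds) - tp, fn=len(golds) - tp)


def match_detections(
    predicted: Mapping[str, Sequence],
    gold: Mapping[str, Sequence],
    criterion: MatchCriterion | None = None,
) -> ConfusionCounts:
    """Aggregate confusion counts over reports keyed by id."""
    per_report = match_detections_per_report(predicted, gold, criterion)
    total = ConfusionCounts()
    for counts in per_report.values():
        total = ConfusionCounts(
            total.tp + counts.tp, total.fp + counts.fp, total.fn + counts.fn
        )
    return total


def match_detections_per_report(
    predicted: Mapping[str, Sequence],
    gold: Mapping[str, Sequence],
    criterion: MatchCriterion | None = None,
) -> dict[str, ConfusionCounts]:
    orphans = set(predicted) ^ set(gold)
    if orphans:
        raise KeyError(f"prediction/gold id mismatch: {sorted(orphans)[:10]}")
    return {
        rid: match_report(predicted[rid], gold[rid], criterion) for rid in sorted(gold)
    }


# ---------------------------------------------------------------------------
# metrics and percentage rendering
# ---------------------------------------------------------------------------

def percent(fraction: float, decimals: int = 1) -> float:
    """Half-up rounding of ``100 * fraction`` to *decimals* places."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(quantum, rounding=ROUND_HALF_UP))


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise MetricUndefinedError("precision undefined: tp + fp == 0")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise MetricUndefinedError("recall undefined: tp + fn == 0")
    return c.tp / (c.tp + c.fn)


def f1(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise MetricUndefinedError("f1 undefined: no predictions or gold")
    return 2 * c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    if c.tn is None:
        raise MetricUndefinedError("accuracy needs a tn convention")
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise MetricUndefinedError("accuracy undefined: empty table")
    return (c.tp + c.tn) / total


def with_report_level_tn(c: ConfusionCounts, total_reports: int) -> ConfusionCounts:
    """Report-level true negatives: reports with neither gold nor predicted
    errors, ``tn = total − tp − fp − fn``."""
    tn = total_reports - c.tp - c.fp - c.fn
    if tn < 0:
        raise ValueError("total_reports smaller than tp + fp + fn")
    return ConfusionCounts(c.tp, c.fp, c.fn, tn)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricWithCI:
    point: float
    ci_low: float
    ci_high: float
    resamples: int = 1000
    rng_seed: int = 0


def bootstrap_ci(
    metric: Callable[[Sequence], float],
    outcomes: Sequence,
    resamples: int = 1000,
    rng_seed: int = 0,
    ci_level: float = 0.95,
) -> MetricWithCI:
    """Percentile bootstrap over report-level outcomes.

    *outcomes* is one entry per report (the resampling unit, because errors
    within a report are dependent); *metric* maps a list of outcomes to a
    number. Resamples where the metric is undefined are dropped; more than
    50% undefined raises.
    """
    if len(outcomes) == 0:
        raise ValueError("outcome list is empty")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    outcomes = list(outcomes)
    n = len(outcomes)
    values = []
    for _ in range(resamples):
        idx = rng.integers(0, n, size=n)
        sample = [outcomes[i] for i in idx]
        try:
            values.append(metric(sample))
        except (MetricUndefinedError, ZeroDivisionError):
            continue
    if len(values) < resamples / 2:
        raise MetricUndefinedError("metric undefined in more than half the resamples")
    tail = (1.0 - ci_level) / 2.0
    low, high = np.quantile(values, [tail, 1.0 - tail])
    return MetricWithCI(
        point=metric(outcomes),
        ci_low=float(low),
        ci_high=float(high),
        resamples=resamples,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    array = np.asarray(table, dtype=float)
    if array.ndim != 2 or array.shape[0] != array.shape[1] or array.shape[0] < 2:
        raise ValueError("rater table must be square with >= 2 categories")
    if (array < 0).any() or array.sum() == 0:
        raise ValueError("rater table needs non-negative counts and total > 0")
    return array


def cohen_kappa(table) -> float:
    """κ = (p_o − p_e) / (1 − p_e), chance agreement from marginal products."""
    array = _as_table(table)
    total = array.sum()
    p_o = np.trace(array) / total
    rows = array.sum(axis=1) / total
    cols = array.sum(axis=0) / total
    p_e = float(rows @ cols)
    if math.isclose(p_e, 1.0):
        raise MetricUndefinedError("kappa undefined: degenerate marginals (p_e == 1)")
    return float((p_o - p_e) / (1.0 - p_e))


def gwet_ac1(table) -> float:
    """AC1 with chance agreement (1/(K−1))·Σ π_k (1−π_k), π_k the mean of the
    two raters' marginal proportions — robust to skewed prevalence."""
    array = _as_table(table)
    total = array.sum()
    p_o = np.trace(array) / total
    pi = (array.sum(axis=1) + array.sum(axis=0)) / (2.0 * total)
    k = array.shape[0]
    p_e = float((pi * (1.0 - pi)).sum() / (k - 1))
    if math.isclose(p_e, 1.0):
        raise MetricUndefinedError("AC1 undefined: p_e == 1")
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# proportion comparison and rates
# ---------------------------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson χ² without continuity correction on table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise MetricUndefinedError("chi-square undefined: zero margin")
    statistic, p_value, _, _ = sps.chi2_contingency(table, correction=False)
    return float(statistic), float(p_value)


@dataclass(frozen=True)
class RateRecord:
    numerator: int
    denominator: int
    modality: str | None = None
    period: str | None = None
    title: str | None = None
    month: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator or self.denominator <= 0:
            raise ValueError("need 0 <= numerator <= denominator, denominator > 0")


def error_rate(records: Sequence[RateRecord], **strata) -> float:
    """Pooled error rate (%) over records matching the stratum filter;
    two decimals below 10%, one decimal otherwise."""
    selected = [
        r for r in records
        if all(getattr(r, key) == value for key, value in strata.items())
    ]
    denominator = sum(r.denominator for r in selected)
    if denominator == 0:
        raise MetricUndefinedError("empty stratum")
    fraction = sum(r.numerator for r in selected) / denominator
    return percent(fraction, 2 if fraction < 0.10 else 1)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    names: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    p_values: tuple[float, ...]
    reference_note: str = "binary predictors encode the stated reference level as 0"

    def coefficient(self, name: str) -> float:
        return self.coefficients[self.names.index(name)]

    def p_value(self, name: str) -> float:
        return self.p_values[self.names.index(name)]

    def standard_error(self, name: str) -> float:
        return self.standard_errors[self.names.index(name)]


def ols_regression(design: Mapping[str, Sequence[float]], response: Sequence[float]) -> RegressionResult:
    """Least squares with classical standard errors and two-tailed t tests.

    *design* maps predictor names to columns; an intercept is added
    automatically.
    """
    names = list(design)
    X = np.column_stack([np.asarray(design[name], dtype=float) for name in names])
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response lengths differ")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least predictors + 2 observations")
    with_const = sm.add_constant(X, has_constant="raise")
    rank = np.linalg.matrix_rank(with_const)
    if rank < with_const.shape[1]:
        raise ValueError(f"rank-deficient design (rank {rank} < {with_const.shape[1]}); "
                         f"check columns {names}")
    fit = sm.OLS(y, with_const).fit()
    all_names = ("intercept", *names)
    return RegressionResult(
        names=all_names,
        coefficients=tuple(float(v) for v in fit.params),
        standard_errors=tuple(float(v) for v in fit.bse),
        p_values=tuple(float(v) for v in fit.pvalues),
    )


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-sum statistic of *x* (midranks for ties) and a two-sided p-value.

    Exact enumeration of all rank assignments for pooled n ≤ 20 (valid with
    ties because it conditions on the observed midranks); tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n = x.size, pooled.size
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if n <= 20:
        deviation = abs(w - mu)
        hits = 0
        total = 0
        for subset in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(subset)].sum() - mu) >= deviation - 1e-12:
                hits += 1
        return w, hits / total

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    n2 = n - n1
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0:  # all observations identical
        return w, 1.0
    z = (w - mu) / math.sqrt(sigma_sq)
    return w, float(2.0 * sps.norm.sf(abs(z)))
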