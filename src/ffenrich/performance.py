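"""Screening performance: confusion counts, Wilson CIs, rate comparison.

Test failures (no-calls) are tallied separately and excluded from every
metric denominator.  Confidence intervals use the Wilson score interval; the
2x2 rate comparison uses Pearson's chi-square without continuity correction
or Fisher's exact test (automatically chosen when an expected cell is
below 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.proportion import proportion_confint


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), used for reporting."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (fractions in [0, 1])."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence,
                                method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class ConfusionCounts:
    """Cohort-level screening counts; failures sit outside the metric math.

    ``called_negative`` is the number of samples reported negative (it
    includes any false negatives); ``condition_negative`` counts truly
    unaffected samples among those with a result.
    """

    n_total: int
    n_fail: int
    test_positive: int
    true_positive: int
    called_negative: int
    condition_negative: int
    false_negative: int = 0

    def __post_init__(self) -> None:
        if self.test_positive < self.true_positive:
            raise ValueError("test_positive must be >= true_positive")
        if min(self.n_total, self.n_fail, self.test_positive,
               self.true_positive, self.called_negative,
               self.condition_negative, self.false_negative) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def false_positive(self) -> int:
        return self.test_positive - self.true_positive

    @property
    def true_negative(self) -> int:
        return self.called_negative - self.false_negative


@dataclass(frozen=True)
class MetricValue:
    """A proportion metric reported as a percentage with its 95% Wilson CI."""

    pct: float
    ci: tuple[float, float]
    numerator: int
    denominator: int

    @classmethod
    def from_counts(cls, k: int, n: int, digits: int = 2) -> "MetricValue":
        lo, hi = wilson_ci(k, n)
        return cls(
            pct=round_half_up(100.0 * k / n, digits),
            ci=(round_half_up(100.0 * lo, digits), round_half_up(100.0 * hi, digits)),
            numerator=k, denominator=n,
        )


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: MetricValue | None
    specificity: MetricValue | None
    ppv: MetricValue | None
    npv: MetricValue | None
    failure_rate: MetricValue | None

    def to_dict(self) -> dict:
        def conv(m):
            if m is None:
                return None
            return {"pct": m.pct, "ci": list(m.ci),
                    "numerator": m.numerator, "denominator": m.denominator}
        return {k: conv(getattr(self, k)) for k in
                ("sensitivity", "specificity", "ppv", "npv", "failure_rate")}


def confusion_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity/specificity/PPV/NPV/failure rate with Wilson CIs.

    Metrics with a zero denominator are reported as None (undefined), never
    as zero.
    """
    tp, fn = counts.true_positive, counts.false_negative
    tn = counts.true_negative

    def metric(k, n):
        return MetricValue.from_counts(k, n) if n > 0 else None

    return MetricsReport(
        sensitivity=metric(tp, tp + fn),
        specificity=metric(tn, counts.condition_negative),
        ppv=metric(tp, counts.test_positive),
        npv=metric(tn, counts.called_negative),
        failure_rate=metric(counts.n_fail, counts.n_total),
    )


def compare_rates(
    a_events: int, a_n: int, b_events: int, b_n: int, method: str = "auto"
) -> float:
    """Two-sided p-value comparing two event rates on a 2x2 table.

    ``chi2`` is Pearson's chi-square without continuity correction;
    ``fisher`` the two-sided exact test; ``auto`` picks Fisher when any
    expected cell is below 5.
    """
    table = np.array([[a_events, a_n - a_events],
                      [b_events, b_n - b_events]], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative cell counts")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    if method == "auto":
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "fisher":
        return float(sstats.fisher_exact(table.astype(int))[1])
    if method == "chi2":
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("chi-square undefined: zero marginal")
        stat = sstats.chi2_contingency(table, correction=False)[0]
        return float(sstats.chi2.sf(stat, df=1))
    raise ValueError("method must be 'chi2', 'fisher' or 'auto'")


def evaluate_cohort(calls, truths) -> tuple[ConfusionCounts, MetricsReport]:
    """Tally pipeline calls against ground truths.

    ``calls`` are :class:`~ffenrich.calling.CallResult` objects and
    ``truths`` matching :class:`~ffenrich.simulate.SampleTruth` objects
    (paired positionally; when both carry sample ids they must agree).
    No-calls count as failures and are excluded from metric denominators.
    A positive call is a true positive only when the truth's trisomic
    chromosome is among the called chromosomes.
    """
    calls, truths = list(calls), list(truths)
    if not calls:
        raise ValueError("empty cohort")
    if len(calls) != len(truths):
        raise ValueError("calls and truths differ in length")
    n_fail = test_pos = true_pos = called_neg = cond_neg = false_neg = 0
    for call, truth in zip(calls, truths):
        if (call.sample_id is not None and truth.sample_id is not None
                and call.sample_id != truth.sample_id):
            raise ValueError(
                f"sample id mismatch: {call.sample_id} vs {truth.sample_id}"
            )
        if call.decision == "no_call":
            n_fail += 1
            continue
        affected = truth.trisomy is not None
        if call.decision == "positive":
            test_pos += 1
            if affected and truth.trisomy in call.positive_chroms:
                true_pos += 1
        else:
            called_neg += 1
            if affected:
                false_neg += 1
        if not affected:
            cond_neg += 1
    counts = ConfusionCounts(
        n_total=len(calls), n_fail=n_fail, test_positive=test_pos,
        true_positive=true_pos, called_negative=called_neg,
        condition_negative=cond_neg, false_negative=false_neg,
    )
    return counts, confusion_metrics(counts)
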