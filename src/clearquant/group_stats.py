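"""Per-treatment summaries and pairwise Mann-Whitney-Wilcoxon comparisons.

Treatments (clearing media, optionally pooled across pre-treatment variants
that showed no difference) are summarized per metric with median, quartiles
and 1.5*IQR whiskers, and compared pairwise with the two-sided
Mann-Whitney-Wilcoxon rank test for unpaired samples.

The U statistic always uses mid-ranks for ties.  The p-value is exact (full
permutation null, computed by the count recursion) whenever the combined
sample size is at most 16 and no ties are present — which covers group
sizes like 7 vs 9 — and otherwise falls back to the normal approximation
with tie and continuity correction.  No multiple-testing correction is
applied; the number of tests performed is reported so callers can apply
their own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .errors import ConfigError

__all__ = [
    "BoxplotStats",
    "GroupSummary",
    "PairwiseTestResult",
    "mann_whitney_u",
    "boxplot_summary",
    "compare_treatments",
    "exact_u_distribution",
]


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number-style summary of one metric within one group."""

    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float


@dataclass(frozen=True)
class GroupSummary:
    """Boxplot summaries of both clearing metrics for one (pooled) group."""

    treatment: str
    n: int
    t_norm: BoxplotStats
    retained_size: BoxplotStats


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    metric: str = ""


@lru_cache(maxsize=None)
def exact_u_distribution(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of labelings per U value under the tie-free permutation null.

    ``result[u]`` is the number of the C(n1+n2, n1) assignments of ranks to
    the first sample that produce U statistic ``u``; the classic recursion
    c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    # table[(i, j)] -> list of counts over u = 0..i*j
    table: dict[tuple[int, int], list[int]] = {}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i == 0 or j == 0:
                table[(i, j)] = [1]
                continue
            counts = [0] * (i * j + 1)
            prev_i = table[(i - 1, j)]
            prev_j = table[(i, j - 1)]
            for u in range(i * j + 1):
                if u - j >= 0 and u - j < len(prev_i):
                    counts[u] += prev_i[u - j]
                if u < len(prev_j):
                    counts[u] += prev_j[u]
            table[(i, j)] = counts
    return tuple(table[(n1, n2)])


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> PairwiseTestResult:
    """Two-sided Mann-Whitney-Wilcoxon test for two unpaired samples.

    Returns the U statistic of ``x`` (mid-ranks for ties) and a two-sided
    p-value: exact when ``len(x) + len(y) <= 16`` and there are no ties,
    else the tie- and continuity-corrected normal approximation.
    """
    if alternative not in ("two_sided", "two-sided"):
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ConfigError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sp_stats.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < n1 + n2

    if not has_ties and n1 + n2 <= 16:
        dist = np.asarray(exact_u_distribution(n1, n2), dtype=float)
        total = dist.sum()
        u_int = int(round(u1))
        p_le = dist[: u_int + 1].sum() / total
        p_ge = dist[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    elif float(np.ptp(combined)) == 0.0:
        p = 1.0  # all observations identical: no evidence either way
        method = "normal_approx"
    else:
        res = sp_stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return PairwiseTestResult(
        group_a="x", group_b="y", n_a=n1, n_b=n2,
        u_statistic=float(u1), p_value=float(p), method=method,
    )


def boxplot_summary(values: Sequence[float], metric: str = "") -> BoxplotStats:
    """Median, inclusive-method quartiles and 1.5*IQR whiskers.

    Quartiles use linear interpolation between order statistics; whiskers
    sit at the most extreme data points within 1.5*IQR of the quartile box
    (the common boxplot convention).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ConfigError(f"empty sample for metric {metric!r}")
    q25, med, q75 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotStats(
        n=int(v.size),
        median=med,
        q25=q25,
        q75=q75,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def compare_treatments(
    records: Sequence[Mapping],
    pooling_rules: Mapping[str, str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    metrics: Sequence[str] = ("t_norm", "retained_size"),
) -> tuple[list[GroupSummary], list[PairwiseTestResult]]:
    """Pool treatment labels, summarize each group and test requested pairs.

    ``records`` are per-specimen mappings carrying at least ``treatment``
    and the metric keys.  ``pooling_rules`` maps raw labels to pooled ones
    (labels absent from the map pass through unchanged); every rule key
    must match at least one specimen.  ``pairs`` defaults to all unordered
    pooled-group pairs; every pair is tested on every metric.
    """
    pooling_rules = dict(pooling_rules or {})
    raw_labels = {str(r["treatment"]) for r in records}
    unknown = set(pooling_rules) - raw_labels
    if unknown:
        raise ConfigError(f"pooling_rules reference unknown treatments: {sorted(unknown)}")

    groups: dict[str, list[Mapping]] = {}
    for rec in records:
        pooled = pooling_rules.get(str(rec["treatment"]), str(rec["treatment"]))
        groups.setdefault(pooled, []).append(rec)

    summaries = [
        GroupSummary(
            treatment=name,
            n=len(recs),
            t_norm=boxplot_summary([r["t_norm"] for r in recs], "t_norm"),
            retained_size=boxplot_summary(
                [r["retained_size"] for r in recs], "retained_size"
            ),
        )
        for name, recs in sorted(groups.items())
    ]

    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    tests: list[PairwiseTestResult] = []
    for ga, gb in pairs:
        if ga not in groups or gb not in groups:
            raise ConfigError(f"requested pair ({ga}, {gb}) names an unknown group")
        for metric in metrics:
            base = mann_whitney_u(
                [r[metric] for r in groups[ga]], [r[metric] for r in groups[gb]]
            )
            tests.append(
                PairwiseTestResult(
                    group_a=ga, group_b=gb, n_a=base.n_a, n_b=base.n_b,
                    u_statistic=base.u_statistic, p_value=base.p_value,
                    method=base.method, metric=metric,
                )
            )
    return summaries, tests
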