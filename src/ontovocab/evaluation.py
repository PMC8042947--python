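"""Ranking evaluation: MRR, MAP@k, rank-sum comparison, and validation
precision arithmetic.

Entities are ranked for each query by groupwise similarity (ties broken
by entity id for determinism); a neighbour is *relevant* when it shares
the query's primary diagnosis code.  Two similarity schemes are compared
by a two-sided Wilcoxon rank-sum test on the ranks at which
matching-diagnosis pairs appear under each scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationCounts",
    "RankingResult",
    "rank_neighbours",
    "reciprocal_rank",
    "average_precision_at_k",
    "evaluate_rankings",
    "mean_reciprocal_rank",
    "mean_average_precision",
    "relevant_pair_ranks",
    "compare_rankings",
    "precision_from_counts",
]


def rank_neighbours(matrix: pd.DataFrame, query: str) -> list[str]:
    """All other entities sorted by similarity to ``query``, descending.

    Ties are broken by entity id ascending so rankings are deterministic.
    """
    if query not in matrix.index:
        raise KeyError(f"unknown query entity {query!r}")
    sims = matrix.loc[query].drop(query)
    return sorted(sims.index, key=lambda e: (-sims[e], e))


def reciprocal_rank(neighbours: Sequence[str], relevant: set[str]) -> float:
    """1/rank of the first relevant neighbour; 0 when none is relevant."""
    for rank, n in enumerate(neighbours, start=1):
        if n in relevant:
            return 1.0 / rank
    return 0.0


def average_precision_at_k(
    neighbours: Sequence[str], relevant: set[str], k: int = 10
) -> float | None:
    """AP over the top-``k`` neighbours, normalised by ``min(k, R)``.

    ``R`` is the number of relevant entities in the cohort, so a query
    with fewer than ``k`` relevant cohort members can still reach 1.
    Returns ``None`` for queries with ``R = 0`` (excluded from MAP).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    r_total = len(relevant)
    if r_total == 0:
        return None
    hits = 0
    ap = 0.0
    for i, n in enumerate(neighbours[:k], start=1):
        if n in relevant:
            hits += 1
            ap += hits / i
    return ap / min(k, r_total)


@dataclass
class RankingResult:
    """Per-query reciprocal ranks / average precisions and their means."""

    per_query_rr: dict[str, float]
    per_query_ap: dict[str, float | None]
    k: int

    @property
    def mrr(self) -> float:
        return float(np.mean(list(self.per_query_rr.values())))

    @property
    def map(self) -> float:
        aps = [v for v in self.per_query_ap.values() if v is not None]
        if not aps:
            raise ValueError("no query has any relevant cohort member")
        return float(np.mean(aps))


def _relevant_sets(
    matrix: pd.DataFrame, diagnoses: Mapping[str, str]
) -> dict[str, set[str]]:
    missing = [e for e in matrix.index if e not in diagnoses]
    if missing:
        raise ValueError(f"entities without a diagnosis code: {missing[:5]}")
    out = {}
    for q in matrix.index:
        code = diagnoses[q]
        out[q] = {e for e in matrix.index if e != q and diagnoses[e] == code}
    return out


def evaluate_rankings(
    matrix: pd.DataFrame, diagnoses: Mapping[str, str], k: int = 10
) -> RankingResult:
    """Rank every entity against the rest and score by shared diagnosis."""
    relevant = _relevant_sets(matrix, diagnoses)
    rr: dict[str, float] = {}
    ap: dict[str, float | None] = {}
    for q in matrix.index:
        neighbours = rank_neighbours(matrix, q)
        rr[q] = reciprocal_rank(neighbours, relevant[q])
        ap[q] = average_precision_at_k(neighbours, relevant[q], k=k)
    return RankingResult(per_query_rr=rr, per_query_ap=ap, k=k)


def mean_reciprocal_rank(matrix: pd.DataFrame, diagnoses: Mapping[str, str]) -> float:
    return evaluate_rankings(matrix, diagnoses).mrr


def mean_average_precision(
    matrix: pd.DataFrame, diagnoses: Mapping[str, str], k: int = 10
) -> float:
    return evaluate_rankings(matrix, diagnoses, k=k).map


def relevant_pair_ranks(
    matrix: pd.DataFrame, diagnoses: Mapping[str, str]
) -> list[int]:
    """Ranks at which matching-diagnosis pairs appear, pooled over queries.

    This is the input sample for the rank-sum comparison of two
    similarity schemes: a scheme that places matching pairs nearer the
    top yields stochastically smaller ranks.
    """
    relevant = _relevant_sets(matrix, diagnoses)
    ranks: list[int] = []
    for q in matrix.index:
        rel = relevant[q]
        if not rel:
            continue
        for rank, n in enumerate(rank_neighbours(matrix, q), start=1):
            if n in rel:
                ranks.append(rank)
    return ranks


def compare_rankings(
    ranks_a: Sequence[float], ranks_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two rank samples.

    Uses exact enumeration for small tie-free samples (both n ≤ 20) and
    the tie-corrected normal approximation otherwise.  Returns the
    rank-sum statistic of the first sample, ``W = U1 + n1(n1+1)/2``, and
    the p-value.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rank samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w, float(res.pvalue)


@dataclass(frozen=True)
class ValidationCounts:
    """Manual-validation tallies for a batch of generated synonyms."""

    terms: int
    total_synonyms: int
    tp: int
    fp: int
    non_english: int
    uncertain: int

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.non_english + self.uncertain != self.total_synonyms:
            raise ValueError("validation counts do not sum to total_synonyms")


def precision_from_counts(
    counts: ValidationCounts | None = None,
    *,
    tp: int | None = None,
    fp: int | None = None,
    non_english: int = 0,
    uncertain: int = 0,
) -> tuple[float, float]:
    """Precision and worst-case precision from validation counts.

    ``precision = tp / (tp + fp)``; the worst case also treats every
    non-English or uncertain synonym as a false positive:
    ``tp / (tp + fp + non_english + uncertain)``.
    """
    if counts is not None:
        tp, fp = counts.tp, counts.fp
        non_english, uncertain = counts.non_english, counts.uncertain
    if tp is None or fp is None:
        raise ValueError("tp and fp are required")
    if tp + fp == 0:
        raise ValueError("precision undefined: tp + fp = 0")
    precision = tp / (tp + fp)
    worst_case = tp / (tp + fp + non_english + uncertain)
    return precision, worst_case
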