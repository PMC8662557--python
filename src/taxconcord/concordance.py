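"""Rank-weighted agreement scoring between taxonomy assignment tables.

Each OTU contributes an identification score of 5/4/3/2/1 for agreement at
the species/genus/family/order/high level between two methods, and 0 when
no rank matches or either method left the OTU unassigned.  The matching
score of a comparison is the summed score divided by N x 5 (for the 71-OTU
study design this denominator is 355).

Against the gold standard, an OTU is *misidentified* when the method's
lineage genuinely conflicts with the gold lineage — i.e. it is not an
ancestor-consistent truncation of it.  A genus-level call under a
species-level gold lineage is coarser but correct, not misidentified;
an unassigned OTU is unresolved, not misidentified, and stays in N.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .io import Assignment
from .taxonomy import Rank, deepest_shared_rank, is_consistent_truncation

__all__ = [
    "ConcordanceRow",
    "MatchingSummary",
    "ConsistencyError",
    "score_pair",
    "misidentification_calls",
    "rank_agreement_profile",
]

MAX_SCORE = Rank.SPECIES.score  # 5


class ConsistencyError(ValueError):
    """Two tables do not cover the same OTU set."""


@dataclass(frozen=True)
class ConcordanceRow:
    otu_id: str
    method_a: str
    method_b: str
    shared_rank: Rank
    identification_score: int
    misidentified: Optional[bool] = None  # defined only against the gold standard


@dataclass(frozen=True)
class MatchingSummary:
    method_a: str
    method_b: str
    n_otus: int
    total_score: int
    denominator: int
    matching_score: float
    misidentification_rate: Optional[float] = None
    n_misidentified: Optional[int] = None
    n_unresolved: Optional[int] = None


def _index(assignments: Sequence[Assignment], side: str) -> dict[str, Assignment]:
    idx = {a.otu_id: a for a in assignments}
    if len(idx) != len(assignments):
        dups = sorted(o for o, k in Counter(a.otu_id for a in assignments).items() if k > 1)
        raise ConsistencyError(f"duplicate OTU ids in {side} table: {', '.join(dups)}")
    return idx


def _check_same_otus(a: dict[str, Assignment], b: dict[str, Assignment]) -> None:
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if only_a or only_b:
        raise ConsistencyError(
            "OTU sets differ between tables; only in first: "
            f"{only_a or '-'}; only in second: {only_b or '-'}"
        )


def score_pair(
    assignments_a: Sequence[Assignment], assignments_b: Sequence[Assignment]
) -> tuple[list[ConcordanceRow], MatchingSummary]:
    """Score agreement between two assignment tables over a shared OTU set.

    OTUs with an empty lineage on either side score 0 but remain in N, so
    the denominator N x 5 is fixed across comparisons.
    """
    idx_a = _index(assignments_a, "first")
    idx_b = _index(assignments_b, "second")
    _check_same_otus(idx_a, idx_b)
    method_a = assignments_a[0].method if assignments_a else "a"
    method_b = assignments_b[0].method if assignments_b else "b"
    rows: list[ConcordanceRow] = []
    for a in assignments_a:
        b = idx_b[a.otu_id]
        shared = deepest_shared_rank(a.lineage, b.lineage)
        rows.append(ConcordanceRow(a.otu_id, method_a, method_b, shared, shared.score))
    total = sum(r.identification_score for r in rows)
    n = len(rows)
    denom = n * MAX_SCORE
    summary = MatchingSummary(
        method_a, method_b, n, total, denom, total / denom if denom else 0.0
    )
    return rows, summary


def misidentification_calls(
    method_assignments: Sequence[Assignment], gold_assignments: Sequence[Assignment]
) -> tuple[list[ConcordanceRow], MatchingSummary]:
    """Score a method against the gold standard and call misidentifications.

    ``misidentified`` is True when the method lineage is non-empty and is
    not an ancestor-consistent truncation of the gold lineage; empty method
    lineages are counted as unresolved.
    """
    idx_m = _index(method_assignments, "method")
    idx_g = _index(gold_assignments, "gold")
    _check_same_otus(idx_m, idx_g)
    method = method_assignments[0].method if method_assignments else "method"
    gold_label = gold_assignments[0].method if gold_assignments else "binning"
    rows: list[ConcordanceRow] = []
    n_unresolved = 0
    for m in method_assignments:
        g = idx_g[m.otu_id]
        shared = deepest_shared_rank(m.lineage, g.lineage)
        if m.lineage.is_empty:
            mis = False
            n_unresolved += 1
        else:
            mis = not is_consistent_truncation(m.lineage, g.lineage)
        rows.append(ConcordanceRow(m.otu_id, method, gold_label, shared, shared.score, mis))
    total = sum(r.identification_score for r in rows)
    n = len(rows)
    denom = n * MAX_SCORE
    n_mis = sum(bool(r.misidentified) for r in rows)
    summary = MatchingSummary(
        method,
        gold_label,
        n,
        total,
        denom,
        total / denom if denom else 0.0,
        misidentification_rate=n_mis / n if n else 0.0,
        n_misidentified=n_mis,
        n_unresolved=n_unresolved,
    )
    return rows, summary


def rank_agreement_profile(rows: Sequence[ConcordanceRow]) -> dict[Rank, int]:
    """Histogram of the shared rank over all six levels; counts sum to N."""
    counts = Counter(r.shared_rank for r in rows)
    return {rank: counts.get(rank, 0) for rank in Rank}
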