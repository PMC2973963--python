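"""Combinatorial ranking of the per-restart best subsets.

Every size-k factor combination (pairs and triplets by default) receives an
identification frequency score: the number of restart best-subsets that
contain it, divided by the number of restarts n.  A combination appearing in
25 of 30 restarts therefore scores 25/30 = 0.833.  Combinations can then be
called either by a frequency cut-off (score strictly greater than the
cut-off, 0.8 by default) or by a dense-rank cut-off (rank <= r, boundary
ties included).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class CombinationScore:
    combination: tuple[str, ...]
    count: int
    frequency: float
    rank: int          # dense rank among combinations of the same size
    rank_overall: int  # dense rank across all sizes

    @property
    def k(self) -> int:
        return len(self.combination)


def enumerate_combinations(
    best_subsets: Sequence[Iterable[str]],
    k_min: int = 2,
    k_max: int = 3,
) -> list[CombinationScore]:
    """Score every size-k combination occurring in the best subsets.

    A combination's count is the number of subsets containing it, so a
    triplet can never outscore the pairs inside it.  Output is ordered by
    frequency descending, then size ascending, then lexicographically.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2 (interactions involve >= 2 factors)")
    n = len(best_subsets)
    counts: Counter[tuple[str, ...]] = Counter()
    for subset in best_subsets:
        members = sorted(set(subset))
        for k in range(k_min, min(k_max, len(members)) + 1):
            counts.update(combinations(members, k))
    ordered = sorted(
        counts.items(), key=lambda item: (-item[1], len(item[0]), item[0])
    )
    overall_ranks = _dense_ranks([c for _, c in ordered])
    per_k_seen: dict[int, list[int]] = {}
    out = []
    for (combo, count), overall in zip(ordered, overall_ranks):
        per_k_seen.setdefault(len(combo), []).append(count)
        out.append((combo, count, overall))
    per_k_ranks = {k: _dense_ranks(v) for k, v in per_k_seen.items()}
    per_k_pos: dict[int, int] = {k: 0 for k in per_k_ranks}
    scores = []
    for combo, count, overall in out:
        k = len(combo)
        rank = per_k_ranks[k][per_k_pos[k]]
        per_k_pos[k] += 1
        scores.append(CombinationScore(combo, count, count / n, rank, overall))
    return scores


def _dense_ranks(descending_counts: Sequence[int]) -> list[int]:
    ranks = []
    rank = 0
    prev: int | None = None
    for c in descending_counts:
        if c != prev:
            rank += 1
            prev = c
        ranks.append(rank)
    return ranks


def call_by_frequency(
    scores: Sequence[CombinationScore], cutoff: float = 0.8
) -> list[CombinationScore]:
    """Call combinations whose frequency is strictly greater than the cut-off."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return [s for s in scores if s.frequency > cutoff]


def call_by_rank(
    scores: Sequence[CombinationScore], max_rank: int, per_k: bool = True
) -> list[CombinationScore]:
    """Call combinations with dense rank <= max_rank (boundary ties included).

    ``per_k=True`` ranks pairs, triplets, ... separately; ``False`` uses the
    pooled ranking across sizes.
    """
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    key = (lambda s: s.rank) if per_k else (lambda s: s.rank_overall)
    return [s for s in scores if key(s) <= max_rank]


def write_ranking(scores: Sequence[CombinationScore], path: str | Path) -> None:
    """TSV of (combination, k, count, frequency, rank, rank_overall)."""
    lines = ["combination\tk\tcount\tfrequency\trank\trank_overall"]
    for s in scores:
        lines.append(
            f"{'x'.join(s.combination)}\t{s.k}\t{s.count}"
            f"\t{s.frequency:.6f}\t{s.rank}\t{s.rank_overall}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
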