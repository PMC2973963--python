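"""Evaluation statistics: power, FDR/TPR curves, and detector complementarity.

Power is the fraction of simulation replicates in which a detector reports
the true functional SNP pair at the top rank.  FDR and TPR are computed at a
rank or frequency cut-off over the replicates' ranked call lists.  For two
detectors X and Y, per-replicate success vectors are cross-tabulated into a
fault table (SS/SF/FS/FF); the single-fault count SF = N_SF + N_FS and the
double-fault count DF = N_FF give the complementarity degree
CD = SF / (DF + SF) and the joint power 100 * (N - FF) / N (success if
either detector succeeds; for three detectors, if any succeeds).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ranking import CombinationScore


@dataclass(frozen=True)
class IdentificationOutcome:
    """Per-replicate success (True = top-ranked the true pair) of one detector."""

    algorithm: str
    successes: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.successes, dtype=bool)
        object.__setattr__(self, "successes", s)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("successes must be a non-empty 1-D vector")

    @property
    def n(self) -> int:
        return self.successes.size

    @property
    def n_success(self) -> int:
        return int(self.successes.sum())


@dataclass(frozen=True)
class FaultTable:
    """2x2 joint success/failure counts of two detectors (first index = X)."""

    ss: int
    sf: int
    fs: int
    ff: int

    def __post_init__(self) -> None:
        if min(self.ss, self.sf, self.fs, self.ff) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.ss + self.sf + self.fs + self.ff

    @property
    def single_fault(self) -> int:
        return self.sf + self.fs

    @property
    def double_fault(self) -> int:
        return self.ff


@dataclass(frozen=True)
class RankedCallSet:
    """One replicate's ranked size-2 calls plus the true functional pair."""

    calls: tuple[CombinationScore, ...]
    truth: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "truth", tuple(sorted(self.truth)))


def success_from_calls(calls: RankedCallSet) -> bool:
    """True if the true pair sits at the top rank (rank-1 ties included)."""
    top = [c for c in calls.calls if c.k == 2 and c.rank == 1]
    return any(c.combination == calls.truth for c in top)


def power(outcome: IdentificationOutcome) -> float:
    """Percentage of replicates with successful identification."""
    return 100.0 * outcome.n_success / outcome.n


def _accepted(calls: RankedCallSet, cutoff, mode: str) -> list[CombinationScore]:
    pairs = [c for c in calls.calls if c.k == 2]
    if mode == "rank":
        return [c for c in pairs if c.rank <= int(cutoff)]
    if mode == "frequency":
        return [c for c in pairs if c.frequency > float(cutoff)]
    raise ValueError("cutoff mode must be 'rank' or 'frequency'")


def fdr_at(
    replicates: Sequence[RankedCallSet], cutoff, mode: str = "rank"
) -> float:
    """Mean per-replicate false discovery rate among accepted calls.

    A replicate accepting no call contributes 0 (the 0/0 convention).
    """
    rates = []
    for calls in replicates:
        accepted = _accepted(calls, cutoff, mode)
        if not accepted:
            rates.append(0.0)
            continue
        false = sum(1 for c in accepted if c.combination != calls.truth)
        rates.append(false / len(accepted))
    return float(np.mean(rates))


def tpr_at(
    replicates: Sequence[RankedCallSet], cutoff, mode: str = "rank"
) -> float:
    """Fraction of replicates whose true pair passes the cut-off.

    Each replicate embeds exactly one true pair, so at rank cut-off 1 this
    equals power/100.
    """
    hits = []
    for calls in replicates:
        accepted = _accepted(calls, cutoff, mode)
        hits.append(1.0 if any(c.combination == calls.truth for c in accepted) else 0.0)
    return float(np.mean(hits))


def fdr_tpr_curve(
    replicates: Sequence[RankedCallSet],
    cutoffs: Sequence,
    mode: str = "rank",
) -> list[tuple[float, float, float]]:
    """(cutoff, FDR, TPR) rows over a grid of cut-offs."""
    return [
        (float(c), fdr_at(replicates, c, mode), tpr_at(replicates, c, mode))
        for c in cutoffs
    ]


# ---------------------------------------------------------------------------
# Complementarity of multiple detectors


def fault_table(a: IdentificationOutcome, b: IdentificationOutcome) -> FaultTable:
    """Cross-tabulate two detectors' per-replicate successes."""
    if a.n != b.n:
        raise ValueError("outcome vectors must have equal length")
    sa, sb = a.successes, b.successes
    return FaultTable(
        ss=int((sa & sb).sum()),
        sf=int((sa & ~sb).sum()),
        fs=int((~sa & sb).sum()),
        ff=int((~sa & ~sb).sum()),
    )


def fault_table_from_marginals(
    n_success_x: int, n_success_y: int, joint_power_count: int, n: int
) -> FaultTable:
    """Reconstruct the fault table from marginal and union success counts.

    By inclusion-exclusion: FF = N - union, SS = n_x + n_y - union,
    SF = n_x - SS, FS = n_y - SS.  Raises if the three counts are mutually
    inconsistent.
    """
    if not max(n_success_x, n_success_y) <= joint_power_count <= min(
        n, n_success_x + n_success_y
    ):
        raise ValueError(
            "inconsistent marginals: union must lie between the larger marginal "
            "and min(N, sum of marginals)"
        )
    ss = n_success_x + n_success_y - joint_power_count
    return FaultTable(
        ss=ss,
        sf=n_success_x - ss,
        fs=n_success_y - ss,
        ff=n - joint_power_count,
    )


def complementarity(ft: FaultTable) -> float:
    """Complementarity degree CD = SF / (DF + SF).

    1 when the detectors never fail together (given some disagreement), 0
    when one detector's successes contain the other's.  Undefined (raises)
    when both detectors are perfect, the excluded 0/0 case.
    """
    sf, df = ft.single_fault, ft.double_fault
    if sf + df == 0:
        raise ValueError(
            "complementarity undefined: both detectors succeed on every replicate"
        )
    return sf / (df + sf)


def joint_power_pair(ft: FaultTable) -> float:
    """Percentage of replicates where at least one of the two detectors succeeds."""
    return 100.0 * (ft.n - ft.ff) / ft.n


def joint_power_triple(
    a: IdentificationOutcome, b: IdentificationOutcome, c: IdentificationOutcome
) -> float:
    """Percentage of replicates where at least one of three detectors succeeds."""
    if not a.n == b.n == c.n:
        raise ValueError("outcome vectors must have equal length")
    triple_fault = int((~a.successes & ~b.successes & ~c.successes).sum())
    return 100.0 * (a.n - triple_fault) / a.n


# ---------------------------------------------------------------------------
# Outcome I/O (for importing external detectors' results)


def read_outcomes(path: str | Path) -> dict[str, IdentificationOutcome]:
    """Read per-replicate success vectors from a TSV.

    Columns: replicate_id, algorithm, success (0/1).  Replicates are ordered
    by replicate_id within each algorithm.
    """
    rows: dict[str, list[tuple[str, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"replicate_id", "algorithm", "success"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"outcome TSV needs columns {sorted(required)}")
        for row in reader:
            rows.setdefault(row["algorithm"], []).append(
                (row["replicate_id"], int(row["success"]))
            )
    out = {}
    for alg, pairs in rows.items():
        pairs.sort(key=lambda p: p[0])
        out[alg] = IdentificationOutcome(alg, np.array([s for _, s in pairs], dtype=bool))
    return out


def write_outcomes(
    outcomes: Sequence[IdentificationOutcome], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["replicate_id", "algorithm", "success"])
        for outcome in outcomes:
            for i, s in enumerate(outcome.successes):
                writer.writerow([f"{i:04d}", outcome.algorithm, int(s)])


def complementarity_table(
    outcomes: Sequence[IdentificationOutcome],
) -> list[dict[str, object]]:
    """Pairwise CD and joint power rows for every detector pair."""
    rows: list[dict[str, object]] = []
    for i in range(len(outcomes)):
        for j in range(i + 1, len(outcomes)):
            ft = fault_table(outcomes[i], outcomes[j])
            try:
                cd: object = round(complementarity(ft), 3)
            except ValueError:
                cd = "n/a"
            rows.append(
                {
                    "pair": f"{outcomes[i].algorithm}+{outcomes[j].algorithm}",
                    "cd": cd,
                    "joint_power": joint_power_pair(ft),
                }
            )
    return rows
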