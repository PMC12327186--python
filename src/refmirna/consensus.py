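"""Rank aggregation across stability methods (RefFinder-style).

Each method contributes a competition-rank vector (tied candidates share
the minimum rank; the next distinct rank skips by the tie size, the
"1-2-2-4" convention).  The comprehensive stability score of a candidate
is the geometric mean of its per-method ranks; the published convention
rounds nothing but *truncates* (floors) the display value to two decimals,
and this module follows it — 1.1892 displays as 1.18.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError

#: Default absolute tolerance under which two stability values tie.
DEFAULT_TIE_TOLERANCE = 1e-12


@dataclass
class RankVector:
    """Competition ranks of one method over a candidate set."""

    method: str
    ranks: dict[str, int]
    tie_sets: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for r in self.ranks.values():
            counts[r] = counts.get(r, 0) + 1
        # competition-rank coherence: rank r with multiplicity m is followed
        # by no rank in (r, r+m)
        expected = 1
        for r in sorted(counts):
            if r != expected:
                raise ContractError(
                    f"{self.method}: rank {r} breaks competition ranking "
                    f"(expected next rank {expected})"
                )
            expected = r + counts[r]
        if not self.tie_sets:
            by_rank: dict[int, list[str]] = {}
            for c, r in self.ranks.items():
                by_rank.setdefault(r, []).append(c)
            self.tie_sets = [sorted(v) for r, v in sorted(by_rank.items()) if len(v) > 1]


def competition_ranks(
    score: pd.Series | Mapping[str, float],
    *,
    method: str = "",
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> RankVector:
    """Rank stability values ascending (lower = more stable) with min-rank ties.

    Values within ``tie_tolerance`` of the first member of a running tie
    group share that group's minimum rank.
    """
    series = pd.Series(dict(score)) if not isinstance(score, pd.Series) else score
    order = series.sort_values(kind="mergesort").index.tolist()
    ranks: dict[str, int] = {}
    pos = 0
    group_start_value = None
    group_rank = 1
    for cand in order:
        pos += 1
        v = float(series[cand])
        if group_start_value is None or v - group_start_value > tie_tolerance:
            group_start_value = v
            group_rank = pos
        ranks[cand] = group_rank
    return RankVector(method=method or getattr(score, "name", "") or "method", ranks=ranks)


def ranks_from_tiers(
    tiers: Sequence[Sequence[str]], *, method: str = ""
) -> RankVector:
    """Competition ranks from an ordered tier list (best tier first).

    Within-tier candidates tie at the tier's minimum rank; each new tier
    advances the rank by the cumulative candidate count so far.
    """
    seen: set[str] = set()
    ranks: dict[str, int] = {}
    pos = 1
    for tier in tiers:
        tier = list(tier)
        if not tier:
            raise ContractError("empty tier")
        for cand in tier:
            if cand in seen:
                raise ContractError(f"candidate {cand!r} repeated across tiers")
            seen.add(cand)
            ranks[cand] = pos
        pos += len(tier)
    return RankVector(method=method, ranks=ranks)


def truncate_display(value: float, decimals: int = 2) -> float:
    """Floor-truncate to ``decimals`` places (1.1892 -> 1.18, 4.0 -> 4.0).

    A 1e-9 guard absorbs float round-off so that an exact integer geometric
    mean (e.g. four identical ranks of 7) truncates to itself.
    """
    scale = 10**decimals
    return math.floor(value * scale + 1e-9) / scale


@dataclass
class ConsensusRanking:
    """Geometric-mean consensus over per-method rank vectors."""

    candidates: list[str]
    geomean: dict[str, float]
    display: dict[str, float]
    order: list[str]                # ascending geomean, lexicographic tie-break
    tied: list[list[str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": self.order,
                "geomean": [self.geomean[c] for c in self.order],
                "display": [self.display[c] for c in self.order],
                "rank": range(1, len(self.order) + 1),
            }
        )


def geometric_mean_rank(vectors: Sequence[RankVector]) -> ConsensusRanking:
    """Aggregate >= 1 rank vectors over an identical candidate set."""
    if not vectors:
        raise ContractError("need at least one rank vector")
    candidates = sorted(vectors[0].ranks)
    for v in vectors[1:]:
        if sorted(v.ranks) != candidates:
            raise ContractError(
                f"candidate sets differ between methods "
                f"({vectors[0].method!r} vs {v.method!r})"
            )
    geomean: dict[str, float] = {}
    for cand in candidates:
        ranks = np.array([v.ranks[cand] for v in vectors], dtype=float)
        geomean[cand] = float(np.exp(np.log(ranks).mean()))
    order = sorted(candidates, key=lambda c: (geomean[c], c))
    tied: list[list[str]] = []
    by_value: dict[float, list[str]] = {}
    for c in candidates:
        by_value.setdefault(round(geomean[c], 12), []).append(c)
    tied = [sorted(v) for v in by_value.values() if len(v) > 1]
    display = {c: truncate_display(geomean[c]) for c in candidates}
    return ConsensusRanking(candidates, geomean, display, order, tied)


def consensus_from_scores(
    scores: Mapping[str, pd.Series],
    *,
    genorm_ranks: pd.Series | None = None,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> ConsensusRanking:
    """Build the consensus from raw per-method stability values.

    ``scores`` maps method name -> stability series (lower = better) to be
    ranked by :func:`competition_ranks`.  geNorm, whose published ranking
    comes from its exclusion order with the final pair tied at rank 1,
    contributes pre-computed ranks via ``genorm_ranks`` instead.
    """
    vectors = [
        competition_ranks(s, method=name, tie_tolerance=tie_tolerance)
        for name, s in scores.items()
    ]
    if genorm_ranks is not None:
        vectors.append(
            RankVector(method="genorm", ranks={c: int(r) for c, r in genorm_ranks.items()})
        )
    return geometric_mean_rank(vectors)
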