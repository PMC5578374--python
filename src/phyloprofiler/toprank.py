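"""Top-rank functional-linkage prediction on binary profiles.

Instead of a global score cutoff — which strands weakly conserved proteins
with no partners — each protein nominates its own best partners: candidates
with non-positive Pearson correlation are removed (a negative correlation
means one protein tends to be present where the other is absent, which is
not co-evolution), the rest are ranked by decreasing Jaccard similarity, and
the top ``T`` ranks are kept.  The union over all proteins, with direction
ignored, is the predicted linkage set.  A protein whose filtered candidate
list is empty still receives its single highest-Jaccard partner, flagged as a
fallback, so no protein is left solo at any threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .measures import pairwise_matrix
from .profiles import BinaryProfile

__all__ = ["Linkage", "LinkageSet", "rank_partners", "predict_linkages",
           "pair_rank_table"]


@dataclass(frozen=True)
class Linkage:
    """One undirected predicted link with its scores and best directed rank."""

    a: str
    b: str
    jaccard: float
    pearson: float
    best_rank: int
    fallback: bool

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class LinkageSet:
    """Symmetrized set of predicted links at one top-rank threshold ``T``."""

    links: list[Linkage]
    top: int

    def pairs(self) -> set[frozenset]:
        return {l.pair for l in self.links}

    def __len__(self) -> int:
        return len(self.links)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs()

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for l in self.links:
            out.add(l.a)
            out.add(l.b)
        return out

    def to_records(self):
        """Rows (from, to, jaccard, cor, rank, fallback), jaccard-descending."""
        return [
            (l.a, l.b, l.jaccard, l.pearson, l.best_rank, l.fallback)
            for l in sorted(self.links,
                            key=lambda l: (-l.jaccard, -_key(l.pearson), l.a, l.b))
        ]


def _key(v: float) -> float:
    return -math.inf if (v is None or np.isnan(v)) else v


class _Scores:
    """Cached Jaccard/Pearson matrices plus per-row candidate orderings."""

    def __init__(self, profile: BinaryProfile):
        if len(profile.proteins) < 2:
            raise ValueError("prediction needs >= 2 proteins")
        self.profile = profile
        self.proteins = profile.proteins
        self.J = pairwise_matrix(profile, "jaccard").values
        self.C = pairwise_matrix(profile, "pearson").values

    def ordered_candidates(self, i: int) -> list[int]:
        """All other proteins ordered by Jaccard desc, Pearson desc, id asc."""
        n = len(self.proteins)
        others = [j for j in range(n) if j != i]
        return sorted(
            others,
            key=lambda j: (-self.J[i, j], -_key(self.C[i, j]), self.proteins[j]),
        )


def rank_partners(profile: BinaryProfile, query: str):
    """Ranked candidate partners of one query protein.

    Returns ``[(protein, jaccard, pearson), ...]`` restricted to candidates
    with strictly positive Pearson correlation (an undefined correlation
    counts as non-positive), ordered by decreasing Jaccard with ties broken
    by decreasing Pearson then lexicographic identifier.  Ranks are the
    1-based positions in this list.
    """
    s = _Scores(profile)
    i = profile.index_of(query)
    return [
        (s.proteins[j], float(s.J[i, j]), float(s.C[i, j]))
        for j in s.ordered_candidates(i)
        if s.C[i, j] > 0
    ]


def predict_linkages(profile: BinaryProfile, top: int,
                strict_rank: bool = False) -> LinkageSet:
    """Predict the symmetrized linkage set at top-rank threshold ``top``.

    Each protein keeps its filtered candidates of rank <= ``top`` (or
    rank < ``top`` with ``strict_rank=True``, the alternative reading of the
    threshold); a protein with no positively correlated candidate falls back
    to its single highest-Jaccard partner, flagged.  The per-link rank is the
    minimum of the two directed ranks.
    """
    n = len(profile.proteins)
    if not 1 <= top <= n - 1:
        raise ValueError(f"top must be in [1, {n - 1}], got {top}")
    s = _Scores(profile)
    cutoff = top - 1 if strict_rank else top
    rank_of: dict[frozenset, int] = {}
    pure_fallback: dict[frozenset, bool] = {}
    for i in range(n):
        ordered = s.ordered_candidates(i)
        filtered = [j for j in ordered if s.C[i, j] > 0]
        if filtered and cutoff >= 1:
            chosen = [(rank, j, False)
                      for rank, j in enumerate(filtered[:cutoff], start=1)]
        else:
            # no positively correlated partner within reach: keep the single
            # best-Jaccard one anyway so the protein is never solo
            chosen = [(1, filtered[0] if filtered else ordered[0], True)]
        for rank, j, fb in chosen:
            key = frozenset((s.proteins[i], s.proteins[j]))
            rank_of[key] = min(rank, rank_of.get(key, rank))
            pure_fallback[key] = fb and pure_fallback.get(key, True)
    links = []
    for key, rank in rank_of.items():
        a, b = sorted(key)
        i, j = profile.index_of(a), profile.index_of(b)
        links.append(Linkage(a, b, float(s.J[i, j]), float(s.C[i, j]),
                             rank, pure_fallback[key]))
    return LinkageSet(links=links, top=top)


def pair_rank_table(profile: BinaryProfile):
    """Minimum directed rank per pair, plus the always-present fallback pairs.

    ``ranks[pair]`` is the smallest 1-based rank at which either endpoint
    selects the other from its positively-correlated, Jaccard-ordered
    candidate list; pairs filtered out in both directions are absent.
    ``fallbacks`` are the no-solo-guarantee pairs of proteins with no
    positively correlated candidate; they are predicted at every threshold.
    The prediction at threshold T (inclusive ranks) is exactly
    ``{p: ranks[p] <= T} | fallbacks``, which lets threshold sweeps reuse one
    scoring pass.
    """
    s = _Scores(profile)
    n = len(s.proteins)
    ranks: dict[frozenset, int] = {}
    fallbacks: set[frozenset] = set()
    for i in range(n):
        ordered = s.ordered_candidates(i)
        filtered = [j for j in ordered if s.C[i, j] > 0]
        if not filtered:
            fallbacks.add(frozenset((s.proteins[i], s.proteins[ordered[0]])))
            continue
        for rank, j in enumerate(filtered, start=1):
            key = frozenset((s.proteins[i], s.proteins[j]))
            ranks[key] = min(rank, ranks.get(key, rank))
    return ranks, fallbacks
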