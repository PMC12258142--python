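"""Consensus-SV merging across callers.

Calls from different tools that describe the same rearrangement agree in
chromosomes and breakend orientations and differ only by small positional
offsets, so relatedness is defined as: identical geometry (both chromosomes
and both orientations) and a per-breakend position difference within a window
(default 150 bp, inclusive).  Related calls are aggregated by single-linkage
connected components, and each cluster collapses to one consensus SV at the
per-breakend *mode* position, with a confidence level equal to the number of
distinct callers contributing.  Consensus SVs below a minimum support
(default 3 callers) are discarded.

Single linkage means chained clusters can span more than one window; the
brute-force oracle tests pin this behavior deliberately.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .breakpoints import (
    Breakend,
    BreakendPair,
    ChromRank,
    SVType,
    classify_svtype,
    sort_pairs,
)

__all__ = [
    "MergeParams",
    "ConsensusSV",
    "are_related",
    "cluster_calls",
    "collapse_cluster",
    "merge_svs",
]

DEFAULT_WINDOW = 150
DEFAULT_MIN_SUPPORT = 3


@dataclass(frozen=True)
class MergeParams:
    """Merge tuning: relatedness window in bp and minimum caller support."""

    window: int = DEFAULT_WINDOW
    min_support: int = DEFAULT_MIN_SUPPORT

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class ConsensusSV:
    """One merged SV: canonical pair at mode positions plus its members."""

    pair: BreakendPair
    supporting_callers: frozenset[str]
    confidence: int
    members: tuple[BreakendPair, ...]


def are_related(x: BreakendPair, y: BreakendPair, window: int = DEFAULT_WINDOW) -> bool:
    """True iff two canonical calls share geometry and lie within the window.

    Both breakends must match in chromosome and orientation, and each
    breakend's position difference must be <= ``window`` (inclusive bound).
    Symmetric by construction.
    """
    return (
        x.key() == y.key()
        and abs(x.a.pos - y.a.pos) <= window
        and abs(x.b.pos - y.b.pos) <= window
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_calls(
    calls: Sequence[BreakendPair], window: int = DEFAULT_WINDOW
) -> list[list[BreakendPair]]:
    """Partition calls into single-linkage components under :func:`are_related`.

    Calls are grouped by geometry key first; within a group, members are sorted
    by first-breakend position and only candidate pairs whose first breakends
    lie within the window are tested, which keeps the common case near-linear.
    The result is a partition of the input, independent of input order.
    """
    order = sorted(range(len(calls)), key=lambda i: (calls[i].key(), calls[i].a.pos, calls[i].b.pos))
    uf = _UnionFind(len(calls))
    by_key: dict[tuple, list[int]] = defaultdict(list)
    for i in order:
        by_key[calls[i].key()].append(i)
    for idxs in by_key.values():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                if calls[j].a.pos - calls[i].a.pos > window:
                    break
                if abs(calls[i].b.pos - calls[j].b.pos) <= window:
                    uf.union(i, j)
    comps: dict[int, list[BreakendPair]] = defaultdict(list)
    for i in order:  # deterministic member order within each cluster
        comps[uf.find(i)].append(calls[i])
    return [comps[r] for r in sorted(comps)]


def _mode_position(values: Iterable[int]) -> int:
    """Statistical mode; ties resolve to the tied value nearest the mean.

    Caller breakend positions are usually all distinct, in which case every
    value ties at count one and the mode is degenerate.  Picking the smallest
    tied value would systematically return the extreme (minimum) member, so
    ties resolve to the tied value closest to the members' arithmetic mean —
    still a deterministic choice of an observed member position — with the
    smaller position winning when two tied values are equidistant.
    """
    vals = list(values)
    counts = Counter(vals)
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    center = sum(vals) / len(vals)
    return min(tied, key=lambda v: (abs(v - center), v))


def collapse_cluster(cluster: Sequence[BreakendPair]) -> ConsensusSV:
    """Collapse one cluster of related calls into a consensus SV.

    The consensus position of each breakend is the mode of the member
    positions (see :func:`_mode_position` for the deterministic tie rule);
    the supporting-caller set counts each
    caller once however many member calls it contributed; the SV type is
    recomputed from the shared geometry rather than voted from caller labels.
    """
    if not cluster:
        raise ValueError("cannot collapse an empty cluster")
    first = cluster[0]
    if any(m.key() != first.key() for m in cluster):
        raise ValueError("cluster members do not share chromosomes/orientations")
    pos_a = _mode_position(m.a.pos for m in cluster)
    pos_b = _mode_position(m.b.pos for m in cluster)
    a = Breakend(first.a.chrom, pos_a, first.a.orient)
    b = Breakend(first.b.chrom, pos_b, first.b.orient)
    svtype = SVType.INS if first.svtype is SVType.INS else classify_svtype(a, b)
    callers = frozenset(m.caller for m in cluster)
    pair = BreakendPair(a=a, b=b, svtype=svtype, caller="consensus")
    return ConsensusSV(
        pair=pair,
        supporting_callers=callers,
        confidence=len(callers),
        members=tuple(cluster),
    )


def merge_svs(
    calls_by_caller: Mapping[str, Sequence[BreakendPair]],
    params: MergeParams = MergeParams(),
    rank: ChromRank | None = None,
) -> list[ConsensusSV]:
    """Merge per-caller canonical call lists into sorted consensus SVs.

    Pools all calls, clusters them, collapses each cluster, drops consensus
    SVs supported by fewer than ``params.min_support`` distinct callers, and
    sorts by (chromosome rank, position).  Deterministic and invariant to the
    ordering of the caller mapping and of calls within each caller.
    """
    rank = rank or ChromRank()
    pooled: list[BreakendPair] = []
    for caller in sorted(calls_by_caller):
        pooled.extend(calls_by_caller[caller])
    pooled = sort_pairs(pooled, rank)
    consensus = [collapse_cluster(c) for c in cluster_calls(pooled, params.window)]
    consensus = [c for c in consensus if c.confidence >= params.min_support]
    consensus.sort(
        key=lambda c: (
            rank.sort_key(c.pair.a),
            rank.sort_key(c.pair.b),
            c.pair.a.orient.value,
            c.pair.b.orient.value,
            c.pair.svtype.value,
        )
    )
    return consensus
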