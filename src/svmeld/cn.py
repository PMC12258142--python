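"""Genome-wide consensus copy-number profile and per-caller concordance.

The procedure turns per-caller copy-number segmentations into one consensus
profile in five stages:

1. *Expansion*: every segment grows 5000 bp (default) upstream and downstream,
   clamped to the chromosome; where two expanded segments of the same caller
   overlap, the overlap is divided equally at its midpoint, so each caller's
   track stays disjoint.
2. *Partition*: the union of all callers' segment boundaries cuts each
   chromosome into consensus alteration sites on which every contributing
   caller has a constant CN.
3. *Weighting*: the consensus CN of a site is the mean of the contributing
   callers' values — genome-wide this is exactly the per-base average over
   covering callers, which is the normative contract tested against a
   per-base oracle.  Sites no caller covers take the diploid default (CN 2).
4. *Concordance*: each caller's bias (length-weighted mean deviation from
   consensus) and volatility (length-weighted SD of that deviation) are
   computed on the pre-smoothing partition and min-max scaled to [0, 1]
   across callers for comparison.
5. *Smoothing*: adjacent sites whose consensus CNs differ by at most a
   tolerance (default 0.1) merge into longer segments with a length-weighted
   mean CN; each merge conserves sum(length x cn) exactly.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "CNSegment",
    "ConsensusCNInterval",
    "CallerConcordance",
    "CNParams",
    "expand_and_divide",
    "partition",
    "weighted_consensus",
    "smooth",
    "concordance",
    "consensus_cn_pipeline",
]

log = logging.getLogger(__name__)

DEFAULT_PAD = 5000
DEFAULT_SMOOTH_TOL = 0.1
DEFAULT_CN = 2.0


@dataclass(frozen=True)
class CNSegment:
    """One caller's copy-number segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    cn: float
    caller: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid segment interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusCNInterval:
    """One consensus alteration site with per-caller contributions."""

    chrom: str
    start: int
    end: int
    cn: float
    contributions: Mapping[str, float] = field(default_factory=dict)
    n_callers: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CallerConcordance:
    """Per-caller deviation summary relative to the consensus profile.

    ``bias`` keeps its sign; the min-max scaling ranks callers by |bias|, so
    the scaled value is a magnitude ranking with the direction preserved in
    the unscaled field.
    """

    caller: str
    bias: float
    volatility: float
    bias_scaled: float
    volatility_scaled: float


@dataclass(frozen=True)
class CNParams:
    pad: int = DEFAULT_PAD
    smooth_tol: float = DEFAULT_SMOOTH_TOL
    default_cn: float = DEFAULT_CN
    chrom_lengths: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.pad < 0 or self.smooth_tol < 0 or self.default_cn < 0:
            raise ValueError("pad, smooth_tol and default_cn must be >= 0")


def expand_and_divide(
    segments: Sequence[CNSegment],
    pad: int = DEFAULT_PAD,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[CNSegment]:
    """Expand one caller's disjoint segments and split resulting overlaps.

    Each segment becomes ``[start - pad, end + pad]`` clamped to
    ``[1, chrom_length]``.  Where two adjacent expanded segments of the same
    caller overlap, the overlap ``[s, e]`` is divided equally at
    ``mid = floor((s + e) / 2)``: the left segment keeps through ``mid``, the
    right starts at ``mid + 1``.  CN values are unchanged; output is disjoint
    and sorted.
    """
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    out: list[CNSegment] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"raw segments overlap for caller {prev.caller!r} on {chrom}: "
                    f"{prev.start}-{prev.end} vs {cur.start}-{cur.end}"
                )
        limit = (chrom_lengths or {}).get(chrom)
        starts = [max(1, s.start - pad) for s in segs]
        ends = [s.end + pad if limit is None else min(limit, s.end + pad) for s in segs]
        for i in range(len(segs) - 1):
            if ends[i] >= starts[i + 1]:
                mid = (starts[i + 1] + ends[i]) // 2
                ends[i] = mid
                starts[i + 1] = mid + 1
        out.extend(
            CNSegment(chrom, s, e, seg.cn, seg.caller)
            for seg, s, e in zip(segs, starts, ends)
        )
    return out


def partition(
    expanded: Mapping[str, Sequence[CNSegment]],
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ConsensusCNInterval]:
    """Cut the genome at the union of all callers' segment boundaries.

    Boundaries on each chromosome are all segment starts and ``end + 1``
    values (plus ``1`` and ``chrom_length + 1`` when lengths are supplied, so
    uncovered genome is represented).  Consecutive boundaries delimit
    intervals; each records the CN of every caller covering it — constant by
    construction.  Intervals covered by no caller carry empty contributions;
    their consensus CN is assigned later.  Returned intervals have ``cn`` set
    to NaN until :func:`weighted_consensus` runs.
    """
    by_chrom: dict[str, dict[str, list[CNSegment]]] = {}
    for caller, segs in expanded.items():
        for seg in segs:
            by_chrom.setdefault(seg.chrom, {}).setdefault(caller, []).append(seg)
    chroms = set(by_chrom) | set(chrom_lengths or {})
    out: list[ConsensusCNInterval] = []
    for chrom in sorted(chroms):
        cuts: set[int] = set()
        if chrom_lengths and chrom in chrom_lengths:
            cuts.update((1, chrom_lengths[chrom] + 1))
        caller_segs = by_chrom.get(chrom, {})
        for segs in caller_segs.values():
            for seg in segs:
                cuts.update((seg.start, seg.end + 1))
        bounds = sorted(cuts)
        pointers = {c: 0 for c in caller_segs}
        sorted_segs = {c: sorted(v, key=lambda s: s.start) for c, v in caller_segs.items()}
        for lo, hi in zip(bounds, bounds[1:]):
            contrib: dict[str, float] = {}
            for caller, segs in sorted_segs.items():
                i = pointers[caller]
                while i < len(segs) and segs[i].end < lo:
                    i += 1
                pointers[caller] = i
                if i < len(segs) and segs[i].start <= lo <= segs[i].end:
                    contrib[caller] = segs[i].cn
            out.append(
                ConsensusCNInterval(
                    chrom=chrom,
                    start=lo,
                    end=hi - 1,
                    cn=math.nan,
                    contributions=contrib,
                    n_callers=len(contrib),
                )
            )
    return out


def weighted_consensus(
    intervals: Sequence[ConsensusCNInterval],
    params: CNParams = CNParams(),
) -> list[ConsensusCNInterval]:
    """Assign each partition interval its consensus CN.

    The consensus on an interval is the arithmetic mean of the contributing
    callers' (constant) values; because intervals are cut at every caller
    boundary this equals the genome-wide per-base average over covering
    callers.  Uncovered intervals take ``params.default_cn``.
    """
    out = []
    for iv in intervals:
        if iv.contributions:
            cn = sum(iv.contributions.values()) / len(iv.contributions)
        else:
            cn = params.default_cn
        out.append(
            ConsensusCNInterval(
                iv.chrom, iv.start, iv.end, cn, dict(iv.contributions), len(iv.contributions)
            )
        )
    return out


def smooth(
    intervals: Sequence[ConsensusCNInterval],
    smooth_tol: float = DEFAULT_SMOOTH_TOL,
) -> list[ConsensusCNInterval]:
    """Merge contiguous intervals whose consensus CNs agree within tolerance.

    Applied left to right to a fixpoint; a merged interval's CN is the
    length-weighted mean (conserving sum(length x cn) exactly) and its
    ``n_callers`` the length-weighted mean of the inputs, rounded down.
    Contributions are dropped, which is why concordance is computed before
    smoothing.
    """
    merged = list(intervals)
    changed = True
    while changed:
        changed = False
        out: list[ConsensusCNInterval] = []
        for iv in merged:
            prev = out[-1] if out else None
            if (
                prev is not None
                and prev.chrom == iv.chrom
                and prev.end + 1 == iv.start
                and abs(prev.cn - iv.cn) <= smooth_tol
            ):
                w1, w2 = prev.length, iv.length
                out[-1] = ConsensusCNInterval(
                    chrom=prev.chrom,
                    start=prev.start,
                    end=iv.end,
                    cn=(w1 * prev.cn + w2 * iv.cn) / (w1 + w2),
                    contributions={},
                    n_callers=(w1 * prev.n_callers + w2 * iv.n_callers) // (w1 + w2),
                )
                changed = True
            else:
                out.append(iv)
        merged = out
    return merged


def concordance(intervals: Sequence[ConsensusCNInterval]) -> list[CallerConcordance]:
    """Score each caller against the pre-smoothing consensus.

    For caller *t* over the intervals it covers, with deviations
    ``d_i = cn_t,i - consensus_i`` and weights ``w_i`` the interval lengths:
    ``bias_t = sum(w d) / sum(w)`` and
    ``volatility_t = sqrt(sum(w (d - bias)^2) / sum(w))``.  Scaled values
    min-max normalize |bias| and volatility across callers (0 when all tie).
    """
    acc: dict[str, list[tuple[int, float]]] = {}
    for iv in intervals:
        for caller, cn in iv.contributions.items():
            acc.setdefault(caller, []).append((iv.length, cn - iv.cn))
    stats: list[tuple[str, float, float]] = []
    for caller in sorted(acc):
        pairs = acc[caller]
        wsum = sum(w for w, _ in pairs)
        if wsum == 0:  # pragma: no cover - lengths are always >= 1
            log.info("caller %s covers no bases; excluded from concordance", caller)
            continue
        bias = sum(w * d for w, d in pairs) / wsum
        var = sum(w * (d - bias) ** 2 for w, d in pairs) / wsum
        stats.append((caller, bias, math.sqrt(max(var, 0.0))))

    def scale(values: list[float]) -> list[float]:
        lo, hi = min(values), max(values)
        if hi == lo:
            return [0.0] * len(values)
        return [(v - lo) / (hi - lo) for v in values]

    if not stats:
        return []
    bias_scaled = scale([abs(b) for _, b, _ in stats])
    vol_scaled = scale([v for _, _, v in stats])
    return [
        CallerConcordance(caller, bias, vol, bs, vs)
        for (caller, bias, vol), bs, vs in zip(stats, bias_scaled, vol_scaled)
    ]


def consensus_cn_pipeline(
    segments_by_caller: Mapping[str, Sequence[CNSegment]],
    params: CNParams = CNParams(),
) -> tuple[list[ConsensusCNInterval], list[CallerConcordance]]:
    """Full consensus procedure: expand, partition, weight, score, smooth.

    Returns the smoothed consensus intervals and the per-caller concordance
    table (computed before smoothing).  Deterministic.
    """
    expanded = {
        caller: expand_and_divide(segs, params.pad, params.chrom_lengths)
        for caller, segs in segments_by_caller.items()
    }
    skeleton = partition(expanded, params.chrom_lengths)
    weighted = weighted_consensus(skeleton, params)
    scores = concordance(weighted)
    return smooth(weighted, params.smooth_tol), scores
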