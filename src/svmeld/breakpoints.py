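"""Canonical data model for structural-variant calls.

An SV call is represented as a pair of oriented *breakends*: each breakend is a
chromosome, a 1-based position, and an orientation flag stating which flank of
the breakpoint is retained in the derivative chromosome.  ``"+"`` means the
sequence 5' of (to the left of) the breakpoint is retained and joined; ``"-"``
means the sequence 3' of (to the right of) it is.  This matches the common
BEDPE strand convention, under which a deletion is ``+/-``, a tandem
duplication ``-/+``, and an inversion ``+/+`` or ``-/-``.

The module also provides the mapping between VCF BND bracket notation and
orientation pairs, chromosome ranking, and canonical breakend ordering.
Standardizing heterogeneous caller outputs into this one representation is
what makes calls from different tools comparable at all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Orientation",
    "SVType",
    "Breakend",
    "BreakendPair",
    "ChromRank",
    "UnrankableChromError",
    "BndParseError",
    "classify_svtype",
    "canonicalize",
    "bnd_alt_to_orientations",
    "parse_bnd_alt",
    "pair_to_bnd_alts",
]


class Orientation(str, Enum):
    """Which flank of the breakpoint is retained in the derivative chromosome."""

    LEFT_RETAINED = "+"
    RIGHT_RETAINED = "-"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_strand(cls, s: str) -> "Orientation":
        if s == "+":
            return cls.LEFT_RETAINED
        if s == "-":
            return cls.RIGHT_RETAINED
        raise ValueError(f"not a strand symbol: {s!r}")


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    TRA = "TRA"
    INS = "INS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class UnrankableChromError(KeyError):
    """A chromosome name not present in the configured ranking."""


class BndParseError(ValueError):
    """A VCF BND ALT allele that matches none of the four bracket shapes."""


@dataclass(frozen=True, order=False)
class Breakend:
    """One side of a novel adjacency."""

    chrom: str
    pos: int
    orient: Orientation

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("breakend chromosome must be non-empty")
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if not isinstance(self.orient, Orientation):
            object.__setattr__(self, "orient", Orientation(self.orient))


@dataclass(frozen=True)
class BreakendPair:
    """A standardized SV call: two oriented breakends plus type and provenance.

    Canonical order (``(a.chrom, a.pos) <= (b.chrom, b.pos)`` under chromosome
    rank) is not enforced by the constructor — apply :func:`canonicalize` after
    building pairs from caller output.
    """

    a: Breakend
    b: Breakend
    svtype: SVType
    caller: str
    qual: float | None = None
    filter: str | None = None

    def key(self) -> tuple:
        """Geometry key: chromosomes and orientations of both breakends.

        Calls are only ever merged within one geometry key.  Insertions keep
        their caller-declared type and are never pooled with orientation-typed
        calls, so the type participates in the key only through the INS flag.
        """
        return (
            self.a.chrom,
            self.b.chrom,
            self.a.orient,
            self.b.orient,
            self.svtype is SVType.INS,
        )


_DEFAULT_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class ChromRank:
    """A total order over chromosome names.

    Ranking is prefix-insensitive: ``chr1`` and ``1`` rank identically.  Names
    outside the configured list (mitochondrial, alt contigs) raise
    :class:`UnrankableChromError` unless added explicitly.
    """

    names: tuple[str, ...] = _DEFAULT_CHROMS
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        stripped = [_strip_chr(n) for n in self.names]
        if len(set(stripped)) != len(stripped):
            raise ValueError("chromosome names must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(stripped)})

    def rank(self, chrom: str) -> int:
        try:
            return self._index[_strip_chr(chrom)]
        except KeyError:
            raise UnrankableChromError(
                f"chromosome {chrom!r} is not rankable; known: "
                f"{', '.join(self.names)}"
            ) from None

    def __contains__(self, chrom: str) -> bool:
        return _strip_chr(chrom) in self._index

    def sort_key(self, be: Breakend) -> tuple[int, int]:
        return (self.rank(be.chrom), be.pos)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "ChromRank":
        return cls(tuple(names))


def classify_svtype(a: Breakend, b: Breakend) -> SVType:
    """Classify a canonical breakend pair from its geometry.

    Interchromosomal pairs are translocations; on one chromosome the
    orientation pair decides: ``+/-`` deletion, ``-/+`` duplication, ``+/+`` or
    ``-/-`` inversion.  Total over all orientation combinations.
    """
    if a.chrom != b.chrom:
        return SVType.TRA
    L, R = Orientation.LEFT_RETAINED, Orientation.RIGHT_RETAINED
    if (a.orient, b.orient) == (L, R):
        return SVType.DEL
    if (a.orient, b.orient) == (R, L):
        return SVType.DUP
    return SVType.INV


def canonicalize(pair: BreakendPair, rank: ChromRank) -> BreakendPair:
    """Order the two breakends by (chromosome rank, position).

    Orientations travel with their breakends.  Idempotent.  For
    orientation-typed calls the SV type is recomputed from the (re)ordered
    geometry; insertions keep their declared type.
    """
    # orientation breaks the (vanishingly rare) tie of two breakends at the
    # same locus, keeping canonical order total
    ka = (*rank.sort_key(pair.a), pair.a.orient.value)
    kb = (*rank.sort_key(pair.b), pair.b.orient.value)
    a, b = (pair.a, pair.b) if ka <= kb else (pair.b, pair.a)
    svtype = pair.svtype if pair.svtype is SVType.INS else classify_svtype(a, b)
    if a is pair.a and b is pair.b and svtype is pair.svtype:
        return pair
    return replace(pair, a=a, b=b, svtype=svtype)


# The four VCF breakend ALT shapes.  t is the local (REF-anchored) sequence,
# p the mate locus.  Bracket direction and t placement jointly encode the
# orientation of both sides of the adjacency:
#
#   t[p[  -> self +, mate -      t]p]  -> self +, mate +
#   ]p]t  -> self -, mate +      [p[t  -> self -, mate -
_BND_RE = re.compile(
    r"""^
    (?:(?P<t_left>[A-Za-z.*<>]+))?
    (?P<open>[\[\]])
    (?P<chrom>[^\[\]:]+):(?P<pos>\d+)
    (?P<close>[\[\]])
    (?:(?P<t_right>[A-Za-z.*<>]+))?
    $""",
    re.VERBOSE,
)


def parse_bnd_alt(alt: str) -> tuple[str, int, Orientation, Orientation]:
    """Decode one BND ALT allele.

    Returns ``(mate_chrom, mate_pos, orient_self, orient_mate)``.  Raises
    :class:`BndParseError` on anything that is not one of the four shapes.
    """
    m = _BND_RE.match(alt)
    if not m or m["open"] != m["close"] or bool(m["t_left"]) == bool(m["t_right"]):
        raise BndParseError(f"malformed BND ALT allele: {alt!r}")
    L, R = Orientation.LEFT_RETAINED, Orientation.RIGHT_RETAINED
    if m["t_left"]:  # t[p[ or t]p]
        orient_self = L
        orient_mate = R if m["open"] == "[" else L
    else:  # ]p]t or [p[t
        orient_self = R
        orient_mate = L if m["open"] == "]" else R
    return m["chrom"], int(m["pos"]), orient_self, orient_mate


def bnd_alt_to_orientations(alt: str) -> tuple[Orientation, Orientation]:
    """Orientation pair ``(self, mate)`` encoded by a BND ALT allele."""
    _, _, o_self, o_mate = parse_bnd_alt(alt)
    return o_self, o_mate


def pair_to_bnd_alts(pair: BreakendPair, ref_a: str = "N", ref_b: str = "N") -> tuple[str, str]:
    """Render a pair as the two mated BND ALT alleles (a's record, b's record)."""

    def one(self_be: Breakend, mate_be: Breakend, ref: str) -> str:
        L = Orientation.LEFT_RETAINED
        locus = f"{mate_be.chrom}:{mate_be.pos}"
        if self_be.orient is L:
            br = "[" if mate_be.orient is not L else "]"
            return f"{ref}{br}{locus}{br}"
        br = "]" if mate_be.orient is L else "["
        return f"{br}{locus}{br}{ref}"

    return one(pair.a, pair.b, ref_a), one(pair.b, pair.a, ref_b)


def sort_pairs(pairs: Sequence[BreakendPair], rank: ChromRank) -> list[BreakendPair]:
    """Stable sort by (chrom rank, pos) of both breakends, then type/caller."""
    return sorted(
        pairs,
        key=lambda p: (
            rank.sort_key(p.a),
            rank.sort_key(p.b),
            p.a.orient.value,
            p.b.orient.value,
            p.svtype.value,
            p.caller,
        ),
    )
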