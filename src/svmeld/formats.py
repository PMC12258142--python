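"""Readers and writers for the formats the merge stack touches.

Supported on the way in: VCF 4.x SV calls (bracket-notation BND pairs and
symbolic <DEL>/<DUP>/<INV>/<INS>/TRA records), 10+ column BEDPE, and
SEG/BED-like tab-separated copy-number segment tables in either coordinate
convention.  On the way out: consensus SVs as BEDPE or mated-BND VCF,
consensus CN and concordance tables as TSV, and circos-style track files.

Caller-specific VCF dialects are handled by a small config (which INFO keys
carry END / mate chromosome / orientation) with shipped presets rather than
per-caller parsers.  Every reader returns its records together with a
:class:`ParseReport` accounting for parsed, dropped and errored records.

Internal coordinates are 1-based inclusive (VCF-style); BEDPE and 0-based
segment tables are converted exactly at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .breakpoints import (
    Breakend,
    BreakendPair,
    BndParseError,
    ChromRank,
    Orientation,
    SVType,
    canonicalize,
    pair_to_bnd_alts,
    parse_bnd_alt,
    sort_pairs,
)
from .cn import CallerConcordance, CNSegment, ConsensusCNInterval
from .merge import ConsensusSV

__all__ = [
    "FormatError",
    "InvariantError",
    "ParseReport",
    "VcfDialect",
    "DIALECTS",
    "SegmentTable",
    "PurityPloidyRecord",
    "MissingEstimateError",
    "read_sv_vcf",
    "read_sv_bedpe",
    "read_segments",
    "write_consensus_sv",
    "write_cn_tsv",
    "write_concordance_tsv",
    "export_tracks",
    "read_purity_ploidy",
    "select_purity_ploidy",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file that cannot be interpreted in its declared format."""


class InvariantError(ValueError):
    """Structurally valid input that violates a documented invariant."""


class MissingEstimateError(LookupError):
    """No purity/ploidy candidate was provided."""


@dataclass
class ParseReport:
    """Record-level accounting for one reader invocation."""

    total: int = 0
    parsed: int = 0
    dropped: int = 0
    errored: int = 0
    messages: list[str] = field(default_factory=list)

    def drop(self, msg: str) -> None:
        self.dropped += 1
        self.messages.append(msg)

    def error(self, msg: str) -> None:
        self.errored += 1
        self.messages.append(msg)


@dataclass(frozen=True)
class VcfDialect:
    """How one caller's VCF spells the non-standard parts of an SV record."""

    name: str = "generic"
    mate_chrom_keys: tuple[str, ...] = ("CHR2",)
    strands_keys: tuple[str, ...] = ("STRANDS",)
    ct_key: str | None = "CT"  # "3to5"-style connection type; 3 => "+", 5 => "-"
    filter_pass: bool = True


DIALECTS: dict[str, VcfDialect] = {
    "generic": VcfDialect(),
    "manta": VcfDialect(name="manta"),
    "delly": VcfDialect(name="delly"),
    "lumpy": VcfDialect(name="lumpy", filter_pass=False),  # lumpy leaves FILTER empty
    "svaba": VcfDialect(name="svaba"),
    "gridss": VcfDialect(name="gridss"),
}

_SYMBOLIC_ORIENTS = {
    SVType.DEL: (Orientation.LEFT_RETAINED, Orientation.RIGHT_RETAINED),
    SVType.DUP: (Orientation.RIGHT_RETAINED, Orientation.LEFT_RETAINED),
    SVType.INS: (Orientation.LEFT_RETAINED, Orientation.RIGHT_RETAINED),
}

_CT_ORIENT = {"3": Orientation.LEFT_RETAINED, "5": Orientation.RIGHT_RETAINED}


def _style_chrom(chrom: str, style: str | None) -> str:
    if style is None:
        return chrom
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if style == "chr" else bare


def _filter_ok(rec, filter_pass: bool) -> bool:
    if not filter_pass:
        return True
    keys = list(rec.filter.keys())
    return not keys or keys == ["PASS"]


def _symbolic_orientations(rec, svtype: SVType, dialect: VcfDialect, inv_orient) -> tuple:
    for key in dialect.strands_keys:
        strands = rec.info.get(key)
        if strands:
            if isinstance(strands, tuple):
                strands = strands[0]
            s = str(strands)
            if len(s) >= 2 and s[0] in "+-" and s[1] in "+-":
                return Orientation.from_strand(s[0]), Orientation.from_strand(s[1])
    if dialect.ct_key:
        ct = rec.info.get(dialect.ct_key)
        if ct:
            s = str(ct[0] if isinstance(ct, tuple) else ct)
            parts = s.split("to")
            if len(parts) == 2 and parts[0] in _CT_ORIENT and parts[1] in _CT_ORIENT:
                return _CT_ORIENT[parts[0]], _CT_ORIENT[parts[1]]
    if svtype is SVType.INV:
        return inv_orient
    return _SYMBOLIC_ORIENTS.get(svtype, (None, None))


def read_sv_vcf(
    path: str | Path,
    caller_id: str,
    chrom_rank: ChromRank | None = None,
    dialect: VcfDialect | str = "generic",
    filter_pass: bool | None = None,
    inv_orient: tuple[Orientation, Orientation] = (
        Orientation.LEFT_RETAINED,
        Orientation.LEFT_RETAINED,
    ),
    chrom_style: str | None = None,
) -> tuple[list[BreakendPair], ParseReport]:
    """Read one caller's SV VCF into canonical breakend pairs.

    Mated BND records collapse to one pair (deduplicated on the unordered
    breakend set); unmated single-breakend records are dropped and counted.
    Records whose FILTER is neither PASS nor empty are excluded when the
    dialect (or the ``filter_pass`` override) requires it.  Chromosomes
    outside the rank are dropped with a note.
    """
    rank = chrom_rank or ChromRank()
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    want_pass = dialect.filter_pass if filter_pass is None else filter_pass

    pairs: list[BreakendPair] = []
    seen: set[tuple] = set()
    report = ParseReport()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            report.total += 1
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                report.drop(f"{rec.chrom}:{rec.pos} has no ALT allele")
                continue
            if not _filter_ok(rec, want_pass):
                report.drop(f"{rec.chrom}:{rec.pos} filtered ({';'.join(rec.filter.keys())})")
                continue
            try:
                pair = _record_to_pair(rec, alt, caller_id, dialect, inv_orient, chrom_style)
            except (BndParseError, FormatError) as exc:
                report.error(f"{rec.chrom}:{rec.pos}: {exc}")
                continue
            if pair is None:
                report.drop(f"{rec.chrom}:{rec.pos} unmated single breakend")
                continue
            if pair.a.chrom not in rank or pair.b.chrom not in rank:
                report.drop(f"{rec.chrom}:{rec.pos} on unranked chromosome")
                continue
            pair = canonicalize(pair, rank)
            key = (pair.a.chrom, pair.a.pos, pair.a.orient, pair.b.chrom, pair.b.pos, pair.b.orient)
            if key in seen:
                report.parsed += 1  # the mate line of an already-built pair
                continue
            seen.add(key)
            report.parsed += 1
            pairs.append(pair)
    return sort_pairs(pairs, rank), report


def _record_to_pair(rec, alt, caller_id, dialect, inv_orient, chrom_style):
    chrom = _style_chrom(rec.chrom, chrom_style)
    qual = float(rec.qual) if rec.qual is not None else None
    filt = ";".join(rec.filter.keys()) or None
    if "[" in alt or "]" in alt:
        mate_chrom, mate_pos, o_self, o_mate = parse_bnd_alt(alt)
        a = Breakend(chrom, rec.pos, o_self)
        b = Breakend(_style_chrom(mate_chrom, chrom_style), mate_pos, o_mate)
        # placeholder type: canonicalize() reclassifies from the geometry
        return BreakendPair(a, b, SVType.DEL, caller_id, qual, filt)
    if alt in (".",) or alt.endswith(".") or alt.startswith("."):
        return None  # single-breakend record
    sym = alt.strip("<>").split(":")[0] if alt.startswith("<") else None
    declared = str(rec.info.get("SVTYPE", sym or ""))
    name = (sym or declared).upper()
    if name in ("TRA", "BND", "CTX"):
        mate_chrom = None
        for key in dialect.mate_chrom_keys:
            if key in rec.info:
                mate_chrom = str(rec.info[key])
                break
        if mate_chrom is None:
            raise FormatError(f"interchromosomal record lacks a mate chromosome key")
        end = rec.stop
        o1, o2 = _symbolic_orientations(rec, SVType.TRA, dialect, inv_orient)
        if o1 is None:
            o1 = o2 = Orientation.LEFT_RETAINED
        return BreakendPair(
            Breakend(chrom, rec.pos, o1),
            Breakend(_style_chrom(mate_chrom, chrom_style), end, o2),
            SVType.TRA,
            caller_id,
            qual,
            filt,
        )
    try:
        svtype = SVType(name)
    except ValueError:
        raise FormatError(f"unsupported ALT/SVTYPE {alt!r}/{declared!r}")
    end = rec.stop
    if end is None or (end == rec.pos and svtype is not SVType.INS):
        if "END" not in rec.info:
            raise FormatError("symbolic SV record lacks END")
    o1, o2 = _symbolic_orientations(rec, svtype, dialect, inv_orient)
    return BreakendPair(
        Breakend(chrom, rec.pos, o1),
        Breakend(chrom, max(end, rec.pos), o2),
        svtype,
        caller_id,
        qual,
        filt,
    )


def read_sv_bedpe(
    path: str | Path,
    caller_id: str,
    chrom_rank: ChromRank | None = None,
    chrom_style: str | None = None,
) -> tuple[list[BreakendPair], ParseReport]:
    """Read a 10+ column BEDPE into canonical breakend pairs.

    The breakend position of each side is ``start + 1`` of its (0-based
    half-open) interval; strand columns 9/10 map ``+`` to left-retained and
    ``-`` to right-retained.
    """
    rank = chrom_rank or ChromRank()
    report = ParseReport()
    pairs: list[BreakendPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            report.total += 1
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(
                    f"{path}:{lineno}: BEDPE needs >= 10 columns, found {len(cols)}"
                )
            try:
                c1 = _style_chrom(cols[0], chrom_style)
                c2 = _style_chrom(cols[3], chrom_style)
                a = Breakend(c1, int(cols[1]) + 1, Orientation.from_strand(cols[8]))
                b = Breakend(c2, int(cols[4]) + 1, Orientation.from_strand(cols[9]))
            except ValueError as exc:
                report.error(f"{path}:{lineno}: {exc}")
                continue
            if a.chrom not in rank or b.chrom not in rank:
                report.drop(f"{path}:{lineno}: unranked chromosome")
                continue
            qual = None
            if cols[7] not in (".", ""):
                try:
                    qual = float(cols[7])
                except ValueError:
                    pass
            svtype = SVType.TRA if a.chrom != b.chrom else None
            if len(cols) > 10 and cols[10].upper() == "INS":
                svtype = SVType.INS
            pair = BreakendPair(a, b, svtype or SVType.DEL, caller_id, qual)
            pairs.append(canonicalize(pair, rank))
            report.parsed += 1
    return sort_pairs(pairs, rank), report


@dataclass(frozen=True)
class SegmentTable:
    """One caller's copy-number segmentation, normalized to 1-based inclusive."""

    segments: tuple[CNSegment, ...]
    caller: str
    convention: str = "1-based-inclusive"


_CONVENTIONS = ("1-based-inclusive", "0-based-half-open")


def read_segments(
    path: str | Path,
    caller_id: str,
    convention: str = "1-based-inclusive",
    chrom_style: str | None = None,
) -> SegmentTable:
    """Read a SEG/BED-like tab-separated CN segment table.

    Needs at least four columns: chrom, start, end, copy number (a header
    line is detected and skipped).  Coordinates are normalized to 1-based
    inclusive; same-caller overlap, ``start > end`` and negative CN raise
    :class:`InvariantError`.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: segment table needs >= 4 columns, found {df.shape[1]}")
    first = df.iloc[0]
    if not str(first[1]).lstrip("-").isdigit():
        df = df.iloc[1:]
    segments: list[CNSegment] = []
    for row in df.itertuples(index=False):
        chrom = _style_chrom(str(row[0]), chrom_style)
        try:
            start, end, cn = int(row[1]), int(row[2]), float(row[3])
        except ValueError as exc:
            raise FormatError(f"{path}: bad segment row {tuple(row)!r}: {exc}") from None
        if convention == "0-based-half-open":
            start += 1
        if start > end:
            raise InvariantError(f"{path}: segment start > end on {chrom}: {start} > {end}")
        if cn < 0:
            raise InvariantError(f"{path}: negative copy number {cn} on {chrom}")
        segments.append(CNSegment(chrom, start, end, cn, caller_id))
    segments.sort(key=lambda s: (s.chrom, s.start))
    for prev, cur in zip(segments, segments[1:]):
        if prev.chrom == cur.chrom and cur.start <= prev.end:
            raise InvariantError(
                f"{path}: overlapping segments for caller {caller_id!r} on {prev.chrom}: "
                f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
            )
    return SegmentTable(tuple(segments), caller_id, "1-based-inclusive")


# ---------------------------------------------------------------- writers


def _consensus_name(i: int) -> str:
    return f"SV{i + 1}"


def write_consensus_sv(
    consensus: Sequence[ConsensusSV],
    path: str | Path,
    format: str = "bedpe",
) -> None:
    """Write consensus SVs as BEDPE or as a mated-BND VCF.

    Output is byte-stable for a given input: callers are sorted, floats are
    not emitted, and records keep the order of the (already sorted) input.
    """
    if format == "bedpe":
        _write_consensus_bedpe(consensus, path)
    elif format == "vcf":
        _write_consensus_vcf(consensus, path)
    else:
        raise ValueError(f"unknown consensus SV format {format!r}")


def _write_consensus_bedpe(consensus: Sequence[ConsensusSV], path: str | Path) -> None:
    lines = [
        "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
        "strand1\tstrand2\tsvtype\tsupp\tsupp_callers"
    ]
    for i, c in enumerate(consensus):
        p = c.pair
        callers = ",".join(sorted(c.supporting_callers))
        lines.append(
            "\t".join(
                [
                    p.a.chrom, str(p.a.pos - 1), str(p.a.pos),
                    p.b.chrom, str(p.b.pos - 1), str(p.b.pos),
                    _consensus_name(i), ".",
                    p.a.orient.value, p.b.orient.value,
                    p.svtype.value, str(c.confidence), callers,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##ALT=<ID=BND,Description="Breakend">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of supporting callers">',
    '##INFO=<ID=SUPP_CALLERS,Number=.,Type=String,Description="Supporting caller ids">',
    '##INFO=<ID=EVTYPE,Number=1,Type=String,Description="Classified SV type">',
]


def _write_consensus_vcf(consensus: Sequence[ConsensusSV], path: str | Path) -> None:
    chroms = sorted(
        {c.pair.a.chrom for c in consensus} | {c.pair.b.chrom for c in consensus}
    )
    lines = list(_VCF_HEADER)
    lines.extend(f"##contig=<ID={c}>" for c in chroms)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, c in enumerate(consensus):
        name = _consensus_name(i)
        alt_a, alt_b = pair_to_bnd_alts(c.pair)
        callers = ",".join(sorted(c.supporting_callers))
        info = f"SVTYPE=BND;EVTYPE={c.pair.svtype.value};SUPP={c.confidence};SUPP_CALLERS={callers}"
        for tag, be, alt, mate in (
            ("_1", c.pair.a, alt_a, "_2"),
            ("_2", c.pair.b, alt_b, "_1"),
        ):
            lines.append(
                "\t".join(
                    [
                        be.chrom, str(be.pos), name + tag, "N", alt, ".", "PASS",
                        f"MATEID={name}{mate};{info}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cn_tsv(intervals: Sequence[ConsensusCNInterval], path: str | Path) -> None:
    """Consensus CN profile as TSV: chrom, start, end, cn, n_callers."""
    lines = ["#chrom\tstart\tend\tcn\tn_callers"]
    for iv in intervals:
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.cn:.6g}\t{iv.n_callers}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_concordance_tsv(scores: Sequence[CallerConcordance], path: str | Path) -> None:
    """Per-caller concordance as TSV: caller, bias, volatility, scaled versions."""
    lines = ["#caller\tbias\tvolatility\tbias_scaled\tvolatility_scaled"]
    for s in scores:
        lines.append(
            f"{s.caller}\t{s.bias:.6g}\t{s.volatility:.6g}"
            f"\t{s.bias_scaled:.6g}\t{s.volatility_scaled:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def export_tracks(
    outdir: str | Path,
    consensus_sv: Sequence[ConsensusSV] = (),
    consensus_cn: Sequence[ConsensusCNInterval] = (),
    event_beds: Mapping[str, str | Path] | None = None,
) -> list[Path]:
    """Write circos-style track files: CN, labelled SV, pass-through BEDs.

    The CN track is ``chrom  start  end  cn``; the SV track is
    ``chrom1  pos1  chrom2  pos2  svtype`` with the type label carried so a
    plotter can distinguish DEL/DUP/INV/TRA links; each extra BED of
    externally called complex-event regions is copied through unchanged as
    ``<name>_track.tsv``.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cn_path = outdir / "cn_track.tsv"
    cn_lines = [f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.cn:.6g}" for iv in consensus_cn]
    cn_path.write_text("\n".join(cn_lines) + ("\n" if cn_lines else ""))
    written.append(cn_path)

    sv_path = outdir / "sv_track.tsv"
    sv_lines = [
        f"{c.pair.a.chrom}\t{c.pair.a.pos}\t{c.pair.b.chrom}\t{c.pair.b.pos}\t{c.pair.svtype.value}"
        for c in consensus_sv
    ]
    sv_path.write_text("\n".join(sv_lines) + ("\n" if sv_lines else ""))
    written.append(sv_path)

    for name, bed in (event_beds or {}).items():
        dest = outdir / f"{name}_track.tsv"
        dest.write_text(Path(bed).read_text())
        written.append(dest)
    return written


# ------------------------------------------------------- purity / ploidy


@dataclass(frozen=True)
class PurityPloidyRecord:
    purity: float
    ploidy: float
    source: str = "other"

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")


def read_purity_ploidy(path: str | Path, source: str) -> PurityPloidyRecord:
    """Read a purity/ploidy summary table.

    Accepts any tab-separated table with a header naming a purity (or
    cellularity) column and a ploidy column — this covers both the Sequenza
    confidence-interval table and the PURPLE purity summary.  The first data
    row is used.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    pur_col = next((cols[c] for c in cols if "purity" in c or "cellularity" in c), None)
    plo_col = next((cols[c] for c in cols if "ploidy" in c), None)
    if pur_col is None or plo_col is None or df.empty:
        raise FormatError(f"{path}: no purity/ploidy columns found")
    return PurityPloidyRecord(
        purity=float(df[pur_col].iloc[0]),
        ploidy=float(df[plo_col].iloc[0]),
        source=source,
    )


def select_purity_ploidy(candidates: Sequence[PurityPloidyRecord]) -> PurityPloidyRecord:
    """Pick the estimate to use: Sequenza first, then PURPLE, then anything.

    Ties within one source resolve to the earliest candidate; an empty list
    raises :class:`MissingEstimateError`.
    """
    order = {"sequenza": 0, "purple": 1}
    if not candidates:
        raise MissingEstimateError("no purity/ploidy estimates provided")
    return min(
        enumerate(candidates),
        key=lambda ic: (order.get(ic[1].source, 2), ic[0]),
    )[1]
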