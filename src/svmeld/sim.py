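"""Seeded simulator of multi-caller SV and CNV outputs with a known truth.

The generator emulates what consensus merging actually has to cope with: a
shared truth set that each caller observes with positional jitter on both
breakends, caller-private false positives, false negatives, and noisy
copy-number boundaries and values.  It does not emulate read-level evidence,
realistic SV size distributions, or correlated errors between callers (a flag
exists to share false positives among callers to study that failure mode).

Truth SVs are placed with pairwise breakend separation greater than twice the
merge window so that cluster membership is unambiguous and recovery against
truth is well defined.  All randomness flows from one root seed through named
substreams (truth, per-caller SV, per-caller CN), so adding a caller leaves
every other caller's output unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .breakpoints import Breakend, BreakendPair, ChromRank, Orientation, SVType, canonicalize
from .cn import CNSegment
from .merge import DEFAULT_WINDOW, ConsensusSV

__all__ = [
    "CallerProfile",
    "SimConfig",
    "EvalMetrics",
    "generate_truth",
    "simulate_caller",
    "simulate_all",
    "evaluate",
]

_ORIENTS = {
    SVType.DEL: (Orientation.LEFT_RETAINED, Orientation.RIGHT_RETAINED),
    SVType.DUP: (Orientation.RIGHT_RETAINED, Orientation.LEFT_RETAINED),
    SVType.INV: (Orientation.LEFT_RETAINED, Orientation.LEFT_RETAINED),
}


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one simulated caller.

    jitter_sd: SD (bp) of Gaussian breakend noise, rounded to integer offsets.
    fn_rate: probability of missing each truth SV.
    fp_rate: expected private false calls per truth SV (Poisson).
    cn_boundary_jitter_sd: SD (bp) of CN segment-boundary noise.
    cn_value_noise_sd: SD (CN units) of segment-value noise.
    """

    name: str
    jitter_sd: float = 20.0
    fn_rate: float = 0.1
    fp_rate: float = 0.2
    cn_boundary_jitter_sd: float = 500.0
    cn_value_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must be in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be >= 0")
        if self.cn_boundary_jitter_sd < 0 or self.cn_value_noise_sd < 0:
            raise ValueError("CN noise SDs must be >= 0")


def _default_callers() -> tuple[CallerProfile, ...]:
    return tuple(CallerProfile(name=f"caller{i + 1}") for i in range(6))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults: one 10 Mb chromosome, 100 truth SVs in a DEL/DUP/INV mix
    (translocations need at least two chromosomes and are off by default),
    20 truth CN segments with integer states around the diploid baseline, and
    six callers with 20 bp breakend jitter, 10% false-negative and 0.2
    private false positives per truth SV.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    n_sv: int = 100
    sv_type_mix: Mapping[SVType, float] = field(
        default_factory=lambda: {SVType.DEL: 0.4, SVType.DUP: 0.3, SVType.INV: 0.3}
    )
    n_cn_segments: int = 20
    cn_values: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0)
    callers: Sequence[CallerProfile] = field(default_factory=_default_callers)
    merge_window: int = DEFAULT_WINDOW
    shared_fp_callers: int = 1  # >1 plants each false positive in that many callers

    def __post_init__(self) -> None:
        total = sum(self.sv_type_mix.values())
        if self.sv_type_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"sv_type_mix proportions must sum to 1, got {total}")
        if self.n_sv < 0:
            raise ValueError("n_sv must be >= 0")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.sv_type_mix.get(SVType.TRA, 0) > 0 and len(self.chrom_lengths) < 2:
            raise ValueError("translocations require at least two chromosomes")

    @property
    def min_separation(self) -> int:
        # strict separation beyond which clusters cannot interact
        return 2 * self.merge_window + 1

    def rank(self) -> ChromRank:
        return ChromRank.from_names(self.chrom_lengths.keys())


class PackingError(RuntimeError):
    """Too many breakends requested for the genome size and spacing rule."""


def _stream(config_seed: int, name: str) -> np.random.Generator:
    """Named substream: stable under adding/removing other streams."""
    return np.random.default_rng([config_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


class _BreakendPlacer:
    """Places breakend positions keeping pairwise separation per chromosome."""

    def __init__(self, chrom_lengths: Mapping[str, int], min_sep: int) -> None:
        self.lengths = dict(chrom_lengths)
        self.min_sep = min_sep
        self.used: dict[str, list[int]] = {c: [] for c in self.lengths}

    def place(self, rng: np.random.Generator, chrom: str, tries: int = 200) -> int:
        length = self.lengths[chrom]
        used = self.used[chrom]
        for _ in range(tries):
            pos = int(rng.integers(1, length + 1))
            if all(abs(pos - u) >= self.min_sep for u in used):
                used.append(pos)
                return pos
        raise PackingError(
            f"cannot place breakend on {chrom} (length {length}) with "
            f"min separation {self.min_sep} after {tries} tries"
        )

    def occupied(self) -> dict[str, list[int]]:
        return {c: sorted(v) for c, v in self.used.items()}


def _pick_chrom(rng: np.random.Generator, lengths: Mapping[str, int]) -> str:
    chroms = sorted(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    return chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]


def generate_truth(config: SimConfig) -> tuple[list[BreakendPair], list[CNSegment]]:
    """Draw the shared truth: SV pairs and a genome-covering CN profile.

    Fully reproducible from ``config.seed``.  Raises :class:`PackingError`
    when the spacing constraint cannot be satisfied.
    """
    rng = _stream(config.seed, "truth")
    rank = config.rank()
    placer = _BreakendPlacer(config.chrom_lengths, config.min_separation)

    types = sorted(config.sv_type_mix, key=lambda t: t.value)
    probs = np.array([config.sv_type_mix[t] for t in types])
    svs: list[BreakendPair] = []
    for _ in range(config.n_sv):
        svtype = types[int(rng.choice(len(types), p=probs))]
        if svtype is SVType.TRA:
            c1 = _pick_chrom(rng, config.chrom_lengths)
            others = {c: l for c, l in config.chrom_lengths.items() if c != c1}
            c2 = _pick_chrom(rng, others)
            o1 = Orientation.LEFT_RETAINED if rng.random() < 0.5 else Orientation.RIGHT_RETAINED
            o2 = Orientation.LEFT_RETAINED if rng.random() < 0.5 else Orientation.RIGHT_RETAINED
            a = Breakend(c1, placer.place(rng, c1), o1)
            b = Breakend(c2, placer.place(rng, c2), o2)
        else:
            chrom = _pick_chrom(rng, config.chrom_lengths)
            p1 = placer.place(rng, chrom)
            p2 = placer.place(rng, chrom)
            lo, hi = min(p1, p2), max(p1, p2)
            o1, o2 = _ORIENTS[svtype]
            if svtype is SVType.INV and rng.random() < 0.5:
                o1 = o2 = Orientation.RIGHT_RETAINED
            a, b = Breakend(chrom, lo, o1), Breakend(chrom, hi, o2)
        svs.append(canonicalize(BreakendPair(a, b, svtype, caller="truth"), rank))

    cn_truth: list[CNSegment] = []
    total_len = sum(config.chrom_lengths.values())
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_seg = max(1, round(config.n_cn_segments * length / total_len))
        if n_seg > length:
            raise PackingError(f"{n_seg} CN segments do not fit on {chrom} (length {length})")
        inner = np.array([], dtype=int)
        if n_seg > 1:
            # draw distinct interior boundaries; collisions are vanishingly
            # rare on realistic genomes but handled by redrawing
            while len(inner) < n_seg - 1:
                draw = rng.integers(2, length + 1, size=n_seg - 1 - len(inner))
                inner = np.unique(np.concatenate([inner, draw]))
            inner = np.sort(inner)
        bounds = [1, *inner.tolist(), length + 1]
        values = rng.choice(np.asarray(config.cn_values, dtype=float), size=n_seg)
        for (lo, hi), cn in zip(zip(bounds, bounds[1:]), values):
            cn_truth.append(CNSegment(chrom, lo, hi - 1, float(cn), caller="truth"))
    return svs, cn_truth


def _jitter_pair(
    pair: BreakendPair, rng: np.random.Generator, sd: float, caller: str, rank: ChromRank
) -> BreakendPair:
    da, db = (int(round(x)) for x in rng.normal(0.0, sd, size=2)) if sd > 0 else (0, 0)
    a = Breakend(pair.a.chrom, max(1, pair.a.pos + da), pair.a.orient)
    b = Breakend(pair.b.chrom, max(1, pair.b.pos + db), pair.b.orient)
    return canonicalize(BreakendPair(a, b, pair.svtype, caller=caller), rank)


def _random_sv_away_from(
    rng: np.random.Generator,
    config: SimConfig,
    placer: _BreakendPlacer,
    caller: str,
) -> BreakendPair:
    types = [t for t in sorted(config.sv_type_mix, key=lambda t: t.value) if t is not SVType.TRA]
    if not types:
        types = [SVType.DEL]
    svtype = types[int(rng.integers(len(types)))]
    chrom = _pick_chrom(rng, config.chrom_lengths)
    p1 = placer.place(rng, chrom)
    p2 = placer.place(rng, chrom)
    o1, o2 = _ORIENTS[svtype]
    a = Breakend(chrom, min(p1, p2), o1)
    b = Breakend(chrom, max(p1, p2), o2)
    return canonicalize(BreakendPair(a, b, svtype, caller=caller), config.rank())


def simulate_caller(
    truth_svs: Sequence[BreakendPair],
    truth_cn: Sequence[CNSegment],
    profile: CallerProfile,
    config: SimConfig,
    fp_pool: Sequence[BreakendPair] = (),
) -> tuple[list[BreakendPair], list[CNSegment]]:
    """One caller's noisy view of the truth.

    Truth SVs are dropped with probability ``fn_rate``; survivors get
    independent rounded-Gaussian jitter per breakend.  ``fp_pool`` supplies
    this caller's false positives, pre-placed away from truth.  CN boundaries
    are jittered (interior boundaries only, order-preserving) and values
    perturbed, keeping the profile disjoint and genome-covering.
    """
    rank = config.rank()
    rng_sv = _stream(config.seed, f"sv:{profile.name}")
    rng_cn = _stream(config.seed, f"cn:{profile.name}")

    calls: list[BreakendPair] = []
    for pair in truth_svs:
        if rng_sv.random() < profile.fn_rate:
            continue
        calls.append(_jitter_pair(pair, rng_sv, profile.jitter_sd, profile.name, rank))
    calls.extend(
        BreakendPair(fp.a, fp.b, fp.svtype, caller=profile.name, qual=fp.qual)
        for fp in fp_pool
    )

    segs: list[CNSegment] = []
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in truth_cn:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in sorted(by_chrom):
        truth_segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        length = config.chrom_lengths[chrom]
        bounds = [s.start for s in truth_segs] + [truth_segs[-1].end + 1]
        jittered = [bounds[0]]
        for i in range(1, len(bounds) - 1):
            b = bounds[i] + int(round(rng_cn.normal(0.0, profile.cn_boundary_jitter_sd)))
            # keep boundaries strictly increasing so segments stay disjoint
            b = min(max(b, jittered[-1] + 1), length + 1 - (len(bounds) - 1 - i))
            jittered.append(b)
        jittered.append(length + 1)
        for seg, lo, hi in zip(truth_segs, jittered, jittered[1:]):
            cn = max(0.0, seg.cn + float(rng_cn.normal(0.0, profile.cn_value_noise_sd)))
            segs.append(CNSegment(chrom, lo, hi - 1, cn, caller=profile.name))
    return calls, segs


def simulate_all(
    config: SimConfig,
) -> tuple[
    list[BreakendPair],
    list[CNSegment],
    dict[str, list[BreakendPair]],
    dict[str, list[CNSegment]],
]:
    """Generate truth and every caller's outputs.

    Returns ``(truth_svs, truth_cn, sv_calls_by_caller, cn_by_caller)``.
    False positives are placed on a shared spacing grid with the truth
    breakends, so no false positive can fall within two windows of any truth
    breakend or of another false positive; when ``shared_fp_callers > 1``
    each false positive is copied into that many consecutive callers.
    """
    truth_svs, truth_cn = generate_truth(config)
    placer = _BreakendPlacer(config.chrom_lengths, config.min_separation)
    for sv in truth_svs:
        placer.used[sv.a.chrom].append(sv.a.pos)
        placer.used[sv.b.chrom].append(sv.b.pos)

    rng_fp = _stream(config.seed, "fp")
    fp_pools: dict[str, list[BreakendPair]] = {p.name: [] for p in config.callers}
    names = [p.name for p in config.callers]
    for i, profile in enumerate(config.callers):
        n_fp = int(rng_fp.poisson(profile.fp_rate * config.n_sv))
        for _ in range(n_fp):
            fp = _random_sv_away_from(rng_fp, config, placer, profile.name)
            for k in range(min(config.shared_fp_callers, len(names))):
                fp_pools[names[(i + k) % len(names)]].append(fp)

    sv_by_caller: dict[str, list[BreakendPair]] = {}
    cn_by_caller: dict[str, list[CNSegment]] = {}
    for profile in config.callers:
        calls, segs = simulate_caller(
            truth_svs, truth_cn, profile, config, fp_pool=fp_pools[profile.name]
        )
        sv_by_caller[profile.name] = calls
        cn_by_caller[profile.name] = segs
    return truth_svs, truth_cn, sv_by_caller, cn_by_caller


@dataclass(frozen=True)
class EvalMetrics:
    """Recovery metrics of a consensus set against truth."""

    n_truth: int
    n_consensus: int
    true_positives: int
    precision: float
    recall: float
    f1: float
    mean_abs_offset: float  # mean |breakend offset| in bp over matched pairs


def evaluate(
    consensus: Sequence[ConsensusSV],
    truth: Sequence[BreakendPair],
    match_window: int = DEFAULT_WINDOW,
) -> EvalMetrics:
    """Greedy one-to-one matching of consensus calls to truth SVs.

    A candidate match requires identical chromosomes and orientations and
    both breakend offsets within ``match_window``; candidates are taken
    smallest-total-offset first.  Precision on an empty consensus set is 1.0
    by convention (no false claims were made), and likewise recall on empty
    truth.
    """
    candidates: list[tuple[int, int, int]] = []
    for ci, cons in enumerate(consensus):
        for ti, t in enumerate(truth):
            if cons.pair.key() != t.key():
                continue
            da, db = abs(cons.pair.a.pos - t.a.pos), abs(cons.pair.b.pos - t.b.pos)
            if da <= match_window and db <= match_window:
                candidates.append((da + db, ci, ti))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    offsets: list[int] = []
    for cost, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        offsets.append(cost)
    tp = len(offsets)
    precision = tp / len(consensus) if consensus else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    mean_abs = (sum(offsets) / (2 * tp)) if tp else 0.0
    return EvalMetrics(
        n_truth=len(truth),
        n_consensus=len(consensus),
        true_positives=tp,
        precision=precision,
        recall=recall,
        f1=f1,
        mean_abs_offset=mean_abs,
    )
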