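# Methods

This note documents the procedures `svmeld` implements, the parameters that
matter, the design choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Breakend representation

Every SV call is normalized to a pair of oriented breakends. The orientation
flag states which flank survives in the derivative chromosome: `+` keeps the
sequence 5′ of the breakpoint, `−` the 3′ side. This is the BEDPE strand
convention, chosen for interoperability with BEDPE consumers: DEL = +/−,
DUP = −/+, INV = +/+ or −/−, interchromosomal = TRA. VCF breakend bracket
notation maps onto it exactly (`t[p[` → +/−, `t]p]` → +/+, `]p]t` → −/+,
`[p[t` → −/−), and the mapping is involutive: a pair rendered as its two
mated BND ALT alleles parses back to the identical pair.

Pairs are stored in canonical order — (chromosome rank, position, orientation)
of the first breakend ≤ the second, with orientations travelling with their
breakends — and the SV type is *recomputed from geometry* after any
reordering rather than voted from caller labels, because labels disagree
across callers while the standardized geometry does not. Insertions are the
exception: a single-locus insertion has no second-breakend geometry, so the
caller-declared INS type is carried through and INS calls are never pooled
with orientation-typed calls.

Chromosome naming is prefix-insensitive (`chr1` ≡ `1`); mitochondrial and alt
contigs are rejected by default and dropped with a note by the readers, since
a call on an unrankable contig cannot be ordered or merged meaningfully.
Internal coordinates are 1-based inclusive; BEDPE (0-based half-open) is
converted exactly at the I/O boundary, using start+1 of each BEDPE interval
as the breakend position.

Single-breakend records (e.g. from assembly-based callers) carry no usable
second anchor for relatedness and are dropped, counted in the reader's parse
report (`parsed + dropped + errored = total` always holds).

## Consensus SVs

Two canonical calls are *related* iff they agree in both chromosomes and both
orientations and each breakend's positions differ by at most the window
(default **150 bp**, inclusive — "within" is read as ≤). The window applies
per breakend, not to a combined distance. Related calls are aggregated as
**single-linkage connected components**: the simplest faithful reading of
"aggregate related calls", accepting that a chain of calls can span more than
one window. The brute-force oracle tests pin exactly this semantics, and the
clustering implementation (geometry-keyed grouping plus a sorted sweep with
union–find) is verified against an independent O(n²) all-pairs brute force on
random instances.

Each cluster collapses to one consensus SV:

* **Position** — the per-breakend statistical mode of member positions. When
  several positions tie for the highest count (with continuous positional
  noise *all* members are usually distinct, every value ties at count one,
  and the mode is degenerate), the tie resolves to the tied value closest to
  the members' arithmetic mean, then to the smaller position. Taking the
  smallest tied value outright would systematically return the *minimum*
  member — an extreme-value estimator whose expected error grows with the
  number of callers — whereas the nearest-to-mean rule stays a deterministic
  choice of an observed member position with roughly half the error at
  realistic jitter. For a two-member tie such as {1000, 1010} both rules
  agree (1000).
* **Confidence** — the number of *distinct* supporting callers; duplicate
  calls from one caller count once toward confidence but remain members.
* **Type** — reclassified from the shared geometry.

Consensus SVs with confidence below `min_support` (default **3**) are
discarded; the output is sorted by (chromosome rank, position) and is
invariant to the order of callers and of calls within callers, byte-for-byte
in the writers.

## Consensus copy number

Per-caller CN segments must be disjoint within a caller (violations are an
input error, not silently fixed). The pipeline:

1. **Expand** each segment by `pad` (default **5000 bp**) both ways, clamped
   to `[1, chromosome length]`. Where two expanded segments of one caller
   overlap, the overlap `[s, e]` is divided equally at `mid = ⌊(s+e)/2⌋`
   (left segment keeps through `mid`). Away from chromosome ends this is
   identical to assigning every base to the nearer original segment; the
   integer floor breaks the even/odd ambiguity deterministically.
2. **Partition** every chromosome at the union of all callers' segment starts
   and end+1 positions (plus 1 and chromosome end when lengths are known), so
   each resulting interval has a constant CN per covering caller.
3. **Weight**: the interval's consensus CN is the arithmetic mean of the
   covering callers' values. Because the partition cuts at every caller
   boundary this equals the genome-wide per-base average over covering
   callers — the normative contract, enforced by a per-base oracle on random
   genomes. Intervals covered by no caller take `default_cn` (**2**, the
   diploid baseline) rather than being omitted.
4. **Concordance** is computed *before* smoothing (smoothing discards the
   per-caller contributions): per caller, the length-weighted mean deviation
   from consensus (bias, sign retained) and the length-weighted standard
   deviation of that deviation (volatility). Min–max scaling across callers
   uses |bias| — the scaled value is a magnitude ranking — and maps everyone
   to 0 when all callers tie. A caller covering no bases is excluded with a
   logged note.
5. **Smooth**: adjacent intervals on one chromosome whose consensus CNs agree
   within `smooth_tol` (default **0.1** CN units) merge left-to-right to a
   fixpoint, with length-weighted mean CN. Each merge conserves Σ length×CN
   exactly; `n_callers` of a merged interval is the length-weighted mean
   rounded down. The tolerance-merge concretization of "smoothing" was an
   open design point; it is conservative, deterministic, and its mass
   conservation is a tested invariant.

## Purity and ploidy

When several purity/ploidy estimates are supplied, the Sequenza estimate is
preferred, then PURPLE, then any other source, deterministically. The reader
accepts any tab-separated summary whose header names a purity (or
cellularity) column and a ploidy column, which covers both tools' native
summaries.

## Synthetic data

The simulator emulates the error structure the merge has to tolerate: a
shared truth observed by each caller with (i) rounded-Gaussian positional
jitter on each breakend, (ii) per-SV false-negative dropout, (iii)
caller-private false positives (Poisson, `fp_rate` expected per truth SV)
and (iv) CN boundary jitter and value noise. Default study conditions: one
10 Mb chromosome, 100 truth SVs (DEL/DUP/INV mix 0.4/0.3/0.3), 20 CN
segments with integer states 0–4, six callers with `jitter_sd` 20 bp,
`fn_rate` 0.1, `fp_rate` 0.2, CN boundary jitter 500 bp and value noise 0.1.
Translocations require at least two chromosomes, so the single-chromosome
default gives them zero weight; configs with ≥ 2 chromosomes can request
them.

Truth breakends keep pairwise separation > 2×window so cluster membership is
unambiguous, and false positives are placed on the same spacing grid —
private FPs therefore cannot reach the support threshold, which makes the
min-support filter's effect provable (a `shared_fp_callers` flag plants each
FP in k callers to study the filter's failure mode). All randomness derives
from one root seed through named substreams (`truth`, `fp`, per-caller SV,
per-caller CN) keyed by a CRC of the stream name, so adding a caller does not
perturb the others.

What passing these tests shows: the merge logic is exact on its contracts
and recovers a planted truth under jitter/FP/FN noise. What it does not
show: performance on real tumor data, where caller errors are correlated,
breakpoint uncertainty is caller- and context-dependent, SV sizes follow
heavy-tailed distributions, and coverage artifacts cluster — none of which
the generator emulates.

## Problem sizes and numerics

The validation suite uses instances of ≤ 200 SV calls against an O(n²)
oracle, random genomes ≤ 100 kb for per-base CN equivalence, and 20
simulation replicates of 100 truth SVs for recovery statistics — sizes at
which the oracles are exact and the whole suite runs in seconds. Smoothing
conservation is asserted to 1e-9 absolute (relative to total mass); oracle
equivalence to 1e-12; everything else is exact integer/rational arithmetic.

Degenerate inputs: empty caller sets produce a whole-genome default profile
and an empty concordance table; an empty cluster is an error; two breakends
at the identical locus are ordered by orientation to keep canonical order
total; `window = 0` and `smooth_tol = 0` are valid boundary settings (merge
only exact agreement).
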