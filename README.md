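# svmeld

Multi-caller consensus calling for somatic structural variants (SVs) and
copy-number (CN) profiles in tumor genomes.

Individual SV and CNV callers disagree substantially on real tumor data; calls
supported by several independent algorithms have markedly fewer false
positives. `svmeld` takes the per-caller output files (VCF with breakend or
symbolic SV records, BEDPE, SEG/BED-like CN segment tables), standardizes them
into a common breakend representation, and produces:

* **consensus SVs** — clusters of calls that agree in chromosomes, breakend
  orientations, and position within a window, collapsed to a single call with
  a caller-support confidence level;
* a **genome-wide consensus CN profile** with per-caller concordance scores;
* the selected **tumor purity/ploidy** estimate;
* tab-separated **track files** ready for circos-style plotting.

It is caller-agnostic: anything that can be expressed as oriented breakends or
CN segments can be merged. A seeded simulator of multi-caller outputs with a
known truth set is included for end-to-end validation.

## The model

An SV call is a pair of oriented breakends `(c₁, p₁, o₁)–(c₂, p₂, o₂)` with
`o ∈ {+, −}`: `+` means the sequence 5′ of the breakpoint is retained in the
derivative chromosome, `−` the 3′ side (the BEDPE strand convention, so
DEL = +/−, DUP = −/+, INV = +/+ or −/−, TRA = interchromosomal). Two calls are
*related* when they share both chromosomes and both orientations and each
breakend differs by at most *w* = 150 bp (inclusive). Related calls are
aggregated into single-linkage connected components; each component collapses
to the consensus SV at the per-breakend **mode position**, with confidence =
number of distinct supporting callers. Consensus SVs below a minimum support
(default 3 callers) are dropped.

For copy number, each caller's segment expands 5000 bp up- and downstream
(overlaps between a caller's expanded segments are divided equally at the
midpoint); the union of all callers' boundaries partitions the genome into
consensus alteration sites on which every caller is constant; the consensus CN
of a site is the mean of the covering callers' values — equivalently the
per-base average — with CN = 2 where nothing is called. Each caller *t* is
then scored over the sites it covers, with `d_i = cn_{t,i} − consensus_i` and
length weights `w_i`:

    bias_t       = Σ wᵢ dᵢ / Σ wᵢ
    volatility_t = sqrt( Σ wᵢ (dᵢ − bias_t)² / Σ wᵢ )

both min–max scaled to [0, 1] across callers. Finally adjacent sites whose
consensus CN differs by ≤ 0.1 are merged (length-weighted mean), yielding the
smoothed profile. When both Sequenza and PURPLE purity/ploidy estimates are
available, Sequenza's is preferred.

## Worked example

Simulate four noisy callers observing 8 true SVs on a 10 Mb chromosome, then
merge:

```
$ svmeld simulate --seed 7 --n-sv 8 --callers 4 --jitter-sd 15 \
      --fp-rate 0.3 --fn-rate 0.1 --outdir demo
$ svmeld merge-sv --sv caller1=demo/caller1.sv.bedpe --sv caller2=demo/caller2.sv.bedpe \
      --sv caller3=demo/caller3.sv.bedpe --sv caller4=demo/caller4.sv.bedpe \
      --min-support 3 --out demo/consensus.bedpe
INFO caller1: 11 parsed, 0 dropped, 0 errored
INFO caller2: 10 parsed, 0 dropped, 0 errored
INFO caller3: 7 parsed, 0 dropped, 0 errored
INFO caller4: 9 parsed, 0 dropped, 0 errored
INFO wrote 8 consensus SVs to demo/consensus.bedpe
```

The callers reported 7–11 calls each (missed truth SVs plus private false
positives), yet exactly the 8 true SVs survive the 3-caller support filter:

```
#chrom1 start1  end1    chrom2  start2  end2    name score strand1 strand2 svtype supp supp_callers
chr1    119512  119513  chr1    5164173 5164174 SV1  .     +       -       DEL    4    caller1,caller2,caller3,caller4
chr1    380967  380968  chr1    4291993 4291994 SV2  .     -       -       INV    3    caller2,caller3,caller4
...
```

`supp` is the confidence level (distinct supporting callers); the private
false positives can never reach support 3 and are gone. Merging the CN tables
likewise:

```
$ svmeld merge-cnv --seg caller1=demo/caller1.cn.tsv ... --out demo/cn.tsv \
      --concordance demo/conc.tsv
INFO wrote 61 consensus intervals to demo/cn.tsv
$ head -3 demo/conc.tsv
#caller   bias        volatility  bias_scaled  volatility_scaled
caller1   0.0369446   0.0879135   1            1
caller2   -0.00715625 0.0842287   0.0606467    0.886937
```

caller1 reads slightly high (bias +0.037 CN units) and is the least
consistent of the four (scaled volatility 1); caller4 is the least biased.

The same operations are available as library functions
(`svmeld.merge_svs`, `svmeld.consensus_cn_pipeline`, …) on plain dataclasses.

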