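"""Consensus copy number: expansion, partition, weighting, smoothing, scores."""

import math

import numpy as np
import pytest

from svmeld.cn import (
    CNParams,
    CNSegment,
    concordance,
    consensus_cn_pipeline,
    expand_and_divide,
    partition,
    smooth,
    weighted_consensus,
)

# ------------------------------------------------------------- per-base oracle


def per_base_consensus(expanded_by_caller, chrom_lengths, default_cn=2.0):
    """Base-wise mean of covering callers over already-disjoint caller tracks."""
    out = {}
    for chrom, length in chrom_lengths.items():
        total = np.zeros(length)
        count = np.zeros(length, dtype=int)
        for segs in expanded_by_caller.values():
            for s in segs:
                if s.chrom != chrom:
                    continue
                total[s.start - 1 : s.end] += s.cn
                count[s.start - 1 : s.end] += 1
        cn = np.where(count > 0, total / np.maximum(count, 1), default_cn)
        out[chrom] = cn
    return out


def intervals_to_per_base(intervals, chrom_lengths):
    out = {c: np.full(l, np.nan) for c, l in chrom_lengths.items()}
    for iv in intervals:
        out[iv.chrom][iv.start - 1 : iv.end] = iv.cn
    return out


def random_segments(rng, chrom, length, n_segs, caller):
    """Disjoint raw segments with random gaps and integer CN states."""
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_segs, replace=False))
    segs = []
    for i in range(0, len(cuts) - 1, 2):
        segs.append(
            CNSegment(chrom, int(cuts[i]), int(cuts[i + 1]), float(rng.integers(0, 6)), caller)
        )
    return segs


# ---------------------------------------------------------- expand_and_divide


def test_expansion_arithmetic():
    (seg,) = expand_and_divide([CNSegment("chr1", 10_001, 20_000, 3.0, "a")], pad=5000)
    assert (seg.start, seg.end, seg.cn) == (5_001, 25_000, 3.0)


def test_expansion_overlap_splits_at_midpoint():
    segs = expand_and_divide(
        [CNSegment("chr1", 1, 10_000, 3.0, "a"), CNSegment("chr1", 12_000, 20_000, 1.0, "a")],
        pad=5000,
    )
    assert [(s.start, s.end) for s in segs] == [(1, 11_000), (11_001, 25_000)]
    assert [s.cn for s in segs] == [3.0, 1.0]


def test_expansion_clamps_to_chromosome():
    (seg,) = expand_and_divide(
        [CNSegment("chr1", 3000, 4000, 2.0, "a")], pad=5000, chrom_lengths={"chr1": 6000}
    )
    assert (seg.start, seg.end) == (1, 6000)


def test_expansion_rejects_overlapping_raw_segments():
    with pytest.raises(ValueError, match="overlap"):
        expand_and_divide(
            [CNSegment("chr1", 1, 5000, 2.0, "a"), CNSegment("chr1", 4000, 8000, 2.0, "a")],
            pad=0,
        )


def test_division_assigns_each_base_to_nearer_original_segment():
    """Per-base oracle for the equal-division rule, away from chromosome ends."""
    rng = np.random.default_rng(11)
    pad = 500
    for _ in range(20):
        s1 = int(rng.integers(2000, 4000))
        e1 = s1 + int(rng.integers(1, 800))
        s2 = e1 + int(rng.integers(1, 2 * pad))  # gap small enough to overlap
        e2 = s2 + int(rng.integers(1, 800))
        raw = [CNSegment("chr1", s1, e1, 3.0, "a"), CNSegment("chr1", s2, e2, 1.0, "a")]
        out = expand_and_divide(raw, pad=pad)
        assert out[0].end + 1 == out[1].start
        for base in range(max(1, s1 - pad), e2 + pad + 1):
            owner = out[0] if base <= out[0].end else out[1]
            d1 = max(s1 - base, base - e1, 0)
            d2 = max(s2 - base, base - e2, 0)
            expected = raw[0] if d1 < d2 or (d1 == d2 and base <= out[0].end) else raw[1]
            if d1 != d2:
                assert owner.cn == expected.cn, f"base {base}"


def test_expansion_preserves_covered_union():
    rng = np.random.default_rng(5)
    length = 50_000
    segs = random_segments(rng, "chr1", length, 6, "a")
    out = expand_and_divide(segs, pad=3000, chrom_lengths={"chr1": length})
    covered_raw = np.zeros(length, dtype=bool)
    covered_out = np.zeros(length, dtype=bool)
    for s in segs:
        covered_raw[max(1, s.start - 3000) - 1 : min(length, s.end + 3000)] = True
    for s in out:
        covered_out[s.start - 1 : s.end] = True
        assert s.start <= s.end
    assert np.array_equal(covered_raw, covered_out)


def test_increasing_pad_never_decreases_coverage():
    rng = np.random.default_rng(9)
    segs = random_segments(rng, "chr1", 50_000, 5, "a")
    prev = 0
    for pad in (0, 1000, 5000, 20_000):
        out = expand_and_divide(segs, pad=pad, chrom_lengths={"chr1": 50_000})
        cov = sum(s.end - s.start + 1 for s in out)
        assert cov >= prev
        prev = cov


# ------------------------------------------------- partition + weighted mean


def test_partition_cuts_at_all_boundaries():
    expanded = {
        "A": [CNSegment("chr1", 1, 10_000, 4.0, "A")],
        "B": [CNSegment("chr1", 5_001, 10_000, 2.0, "B")],
    }
    ivs = partition(expanded)
    assert [(iv.start, iv.end, dict(iv.contributions)) for iv in ivs] == [
        (1, 5_000, {"A": 4.0}),
        (5_001, 10_000, {"A": 4.0, "B": 2.0}),
    ]


def test_partition_single_caller_is_identity():
    segs = [CNSegment("chr1", 10, 20, 1.0, "A"), CNSegment("chr1", 50, 80, 3.0, "A")]
    ivs = partition({"A": segs})
    covered = [(iv.start, iv.end) for iv in ivs if iv.contributions]
    assert covered == [(10, 20), (50, 80)]


def test_weighted_mean_and_default():
    expanded = {
        "A": [CNSegment("chr1", 1, 10_000, 4.0, "A")],
        "B": [CNSegment("chr1", 5_001, 10_000, 2.0, "B")],
    }
    ivs = weighted_consensus(partition(expanded, {"chr1": 12_000}), CNParams(default_cn=2.0))
    by_span = {(iv.start, iv.end): iv for iv in ivs}
    assert by_span[(1, 5_000)].cn == 4.0
    assert by_span[(5_001, 10_000)].cn == 3.0
    assert by_span[(10_001, 12_000)].cn == 2.0 and by_span[(10_001, 12_000)].n_callers == 0


def test_consensus_equals_per_base_oracle_on_random_genomes():
    rng = np.random.default_rng(42)
    for trial in range(10):
        length = int(rng.integers(20_000, 60_000))
        chrom_lengths = {"chr1": length}
        n_callers = int(rng.integers(1, 6))
        raw = {
            f"c{k}": random_segments(rng, "chr1", length, int(rng.integers(1, 6)), f"c{k}")
            for k in range(n_callers)
        }
        expanded = {c: expand_and_divide(s, 2000, chrom_lengths) for c, s in raw.items()}
        ivs = weighted_consensus(partition(expanded, chrom_lengths), CNParams())
        got = intervals_to_per_base(ivs, chrom_lengths)["chr1"]
        want = per_base_consensus(expanded, chrom_lengths)["chr1"]
        assert np.allclose(got, want, atol=1e-12), f"trial {trial}"


# ------------------------------------------------------------------ smoothing


def test_smoothing_merges_within_tolerance():
    ivs = weighted_consensus(
        partition({"A": [CNSegment("chr1", 1, 100, 3.0, "A"), CNSegment("chr1", 101, 200, 3.05, "A")]}),
        CNParams(),
    )
    (merged,) = smooth(ivs, smooth_tol=0.1)
    assert (merged.start, merged.end) == (1, 200)
    assert merged.cn == pytest.approx(3.025)


def test_smoothing_respects_tolerance_and_zero_tol_boundary():
    ivs = weighted_consensus(
        partition({"A": [CNSegment("chr1", 1, 100, 2.0, "A"), CNSegment("chr1", 101, 200, 4.0, "A")]}),
        CNParams(),
    )
    assert len(smooth(ivs, smooth_tol=0.1)) == 2
    equal = weighted_consensus(
        partition({"A": [CNSegment("chr1", 1, 100, 2.0, "A"), CNSegment("chr1", 101, 200, 2.0, "A")]}),
        CNParams(),
    )
    assert len(smooth(equal, smooth_tol=0.0)) == 1


def test_smoothing_conserves_length_weighted_mass():
    rng = np.random.default_rng(17)
    length = 40_000
    raw = {
        f"c{k}": random_segments(rng, "chr1", length, 5, f"c{k}") for k in range(3)
    }
    expanded = {c: expand_and_divide(s, 1500, {"chr1": length}) for c, s in raw.items()}
    ivs = weighted_consensus(partition(expanded, {"chr1": length}), CNParams())
    for tol in (0.0, 0.1, 0.5, 10.0):
        out = smooth(ivs, smooth_tol=tol)
        mass_in = sum(iv.length * iv.cn for iv in ivs)
        mass_out = sum(iv.length * iv.cn for iv in out)
        assert math.isclose(mass_in, mass_out, rel_tol=0, abs_tol=1e-9 * max(1.0, mass_in))


# ---------------------------------------------------------------- concordance


def test_single_caller_has_zero_bias_and_volatility():
    ivs = weighted_consensus(partition({"A": [CNSegment("chr1", 1, 1000, 3.0, "A")]}), CNParams())
    (score,) = concordance(ivs)
    assert score.bias == 0.0 and score.volatility == 0.0
    assert score.bias_scaled == 0.0 and score.volatility_scaled == 0.0


def test_two_caller_bias_is_signed_deviation():
    expanded = {
        "A": [CNSegment("chr1", 1, 10_000, 4.0, "A")],
        "B": [CNSegment("chr1", 1, 10_000, 2.0, "B")],
    }
    ivs = weighted_consensus(partition(expanded), CNParams())
    scores = {s.caller: s for s in concordance(ivs)}
    assert scores["A"].bias == pytest.approx(1.0)
    assert scores["B"].bias == pytest.approx(-1.0)
    assert scores["A"].volatility == 0.0 and scores["B"].volatility == 0.0


def test_scaled_scores_hit_min_max_endpoints():
    expanded = {
        "A": [CNSegment("chr1", 1, 9000, 2.0, "A")],
        "B": [CNSegment("chr1", 1, 9000, 3.0, "B")],
        "C": [CNSegment("chr1", 1, 9000, 7.0, "C")],
    }
    ivs = weighted_consensus(partition(expanded), CNParams())
    scores = sorted(concordance(ivs), key=lambda s: abs(s.bias))
    assert scores[0].bias_scaled == 0.0
    assert scores[-1].bias_scaled == 1.0
    assert 0.0 <= scores[1].bias_scaled <= 1.0


# ------------------------------------------------------------------- pipeline


def test_empty_input_gives_whole_genome_default():
    ivs, scores = consensus_cn_pipeline({}, CNParams(chrom_lengths={"chr1": 5000}, default_cn=2))
    assert scores == []
    assert [(iv.start, iv.end, iv.cn) for iv in ivs] == [(1, 5000, 2.0)]


def test_identical_callers_reproduce_input_with_zero_bias():
    segs = [CNSegment("chr1", 1, 3000, 3.0, ""), CNSegment("chr1", 3001, 8000, 1.0, "")]
    tables = {f"c{k}": [CNSegment(s.chrom, s.start, s.end, s.cn, f"c{k}") for s in segs] for k in range(5)}
    ivs, scores = consensus_cn_pipeline(tables, CNParams(pad=0, smooth_tol=0.0, chrom_lengths={"chr1": 8000}))
    assert [(iv.start, iv.end, iv.cn) for iv in ivs] == [(1, 3000, 3.0), (3001, 8000, 1.0)]
    assert all(s.bias == 0.0 and s.volatility == 0.0 for s in scores)


def test_pipeline_matches_per_base_oracle_end_to_end():
    rng = np.random.default_rng(23)
    length = 50_000
    chrom_lengths = {"chr1": length}
    raw = {f"c{k}": random_segments(rng, "chr1", length, 4, f"c{k}") for k in range(4)}
    params = CNParams(pad=2000, smooth_tol=0.0, chrom_lengths=chrom_lengths)
    expanded = {c: expand_and_divide(s, params.pad, chrom_lengths) for c, s in raw.items()}
    pre = weighted_consensus(partition(expanded, chrom_lengths), params)
    want = per_base_consensus(expanded, chrom_lengths)["chr1"]
    got = intervals_to_per_base(pre, chrom_lengths)["chr1"]
    assert np.allclose(got, want)
    # the full pipeline with tol 0 only merges exactly-equal neighbours: same profile
    ivs, _ = consensus_cn_pipeline(raw, params)
    smoothed = intervals_to_per_base(ivs, chrom_lengths)["chr1"]
    assert np.allclose(smoothed, want)
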