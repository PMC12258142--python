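import pytest

from svmeld.breakpoints import Breakend, BreakendPair, ChromRank, Orientation, SVType, canonicalize

L = Orientation.LEFT_RETAINED
R = Orientation.RIGHT_RETAINED


def make_pair(
    chrom1="chr1",
    pos1=1000,
    o1=L,
    chrom2=None,
    pos2=5000,
    o2=R,
    svtype=None,
    caller="callerA",
    rank=None,
):
    """Build a canonical BreakendPair with deletion-like defaults."""
    chrom2 = chrom2 or chrom1
    a = Breakend(chrom1, pos1, o1)
    b = Breakend(chrom2, pos2, o2)
    if svtype is None:
        from svmeld.breakpoints import classify_svtype

        svtype = classify_svtype(a, b)
    pair = BreakendPair(a, b, svtype, caller)
    return canonicalize(pair, rank or ChromRank())


@pytest.fixture
def rank():
    return ChromRank()


@pytest.fixture
def pair_factory():
    return make_pair
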