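import random

import pytest
from hypothesis import HealthCheck, settings

from soeprimer.design import enumerate_tetrads
from soeprimer.fixtures import FixtureSpec, generate_pair
from soeprimer.seqio import FragmentPair, FragmentRecord, reverse_complement

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Experimentally validated reference tetrad for an E. coli dnaQ x
# M. tuberculosis dnaN gene fusion (wet-lab confirmed SOE-PCR design).
GENE_5 = "ATGAGCACTGCAATTACACGCCAGATCGTT"
OVERLAP_3 = "GCCGCGTCCATTTATGCTCGCCAGAG"
OVERLAP_5 = "GGCGAGCATAAATGGACGCGGCTACG"
GENE_3 = "TCAGCCCGGCAACCGAACCGG"

# junction context implied by the reference tetrad: the last 15 nt of
# fragment 1 and the first 15 nt of fragment 2
JUNCTION_LEFT = reverse_complement(OVERLAP_3)[:15]    # CTCTGGCGAGCATAA
JUNCTION_RIGHT = OVERLAP_5[-15:]                      # ATGGACGCGGCTACG


@pytest.fixture(scope="session")
def demo_pair():
    """Default synthetic fragment pair (seed 42, 300 + 300 nt, GC 0.5)."""
    return generate_pair(FixtureSpec())


@pytest.fixture(scope="session")
def demo_ranked(demo_pair):
    """Full default enumeration of the demo pair, ranked (computed once)."""
    return enumerate_tetrads(demo_pair)


@pytest.fixture(scope="session")
def reference_pair():
    """Synthetic stand-in fragment pair for the reference fusion design.

    The real dnaQ/dnaN genes are not bundled; this pair reproduces exactly
    the terminal and junction sequence context that the reference tetrad's
    primers read (first 30 nt, last 21 nt, and 15 nt on each side of the
    junction), with seeded random filler in between.
    """
    rng = random.Random(11)
    filler = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    frag1 = GENE_5 + filler(75) + JUNCTION_LEFT
    frag2 = JUNCTION_RIGHT + filler(75) + reverse_complement(GENE_3)
    return FragmentPair(first=FragmentRecord("synthQ", frag1),
                        second=FragmentRecord("synthN", frag2))
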