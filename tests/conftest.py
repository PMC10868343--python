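import random

import pytest

from perfumes.fold import InternalEngine
from perfumes.motif_library import LoopMotif, MotifLibrary


@pytest.fixture(scope="session")
def engine():
    return InternalEngine()


@pytest.fixture()
def hairpin_motif():
    """Loop-4 hairpin with a GCAx consensus (closing pair included)."""
    return LoopMotif(
        motif_id="HL_T.1", loop_type="hairpin", strand_lengths=[4],
        closing_pairs=[(0, 5)], interactions=[(1, 4, "tWH")],
        instances=["CGCACG", "CGCAAG", "GGCACC", "UGCACA", "AGCACU"])


@pytest.fixture()
def internal_motif():
    """2x2 internal loop motif; loop strands chosen non-complementary so a
    planted loop cannot zip shut."""
    return LoopMotif(
        motif_id="IL_T.1", loop_type="internal", strand_lengths=[2, 2],
        closing_pairs=[(0, 7), (3, 4)], interactions=[(1, 6, "tHS")],
        instances=["CAAG&CACG", "CAAG&CAAG", "GAAC&GACC",
                   "CACG&CAAG", "UAAA&UACA"])


@pytest.fixture()
def tiny_library(hairpin_motif, internal_motif):
    return MotifLibrary([hairpin_motif, internal_motif], source="test")


def random_rna(n, rng):
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture()
def rng():
    return random.Random(20251001)
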