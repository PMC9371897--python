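import pytest

from nicklattice import DomainSpec, LatticeGraph, Nick, Strand
from nicklattice.builtin import build_design
from nicklattice.lattice import Duplex


@pytest.fixture(scope="session")
def j4_lattice():
    """The 6×6 4-arm-junction lattice (J4-I): 60 edges, 120 nicks."""
    return build_design("J4-I")


@pytest.fixture(scope="session")
def small_lattice():
    """The 2×2 calibration lattice: 4 edges, 8 nicks, one designed cycle."""
    return build_design("J4-I_2x2")


@pytest.fixture(scope="session")
def tube_lattice():
    """J4-I with complementary 3-nt east/west overhangs (sheet-to-tube)."""
    return build_design("fig4d_tube")


@pytest.fixture()
def toy_circle():
    """Two 10-nt strands closing into one 20-nt circle via two nicks, plus
    a 10-nt template strand that stays linear."""
    s1 = Strand("s1", (0, 0), "N", (DomainSpec("root", 5), DomainSpec("root", 5)))
    s2 = Strand("s2", (0, 0), "S", (DomainSpec("root", 5), DomainSpec("root", 5)))
    s3 = Strand("s3", (0, 0), "E", (DomainSpec("root", 10),))
    nicks = {
        "nA": Nick("nA", "s1", "s2", "s3", ("dA",), 10),
        "nB": Nick("nB", "s2", "s1", "s3", ("dA",), 10),
    }
    duplexes = {"dA": Duplex("dA", "intramotif", 10, "s1", "s3")}
    return LatticeGraph(
        {s.id: s for s in (s1, s2, s3)}, duplexes, nicks, {(0, 0): ("s1", "s2", "s3")}
    )
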