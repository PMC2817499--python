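import pytest

from rlgsim import GelModel, nipponbare_kasalath_fixture
from rlgsim.enzymes import Haplotype, MethylationState


@pytest.fixture(scope="session")
def gel():
    return GelModel()


@pytest.fixture(scope="session")
def fixture_seed1():
    """The packaged two-parent fixture, built once per session (seed 1)."""
    return nipponbare_kasalath_fixture(seed=1)


def single_locus_sequence():
    """A hand-laid sequence: NotI cut at 7, BamHI cut at 21, MspI cut at 31."""
    seq = "A" * 5 + "GCGGCCGC" + "A" * 7 + "GGATCC" + "A" * 4 + "CCGG" + "A" * 6
    assert len(seq) == 40
    return seq


@pytest.fixture
def single_locus_haplotype():
    return Haplotype(id="toy", sequences={"c1": single_locus_sequence()})


@pytest.fixture
def single_locus_blocked():
    """Same geometry with outer-C (blocking) methylation at the MspI site."""
    return Haplotype(
        id="toy_blocked",
        sequences={"c1": single_locus_sequence()},
        overlay={("c1", 30): MethylationState.OUTER_C},
    )
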