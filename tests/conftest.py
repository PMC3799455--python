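import pytest

from zfnscan import SiteDefinition
from zfnscan._dna import revcomp


@pytest.fixture(scope="session")
def ccr5_def() -> SiteDefinition:
    """The CCR5 ZFN pair: 12-bp cores, no flanks, 5/6-nt spacers."""
    return SiteDefinition("GTCATCCTCATC", "AAACTGCAAAAG", flank_width=0)


@pytest.fixture(scope="session")
def toy_def() -> SiteDefinition:
    """A tiny site definition for fast enumeration tests."""
    return SiteDefinition("ACG", "TGC", flank_width=0, spacer_lengths={2, 3})


def make_amplicon(core: str, pad_left: str, pad_right: str, spacer_start: int, spacer_end: int, name: str = "amp"):
    """Build an Amplicon with 20-bp primer ends taken from the reference."""
    from zfnscan import Amplicon

    ref = pad_left + core + pad_right
    return Amplicon(name, ref, ref[:20], revcomp(ref[-20:]), spacer_start, spacer_end)
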