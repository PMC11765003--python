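import hypothesis
import pytest

from niph.core import Genotype, SNVSite

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


def make_site(pos: int = 100, ref: str = "A", alt: str = "G", chrom: str = "11"):
    return SNVSite(chrom, pos, ref, alt)


@pytest.fixture
def site():
    return make_site()


@pytest.fixture
def trio_panel():
    """Three-site hand panel covering the informative / cut-off / unusable mix."""
    return [
        SNVSite("11", 100, "A", "G", "rs1"),
        SNVSite("11", 200, "C", "T", "rs2"),
        SNVSite("11", 300, "G", "A", "rs3"),
    ]


GT = Genotype  # shorthand for parametrized tables
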