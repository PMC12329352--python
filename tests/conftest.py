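import pytest

from hybridzone import study
from hybridzone.panel import find_diagnostic_sites
from hybridzone.seqio import SequenceRecord


@pytest.fixture(scope="session")
def tyr_refs():
    """Unambiguous Tyrosinase references engineered to carry the published
    diagnostic bases (two per taxon)."""
    return study.build_panel_references()


@pytest.fixture(scope="session")
def tyr_panel(tyr_refs):
    """Panel recovered from the engineered references."""
    return find_diagnostic_sites(tyr_refs)


@pytest.fixture(scope="session")
def f1_np_sequence(tyr_refs):
    """A Tyrosinase sequence of an F1 between the two species: two-base
    IUPAC codes at all eight species-diagnostic sites, homozygous at the
    subspecies sites (A at 13, G at 532, which the parents share)."""
    bases = list(tyr_refs["nigromaculatus"][0].bases)
    for pos, code in [
        (32, "Y"), (46, "R"), (74, "Y"), (81, "Y"),
        (219, "S"), (397, "W"), (636, "Y"), (708, "R"),
    ]:
        bases[pos - 1] = code
    return SequenceRecord("f1_np", "tyr", "".join(bases))
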