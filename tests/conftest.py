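import pytest
from hypothesis import settings

from slimamp import panel as pm
from slimamp import readsim

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_ref():
    return readsim.make_reference(6000, 0.5, 2)


@pytest.fixture(scope="session")
def small_panel(small_ref):
    """21-amplicon chain over a 4.9 kb interval (the large-exon regime)."""
    return pm.design_panel([("chrS", 500, 5400)], small_ref)


@pytest.fixture(scope="session")
def two_amp_ref():
    return readsim.make_reference(2500, 0.5, 11)


@pytest.fixture(scope="session")
def two_amp_panel(two_amp_ref):
    """Minimal overlapping pair: one junction, one shared tag."""
    panel = pm.design_panel([("chrS", 900, 1450)], two_amp_ref)
    assert len(panel.amplicons) == 2 and len(panel.junctions) == 1
    return panel


def amplicon_seqs(panel, reference):
    return {a.id: pm.amplicon_sequence(a, reference).upper()
            for a in panel.amplicons}


@pytest.fixture(scope="session")
def small_panel_seqs(small_panel, small_ref):
    return amplicon_seqs(small_panel, small_ref)


@pytest.fixture(scope="session")
def two_amp_seqs(two_amp_panel, two_amp_ref):
    return amplicon_seqs(two_amp_panel, two_amp_ref)
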