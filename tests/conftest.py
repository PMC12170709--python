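import pytest

from nogmap.molecules import named
from nogmap.network import default_network
from nogmap.pathways import FlowQuery, enumerate_pathways


@pytest.fixture(scope="session")
def net():
    """The headline network: default seeds, seven templates, 7-carbon cap."""
    return default_network()


@pytest.fixture(scope="session")
def nog_pathways(net):
    """All NOG hyperflows (F6P -> 3 AcP) with total flow <= 8."""
    q = FlowQuery(inflow={"F6P": 1}, outflow={"AcP": 3}, max_total=8)
    return enumerate_pathways(net, q)


@pytest.fixture(scope="session")
def mols():
    names = ["F6P", "G3P", "DHAP", "E4P", "Eu4P", "X5P", "R5P", "S7P",
             "FBP", "SBP", "XBP", "Gly2P", "AcP", "AcH", "HPA", "Pi", "H2O",
             "formaldehyde"]
    return {n: named(n) for n in names}
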