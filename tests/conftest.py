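import numpy as np
import pytest

from hgtsignal.acquisition_timing import GeneEvidence
from hgtsignal.phylo_core import parse_newick

MIDGE_TREE = (
    "(Bibio_marci:3,(Catotricha_subobsoleta:2.5,(Mayetiola_destructor:2,"
    "(Sitodiplosis_mosellana:1,Contarinia_nasturtii:1)90:1)95:0.5)99:0.5);"
)

# copy numbers on bona fide eukaryotic scaffolds, per gene and species
MIDGE_PRESENCE = {
    "aip56": {"Contarinia_nasturtii": 2, "Mayetiola_destructor": 1},
    "cdtB": {"Contarinia_nasturtii": 1},
    "lysozyme": {"Contarinia_nasturtii": 3, "Mayetiola_destructor": 1},
    "rhs": {"Mayetiola_destructor": 1, "Sitodiplosis_mosellana": 1},
    "sltxB": {"Contarinia_nasturtii": 2, "Sitodiplosis_mosellana": 7},
}

# micro-synteny findings and gene-tree monophyly calls per gene
MIDGE_EVIDENCE = {
    "sltxB": GeneEvidence({("Contarinia_nasturtii", "Sitodiplosis_mosellana")}),
    "lysozyme": GeneEvidence({("Mayetiola_destructor", "Contarinia_nasturtii")}),
    "rhs": GeneEvidence(set(), carriers_monophyletic=False),
    "aip56": GeneEvidence(set(), carriers_monophyletic=None),
}


@pytest.fixture
def species_tree():
    return parse_newick(MIDGE_TREE)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
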