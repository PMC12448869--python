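import numpy as np
import pytest

from glycoforge.notation import parse_iupac_condensed
from glycoforge.synthetic import build_glycan_coords
from glycoforge.templates import GLYCANS


def graphs_equal(a, b) -> bool:
    """Structural equality of two glycan graphs (canonical numbering)."""
    ga, gb = a.canonicalized(), b.canonicalized()
    if set(ga.residues) != set(gb.residues):
        return False
    for idx in ga.residues:
        ra, rb = ga.residues[idx], gb.residues[idx]
        if (ra.sugar_name, ra.absolute_config, ra.ring_form, ra.anomer,
                sorted(ra.modifications)) != \
           (rb.sugar_name, rb.absolute_config, rb.ring_form, rb.anomer,
                sorted(rb.modifications)):
            return False
    la = sorted((l.donor_index, l.acceptor_index, l.acceptor_position)
                for l in ga.linkages)
    lb = sorted((l.donor_index, l.acceptor_index, l.acceptor_position)
                for l in gb.linkages)
    return la == lb


@pytest.fixture(scope="session")
def g2_graph():
    return parse_iupac_condensed(GLYCANS["g2"])


@pytest.fixture(scope="session")
def m9_graph():
    return parse_iupac_condensed(GLYCANS["m9"])


@pytest.fixture(scope="session")
def lnnt_graph():
    return parse_iupac_condensed(GLYCANS["lnnt"])


@pytest.fixture(scope="session")
def lactose_model_and_graph():
    g = parse_iupac_condensed("Galb1-4Glc")
    return build_glycan_coords(g), g


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
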