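"""Topology model: residue/linkage invariants and canonical numbering."""

import pytest

from glycoforge.errors import TopologyError, UnsupportedSugarError
from glycoforge.graph import (AttachmentSpec, GlycanGraph, MonosaccharideResidue,
                              modification_slots)
from glycoforge.notation import parse_iupac_condensed


def res(name, anomer="beta", config=None, ring="pyranose", mods=()):
    from glycoforge.registry import REGISTRY
    cfg = config or REGISTRY[name].default_config
    return MonosaccharideResidue(name, cfg, ring, anomer, list(mods))


class TestAddResidue:
    def test_first_residue_gets_index_one(self):
        g = GlycanGraph()
        assert g.add_residue(res("Glc")) == 1
        assert g.root_index == 1

    def test_lnnt_built_residue_by_residue(self):
        g = GlycanGraph()
        i1 = g.add_residue(res("Glc"))
        i2 = g.add_residue(res("Gal"))
        i3 = g.add_residue(res("GlcNAc"))
        i4 = g.add_residue(res("Gal"))
        g.add_linkage(i2, i1, 4)
        g.add_linkage(i3, i2, 3)
        g.add_linkage(i4, i3, 4)
        assert len(g) == 4
        assert g.validate_graph() == []

    def test_unknown_sugar_rejected(self):
        with pytest.raises(UnsupportedSugarError):
            GlycanGraph().add_residue(
                MonosaccharideResidue("Frobnose", "D", "pyranose", "beta"))

    def test_modification_at_invalid_position_rejected(self):
        # aldoses have no substitutable position 1 (the anomeric hydroxyl)
        with pytest.raises(TopologyError):
            GlycanGraph().add_residue(res("Glc", mods=[(1, "sulfate")]))

    def test_valid_modification_accepted(self):
        g = GlycanGraph()
        g.add_residue(res("GlcNAc", mods=[(6, "sulfate")]))
        assert g.validate_graph() == []


class TestAddLinkage:
    def test_chitobiose_donor_anomeric_carbon(self):
        g = GlycanGraph()
        a = g.add_residue(res("GlcNAc"))
        b = g.add_residue(res("GlcNAc"))
        lk = g.add_linkage(b, a, 4)
        assert lk.donor_anomeric_carbon == "C1"

    def test_sialic_links_through_c2(self):
        g = GlycanGraph()
        gal = g.add_residue(res("Gal"))
        sia = g.add_residue(res("Neu5Ac", anomer="alpha"))
        lk = g.add_linkage(sia, gal, 6)
        assert lk.donor_anomeric_carbon == "C2"

    def test_occupied_position_rejected(self):
        g = GlycanGraph()
        a = g.add_residue(res("Glc"))
        b = g.add_residue(res("Gal"))
        c = g.add_residue(res("Gal"))
        g.add_linkage(b, a, 4)
        with pytest.raises(TopologyError):
            g.add_linkage(c, a, 4)

    def test_donor_reuse_rejected(self):
        g = GlycanGraph()
        a = g.add_residue(res("Glc"))
        b = g.add_residue(res("Gal"))
        c = g.add_residue(res("Man"))
        g.add_linkage(b, a, 4)
        with pytest.raises(TopologyError):
            g.add_linkage(b, c, 3)

    def test_cycle_rejected(self):
        g = GlycanGraph()
        a = g.add_residue(res("Glc"))
        b = g.add_residue(res("Gal"))
        g.add_linkage(b, a, 4)
        with pytest.raises(TopologyError):
            g.add_linkage(a, b, 3)


class TestNumbering:
    def test_g2_gal_residues_numbered_8_and_9(self, g2_graph):
        g = g2_graph.canonicalized()
        gals = sorted(i for i, r in g.residues.items() if r.sugar_name == "Gal")
        assert gals == [8, 9]

    def test_m9_three_arm_mannoses_numbered_4_6_9(self, m9_graph):
        g = m9_graph.canonicalized()
        # the 3-arm is the subtree rooted at the alpha-1,3 child of residue 3
        arm_root = next(lk.donor_index for lk in g.children(3)
                        if lk.acceptor_position == 3)
        members = {arm_root}
        for num in g.residue_numbering():
            lk = g.parent_linkage(num)
            if lk and lk.acceptor_index in members:
                members.add(num)
        assert members == {4, 6, 9}

    def test_linear_chain_identity_order(self, lnnt_graph):
        g = lnnt_graph.canonicalized()
        assert g.residue_numbering() == [1, 2, 3, 4]

    def test_numbering_is_permutation_with_root_first(self, g2_graph, m9_graph):
        for g in (g2_graph, m9_graph):
            order = g.residue_numbering()
            assert sorted(order) == sorted(g.residues)
            assert order[0] == g.root_index

    def test_adding_unlinked_residue_keeps_existing_numbering(self, g2_graph):
        import copy
        g = copy.deepcopy(g2_graph)
        before = g.residue_numbering()
        g.add_residue(res("Fuc", anomer="alpha"))
        assert g.residue_numbering() == before


class TestValidateGraph:
    def test_valid_g2_graph_is_clean(self, g2_graph):
        assert g2_graph.validate_graph() == []

    def test_orphan_residue_reported(self):
        g = GlycanGraph()
        a = g.add_residue(res("Glc"))
        b = g.add_residue(res("Gal"))
        g.add_linkage(b, a, 4)
        g.add_residue(res("Man"))  # never linked
        issues = g.validate_graph()
        assert len(issues) == 1
        assert issues[0]["category"] == "orphan-residue"

    def test_registry_contradiction_reported(self):
        # C1 recorded as the anomeric carbon of a sialic donor contradicts
        # the registry (ketoses link through C2)
        g = GlycanGraph()
        gal = g.add_residue(res("Gal"))
        sia = g.add_residue(res("Neu5Ac", anomer="alpha"))
        lk = g.add_linkage(sia, gal, 6)
        lk.donor_anomeric_carbon = "C1"
        issues = g.validate_graph()
        assert [i["category"] for i in issues] == ["anomeric-carbon-mismatch"]


def test_attachment_default_atoms():
    assert AttachmentSpec("N-linked", "A", 5).resolved_atom() == "ND2"
    assert AttachmentSpec("O-Ser", "A", 5).resolved_atom() == "OG"
    assert AttachmentSpec("O-Thr", "A", 5).resolved_atom() == "OG1"
    assert AttachmentSpec("O-Thr", "A", 5, "OD1").resolved_atom() == "OD1"


def test_modification_slots_follow_numbering():
    g = parse_iupac_condensed("Gal6Sb1-4GlcNAc6Sb1-3Galb1-4Glc")
    slots = modification_slots(g)
    assert [(s, h, p, m) for s, h, p, m in slots] == [
        (5, 3, 6, "sulfate"), (6, 4, 6, "sulfate")]
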