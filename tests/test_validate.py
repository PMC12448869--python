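"""Structure IO, bond inference, torsions, confidence, valence."""

import numpy as np
import pytest

from glycoforge.errors import StructureError
from glycoforge.notation import parse_iupac_condensed
from glycoforge.structure import StructureModel, read_structure, write_structure
from glycoforge.synthetic import build_glycan_coords
from glycoforge.validate import check_stereocenters, check_valence, glycosidic_torsions


class TestStructureIO:
    def test_mmcif_round_trip(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        back = read_structure(write_structure(model, "mmcif"), "mmcif")
        assert [(a.entity, a.residue_index, a.name) for a in back.atoms] == \
            [(a.entity, a.residue_index, a.name) for a in model.atoms]
        assert np.allclose(back.coords(), model.coords(), atol=1e-3)

    def test_pdb_round_trip_matches_mmcif(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        from_pdb = read_structure(write_structure(model, "pdb"), "pdb")
        from_cif = read_structure(write_structure(model, "mmcif"), "mmcif")
        assert np.allclose(from_pdb.coords(), from_cif.coords(), atol=1e-2)

    def test_single_residue_mmcif(self):
        g = parse_iupac_condensed("Glc")
        model = build_glycan_coords(g)
        back = read_structure(write_structure(model, "mmcif"), "mmcif")
        assert len(back.residues()) == 1
        assert len(back.atoms) == 12

    def test_unparseable_input_rejected(self):
        with pytest.raises(StructureError):
            read_structure("not a structure at all {", "mmcif")

    def test_confidence_survives_round_trip(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        back = read_structure(write_structure(model, "mmcif"), "mmcif")
        assert back.atoms[0].confidence == pytest.approx(90.0, abs=0.01)


class TestBondInference:
    def test_distant_atoms_not_bonded(self):
        m = StructureModel()
        m.add_atom("A", 1, "GLC", "C1", "C", [0, 0, 0])
        m.add_atom("A", 1, "GLC", "O1", "O", [5, 0, 0])
        assert m.infer_bonds() == []

    def test_bonded_pair_detected(self):
        m = StructureModel()
        m.add_atom("A", 1, "GLC", "C1", "C", [0, 0, 0])
        m.add_atom("A", 1, "GLC", "O1", "O", [1.43, 0, 0])
        assert m.infer_bonds() == [(0, 1)]

    def test_hydrogens_ignored(self):
        m = StructureModel()
        m.add_atom("A", 1, "GLC", "O1", "O", [0, 0, 0])
        m.add_atom("A", 1, "GLC", "HO1", "H", [0.97, 0, 0])
        assert m.infer_bonds() == []


class TestTorsions:
    def test_constructed_torsions_recovered(self):
        g = parse_iupac_condensed("Galb1-4Glc")
        model = build_glycan_coords(g, phi=60.0, psi=-120.0)
        t = glycosidic_torsions(model, g, 2)
        assert t["phi"] == pytest.approx(60.0, abs=1e-6)
        assert t["psi"] == pytest.approx(-120.0, abs=1e-6)

    def test_one_six_linkage_has_omega(self):
        g = parse_iupac_condensed("Galb1-6Glc")
        model = build_glycan_coords(g)
        assert "omega" in glycosidic_torsions(model, g, 2)

    def test_one_four_linkage_has_no_omega(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        assert "omega" not in glycosidic_torsions(model, g, 2)

    def test_root_residue_has_no_torsions(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        assert glycosidic_torsions(model, g, 1) == {}


class TestConfidence:
    def test_constant_confidence_mean(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        values, summary = model.extract_confidence(entity="NG")
        assert summary["mean"] == pytest.approx(90.0)

    def test_gradient_minimum_at_terminal_residue(self):
        m = StructureModel()
        for i, conf in ((1, 95.0), (2, 80.0), (3, 50.0)):
            m.add_atom("NG", i, "GLC", "C1", "C", [i * 5.0, 0, 0], conf)
        values, summary = m.extract_confidence(entity="NG")
        assert summary["min"] == 50.0

    def test_missing_entity_is_empty(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        values, summary = model.extract_confidence(entity="ZZ")
        assert values == [] and summary is None

    def test_absent_confidence_column(self):
        m = StructureModel()
        m.add_atom("NG", 1, "GLC", "C1", "C", [0, 0, 0], None)
        values, summary = m.extract_confidence()
        assert values == [] and summary is None


class TestValence:
    def test_clean_junction_has_no_flags(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        assert check_valence(model) == []

    def test_overcoordinated_oxygen_flagged(self):
        m = StructureModel()
        m.add_atom("A", 1, "GLC", "O4", "O", [0, 0, 0])
        for i, x in enumerate((1.43, -1.43, 0.0)):
            pos = [x, 0, 0] if x else [0, 1.43, 0]
            m.add_atom("A", 1, "GLC", f"C{i + 1}", "C", pos)
        flags = check_valence(m)
        assert [f["category"] for f in flags] == ["oxygen-overcoordination"]


class TestReport:
    def test_report_serializes_and_formats(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        report = check_stereocenters(model, g)
        doc = report.to_dict()
        assert doc["clean"] is True
        assert len(doc["residues"]) == 2
        table = report.format_table()
        assert "4C1" in table

    def test_missing_atom_is_indeterminate_not_fatal(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        import copy
        m = copy.deepcopy(model)
        m.atoms = [a for a in m.atoms if not (a.residue_index == 2 and a.name == "O2")]
        report = check_stereocenters(m, g)
        assert "C2" in report.residues[1].indeterminate_centers
        assert report.clean  # indeterminate is reported, not flagged
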