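"""AlphaFold 3 job assembly: bond emission, validation, serialization."""

import json
from pathlib import Path

import pytest

from glycoforge import af3
from glycoforge.af3 import (AF3Job, BondedAtomPair, add_glycan, attach_glycan,
                            build_job, emit_glycan_bonds, validate_job,
                            write_json)
from glycoforge.errors import JobError
from glycoforge.graph import AttachmentSpec, GlycanGraph, MonosaccharideResidue
from glycoforge.notation import parse_iupac_condensed
from glycoforge.templates import (EPO_N_SITES, GLYCANS, protein_sequence,
                                  template)

GOLDEN = Path(__file__).parent / "data" / "g2_golden.json"


class TestEmitGlycanBonds:
    def test_g2_contains_the_nag_bma_pair(self, g2_graph):
        pairs = emit_glycan_bonds(g2_graph, "NG")
        assert BondedAtomPair(("NG", 2, "O4"), ("NG", 3, "C1")) in pairs
        assert len(pairs) == 8  # 9 residues - 1

    def test_single_residue_glycan_has_no_bonds(self):
        g = GlycanGraph()
        g.add_residue(MonosaccharideResidue("Glc"))
        assert emit_glycan_bonds(g, "NG") == []

    def test_g2s2_bond_audit(self):
        g = parse_iupac_condensed(GLYCANS["g2s2"])
        pairs = emit_glycan_bonds(g, "NG")
        assert len(pairs) == 10
        donor_atoms = [p.second[2] for p in pairs]
        assert donor_atoms.count("C1") == 8 and donor_atoms.count("C2") == 2

    def test_pairs_ordered_acceptor_first(self, g2_graph):
        for pair in emit_glycan_bonds(g2_graph, "NG"):
            assert pair.first[2].startswith("O")
            assert pair.second[2].startswith("C")

    def test_modifications_add_one_pair_each(self):
        g = parse_iupac_condensed(GLYCANS["ks-core2"])
        n_mods = sum(len(r.modifications) for r in g.residues.values())
        pairs = emit_glycan_bonds(g, "OG1")
        assert len(pairs) == len(g) - 1 + n_mods


class TestAttachGlycan:
    def _job_with_glycan(self, glycan_text="GlcNAcb1-4GlcNAc"):
        job = AF3Job(name="t")
        job.entities.append(af3.EntitySpec(
            "A", "protein", sequence=protein_sequence("EPO_SYNTHETIC")))
        add_glycan(job, parse_iupac_condensed(glycan_text), "NG")
        return job

    def test_n_linked_defaults_to_nd2_and_root_c1(self):
        job = self._job_with_glycan()
        pair = attach_glycan(job, "NG", AttachmentSpec("N-linked", "A",
                                                       EPO_N_SITES[0]))
        assert pair.first == ("A", EPO_N_SITES[0], "ND2")
        assert pair.second == ("NG", 1, "C1")

    def test_o_thr_uses_og1(self):
        job = self._job_with_glycan("Galb1-3GalNAca")
        pair = attach_glycan(job, "NG", AttachmentSpec("O-Thr", "A", 10))
        assert pair.first[2] == "OG1"

    def test_free_attachment_is_an_error(self):
        job = self._job_with_glycan()
        with pytest.raises(JobError):
            attach_glycan(job, "NG", AttachmentSpec("free"))

    def test_residue_outside_sequence_rejected(self):
        job = self._job_with_glycan()
        with pytest.raises(JobError):
            attach_glycan(job, "NG", AttachmentSpec("N-linked", "A", 9999))


class TestValidateJob:
    def test_valid_template_is_clean(self):
        assert validate_job(template("g2")) == []

    def test_dangling_pair_detected(self):
        job = template("g2s2")
        job.bonded_atom_pairs.append(BondedAtomPair(("NG", 12, "O4"),
                                                    ("NG", 1, "C1")))
        issues = validate_job(job)
        assert any(i["category"] == "dangling-pair" for i in issues)

    def test_unedited_sialic_donor_flagged(self):
        # hand-build a job that uses plain SIA as a donor: missing-userCCD
        job = AF3Job(name="bad")
        g = parse_iupac_condensed("Neu5Aca2-6Galb1-4Glc")
        add_glycan(job, g, "NG")
        sia_index = job.entity("NG").ccd_codes.index("SIAX") + 1
        job.entity("NG").ccd_codes[sia_index - 1] = "SIA"
        issues = validate_job(job)
        assert any(i["category"] == "missing-userCCD" for i in issues)

    def test_duplicate_entity_id_flagged(self):
        job = template("g2")
        job.entities.append(af3.EntitySpec("NG", "ion", ccd_codes=["CA"]))
        assert any(i["category"] == "duplicate-id" for i in validate_job(job))

    def test_bad_atom_name_flagged(self):
        job = template("g2")
        job.bonded_atom_pairs.append(BondedAtomPair(("NG", 1, "O99"),
                                                    ("NG", 2, "C1")))
        assert any(i["category"] == "bad-atom-name" for i in validate_job(job))

    def test_linkage_at_position_the_acceptor_lacks_is_rejected(self):
        g = GlycanGraph()
        xyl = g.add_residue(MonosaccharideResidue("Xyl"))
        from glycoforge.errors import TopologyError
        gal = g.add_residue(MonosaccharideResidue("Gal"))
        with pytest.raises(TopologyError):
            g.add_linkage(gal, xyl, 6)  # xylose has no O6


class TestWriteJson:
    def test_serialization_is_deterministic(self):
        assert write_json(template("g2")) == write_json(template("g2"))

    def test_g2_matches_golden_fixture(self):
        assert write_json(template("g2")) == GOLDEN.read_text()

    def test_g2_ccdcodes_begin_nag_nag_bma(self):
        doc = json.loads(write_json(template("g2")))
        assert doc["sequences"][0]["ligand"]["ccdCodes"][:3] == [
            "NAG", "NAG", "BMA"]

    def test_dialect_and_version(self):
        doc = json.loads(write_json(template("g2")))
        assert doc["dialect"] == "alphafold3" and doc["version"] == 2

    def test_round_trip_preserves_fields(self):
        job = template("g2s2")
        doc = json.loads(write_json(job))
        assert doc["name"] == job.name
        assert doc["modelSeeds"] == job.model_seeds
        assert len(doc["bondedAtomPairs"]) == len(job.bonded_atom_pairs)
        assert "SIAX" in doc["userCCD"]


class TestBuildJob:
    def test_ligand_only_job_is_valid(self):
        job = build_job("free", glycans=[
            ("NG", parse_iupac_condensed("Galb1-4Glc"), None)])
        assert validate_job(job) == []
        assert len(job.entities) == 1

    def test_m9_man1a1_assembly(self):
        job = template("m9-man1a1")
        kinds = sorted(e.kind for e in job.entities)
        assert kinds == ["ion", "ligand-chain", "protein"]
        assert len(job.bonded_atom_pairs) == 10  # M9: 11 residues

    def test_dolpp_root_is_alpha_glcnac(self):
        job = template("dolpp-chitobiose-alg1")
        ng = job.entity("NG")
        assert ng.ccd_codes[0] == "NDG"  # alpha anomer of GlcNAc

    def test_aggregated_errors_on_invalid_parts(self):
        g = GlycanGraph()
        g.add_residue(MonosaccharideResidue("Glc"))
        g.add_residue(MonosaccharideResidue("Gal"))  # orphan
        with pytest.raises(JobError):
            build_job("bad", glycans=[("NG", g, None)])
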