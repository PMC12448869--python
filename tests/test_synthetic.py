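"""Synthetic builder: residues, assemblies, corruption semantics."""

import numpy as np
import pytest

from glycoforge.errors import GeometryError
from glycoforge.graph import GlycanGraph, MonosaccharideResidue
from glycoforge.notation import parse_iupac_condensed
from glycoforge.pucker import cremer_pople, ring_displacements
from glycoforge.registry import REGISTRY
from glycoforge.synthetic import (CorruptionSpec, RingBuildSpec, build_glycan_coords,
                                  build_residue, build_ring, corrupt)
from glycoforge.templates import GLYCANS
from glycoforge.validate import check_stereocenters, check_valence, perceive_ring


def axiality(build, center, sub):
    """|cos| of the substituent bond against the ring mean-plane normal."""
    ring = np.vstack([build.atoms[n] for n in build.ring_atoms])
    j = np.arange(len(ring))
    rel = ring - ring.mean(axis=0)
    rp = (rel * np.sin(2 * np.pi * j / len(ring))[:, None]).sum(axis=0)
    rpp = (rel * np.cos(2 * np.pi * j / len(ring))[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    normal /= np.linalg.norm(normal)
    v = build.atoms[sub] - build.atoms[center]
    return abs(float(v @ normal) / np.linalg.norm(v))


class TestBuildResidue:
    def test_beta_glucose_all_equatorial(self):
        b = build_residue(REGISTRY["Glc"], "beta")
        for center, sub in (("C1", "O1"), ("C2", "O2"), ("C3", "O3"),
                            ("C4", "O4"), ("C5", "C6")):
            assert axiality(b, center, sub) < 0.5

    def test_beta_galactose_o4_axial(self):
        b = build_residue(REGISTRY["Gal"], "beta")
        assert axiality(b, "C4", "O4") > 0.8
        assert axiality(b, "C2", "O2") < 0.5

    def test_alpha_mannose_o2_and_o1_axial(self):
        b = build_residue(REGISTRY["Man"], "alpha")
        assert axiality(b, "C2", "O2") > 0.8
        assert axiality(b, "C1", "O1") > 0.8

    def test_alpha_beta_differ_only_at_the_anomeric_slot(self):
        a = build_residue(REGISTRY["Glc"], "alpha")
        b = build_residue(REGISTRY["Glc"], "beta")
        assert axiality(a, "C1", "O1") > 0.8
        assert axiality(b, "C1", "O1") < 0.5
        for name in ("C2", "O2", "C3", "O3"):
            assert np.allclose(a.atoms[name], b.atoms[name])

    def test_fucose_is_mirrored(self):
        fuc = build_residue(REGISTRY["Fuc"], "alpha")
        assert fuc.mirrored
        q, th, _ph = cremer_pople(np.vstack([fuc.atoms[n] for n in fuc.ring_atoms]))
        assert th > 170.0  # mirror of the 4C1 build sits at the 1C4 pole

    def test_furanose_build_forbids_polar_angle(self):
        with pytest.raises(GeometryError):
            build_residue(REGISTRY["Rib"], "beta", conformer=(0.35, 30.0, 90.0))


class TestBuildGlycan:
    def test_lnnt_model_is_clean(self, lnnt_graph):
        model = build_glycan_coords(lnnt_graph)
        report = check_stereocenters(model, lnnt_graph)
        assert report.clean
        assert len(model.residues()) == 4

    def test_g2s2_model_is_clean(self):
        g = parse_iupac_condensed(GLYCANS["g2s2"])
        report = check_stereocenters(build_glycan_coords(g), g)
        assert report.clean
        assert all(r.anomeric_verdict == "ok" for r in report.residues)

    def test_ribitol_segment_skips_pucker(self):
        g = parse_iupac_condensed("Xyla1-2Rbo-ol5P1-3GalNAcb1-3GlcNAcb1-4Man6Pa")
        model = build_glycan_coords(g)
        report = check_stereocenters(model, g)
        assert report.clean
        rbo = next(r for r in report.residues
                   if r.expected_code == "RBL")
        assert rbo.pucker is None

    def test_junction_has_exactly_one_inter_residue_bond(self,
                                                         lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        bonds = model.infer_bonds()
        inter = [(i, j) for i, j in bonds
                 if model.atoms[i].residue_index != model.atoms[j].residue_index]
        assert len(inter) == 1

    def test_glucose_has_twelve_heavy_bonds(self):
        g = GlycanGraph()
        g.add_residue(MonosaccharideResidue("Glc"))
        model = build_glycan_coords(g)
        assert len(model.infer_bonds()) == 12  # 6 ring + 6 exocyclic


class TestCorrupt:
    def test_gal_c4_flip_reads_as_glucose_like(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        bad = corrupt(model, CorruptionSpec("NG", 2, "epimer-flip", "C4"), g)
        findings = check_stereocenters(bad, g).findings()
        assert findings == [{"category": "epimer-flip", "residue": 2,
                             "center": "C4"}]

    def test_anomer_flip_at_linkage(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        bad = corrupt(model, CorruptionSpec("NG", 2, "anomer-flip"), g)
        report = check_stereocenters(bad, g)
        assert report.residues[1].anomeric_verdict == "flipped"
        assert report.findings() == [{"category": "anomer-flip", "residue": 2}]

    def test_retained_leaving_oxygen_at_sialic_junction(self):
        g = parse_iupac_condensed("Neu5Aca2-6Galb1-4Glc")
        model = build_glycan_coords(g)
        bad = corrupt(model, CorruptionSpec("NG", 3, "retain-leaving-oxygen"), g)
        flags = check_valence(bad)
        retained = [f for f in flags if f["category"] == "retained-leaving-oxygen"]
        assert len(retained) == 1
        assert retained[0]["atom"] == "C2" and retained[0]["residue"] == 3

    def test_ring_flatten_reports_planar(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        bad = corrupt(model, CorruptionSpec("NG", 1, "ring-flatten"), g)
        report = check_stereocenters(bad, g)
        assert report.residues[0].pucker.conformer == "planar"

    def test_incompatible_target_rejected(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        with pytest.raises(GeometryError):
            corrupt(model, CorruptionSpec("NG", 1, "epimer-flip", "O5"), g)

    def test_clean_model_untouched_by_corrupt(self, lactose_model_and_graph):
        model, g = lactose_model_and_graph
        before = model.coords().copy()
        corrupt(model, CorruptionSpec("NG", 2, "epimer-flip", "C4"), g)
        assert np.array_equal(model.coords(), before)


class TestRingPerception:
    def test_pyranose_ring_starts_at_oxygen(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        ring = perceive_ring(model, "NG", 1)
        assert len(ring) == 6
        assert ring[0].element == "O"
        assert ring[1].name == "C1"

    def test_furanose_ring_has_five_atoms(self):
        g = GlycanGraph()
        g.add_residue(MonosaccharideResidue("Rib", "D", "furanose", "beta"))
        model = build_glycan_coords(g)
        ring = perceive_ring(model, "NG", 1)
        assert len(ring) == 5

    def test_open_chain_is_indeterminate(self):
        g = GlycanGraph()
        g.add_residue(MonosaccharideResidue("Rbo-ol", "D", "open-chain", "none"))
        model = build_glycan_coords(g)
        assert perceive_ring(model, "NG", 1) is None

    def test_forward_pucker_of_built_ring_matches_spec(self):
        ring = build_ring(RingBuildSpec(6, 0.76, 90.0, 0.0))
        z = ring_displacements(ring)
        assert abs(z.sum()) < 1e-10
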