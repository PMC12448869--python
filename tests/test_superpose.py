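"""Kabsch superposition, refinement, structure comparison."""

import numpy as np
import pytest

from glycoforge.errors import GeometryError
from glycoforge.geometry import rotation_about_axis
from glycoforge.superpose import align_refine, compare_glycans, kabsch


def sampled_rotation_rmsd(p, q, n_samples=20_000, seed=0, zoom_levels=6):
    """Independent oracle: best RMSD over sampled rotations (centered),
    with progressive zoom around the best candidate."""
    p = np.asarray(p) - np.asarray(p).mean(axis=0)
    q = np.asarray(q) - np.asarray(q).mean(axis=0)
    rng = np.random.default_rng(seed)

    def rand_quats(n):
        v = rng.normal(size=(n, 4))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def quat_to_mat(quats):
        w, x, y, z = quats.T
        return np.stack([
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ], axis=1)

    def best_of(mats):
        fitted = np.einsum("rij,nj->rni", mats, p)
        rmsds = np.sqrt(((fitted - q) ** 2).sum(axis=(1, 2)) / len(p))
        k = int(rmsds.argmin())
        return rmsds[k], mats[k]

    best_rmsd, best_mat = best_of(quat_to_mat(rand_quats(n_samples)))
    scale = 0.3
    for _level in range(zoom_levels):
        axes = rng.normal(size=(n_samples // 4, 3))
        angles = rng.normal(scale=scale, size=n_samples // 4)
        perturbed = np.stack([
            rotation_about_axis(a, np.degrees(t)) @ best_mat
            for a, t in zip(axes, angles)])
        r, m = best_of(perturbed)
        if r < best_rmsd:
            best_rmsd, best_mat = r, m
        scale *= 0.3
    return best_rmsd


class TestKabsch:
    def test_identity(self, rng):
        p = rng.normal(size=(8, 3))
        assert kabsch(p, p).rmsd < 1e-12

    def test_rigid_copy_recovers_zero(self, rng):
        p = rng.normal(size=(10, 3))
        rot = rotation_about_axis([1, 2, 3], 71.0)
        q = p @ rot.T + np.array([4.0, -5.0, 6.0])
        result = kabsch(p, q)
        assert result.rmsd < 1e-9
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_is_always_proper(self, rng):
        # mirror-image inputs must not produce a reflection
        p = rng.normal(size=(7, 3))
        q = p * np.array([-1.0, 1.0, 1.0])
        result = kabsch(p, q)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)
        assert result.rmsd > 0.1

    def test_closed_form_beats_sampled_search(self, rng):
        for case in range(5):
            p = rng.normal(size=(10, 3))
            q = rng.normal(size=(10, 3))
            exact = kabsch(p, q).rmsd
            sampled = sampled_rotation_rmsd(p, q, seed=case)
            assert exact <= sampled + 1e-12
            assert sampled - exact < 1e-3

    def test_symmetric_in_arguments(self, rng):
        p = rng.normal(size=(9, 3))
        q = rng.normal(size=(9, 3))
        assert kabsch(p, q).rmsd == pytest.approx(kabsch(q, p).rmsd, abs=1e-12)

    def test_invariant_under_prerotation(self, rng):
        p = rng.normal(size=(9, 3))
        q = rng.normal(size=(9, 3))
        rot = rotation_about_axis([0, 1, 1], 123.0)
        assert kabsch(p @ rot.T, q).rmsd == pytest.approx(kabsch(p, q).rmsd,
                                                          abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(GeometryError):
            kabsch(line, line + 1.0)
        with pytest.raises(GeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAlignRefine:
    def test_clean_data_retains_all_pairs(self, rng):
        p = rng.normal(size=(12, 3))
        rot = rotation_about_axis([1, 0, 0], 30.0)
        q = p @ rot.T + 2.0
        result = align_refine(p, q)
        assert result.n_retained == 12
        assert result.rmsd_refined == pytest.approx(result.rmsd_all, abs=1e-12)

    def test_injected_outlier_rejected(self, rng):
        p = rng.normal(size=(10, 3))
        q = p + rng.normal(scale=0.05, size=(10, 3))
        clean_rmsd = kabsch(p, q).rmsd
        q_out = q.copy()
        q_out[4] += np.array([10.0, 0.0, 0.0])
        result = align_refine(p, q_out)
        assert not result.retained_mask[4]
        assert result.n_retained == 9
        assert result.rmsd_refined == pytest.approx(clean_rmsd, abs=0.02)
        assert result.rmsd_refined <= result.rmsd_all

    def test_zero_cycles_equals_kabsch_exactly(self, rng):
        p = rng.normal(size=(10, 3))
        q = p + rng.normal(scale=0.2, size=(10, 3))
        base = kabsch(p, q)
        refined = align_refine(p, q, cycles=0)
        assert refined.rmsd_all == base.rmsd
        assert refined.rmsd_refined == base.rmsd
        assert np.array_equal(refined.rotation, base.rotation)

    def test_never_drops_below_three_pairs(self, rng):
        p = rng.normal(size=(4, 3))
        q = p + rng.normal(scale=1.0, size=(4, 3))
        result = align_refine(p, q, cycles=10, reject_sigma=0.1)
        assert result.n_retained >= 3


class TestCompareGlycans:
    def test_self_comparison_is_zero(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        residue_map = [(("NG", 1), ("NG", 1)), (("NG", 2), ("NG", 2))]
        report = compare_glycans(model, model, residue_map)
        assert report.rmsd_all < 1e-9
        assert report.n_pairs == len(model.atoms)

    def test_pure_translation_of_rigid_copy_refits_to_zero(self,
                                                           lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        moved = model.transformed(np.eye(3), np.array([3.0, 4.0, 0.0]))
        residue_map = [(("NG", 1), ("NG", 1)), (("NG", 2), ("NG", 2))]
        report = compare_glycans(model, moved, residue_map)
        assert report.rmsd_all < 1e-9

    def test_perturbed_subset_rmsd_matches_analytic_value(self,
                                                          lactose_model_and_graph):
        # translating ALL atoms of one structure is absorbed by the fit;
        # per-residue residuals localize a perturbation of a single residue
        model, _g = lactose_model_and_graph
        import copy
        moved = copy.deepcopy(model)
        n = len(moved.atoms)
        n_moved = sum(1 for a in moved.atoms if a.residue_index == 2)
        for a in moved.atoms:
            if a.residue_index == 2:
                a.pos = a.pos + np.array([0.0, 0.0, 0.4])
        residue_map = [(("NG", 1), ("NG", 1)), (("NG", 2), ("NG", 2))]
        report = compare_glycans(model, moved, residue_map, cycles=0)
        assert report.per_residue[("NG", 2)] > report.per_residue[("NG", 1)]

    def test_atom_filter_restricts_pairing(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        residue_map = [(("NG", 1), ("NG", 1))]
        report = compare_glycans(model, model, residue_map,
                                 atom_filter={"C1", "C2", "C3", "C4", "C5", "O5"})
        assert report.n_pairs == 6

    def test_empty_pairing_rejected(self, lactose_model_and_graph):
        model, _g = lactose_model_and_graph
        with pytest.raises(GeometryError):
            compare_glycans(model, model, [(("ZZ", 1), ("ZZ", 1))])
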