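import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from carbsorb.chemstruct import AtomRecord, MoleculeGeometry, center_of_mass
from carbsorb.physisorption import (
    MMFF_BUF147,
    UFF_LJ,
    AdsorptionPose,
    PhysisorptionResult,
    carve_cluster,
    conformer_referenced_potential,
    filter_conformers,
    interaction_energy,
    isomer_binding_summary,
    minimize_pose,
    pair_vdw_energy,
    sample_poses,
)


def one_atom(element="C", position=(0.0, 0.0, 0.0)):
    return MoleculeGeometry([AtomRecord(element, position)])


def identity_pose(adsorbate, translation):
    return AdsorptionPose(0, translation, np.array([0.0, 0.0, 0.0, 1.0]), adsorbate)


class TestPairPotential:
    def test_lj_zero_crossing_at_sigma(self):
        sigma = UFF_LJ.size["C"]
        assert pair_vdw_energy(sigma, "C", "C", UFF_LJ) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum(self):
        sigma, eps = UFF_LJ.size["C"], UFF_LJ.eps["C"]
        r_min = 2 ** (1 / 6) * sigma
        assert pair_vdw_energy(r_min, "C", "C", UFF_LJ) == pytest.approx(-eps, rel=1e-12)

    def test_buffered147_value_at_rstar(self):
        rstar, eps = MMFF_BUF147.size["C"], MMFF_BUF147.eps["C"]
        assert pair_vdw_energy(rstar, "C", "C", MMFF_BUF147) == pytest.approx(
            -eps, rel=1e-12
        )
        # published form: the true minimum sits within 0.5% of r* and is at
        # most 0.1% deeper than -eps
        grid = np.linspace(0.9 * rstar, 1.1 * rstar, 20001)
        vals = [pair_vdw_energy(r, "C", "C", MMFF_BUF147) for r in grid]
        r_min = grid[int(np.argmin(vals))]
        assert abs(r_min - rstar) / rstar < 0.005
        assert -1.001 * eps < min(vals) <= -eps

    def test_cross_rule_symmetric(self):
        assert UFF_LJ.cross("C", "H") == UFF_LJ.cross("H", "C")

    def test_unparameterized_element(self):
        with pytest.raises(KeyError):
            pair_vdw_energy(3.0, "C", "N", UFF_LJ)


class TestInteractionEnergy:
    def test_beyond_cutoff_is_zero(self, small_slab):
        ads = one_atom("C", (0.0, 0.0, small_slab.top_z + 100.0))
        assert interaction_energy(ads, small_slab, cutoff=6.0) == 0.0

    def test_single_pair_minimum(self):
        surface = one_atom("C")
        sigma, eps = UFF_LJ.size["C"], UFF_LJ.eps["C"]
        ads = one_atom("C", (0.0, 0.0, 2 ** (1 / 6) * sigma))
        e = interaction_energy(ads, surface, cutoff=12.0)
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_lattice_translation_invariance(self, small_slab, cis_conformers):
        pose = identity_pose(
            cis_conformers.geometries[0],
            np.array([5.0, 5.0, small_slab.top_z + 3.0]),
        )
        placed = pose.place()
        shifted = placed.translated(small_slab.cell_a)
        e0 = interaction_energy(placed, small_slab, cutoff=6.0)
        e1 = interaction_energy(shifted, small_slab, cutoff=6.0)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_rigid_transform_invariance(self, cis_conformers):
        # rotate both adsorbate and (non-periodic) surface together
        surface = MoleculeGeometry(
            [AtomRecord("C", [x, y, 0.0]) for x in (-2, 0, 2) for y in (-2, 0, 2)]
        )
        ads = cis_conformers.geometries[0].translated([0.0, 0.0, 4.0])
        rot = Rotation.from_euler("xyz", [0.3, -0.7, 1.1]).as_matrix()
        shift = np.array([3.0, -2.0, 5.0])
        e0 = interaction_energy(ads, surface, cutoff=12.0)
        e1 = interaction_energy(
            ads.transformed(rot, shift), surface.transformed(rot, shift), cutoff=12.0
        )
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_overlap_flagged_energy_returned(self):
        surface = one_atom("C")
        ads = one_atom("C", (0.0, 0.0, 0.3))
        e, overlap = interaction_energy(ads, surface, cutoff=12.0, details=True)
        assert overlap
        assert np.isfinite(e)

    def test_cutoff_exceeding_half_cell_rejected(self, small_slab):
        ads = one_atom("C", (0.0, 0.0, small_slab.top_z + 3.0))
        with pytest.raises(ValueError, match="cutoff"):
            interaction_energy(ads, small_slab, cutoff=100.0)


class TestSamplePoses:
    def test_seed_determinism(self, small_slab, cis_conformers):
        a = sample_poses(small_slab, cis_conformers, 6, seed=9)
        b = sample_poses(small_slab, cis_conformers, 6, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.translation, pb.translation)
            np.testing.assert_array_equal(pa.orientation, pb.orientation)
            assert pa.conformer_index == pb.conformer_index

    def test_lateral_positions_in_patch(self, small_slab, cis_conformers):
        poses = sample_poses(
            small_slab, cis_conformers, 40, patch_fraction=0.6, seed=1
        )
        La, Lb = small_slab.cell_a[0], small_slab.cell_b[1]
        for p in poses:
            assert 0.2 * La <= p.translation[0] <= 0.8 * La
            assert 0.2 * Lb <= p.translation[1] <= 0.8 * Lb

    def test_lowest_conformers_forced(self, small_slab, cis_conformers):
        n_forced = min(3, len(cis_conformers))
        poses = sample_poses(small_slab, cis_conformers, max(3, n_forced), seed=2)
        seen = {p.conformer_index for p in poses}
        assert set(range(n_forced)) <= seen

    def test_empty_conformer_set_rejected(self, small_slab):
        from carbsorb.surfaces import ConformerSet

        empty = ConformerSet("cis", [], np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            sample_poses(small_slab, empty, 3)


class TestMinimizePose:
    def test_two_atom_height_scan_oracle(self):
        """Single C above a single-C 'surface' must land at the pair
        minimum found by brute-force 1-D scanning."""
        surface = one_atom("C")
        ads = one_atom("C")
        pose = identity_pose(ads, np.array([0.0, 0.0, 5.0]))
        res = minimize_pose(pose, surface, UFF_LJ, cutoff=12.0)
        heights = np.linspace(2.5, 6.0, 70001)
        energies = [pair_vdw_energy(h, "C", "C", UFF_LJ) for h in heights]
        h_best = heights[int(np.argmin(energies))]
        # the minimum is a sphere of radius h_best around the surface atom
        assert abs(np.linalg.norm(res.pose.translation) - h_best) < 5e-3
        assert res.E_int == pytest.approx(min(energies), abs=1e-6)

    def test_descent_contract(self, small_slab, cis_conformers):
        pose = sample_poses(small_slab, cis_conformers, 1, seed=5)[0]
        e_start = interaction_energy(pose, small_slab, cutoff=6.0)
        res = minimize_pose(pose, small_slab, UFF_LJ, cutoff=6.0)
        assert res.E_int <= e_start

    def test_idempotent_at_minimum(self):
        surface = one_atom("C")
        sigma = UFF_LJ.size["C"]
        pose = identity_pose(one_atom("C"), np.array([0.0, 0.0, 2 ** (1 / 6) * sigma]))
        first = minimize_pose(pose, surface, UFF_LJ, cutoff=12.0)
        second = minimize_pose(first.pose, surface, UFF_LJ, cutoff=12.0)
        assert np.linalg.norm(second.pose.translation - first.pose.translation) < 2e-3
        assert second.E_int == pytest.approx(first.E_int, abs=1e-6)


class TestFilterAndReference:
    def make_results(self, energies):
        out = []
        for e in energies:
            pose = identity_pose(one_atom("C"), np.zeros(3))
            out.append(PhysisorptionResult(pose, E_int=e))
        return out

    def test_window_seven(self):
        rs = self.make_results([-10.0, -7.0, -2.9])  # relative 0, 3.0, 7.1
        kept = filter_conformers(rs, window=7.0)
        assert [r.E_int for r in kept] == [-10.0, -7.0]

    def test_infinite_window_keeps_all(self):
        rs = self.make_results([-5.0, 0.0, 12.0])
        assert len(filter_conformers(rs, window=math.inf)) == 3

    def test_equal_energies_all_kept(self):
        rs = self.make_results([-3.0] * 4)
        assert len(filter_conformers(rs, window=7.0)) == 4

    def test_order_independence(self):
        energies = [-10.0, -7.0, -2.9, -9.5]
        fwd = filter_conformers(self.make_results(energies))
        rev = filter_conformers(self.make_results(energies[::-1]))
        assert sorted(r.E_int for r in fwd) == sorted(r.E_int for r in rev)

    def test_rigid_adsorbate_reduces_to_minus_eint(self):
        # conformer energy identical in and out of the complex cancels
        assert conformer_referenced_potential(-6.2 + 1.0, 1.0, [0.0] * 5) == (
            pytest.approx(6.2)
        )

    def test_sign_convention_example(self):
        assert conformer_referenced_potential(-6.2, 0.0, [0.0] * 5) == pytest.approx(6.2)

    def test_gauge_invariance(self):
        base = conformer_referenced_potential(-4.0, 2.0, [0.0, 0.5, 1.0, 1.5, 2.0])
        shifted = conformer_referenced_potential(
            -4.0 + 7.0, 2.0 + 7.0, [0.0, 0.5, 1.0, 1.5, 2.0]
        )
        assert shifted == pytest.approx(base)


class TestIsomerSummary:
    def make(self, e_phys_values):
        return [
            PhysisorptionResult(identity_pose(one_atom("C"), np.zeros(3)), -v)
            for v in e_phys_values
        ]

    def test_planar_vs_amorphous_differences(self):
        # means 7.2 (cis) and 8.5 (trans) -> delta 1.3
        s = isomer_binding_summary(self.make([7.2, 7.2]), self.make([8.5, 8.5]))
        assert s.delta == pytest.approx(1.3)

    def test_identical_distributions_zero(self):
        s = isomer_binding_summary(self.make([5.0, 6.0]), self.make([5.0, 6.0]))
        assert s.delta == 0.0

    def test_cluster_ensemble_difference(self):
        s = isomer_binding_summary(self.make([18.6] * 3), self.make([23.2] * 3))
        assert s.delta == pytest.approx(4.6)

    def test_delta_consistency_invariant(self):
        s = isomer_binding_summary(self.make([7.0, 7.4]), self.make([9.1, 8.9]))
        assert abs(s.delta - (s.mean_trans - s.mean_cis)) < 1e-12


class TestCarveCluster:
    def test_radius_exceeding_extent_keeps_all_no_caps(self):
        from carbsorb.surfaces import build_pah_flake

        flake = build_pah_flake(1, 1)
        probe = one_atom("C", (0.0, 0.0, 3.0))
        carved = carve_cluster(flake, probe, radius=1000.0)
        assert carved.geometry.n_atoms == flake.n_atoms
        assert carved.n_caps == 0

    def test_paper_scale_cluster_size(self, paper_scale_slab, cis_conformers):
        pose = sample_poses(paper_scale_slab, cis_conformers, 1, seed=4)[0]
        res = minimize_pose(
            pose, paper_scale_slab, UFF_LJ, cutoff=12.0, max_iters=200
        )
        carved = carve_cluster(paper_scale_slab, res.pose, radius=12.0)
        assert 300 <= carved.cap_start <= 1200  # surface atoms, caps excluded

    def test_odd_electron_cluster_discarded(self):
        surface = MoleculeGeometry(
            [AtomRecord("H", [0, 0, 0]), AtomRecord("C", [5, 0, 0])]
        )
        probe = one_atom("C", (0.0, 0.0, 1.0))
        carved = carve_cluster(surface, probe, radius=2.0)
        assert carved.discarded
        assert "odd" in carved.reason

    def test_cluster_matches_slab_at_radius_ge_cutoff(self, small_slab):
        probe = one_atom("C", (9.0, 9.0, small_slab.top_z + 3.0))
        cutoff = 6.0
        e_full = interaction_energy(probe, small_slab, cutoff=cutoff)
        carved = carve_cluster(small_slab, probe, radius=cutoff)
        e_cluster = interaction_energy(
            carved.without_caps(), probe, cutoff=cutoff
        )
        assert e_cluster == pytest.approx(e_full, rel=1e-12)

    def test_cluster_energy_converges_monotonically(self, small_slab):
        probe = one_atom("C", (9.0, 9.0, small_slab.top_z + 3.0))
        cutoff = 6.0
        e_full = interaction_energy(probe, small_slab, cutoff=cutoff)
        errors = []
        for radius in (3.0, 4.0, 5.0, 6.0):
            carved = carve_cluster(small_slab, probe, radius=radius)
            e = interaction_energy(carved.without_caps(), probe, cutoff=cutoff)
            errors.append(abs(e - e_full))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-12
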