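"""Torsion moves, clash detection, superposition and the MC sampler."""

import math

import numpy as np
import pytest

from flexsaxs import (
    FlexibleRegion,
    MCConfig,
    TorsionMove,
    apply_torsion,
    check_overlap,
    run_mc,
    superpose,
)
from flexsaxs.mc import bond_exclusions

from conftest import make_atoms

NO_BONDS = frozenset()


class TestApplyTorsion:
    def test_zero_delta_is_identity(self, toy_chain):
        moved = apply_torsion(toy_chain, TorsionMove(25, "phi", 0.0))
        np.testing.assert_array_equal(moved.coords, toy_chain.coords)

    @pytest.mark.parametrize("angle", ["phi", "psi"])
    def test_inverse_move_restores_coordinates(self, toy_chain, angle):
        fwd = apply_torsion(toy_chain, TorsionMove(25, angle, 30.0))
        back = apply_torsion(fwd, TorsionMove(25, angle, -30.0))
        np.testing.assert_allclose(back.coords, toy_chain.coords, atol=1e-9)

    def test_matches_rotation_matrix_oracle(self, toy_chain):
        """Explicit Rodrigues rotation-matrix construction, applied
        independently to the downstream atom set, reproduces the move."""
        residue, delta = 23, 17.3
        moved = apply_torsion(toy_chain, TorsionMove(residue, "psi", delta))

        atom_map = {
            (a.residue_index, a.name): i for i, a in enumerate(toy_chain.atoms)
        }
        coords = toy_chain.coords
        origin = coords[atom_map[(residue, "CA")]]
        axis = coords[atom_map[(residue, "C")]] - origin
        k = axis / np.linalg.norm(axis)
        t = math.radians(delta)
        kx, ky, kz = k
        K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        R = np.eye(3) * math.cos(t) + math.sin(t) * K + (1 - math.cos(t)) * np.outer(k, k)

        expected = coords.copy()
        for i, a in enumerate(toy_chain.atoms):
            downstream = a.residue_index > residue or (
                a.residue_index == residue and a.name in ("O", "OXT")
            )
            if downstream:
                expected[i] = R @ (coords[i] - origin) + origin
        np.testing.assert_allclose(moved.coords, expected, atol=1e-10)

    def test_downstream_pairwise_distances_preserved(self, toy_chain):
        from scipy.spatial.distance import pdist

        moved = apply_torsion(toy_chain, TorsionMove(25, "phi", 44.0))
        downstream = [
            i for i, a in enumerate(toy_chain.atoms) if a.residue_index > 25
        ]
        d0 = pdist(toy_chain.coords[downstream])
        d1 = pdist(moved.coords[downstream])
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_upstream_atoms_untouched(self, toy_chain):
        moved = apply_torsion(toy_chain, TorsionMove(25, "psi", 44.0))
        upstream = [i for i, a in enumerate(toy_chain.atoms) if a.residue_index < 25]
        np.testing.assert_array_equal(
            moved.coords[upstream], toy_chain.coords[upstream]
        )

    def test_undefined_terminal_torsions_rejected(self, toy_chain):
        with pytest.raises(ValueError, match="phi"):
            apply_torsion(toy_chain, TorsionMove(1, "phi", 10.0))
        with pytest.raises(ValueError, match="psi"):
            apply_torsion(toy_chain, TorsionMove(50, "psi", 10.0))


class TestCheckOverlap:
    def test_close_nonbonded_pair_clashes(self):
        s = make_atoms([[0, 0, 0], [1.0, 0, 0]], residue_index=[1, 5])
        assert check_overlap(s, cutoff=2.0, exclusions=NO_BONDS)

    def test_bonded_neighbours_excluded(self):
        # peptide-bond distance: inferred as covalent, hence excluded
        s = make_atoms([[0, 0, 0], [1.33, 0, 0]], residue_index=[1, 2])
        assert not check_overlap(s, cutoff=2.0)

    def test_distance_equal_to_cutoff_is_not_a_clash(self):
        s = make_atoms([[0, 0, 0], [2.0, 0, 0]], residue_index=[1, 5])
        assert not check_overlap(s, cutoff=2.0, exclusions=NO_BONDS)

    def test_all_basis_requires_hydrogens(self, toy_chain):
        with pytest.raises(ValueError, match="hydrogen"):
            check_overlap(toy_chain, basis="all")

    def test_vdw_default_cutoff(self):
        # two carbons at 2.0 Å: 0.8*(1.7+1.7) = 2.72 → clash
        s = make_atoms([[0, 0, 0], [2.0, 0, 0]], residue_index=[1, 5])
        assert check_overlap(s, exclusions=NO_BONDS)
        # at 3.0 Å they are apart
        s2 = make_atoms([[0, 0, 0], [3.0, 0, 0]], residue_index=[1, 5])
        assert not check_overlap(s2, exclusions=NO_BONDS)


class TestSuperpose:
    def test_self_superposition_is_exact(self, toy_chain, align_range):
        _, rmsd = superpose(toy_chain, toy_chain, align_range)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rigid_transform(self, toy_chain, align_range):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 12.0])
        moved = toy_chain.with_coords(toy_chain.coords @ rot.T + t)
        aligned, rmsd = superpose(moved, toy_chain, align_range)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(aligned.coords, toy_chain.coords, atol=1e-8)

    def test_rmsd_matches_independent_kabsch_oracle(self, toy_chain, align_range):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        noisy = toy_chain.with_coords(
            toy_chain.coords + 0.3 * rng.standard_normal(toy_chain.coords.shape)
        )
        _, rmsd = superpose(noisy, toy_chain, align_range)

        idx = [
            i
            for i, a in enumerate(toy_chain.atoms)
            if a.name == "CA" and align_range.start <= a.residue_index <= align_range.end
        ]
        mob = noisy.coords[idx] - noisy.coords[idx].mean(axis=0)
        ref = toy_chain.coords[idx] - toy_chain.coords[idx].mean(axis=0)
        _, rssd = Rotation.align_vectors(ref, mob)
        assert rmsd == pytest.approx(rssd / math.sqrt(len(idx)), abs=1e-10)

    def test_too_few_calpha_rejected(self, toy_chain):
        with pytest.raises(ValueError, match="fewer than 3"):
            superpose(toy_chain, toy_chain, FlexibleRegion(1, 2))


class TestRunMC:
    def test_zero_trials_gives_empty_pool(self, toy_chain, toy_regions, align_range):
        pool = run_mc(
            toy_chain, toy_regions, MCConfig(trial_attempts=0, align_range=align_range)
        )
        assert len(pool) == 0
        assert pool.acceptance_log == []

    def test_no_regions_rejected(self, toy_chain):
        with pytest.raises(ValueError, match="region"):
            run_mc(toy_chain, [], MCConfig(trial_attempts=10))

    def test_seeded_run_is_reproducible(self, toy_chain, toy_regions, align_range):
        cfg = MCConfig(trial_attempts=150, align_range=align_range, seed=42)
        p1 = run_mc(toy_chain, toy_regions, cfg)
        p2 = run_mc(toy_chain, toy_regions, cfg)
        assert p1.acceptance_log == p2.acceptance_log
        assert len(p1) <= 150
        for (_, s1), (_, s2) in zip(p1.frames, p2.frames):
            np.testing.assert_array_equal(s1.coords, s2.coords)

    def test_accepted_frames_are_clash_free(self, toy_chain, mc_pool):
        exclusions = bond_exclusions(toy_chain)
        for _, frame in mc_pool.frames[::25]:
            assert not check_overlap(frame, exclusions=exclusions)

    def test_bonded_geometry_conserved_pool_wide(self, toy_chain, mc_pool):
        """Torsion moves never change bond lengths or 1-3 distances."""
        pairs = np.array(sorted(bond_exclusions(toy_chain)))
        ref = np.linalg.norm(
            toy_chain.coords[pairs[:, 0]] - toy_chain.coords[pairs[:, 1]], axis=1
        )
        for _, frame in mc_pool.frames[::10]:
            d = np.linalg.norm(
                frame.coords[pairs[:, 0]] - frame.coords[pairs[:, 1]], axis=1
            )
            np.testing.assert_allclose(d, ref, atol=1e-8)

    def test_rigid_domains_keep_internal_distances(self, toy_chain, mc_pool):
        from scipy.spatial.distance import pdist

        domain2 = [i for i, a in enumerate(toy_chain.atoms) if a.residue_index > 30]
        ref = pdist(toy_chain.coords[domain2])
        _, frame = mc_pool.frames[-1]
        np.testing.assert_allclose(pdist(frame.coords[domain2]), ref, atol=1e-8)

    def test_sampling_actually_moves_the_structure(self, mc_pool):
        assert len(mc_pool) >= 100
        assert mc_pool.rg.std() > 0.0
        assert mc_pool.rg.max() - mc_pool.rg.min() > 1.0

    def test_model_numbers_consecutive_and_trials_recorded(self, mc_pool):
        assert mc_pool.model_numbers == list(range(1, len(mc_pool) + 1))
        assert len(mc_pool.acceptance_log) == 800
        assert sum(mc_pool.acceptance_log) == len(mc_pool)
        assert all(
            t2 > t1 for t1, t2 in zip(mc_pool.trial_index, mc_pool.trial_index[1:])
        )
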