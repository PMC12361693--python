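"""Isomerization operator, time-series analytics, pocket counters, IE."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from opsinsol import (
    HbondCriteria,
    IsomerizationSpec,
    NonbondedParams,
    StructureModel,
    Trajectory,
    count_hbonds,
    count_pocket_waters,
    define_pocket,
    dihedral,
    interaction_energy,
    isomerize,
    make_harmonic_trajectory,
    make_pocket_scene,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    running_average,
    signed_pseudo_log,
)
from opsinsol.traj_analysis import COULOMB_CONSTANT

from conftest import ca_model_from_sequence


def toy_retinal():
    """Six carbons mimicking the C10..C15 stretch of a bent polyene."""
    coords = np.array([
        [-1.3, 0.8, 0.2],   # C10
        [0.0, 0.0, 0.0],    # C11 (axis)
        [1.5, 0.0, 0.0],    # C12 (axis)
        [2.3, 1.2, 0.1],    # C13 (moving)
        [3.8, 1.3, 0.3],    # C14 (moving)
        [4.6, 2.5, 0.2],    # C15 (moving)
    ])
    return StructureModel(
        atom_names=np.array(["C10", "C11", "C12", "C13", "C14", "C15"]),
        elements=np.array(["C"] * 6),
        res_indices=np.full(6, 296),
        res_names=np.array(["RET"] * 6),
        chain_ids=np.array(["A"] * 6),
        coords=coords,
    )


CIS_TRANS = IsomerizationSpec(axis=(1, 2), moving=(3, 4, 5), angle_deg=180.0)


class TestIsomerize:
    def test_involution(self):
        model = toy_retinal()
        twice = isomerize(isomerize(model, CIS_TRANS), CIS_TRANS)
        np.testing.assert_allclose(twice.coords, model.coords, atol=1e-9)

    def test_rigidity_of_moving_set(self):
        model = toy_retinal()
        flipped = isomerize(model, CIS_TRANS)
        before = pdist(model.coords[[3, 4, 5]])
        after = pdist(flipped.coords[[3, 4, 5]])
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_fixed_atoms_untouched(self):
        model = toy_retinal()
        flipped = isomerize(model, CIS_TRANS)
        np.testing.assert_array_equal(flipped.coords[[0, 1, 2]],
                                      model.coords[[0, 1, 2]])

    def test_dihedral_flips_by_180(self):
        model = toy_retinal()
        before = dihedral(*model.coords[[0, 1, 2, 3]])
        after = dihedral(*isomerize(model, CIS_TRANS).coords[[0, 1, 2, 3]])
        assert (after - before) % 360.0 == pytest.approx(180.0, abs=1e-9)

    def test_dihedral_against_independent_formula(self):
        # cross-product (Gram-Schmidt-free) dihedral as the oracle
        p = toy_retinal().coords[[0, 1, 2, 3]]
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        oracle = np.degrees(np.arctan2(
            np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)),
            np.dot(n1, n2)))
        assert dihedral(*p) == pytest.approx(oracle, abs=1e-9)

    def test_axis_atom_in_moving_set_rejected(self):
        with pytest.raises(ValueError):
            IsomerizationSpec(axis=(1, 2), moving=(2, 3))

    def test_bond_rotation_preserves_all_distances_to_axis(self):
        model = toy_retinal()
        flipped = isomerize(model, CIS_TRANS)
        for m in (3, 4, 5):
            for ax in (1, 2):
                d0 = np.linalg.norm(model.coords[m] - model.coords[ax])
                d1 = np.linalg.norm(flipped.coords[m] - flipped.coords[ax])
                assert d1 == pytest.approx(d0, abs=1e-9)


def _static_traj(model, n_frames=5, spacing=100.0):
    coords = np.repeat(model.coords[None], n_frames, axis=0)
    return Trajectory(topology=model, times=spacing * np.arange(n_frames),
                      coords=coords)


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self):
        model = ca_model_from_sequence("MKTAYIAKQRQISF")
        traj = _static_traj(model)
        series = rmsd_series(traj, model)
        np.testing.assert_allclose(series["rmsd"], 0.0, atol=1e-12)

    def test_rigid_motion_frames_are_zero(self, rng):
        model = ca_model_from_sequence("MKTAYIAKQRQISF")
        frames = []
        for _ in range(4):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(2 ** 31))).as_matrix()
            frames.append(model.coords @ R.T + rng.normal(0, 5, 3))
        traj = Trajectory(topology=model, times=np.arange(4.0),
                          coords=np.stack(frames))
        series = rmsd_series(traj, model)
        np.testing.assert_allclose(series["rmsd"], 0.0, atol=1e-9)

    def test_single_displaced_atom_hand_value(self):
        # fit atoms identical -> transform is identity; one measured atom
        # displaced by a 3-4-0 vector gives RMSD 0.5 over that selection
        model = ca_model_from_sequence("MKTA")
        frame = model.coords.copy()
        frame[3] += np.array([0.3, 0.4, 0.0])
        traj = Trajectory(topology=model, times=np.array([0.0]),
                          coords=frame[None])
        fit_sel = np.array([True, True, True, False])
        meas_sel = ~fit_sel
        series = rmsd_series(traj, model, fit_sel, meas_sel)
        assert series["rmsd"].iloc[0] == pytest.approx(0.5, abs=1e-9)


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        out = running_average(np.full(10, 3.3), 500.0, 100.0)
        np.testing.assert_allclose(out, 3.3)

    def test_single_frame_window_is_identity(self):
        x = np.array([4.0, 2.0, 9.0])
        np.testing.assert_array_equal(running_average(x, 100.0, 100.0), x)

    def test_hand_means_with_edge_truncation(self):
        out = running_average(np.array([0.0, 1.0, 2.0, 3.0]), 3.0, 1.0)
        np.testing.assert_allclose(out, [0.5, 1.0, 2.0, 2.5])

    def test_window_shorter_than_spacing_rejected(self):
        with pytest.raises(ValueError):
            running_average(np.arange(4.0), 10.0, 100.0)

    def test_bounded_by_input_extremes(self, rng):
        x = rng.normal(0, 1, 200)
        out = running_average(x, 1100.0, 100.0)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        model = ca_model_from_sequence("MKTAYIAKQR")
        out = rmsf(_static_traj(model))
        np.testing.assert_allclose(out["rmsf"], 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        model = ca_model_from_sequence("MKTA")
        traj = Trajectory(topology=model, times=np.array([0.0]),
                          coords=model.coords[None])
        with pytest.raises(ValueError):
            rmsf(traj)

    def test_two_frame_toy_arithmetic(self):
        # one atom moves by d between two frames: fluctuation about the
        # mean is d/2 in each frame, so its RMSF is exactly d/2
        model = ca_model_from_sequence("MKTAY")
        c2 = model.coords.copy()
        c2[4] += np.array([0.0, 0.0, 0.8])
        traj = Trajectory(topology=model, times=np.array([0.0, 1.0]),
                          coords=np.stack([model.coords, c2]))
        out = rmsf(traj, superpose=False)
        assert out["rmsf"].iloc[4] == pytest.approx(0.4, abs=1e-12)
        np.testing.assert_allclose(out["rmsf"].iloc[:4], 0.0, atol=1e-12)

    def test_gaussian_jitter_recovers_sigma_sqrt3(self, bundle):
        model, _ = bundle
        traj = make_harmonic_trajectory(model, 0.1, n_frames=2000, seed=21)
        out = rmsf(traj)
        expected = 0.1 * np.sqrt(3.0)
        assert out["rmsf"].mean() == pytest.approx(expected, rel=0.05)

    def test_planted_two_level_profile_ratio(self, bundle):
        model, _ = bundle
        lo, hi = 0.05, 0.20
        profile = {int(r): (hi if r <= model.res_indices.max() // 2 else lo)
                   for r in model.res_indices}
        traj = make_harmonic_trajectory(model, profile, n_frames=2000,
                                        seed=22)
        out = rmsf(traj)
        half = model.res_indices.max() // 2
        got_hi = out[out["res_index"] <= half]["rmsf"].mean()
        got_lo = out[out["res_index"] > half]["rmsf"].mean()
        assert got_hi / got_lo == pytest.approx(hi / lo, rel=0.05)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_equal_masses(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(2.0)

    def test_unit_square(self):
        s = 3.0
        coords = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]],
                          dtype=float)
        assert radius_of_gyration(coords) == pytest.approx(s / np.sqrt(2))

    def test_mdanalysis_cross_check(self, rng):
        mda = pytest.importorskip("MDAnalysis")
        coords = rng.normal(0, 5, (30, 3))
        masses = rng.uniform(1, 16, 30)
        u = mda.Universe.empty(30, trajectory=True)
        u.add_TopologyAttr("masses", masses)
        u.atoms.positions = coords
        assert radius_of_gyration(coords, masses) == pytest.approx(
            float(u.atoms.radius_of_gyration()), rel=1e-6)


class TestPocket:
    def test_zero_cutoff_is_empty_pocket_error(self):
        scene, _ = make_pocket_scene(seed=0)
        with pytest.raises(ValueError):
            define_pocket(scene, "RET", cutoff=0.0)

    def test_near_residue_selected_far_residue_not(self):
        model = StructureModel(
            atom_names=np.array(["C1", "CB", "CB"]),
            elements=np.array(["C", "C", "C"]),
            res_indices=np.array([900, 1, 2]),
            res_names=np.array(["RET", "ALA", "ALA"]),
            chain_ids=np.array(["L", "A", "A"]),
            coords=np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]),
            is_hetero=np.array([True, False, False]),
        )
        pocket = define_pocket(model, "RET", cutoff=5.0)
        assert pocket.residues == frozenset({("A", 1)})

    def test_missing_ligand(self):
        scene, _ = make_pocket_scene(seed=0)
        with pytest.raises(ValueError):
            define_pocket(scene, "XYZ")

    def test_planted_scene_recovered_exactly(self):
        scene, truth = make_pocket_scene(3, 5, 2, seed=4)
        pocket = define_pocket(scene, "RET", cutoff=truth["pocket_cutoff"])
        assert set(pocket.residues) == truth["pocket_residues"]


class TestHbonds:
    def water_dimer(self, oo=2.8, angle_deg=0.0):
        # donor O with H pointing along the O-O axis (or off it)
        h = np.array([0.96 * np.cos(np.radians(angle_deg)),
                      0.96 * np.sin(np.radians(angle_deg)), 0.0])
        model = StructureModel(
            atom_names=np.array(["O", "H1", "O"]),
            elements=np.array(["O", "H", "O"]),
            res_indices=np.array([1, 1, 2]),
            res_names=np.array(["HOH", "HOH", "HOH"]),
            chain_ids=np.array(["W"] * 3),
            coords=np.array([[0.0, 0, 0], h, [oo, 0.0, 0.0]]),
        )
        return model, [(0, (1,))], [2]

    def test_aligned_dimer_counts_one(self):
        model, donors, acceptors = self.water_dimer()
        assert count_hbonds(model, donors, acceptors) == 1

    def test_distance_criterion_fails(self):
        model, donors, acceptors = self.water_dimer(oo=4.0)
        assert count_hbonds(model, donors, acceptors) == 0

    def test_angle_criterion_fails(self):
        model, donors, acceptors = self.water_dimer(angle_deg=90.0)
        assert count_hbonds(model, donors, acceptors) == 0

    def test_donor_without_hydrogens_warns_and_skips(self):
        model, donors, acceptors = self.water_dimer()
        with pytest.warns(UserWarning):
            assert count_hbonds(model, [(0, ())], acceptors) == 0

    def test_pair_counted_once_with_two_hydrogens(self):
        model, donors, acceptors = self.water_dimer()
        donors = [(0, (1, 1))]
        assert count_hbonds(model, donors, acceptors) == 1

    def test_planted_scene_counts(self):
        scene, truth = make_pocket_scene(3, 5, 4, seed=9)
        got = count_hbonds(scene, truth["donors"], truth["acceptors"])
        assert got == truth["hbond_pairs"]


class TestPocketWaters:
    def test_no_waters(self):
        scene, truth = make_pocket_scene(0, 0, 1, seed=2)
        pocket = define_pocket(scene, "RET", cutoff=truth["pocket_cutoff"])
        assert count_pocket_waters(scene, pocket) == 0

    def test_planted_counts(self):
        scene, truth = make_pocket_scene(5, 7, 0, seed=3)
        pocket = define_pocket(scene, "RET", cutoff=truth["pocket_cutoff"])
        assert count_pocket_waters(
            scene, pocket, cutoff=truth["water_cutoff"]) == 5

    def test_boundary_water_counted(self):
        model = StructureModel(
            atom_names=np.array(["CB", "O"]),
            elements=np.array(["C", "O"]),
            res_indices=np.array([1, 100]),
            res_names=np.array(["ALA", "HOH"]),
            chain_ids=np.array(["A", "W"]),
            coords=np.array([[0.0, 0, 0], [3.5, 0.0, 0.0]]),
            is_hetero=np.array([False, True]),
        )
        from opsinsol import PocketDefinition
        pocket = PocketDefinition(frozenset({("A", 1)}), "RET", 5.0)
        assert count_pocket_waters(model, pocket, cutoff=3.5) == 1


class TestInteractionEnergy:
    def two_charges(self, r_nm, qa=1.0, qb=-1.0, sigma=0.3, eps=0.0):
        coords = np.array([[0.0, 0, 0], [r_nm * 10.0, 0.0, 0.0]])  # nm -> A
        params = NonbondedParams(charges=[qa, qb], sigmas=[sigma, sigma],
                                 epsilons=[eps, eps])
        return coords, params

    def test_hand_coulomb_value(self):
        coords, params = self.two_charges(0.5)
        c, lj = interaction_energy(coords, [0], [1], params)
        assert c == pytest.approx(COULOMB_CONSTANT * -1.0 / 0.5, abs=1e-9)
        assert c == pytest.approx(-277.87, abs=0.01)
        assert lj == 0.0

    def test_lj_zero_at_sigma(self):
        coords, params = self.two_charges(0.3, qa=0.0, qb=0.0, eps=0.5)
        _, lj = interaction_energy(coords, [0], [1], params)
        assert lj == pytest.approx(0.0, abs=1e-9)

    def test_lj_minimum_at_r_min(self):
        sigma, eps = 0.3, 0.7
        coords, params = self.two_charges(sigma * 2 ** (1 / 6), qa=0.0,
                                          qb=0.0, sigma=sigma, eps=eps)
        _, lj = interaction_energy(coords, [0], [1], params)
        assert lj == pytest.approx(-eps, abs=1e-9)

    def test_cutoff_excludes_far_pairs(self):
        coords, params = self.two_charges(1.5)  # beyond 1.2 nm
        c, lj = interaction_energy(coords, [0], [1], params)
        assert (c, lj) == (0.0, 0.0)

    def test_group_exchange_symmetry_and_charge_linearity(self, rng):
        coords = rng.normal(0, 3, (12, 3))
        params = NonbondedParams(
            charges=rng.normal(0, 0.5, 12),
            sigmas=rng.uniform(0.25, 0.4, 12),
            epsilons=rng.uniform(0.1, 0.9, 12),
        )
        a, b = np.arange(6), np.arange(6, 12)
        ab = interaction_energy(coords, a, b, params)
        ba = interaction_energy(coords, b, a, params)
        assert ab == pytest.approx(ba, abs=1e-9)
        doubled = NonbondedParams(
            charges=np.where(np.arange(12) < 6, 2.0, 1.0) * params.charges,
            sigmas=params.sigmas, epsilons=params.epsilons)
        c2, _ = interaction_energy(coords, a, b, doubled)
        assert c2 == pytest.approx(2.0 * ab[0], abs=1e-9)

    def test_matches_no_cutoff_quadratic_oracle(self, rng):
        coords = rng.normal(0, 2, (10, 3))
        params = NonbondedParams(
            charges=rng.normal(0, 0.5, 10),
            sigmas=rng.uniform(0.25, 0.4, 10),
            epsilons=rng.uniform(0.1, 0.9, 10),
            cutoff_nm=1e6,  # exceeds any system diameter
        )
        a, b = np.arange(5), np.arange(5, 10)
        c, lj = interaction_energy(coords, a, b, params)
        oc = olj = 0.0
        for i in a:
            for j in b:
                r = np.linalg.norm(coords[i] - coords[j]) * 0.1
                oc += COULOMB_CONSTANT * params.charges[i] \
                    * params.charges[j] / r
                s = 0.5 * (params.sigmas[i] + params.sigmas[j])
                e = np.sqrt(params.epsilons[i] * params.epsilons[j])
                olj += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert c == pytest.approx(oc, rel=1e-12)
        assert lj == pytest.approx(olj, rel=1e-12)

    def test_overlapping_groups_rejected(self):
        coords, params = self.two_charges(0.5)
        with pytest.raises(ValueError):
            interaction_energy(coords, [0, 1], [1], params)

    def test_missing_parameters_named(self):
        coords, params = self.two_charges(0.5)
        with pytest.raises(IndexError, match="atom 5"):
            interaction_energy(coords, [0], [5], params)


class TestSignedPseudoLog:
    def test_zero(self):
        assert signed_pseudo_log(0.0) == 0.0

    def test_odd_symmetry(self, rng):
        x = rng.normal(0, 100, 50)
        np.testing.assert_allclose(signed_pseudo_log(-x),
                                   -signed_pseudo_log(x), atol=1e-12)

    def test_decade_value(self):
        assert signed_pseudo_log(9.0, scale=1.0) == pytest.approx(1.0)

    def test_monotone(self, rng):
        x = np.sort(rng.normal(0, 50, 100))
        y = signed_pseudo_log(x)
        assert np.all(np.diff(y) >= 0)
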