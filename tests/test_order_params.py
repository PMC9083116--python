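"""Order parameters: superposition, RMSD, Rg, RMSF, contacts, H-bonds."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from unfoldkit import (
    Trajectory,
    kabsch_superpose,
    native_contacts,
    nc_fraction_series,
    radius_of_gyration_series,
    rmsd_series,
    rmsf_per_residue,
    hbond_count_series,
)
from unfoldkit.order_params import OrderParameterSeries
from unfoldkit.synthetic import _HELIX, _build_coords
from unfoldkit.topology import Atom, StructureModel

from conftest import static_trajectory


def quaternion_oracle_rmsd(ref, mob):
    """Independent optimal-superposition RMSD via scipy's quaternion solver."""
    ref_c = ref - ref.mean(0)
    mob_c = mob - mob.mean(0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return float(np.sqrt(((rot.apply(mob_c) - ref_c) ** 2).sum(1).mean()))


class TestKabsch:
    def test_identical_sets_rmsd_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        assert kabsch_superpose(X, X).rmsd < 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Y = X @ R.T + np.array([5.0, 5.0, 5.0])
        res = kabsch_superpose(X, Y)
        assert res.rmsd < 1e-9
        assert np.isclose(np.linalg.det(res.rotation), 1.0)

    def test_two_point_stretch_closed_form(self):
        # centered: ref at ±1, mobile at ±2 along x -> residual 1 per point
        ref = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        mob = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        res = kabsch_superpose(ref, mob)
        assert res.rmsd == pytest.approx(1.0, abs=1e-12)
        assert not res.unique  # collinear: rotation not unique

    def test_matches_quaternion_oracle_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            ref = rng.normal(size=(10, 3))
            mob = rng.normal(size=(10, 3))
            ours = kabsch_superpose(ref, mob).rmsd
            assert ours == pytest.approx(quaternion_oracle_rmsd(ref, mob),
                                         abs=1e-8)

    def test_reflection_corrected_proper_rotation(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3))
        mob = ref.copy()
        mob[:, 0] *= -1  # mirror image
        res = kabsch_superpose(ref, mob)
        assert np.isclose(np.linalg.det(res.rotation), 1.0)
        assert res.rmsd > 0.1  # a mirror cannot be superposed rigidly

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.empty((0, 3)), np.empty((0, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, toy):
        traj = static_trajectory(toy.model, toy.native.coords)
        s = rmsd_series(traj, 0, "calpha")
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_translated_frame_zero(self, toy):
        coords = np.stack(
            [toy.native.coords, toy.native.coords + np.array([3.0, -2.0, 7.0])]
        )
        traj = Trajectory(toy.model, coords)
        s = rmsd_series(traj, 0, "calpha")
        assert s.values[1] < 1e-9

    def test_matches_oracle_on_jittered_frames(self, native_traj, toy):
        sub = native_traj.slice_frames(0, 5)
        from unfoldkit.topology import select_atoms

        sel = select_atoms(toy.model, "calpha")
        s = rmsd_series(sub, toy.native.coords, "calpha")
        for f in range(5):
            oracle = quaternion_oracle_rmsd(
                toy.native.coords[sel], sub.coords[f][sel]
            )
            assert s.values[f] == pytest.approx(oracle, abs=1e-6)

    def test_empty_selection_rejected(self, toy, native_traj):
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(native_traj, 0, np.array([], dtype=int))


class TestRadiusOfGyration:
    def make_point_model(self, n):
        atoms = [
            Atom(serial=i + 1, name="CA", element="C", residue_index=i,
                 residue_name="ALA", mass=1.0, vdw_radius=1.7)
            for i in range(n)
        ]
        return StructureModel(atoms)

    def test_two_unit_masses_two_angstrom_apart(self):
        m = self.make_point_model(2)
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        s = radius_of_gyration_series(Trajectory(m, coords), "all")
        assert s.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_coincident_atoms_zero(self):
        m = self.make_point_model(4)
        coords = np.zeros((1, 4, 3))
        s = radius_of_gyration_series(Trajectory(m, coords), "all")
        assert s.values[0] == 0.0

    def test_unit_cube_corners(self):
        m = self.make_point_model(8)
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        s = radius_of_gyration_series(Trajectory(m, corners[None]), "all")
        assert s.values[0] == pytest.approx(np.sqrt(0.75), abs=1e-12)

    def test_rotation_invariance_without_alignment(self, toy):
        X = toy.native.coords
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        coords = np.stack([X, X @ R.T + 11.0])
        s = radius_of_gyration_series(Trajectory(toy.model, coords), "heavy")
        assert s.values[0] == pytest.approx(s.values[1], rel=1e-12)


class TestRmsf:
    def test_static_trajectory_zero(self, toy):
        traj = static_trajectory(toy.model, toy.native.coords, n_frames=4)
        assert np.allclose(rmsf_per_residue(traj, "calpha"), 0.0)

    def test_alternating_single_atom_displacement(self, toy):
        d = 0.7
        X = toy.native.coords
        ca0 = int(np.flatnonzero(
            [a.name == "CA" for a in toy.model.atoms])[0])
        plus, minus = X.copy(), X.copy()
        plus[ca0, 0] += d
        minus[ca0, 0] -= d
        coords = np.stack([plus, minus] * 5)
        traj = Trajectory(toy.model, coords)
        rmsf = rmsf_per_residue(traj, "calpha", align=False)
        assert rmsf[0] == pytest.approx(d, abs=1e-12)
        np.testing.assert_allclose(rmsf[1:], 0.0, atol=1e-12)

    def test_isotropic_jitter_gives_sigma_sqrt3(self, toy):
        sigma = 0.4
        rng = np.random.default_rng(7)
        base = toy.native.coords
        coords = base[None] + rng.normal(0, sigma, size=(10000, *base.shape))
        traj = Trajectory(toy.model, coords)
        rmsf = rmsf_per_residue(traj, "calpha", align=False)
        assert np.abs(rmsf.mean() - sigma * np.sqrt(3)) / (
            sigma * np.sqrt(3)
        ) < 0.05

    def test_single_frame_rejected(self, toy):
        traj = static_trajectory(toy.model, toy.native.coords, n_frames=1)
        with pytest.raises(ValueError):
            rmsf_per_residue(traj)


def two_residue_pair_model(distance):
    """Two single-heavy-atom residues `distance` Å apart, 3 residues apart
    in sequence (two spacer residues in between keep indices contiguous)."""
    atoms, coords = [], []
    positions = [
        (0, [0.0, 0.0, 0.0]),
        (1, [0.0, 50.0, 0.0]),
        (2, [0.0, 100.0, 0.0]),
        (3, [distance, 0.0, 0.0]),
    ]
    for serial, (res, xyz) in enumerate(positions, start=1):
        atoms.append(
            Atom(serial=serial, name="CA", element="C", residue_index=res,
                 residue_name="ALA")
        )
        coords.append(xyz)
    return StructureModel(atoms), np.array(coords)


class TestNativeContacts:
    @pytest.mark.parametrize(
        "distance,included", [(3.9, True), (4.0, True), (4.1, False)]
    )
    def test_four_angstrom_cutoff_boundary(self, distance, included):
        model, coords = two_residue_pair_model(distance)
        if included:
            nc = native_contacts(model, coords, cutoff=4.0,
                                 min_sequence_separation=3)
            assert nc.n_pairs == 1
        else:
            with pytest.raises(ValueError, match="no native contacts"):
                native_contacts(model, coords, cutoff=4.0,
                                min_sequence_separation=3)

    def test_extended_chain_has_no_contacts(self, templates, toy):
        with pytest.raises(ValueError, match="no native contacts"):
            native_contacts(toy.model, templates["unfolded"].coords,
                            min_sequence_separation=3)

    def test_pairs_stored_once_lower_index_first(self, toy):
        nc = native_contacts(toy.model, toy.native.coords)
        assert np.all(nc.pairs[:, 0] < nc.pairs[:, 1])
        assert len({tuple(p) for p in nc.pairs}) == nc.n_pairs

    def test_min_separation_respected(self, toy):
        nc = native_contacts(toy.model, toy.native.coords,
                             min_sequence_separation=3)
        res = toy.model.residue_of_atom
        sep = np.abs(res[nc.pairs[:, 0]] - res[nc.pairs[:, 1]])
        assert sep.min() >= 3


class TestNcFraction:
    def test_reference_frame_scores_exactly_one(self, toy):
        nc = native_contacts(toy.model, toy.native.coords)
        traj = static_trajectory(toy.model, toy.native.coords, n_frames=2)
        s = nc_fraction_series(traj, nc)
        assert np.all(s.values == 1.0)

    def test_everything_stretched_scores_zero(self, toy):
        nc = native_contacts(toy.model, toy.native.coords)
        traj = static_trajectory(toy.model, toy.native.coords * 3.0,
                                 n_frames=2)
        s = nc_fraction_series(traj, nc)
        assert np.all(s.values == 0.0)

    def test_partial_maintenance_counted_exactly(self):
        # 5 contact pairs; stretch 2 of them beyond cutoff -> 3/5
        atoms, coords = [], []
        serial = 1
        for r in range(10):
            atoms.append(Atom(serial=serial, name="CA", element="C",
                              residue_index=r, residue_name="ALA"))
            # residues r and r+5 are 3.0 Å apart in x for r < 5
            coords.append([3.0 * (r >= 5), 30.0 * (r % 5), 0.0])
            serial += 1
        model = StructureModel(atoms)
        X = np.array(coords, dtype=float)
        nc = native_contacts(model, X, cutoff=4.0, min_sequence_separation=3)
        assert nc.n_pairs == 5
        X2 = X.copy()
        moved = 0
        for i, j in nc.pairs:
            if moved == 2:
                break
            X2[j, 0] += 10.0
            moved += 1
        traj = Trajectory(model, X2[None])
        s = nc_fraction_series(traj, nc)
        assert s.values[0] == pytest.approx(0.6)

    def test_brute_force_equivalence_on_mixture(self, toy, two_state_traj):
        traj, _ = two_state_traj
        nc = native_contacts(toy.model, toy.native.coords)
        s = nc_fraction_series(traj, nc)
        # independent recomputation: plain loop over frames and pairs
        for f in range(0, traj.n_frames, 250):
            kept = 0
            for i, j in nc.pairs:
                if np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]) <= nc.cutoff:
                    kept += 1
            assert s.values[f] == pytest.approx(kept / nc.n_pairs, abs=1e-12)


class TestHbonds:
    def test_far_apart_counts_zero(self):
        model, coords = two_residue_pair_model(40.0)
        # add backbone O/N names so the routine has donors and acceptors
        atoms = []
        for r in range(4):
            for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                atoms.append(Atom(serial=len(atoms) + 1, name=nm, element=el,
                                  residue_index=r, residue_name="ALA"))
        m = StructureModel(atoms)
        X = np.arange(m.n_atoms * 3, dtype=float).reshape(-1, 3) * 20.0
        s = hbond_count_series(Trajectory(m, X[None]))
        assert s.values[0] == 0

    def test_constructed_linear_hbond_counts_one(self):
        # donor N-H...O acceptor at 2.9 Å, 180°, residues 2 apart
        atoms, coords = [], []
        geometry = {
            0: {"N": [0, 0, 0], "CA": [1.4, 0, 0], "C": [2.0, 1.3, 0],
                "O": [10.0, 10.0, 10.0], "H": [-1.01, 0, 0]},
            1: {"N": [50, 50, 50], "CA": [51.4, 50, 50], "C": [52, 51.3, 50],
                "O": [52, 52.5, 50]},
            2: {"N": [100, 0, 0], "CA": [101, 0, 0], "C": [102, 1, 0],
                "O": [-2.9, 0.0, 0.0]},  # N...O 2.9 Å, D-H...A 180°
        }
        for r, spec in geometry.items():
            for nm, xyz in spec.items():
                el = "H" if nm == "H" else nm[0]
                atoms.append(Atom(serial=len(atoms) + 1, name=nm, element=el,
                                  residue_index=r, residue_name="ALA"))
                coords.append(xyz)
        m = StructureModel(atoms)
        s = hbond_count_series(Trajectory(m, np.array(coords, float)[None]))
        assert s.values[0] == 1

    def test_ideal_helix_interior_bond_count(self):
        atoms, X = _build_coords(12, ["ALA"] * 12, [_HELIX] * 12, False)
        m = StructureModel(atoms)
        s = hbond_count_series(Trajectory(m, X[None]))
        # i -> i+4 donors for interior residues of a 12-mer: 8 ± 1
        assert 7 <= s.values[0] <= 9


class TestSeriesContainer:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            OrderParameterSeries("x", "u", np.ones(3), np.ones(4))

    def test_mean_sd_discard(self):
        s = OrderParameterSeries("x", "u", np.array([9.0, 9.0, 1.0, 3.0]),
                                 np.arange(4.0))
        mean, sd = s.mean_sd(0.5)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0))
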