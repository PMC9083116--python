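"""Topology construction, atom selection, and file round-trips."""

import numpy as np
import pytest

from unfoldkit import (
    Atom,
    StructureModel,
    Trajectory,
    read_grid,
    read_matrix,
    read_multimodel_pdb,
    read_series_csv,
    select_atoms,
    write_grid,
    write_matrix,
    write_multimodel_pdb,
    write_series_csv,
)
from unfoldkit.dccm import DCCMatrix
from unfoldkit.fel import FELGrid
from unfoldkit.io import PDBParseError
from unfoldkit.order_params import OrderParameterSeries


def tiny_model(n_residues=3, names=("N", "CA", "C", "O", "CB")):
    atoms = []
    serial = 1
    for r in range(n_residues):
        for nm in names:
            atoms.append(
                Atom(serial=serial, name=nm, element=nm[0],
                     residue_index=r, residue_name="ALA", residue_seq=r + 1)
            )
            serial += 1
    return StructureModel(atoms)


class TestStructureModel:
    def test_residue_spans_partition_atoms(self):
        m = tiny_model(4)
        covered = [i for r in range(4) for i in m.residue_atoms(r)]
        assert covered == list(range(m.n_atoms))

    def test_noncontiguous_residues_rejected(self):
        atoms = [
            Atom(serial=1, name="CA", element="C", residue_index=0,
                 residue_name="ALA"),
            Atom(serial=2, name="CA", element="C", residue_index=2,
                 residue_name="ALA"),
        ]
        with pytest.raises(ValueError, match="contiguous"):
            StructureModel(atoms)

    def test_backbone_atoms_are_heavy(self):
        m = tiny_model()
        for a in m.atoms:
            if a.is_backbone:
                assert a.is_heavy


class TestSelectAtoms:
    def test_calpha_one_per_residue(self):
        m = tiny_model(10)
        idx = select_atoms(m, "calpha")
        assert len(idx) == 10
        assert all(m.atoms[i].name == "CA" for i in idx)

    def test_heavy_excludes_hydrogens(self):
        atoms = [
            Atom(serial=1, name="N", element="N", residue_index=0,
                 residue_name="ALA"),
            Atom(serial=2, name="H", element="H", residue_index=0,
                 residue_name="ALA"),
            Atom(serial=3, name="CA", element="C", residue_index=0,
                 residue_name="ALA"),
        ]
        m = StructureModel(atoms)
        idx = select_atoms(m, "heavy")
        assert all(m.atoms[i].element != "H" for i in idx)
        assert len(idx) == 2

    def test_sidechain_of_tryptophan_has_ten_heavy_atoms(self, toy):
        # CB plus the nine indole ring atoms
        idx = select_atoms(toy.model, ("sidechain_of", toy.trp_residue))
        assert len(idx) == 10

    def test_glycine_sidechain_empty_with_warning(self, toy):
        with pytest.warns(UserWarning, match="no side-chain"):
            idx = select_atoms(toy.model, ("sidechain_of", toy.gly_residue))
        assert len(idx) == 0

    def test_selections_strictly_increasing(self, toy):
        for sel in ("calpha", "heavy", "backbone", "all"):
            idx = select_atoms(toy.model, sel)
            assert np.all(np.diff(idx) > 0)

    def test_selection_independent_of_serials(self):
        m1 = tiny_model(3)
        atoms2 = [
            Atom(serial=a.serial + 1000, name=a.name, element=a.element,
                 residue_index=a.residue_index, residue_name=a.residue_name)
            for a in m1.atoms
        ]
        m2 = StructureModel(atoms2)
        for sel in ("calpha", "heavy", "backbone"):
            assert np.array_equal(select_atoms(m1, sel), select_atoms(m2, sel))


class TestMultiModelPDB:
    def test_roundtrip_is_fixed_point(self, tmp_path, toy, native_traj):
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        short = native_traj.slice_frames(0, 3)
        write_multimodel_pdb(p1, short)
        model, traj = read_multimodel_pdb(p1)
        assert traj.n_frames == 3
        assert model.n_atoms == toy.model.n_atoms
        assert model.n_residues == toy.model.n_residues
        # PDB stores 3 decimals; a second round-trip is exact
        write_multimodel_pdb(p2, traj)
        _, traj2 = read_multimodel_pdb(p2)
        np.testing.assert_array_equal(traj.coords, traj2.coords)
        np.testing.assert_allclose(traj.coords, short.coords, atol=5e-4)

    def test_single_model_file_gives_one_frame(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.009   1.420   0.000"
            "  1.00  0.00           C\n"
            "ATOM      4  O   ALA A   1       1.251   2.390   0.000"
            "  1.00  0.00           O\n"
            "ATOM      5  CB  ALA A   1       2.000  -1.000   1.000"
            "  1.00  0.00           C\n"
            "END\n"
        )
        model, traj = read_multimodel_pdb(pdb)
        assert traj.n_frames == 1
        assert model.n_atoms == 5

    def test_atom_count_mismatch_names_model(self, tmp_path):
        line = ("ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
                "  1.00  0.00           C\n")
        pdb = tmp_path / "bad.pdb"
        pdb.write_text(
            "MODEL        1\n" + line + line.replace(" 1 ", " 2 ")
            + "ENDMDL\nMODEL        2\n" + line + "ENDMDL\nEND\n"
        )
        with pytest.raises(PDBParseError, match="model 2"):
            read_multimodel_pdb(pdb)

    def test_unparseable_record_reports_line_number(self, tmp_path):
        pdb = tmp_path / "junk.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      X  CA  ALA A   2  garbage\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_multimodel_pdb(pdb)


class TestTabularRoundtrips:
    def test_series_roundtrip_exact(self, tmp_path):
        s = OrderParameterSeries(
            "rg", "angstrom",
            np.array([1.0 / 3.0, 2.0 / 7.0, np.pi]),
            np.array([0.0, 1.0, 2.0]),
        )
        path = tmp_path / "s.csv"
        write_series_csv(path, s)
        s2 = read_series_csv(path)
        np.testing.assert_array_equal(s2.values, s.values)
        assert s2.name == "rg" and s2.units == "angstrom"

    def test_grid_roundtrip_preserves_mask_and_values(self, tmp_path):
        F = np.array([[0.0, 1.5], [0.0, 2.0 / 3.0]])
        mask = np.array([[False, False], [True, False]])
        g = FELGrid(
            x_name="nc", y_name="rmsd",
            x_edges=np.array([0.0, 0.5, 1.0]),
            y_edges=np.array([0.0, 1.0, 2.0]),
            F=F, mask=mask, RT=0.59616, n_frames=1000,
        )
        path = tmp_path / "g.dat"
        write_grid(path, g)
        g2 = read_grid(path)
        np.testing.assert_array_equal(g2.mask, mask)
        np.testing.assert_array_equal(g2.F[~mask], F[~mask])
        np.testing.assert_array_equal(g2.x_edges, g.x_edges)
        assert g2.RT == g.RT and g2.n_frames == 1000

    def test_matrix_roundtrip_preserves_symmetry(self, tmp_path):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5))
        C = (A + A.T) / 2
        np.fill_diagonal(C, 1.0)
        m = DCCMatrix(values=C, window=(0, 100),
                      labels=[f"ALA{i}" for i in range(5)])
        path = tmp_path / "m.csv"
        write_matrix(path, m)
        m2 = read_matrix(path)
        np.testing.assert_array_equal(m2.values, C)
        assert m2.window == (0, 100)
        np.testing.assert_array_equal(m2.values, m2.values.T)

    def test_trajectory_times_must_increase(self, toy):
        coords = np.repeat(toy.native.coords[None], 3, axis=0)
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory(toy.model, coords, times=np.array([0.0, 2.0, 1.0]))
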