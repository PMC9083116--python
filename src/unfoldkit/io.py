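"""Reading and writing of trajectories and analysis outputs.

Trajectories enter as multi-model PDB files: one fixed topology taken from
the first MODEL, every later MODEL supplying a new coordinate frame.
Analysis outputs leave as plain text: per-frame series as CSV, free-energy
grids as a commented-header matrix with ``NA`` for unvisited bins, and
residue-residue matrices as CSV with residue labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .topology import Atom, StructureModel, element_from_name
from .trajectory import Trajectory

__all__ = [
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "write_series_csv",
    "read_series_csv",
    "write_grid",
    "read_grid",
    "write_matrix",
    "read_matrix",
]


class PDBParseError(ValueError):
    """Malformed or internally inconsistent PDB input."""


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_seq = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = element_from_name(name)
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"unparseable ATOM/HETATM record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    atom = Atom(
        serial=serial,
        name=name,
        element=element.capitalize() if len(element) > 1 else element,
        residue_index=-1,  # assigned after the full first model is read
        residue_name=res_name,
        chain_id=chain_id,
        residue_seq=res_seq,
    )
    return atom, xyz


def read_multimodel_pdb(
    path, temperature_label: float = 300.0
) -> tuple[StructureModel, Trajectory]:
    """Read a (multi-)model PDB file into a topology and a trajectory.

    The topology is built from the first model; every subsequent MODEL must
    contain exactly the same number of ATOM/HETATM records, mapped onto the
    fixed topology in record order.  Coordinates are Å (PDB native).
    A file without MODEL records is a one-frame trajectory.

    Raises
    ------
    PDBParseError
        On an unparseable ATOM record (with its line number) or an atom
        count that changes between models (naming the offending model).
    """
    frames: list[list[np.ndarray]] = []
    raw_atoms: list[Atom] = []
    current: list[np.ndarray] | None = None
    model_numbers: list[int] = []
    in_first = True

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                if current is not None:
                    frames.append(current)
                    in_first = False
                try:
                    model_numbers.append(int(line.split()[1]))
                except (IndexError, ValueError):
                    model_numbers.append(len(frames) + 1)
                current = []
            elif record in ("ATOM  ", "HETATM"):
                atom, xyz = _parse_atom_record(line, lineno)
                if current is None:  # file without MODEL records
                    current = []
                    model_numbers.append(1)
                if in_first:
                    raw_atoms.append(atom)
                current.append(xyz)
            elif record.startswith(("ENDMDL", "END")):
                continue
    if current is not None:
        frames.append(current)

    if not frames or not raw_atoms:
        raise PDBParseError(f"no ATOM records found in {path}")

    n_atoms = len(raw_atoms)
    for k, frame in enumerate(frames):
        if len(frame) != n_atoms:
            raise PDBParseError(
                f"model {model_numbers[k]} has {len(frame)} atoms, "
                f"expected {n_atoms} (from model {model_numbers[0]})"
            )

    # Contiguous 0-based residue indices from (chain, resSeq) transitions.
    atoms: list[Atom] = []
    res_idx = -1
    prev_key = None
    for a in raw_atoms:
        key = (a.chain_id, a.residue_seq)
        if key != prev_key:
            res_idx += 1
            prev_key = key
        atoms.append(
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_index=res_idx,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                residue_seq=a.residue_seq,
            )
        )

    model = StructureModel(atoms)
    coords = np.array(frames)
    traj = Trajectory(model, coords, temperature_label=temperature_label)
    return model, traj


def write_multimodel_pdb(path, traj: Trajectory) -> None:
    """Write a trajectory as sequential MODEL records over its topology."""
    model = traj.model
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:8d}\n")
            for i, atom in enumerate(model.atoms):
                x, y, z = traj.coords[f, i]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                seq = atom.residue_seq if atom.residue_seq is not None else (
                    atom.residue_index + 1
                )
                fh.write(
                    f"ATOM  {atom.serial % 100000:5d} {name}"
                    f"{atom.residue_name:>4s} {atom.chain_id}{seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# tabular / grid persistence
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_series_csv(path, series) -> None:
    """Write an order-parameter series as CSV (time_ps, value).

    Name and units go into a ``#`` comment header so the file is
    self-describing.
    """
    with open(path, "w") as fh:
        fh.write(f"# name: {series.name}\n# units: {series.units}\n")
        fh.write("time_ps,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{_FLOAT_FMT % t},{_FLOAT_FMT % v}\n")


def read_series_csv(path):
    """Read a series CSV written by :func:`write_series_csv`."""
    from .order_params import OrderParameterSeries

    name, units = "", ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# name:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("# units:"):
                units = line.split(":", 1)[1].strip()
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return OrderParameterSeries(
        name=name,
        units=units,
        values=df["value"].to_numpy(),
        times=df["time_ps"].to_numpy(),
    )


def write_grid(path, grid) -> None:
    """Write a 2-D free-energy grid: commented header + row-major F matrix.

    Masked (unvisited) bins are written as ``NA``.
    """
    with open(path, "w") as fh:
        fh.write(f"# x_name: {grid.x_name}\n")
        fh.write(f"# y_name: {grid.y_name}\n")
        fh.write(f"# RT_kcal_mol: {_FLOAT_FMT % grid.RT}\n")
        fh.write(f"# n_frames: {grid.n_frames}\n")
        fh.write("# x_edges: " + " ".join(_FLOAT_FMT % e for e in grid.x_edges) + "\n")
        fh.write("# y_edges: " + " ".join(_FLOAT_FMT % e for e in grid.y_edges) + "\n")
        for i in range(grid.F.shape[0]):
            row = [
                "NA" if grid.mask[i, j] else _FLOAT_FMT % grid.F[i, j]
                for j in range(grid.F.shape[1])
            ]
            fh.write(" ".join(row) + "\n")


def read_grid(path):
    """Read a grid file written by :func:`write_grid`."""
    from .fel import FELGrid

    header: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            elif line.strip():
                rows.append(line.split())
    F = np.array(
        [[np.nan if tok == "NA" else float(tok) for tok in row] for row in rows]
    )
    mask = np.isnan(F)
    F = np.where(mask, 0.0, F)
    return FELGrid(
        x_name=header["x_name"],
        y_name=header["y_name"],
        x_edges=np.array([float(t) for t in header["x_edges"].split()]),
        y_edges=np.array([float(t) for t in header["y_edges"].split()]),
        F=F,
        mask=mask,
        RT=float(header["RT_kcal_mol"]),
        n_frames=int(header["n_frames"]),
    )


def write_matrix(path, matrix) -> None:
    """Write a residue-residue correlation matrix as labelled CSV."""
    n = matrix.values.shape[0]
    labels = matrix.labels if matrix.labels is not None else [
        f"res{i}" for i in range(n)
    ]
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(f"# window: {matrix.window[0]} {matrix.window[1]}\n")
        df.to_csv(fh, float_format=_FLOAT_FMT)


def read_matrix(path):
    """Read a matrix CSV written by :func:`write_matrix`."""
    from .dccm import DCCMatrix

    with open(path) as fh:
        first = fh.readline()
    window = (0, 0)
    if first.startswith("# window:"):
        parts = first.split(":", 1)[1].split()
        window = (int(parts[0]), int(parts[1]))
    df = pd.read_csv(path, comment="#", index_col=0,
                     float_precision="round_trip")
    return DCCMatrix(
        values=df.to_numpy(), window=window, labels=list(df.index)
    )
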