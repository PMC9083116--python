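"""Fixed protein topology: atoms, residues, and atom selection.

A :class:`StructureModel` is an ordered list of atoms grouped into
contiguous residues.  It carries everything the analyses need that is not
a coordinate: element, van der Waals radius, mass, and backbone/side-chain
flags.  Coordinates live in :class:`~unfoldkit.trajectory.Trajectory`
frames, always in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "BACKBONE_NAMES",
    "select_atoms",
]

#: Per-element van der Waals radii in Å, applied uniformly (Bondi-style).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

#: Per-element atomic masses in u.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "H": 1.008,
}

#: Backbone atom names of a peptide chain.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_DEFAULT_RADIUS = 1.70
_DEFAULT_MASS = 12.011


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Standard PDB convention: the element occupies columns 13-14 of the atom
    name field; for protein heavy atoms the first alphabetic character that
    is not a digit identifies the element (CA -> C, NE1 -> N, 1HB -> H).
    """
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return "H" if ch in ("H", "D") else ch
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class Atom:
    """One atom of the fixed topology.

    ``residue_index`` is 0-based and contiguous internally; the original
    file numbering is kept in ``residue_seq`` for reporting.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str = "A"
    residue_seq: int | None = None
    vdw_radius: float = field(default=0.0)
    mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.vdw_radius == 0.0:
            object.__setattr__(
                self, "vdw_radius", VDW_RADII.get(self.element, _DEFAULT_RADIUS)
            )
        if self.mass == 0.0:
            object.__setattr__(
                self, "mass", ATOMIC_MASSES.get(self.element, _DEFAULT_MASS)
            )
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class StructureModel:
    """Ordered atoms partitioned into contiguous residues.

    Parameters
    ----------
    atoms
        Atom records in file order.  Residue indices must be non-decreasing
        and contiguous (0, 0, 1, 1, 2, ...); every atom belongs to exactly
        one residue.
    """

    def __init__(self, atoms: list[Atom]):
        if not atoms:
            raise ValueError("StructureModel requires at least one atom")
        self.atoms = list(atoms)
        indices = [a.residue_index for a in self.atoms]
        uniq = sorted(set(indices))
        if uniq != list(range(len(uniq))):
            raise ValueError("residue indices must be contiguous from 0")
        if any(b < a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be non-decreasing in atom order")
        self.n_residues = len(uniq)
        # residue -> (start, stop) atom index range
        self.residue_spans: list[tuple[int, int]] = []
        start = 0
        for r in range(self.n_residues):
            stop = start
            while stop < len(self.atoms) and self.atoms[stop].residue_index == r:
                stop += 1
            self.residue_spans.append((start, stop))
            start = stop

        self.radii = np.array([a.vdw_radius for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms])
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms])
        self.residue_of_atom = np.array(indices, dtype=np.intp)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_name(self, residue_index: int) -> str:
        start, _ = self.residue_spans[residue_index]
        return self.atoms[start].residue_name

    def residue_atoms(self, residue_index: int) -> range:
        start, stop = self.residue_spans[residue_index]
        return range(start, stop)

    def atom_index(self, residue_index: int, name: str) -> int | None:
        """Index of the named atom in a residue, or None if absent."""
        for i in self.residue_atoms(residue_index):
            if self.atoms[i].name == name:
                return i
        return None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StructureModel {self.n_atoms} atoms, {self.n_residues} residues>"
        )


def select_atoms(model: StructureModel, selector: str | tuple) -> np.ndarray:
    """Resolve an atom selector to a strictly increasing index array.

    Selectors
    ---------
    ``"calpha"``
        One CA atom per residue that has one.
    ``"heavy"``
        Every non-hydrogen atom.
    ``"backbone"``
        Backbone heavy atoms N, CA, C, O.
    ``"all"``
        Every atom.
    ``("sidechain_of", residue_index)``
        Heavy side-chain atoms of one residue.  Glycine yields an empty
        selection with a warning (it has no side-chain heavy atoms).
    """
    if selector == "calpha":
        idx = [
            i
            for r in range(model.n_residues)
            for i in model.residue_atoms(r)
            if model.atoms[i].name == "CA"
        ]
    elif selector == "heavy":
        idx = [i for i, a in enumerate(model.atoms) if a.is_heavy]
    elif selector == "backbone":
        idx = [i for i, a in enumerate(model.atoms) if a.is_backbone]
    elif selector == "all":
        idx = list(range(model.n_atoms))
    elif (
        isinstance(selector, tuple)
        and len(selector) == 2
        and selector[0] == "sidechain_of"
    ):
        residue_index = selector[1]
        if not 0 <= residue_index < model.n_residues:
            raise IndexError(
                f"residue_index {residue_index} out of range "
                f"(0..{model.n_residues - 1})"
            )
        idx = [
            i
            for i in model.residue_atoms(residue_index)
            if model.atoms[i].is_heavy and not model.atoms[i].is_backbone
        ]
        if not idx:
            warnings.warn(
                f"residue {residue_index} "
                f"({model.residue_name(residue_index)}) has no side-chain "
                "heavy atoms; empty selection",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return np.asarray(idx, dtype=np.intp)
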