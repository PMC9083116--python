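"""Synthetic multi-state unfolding trajectories with known ground truth.

Real thermal-unfolding trajectories interconvert among a native state,
partially unfolded intermediates and an expanded unfolded state.  This
module emulates exactly that statistical structure — and nothing more —
so every analysis stage can be verified against known populations:

* a deterministic toy protein (one α-helix packed against a β-hairpin,
  built from ideal backbone dihedrals) stands in for a small α/β domain;
* an *intermediate* template unwinds the helix but keeps the hairpin,
  retaining roughly half the native contacts; an *unfolded* template is a
  fully extended chain that breaks every long-range contact;
* frames follow a Markov chain over the templates with prescribed
  stationary occupancies, plus i.i.d. Gaussian coordinate jitter.

No physics is simulated: temperature labels are labels, and the
occupancy schedule is the ground truth that recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Atom, StructureModel
from .trajectory import Trajectory

__all__ = [
    "ConformerTemplate",
    "ToyProtein",
    "SyntheticConfig",
    "DEFAULT_SCHEDULE",
    "make_toy_protein",
    "make_templates",
    "simulate_trajectory",
    "thermal_series",
]

# ideal peptide internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

_HELIX = (-57.0, -47.0)
_STRAND = (-139.0, 135.0)
#: β-hairpin connecting turn: two-residue turn whose dihedrals were chosen
#: (by a one-off deterministic grid search over turn space) to maximise
#: cross-strand Kabsch-Sander H-bonds of the flanking antiparallel strands
_TURN = [(90.0, -90.0), (-150.0, 30.0)]
#: extended loop joining the helix C-terminus to the sheet, directing the
#: helix away from the hairpin so segments stay sterically clean
_LOOP = [(-139.0, 135.0), (-139.0, 135.0)]
#: CB tilt out of the backbone plane (degrees); larger values push side
#: chains off the sheet faces and avoid cross-strand CB collisions
_CB_TILT_DEG = 60.0

# idealised indole ring, 2-D coordinates relative to CG in the ring plane
_INDOLE_2D = {
    "CG": (0.00, 0.00),
    "CD1": (1.09, 0.85),
    "NE1": (0.69, 2.15),
    "CE2": (-0.71, 2.16),
    "CD2": (-1.15, 0.82),
    "CE3": (-2.48, 0.40),
    "CZ3": (-3.43, 1.35),
    "CZ2": (-1.66, 3.10),
    "CH2": (-3.02, 2.68),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next chain atom D from A-B-C via bond length, angle B-C-D, torsion A-B-C-D."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phipsi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with given (φ, ψ) per residue."""
    n_res = len(phipsi)
    res: list[dict[str, np.ndarray]] = [dict() for _ in range(n_res)]
    theta0 = np.deg2rad(_A_N_CA_C)
    res[0]["N"] = np.zeros(3)
    res[0]["CA"] = np.array([_B_N_CA, 0.0, 0.0])
    res[0]["C"] = res[0]["CA"] + _B_CA_C * np.array(
        [-np.cos(theta0), np.sin(theta0), 0.0]
    )
    for i in range(1, n_res):
        psi_prev = phipsi[i - 1][1]
        res[i]["N"] = _place(
            res[i - 1]["N"], res[i - 1]["CA"], res[i - 1]["C"],
            _B_C_N, _A_CA_C_N, psi_prev,
        )
        res[i]["CA"] = _place(
            res[i - 1]["CA"], res[i - 1]["C"], res[i]["N"],
            _B_N_CA, _A_C_N_CA, 180.0,
        )
        res[i]["C"] = _place(
            res[i - 1]["C"], res[i]["N"], res[i]["CA"],
            _B_CA_C, _A_N_CA_C, phipsi[i][0],
        )
    for i in range(n_res):
        psi = phipsi[i][1]
        res[i]["O"] = _place(
            res[i]["N"], res[i]["CA"], res[i]["C"],
            _B_C_O, _A_CA_C_O, psi + 180.0,
        )
    return res


def _sidechain_frame(bb: dict[str, np.ndarray]):
    """CB position and an orthonormal ring frame from one residue's backbone.

    CB points away from the N/C bisector, tilted ``_CB_TILT_DEG`` out of
    the backbone plane; the ring plane of a bulky side chain is spanned by
    the local chain direction (e1) and the CB direction (e2), so rings
    extend along the strand rather than into a paired strand.
    """
    b1 = bb["N"] - bb["CA"]
    b1 /= np.linalg.norm(b1)
    b2 = bb["C"] - bb["CA"]
    b2 /= np.linalg.norm(b2)
    bisector = b1 + b2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    tilt = np.deg2rad(_CB_TILT_DEG)
    direction = -bisector * np.cos(tilt) + perp * np.sin(tilt)
    direction /= np.linalg.norm(direction)
    cb = bb["CA"] + _B_CA_CB * direction
    e2 = direction
    chain = bb["C"] - bb["N"]
    chain = chain - (chain @ e2) * e2
    e1 = chain / np.linalg.norm(chain)
    return cb, e1, e2


@dataclass(frozen=True)
class ConformerTemplate:
    """One reference conformation of the toy topology."""

    label: str                       # native | intermediate | unfolded
    coords: np.ndarray = field(repr=False)
    description: str = ""


@dataclass
class ToyProtein:
    """Toy topology plus native template and the layout that built it."""

    model: StructureModel
    native: ConformerTemplate
    helix: tuple[int, int]           # [start, stop) residue ranges
    strand1: tuple[int, int]
    turn: tuple[int, int]
    strand2: tuple[int, int]
    loop: tuple[int, int]
    trp_residue: int
    gly_residue: int
    phipsi: list[tuple[float, float]]
    with_sidechains: bool


def _layout(n_residues: int):
    # helix ~27% of the non-loop residues: balances helix-internal vs
    # cross-strand contact counts so the intermediate retains about half
    loop_len, turn_len = 2, 2
    remaining = n_residues - loop_len - turn_len
    helix_len = min(max(6, round(0.27 * remaining)), remaining - 4)
    strand_total = remaining - helix_len
    s1 = strand_total // 2 + strand_total % 2
    s2 = strand_total // 2
    helix = (0, helix_len)
    loop = (helix_len, helix_len + loop_len)
    strand1 = (loop[1], loop[1] + s1)
    turn = (strand1[1], strand1[1] + turn_len)
    strand2 = (turn[1], turn[1] + s2)
    return helix, loop, strand1, turn, strand2


def _phipsi_for(n_residues: int, unwind_helix: bool, fully_extended: bool):
    helix, loop, strand1, turn, strand2 = _layout(n_residues)
    phipsi = []
    for r in range(n_residues):
        if fully_extended:
            phipsi.append(_STRAND)
        elif helix[0] <= r < helix[1]:
            phipsi.append(_STRAND if unwind_helix else _HELIX)
        elif loop[0] <= r < loop[1]:
            phipsi.append(_STRAND if unwind_helix else _LOOP[r - loop[0]])
        elif turn[0] <= r < turn[1]:
            phipsi.append(_TURN[r - turn[0]])
        else:
            phipsi.append(_STRAND)
    return phipsi


def _build_coords(
    n_residues: int,
    residue_names: list[str],
    phipsi: list[tuple[float, float]],
    with_sidechains: bool,
) -> tuple[list[Atom], np.ndarray]:
    bb = _build_backbone(phipsi)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for r in range(n_residues):
        name3 = residue_names[r]
        for atom_name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(serial=serial, name=atom_name,
                     element=atom_name[0], residue_index=r,
                     residue_name=name3, residue_seq=r + 1)
            )
            coords.append(bb[r][atom_name])
            serial += 1
        if with_sidechains and name3 != "GLY":
            cb, e1, e2 = _sidechain_frame(bb[r])
            atoms.append(
                Atom(serial=serial, name="CB", element="C",
                     residue_index=r, residue_name=name3, residue_seq=r + 1)
            )
            coords.append(cb)
            serial += 1
            if name3 == "TRP":
                cg_origin = cb + 1.5 * e2
                for ring_name, (x, y) in _INDOLE_2D.items():
                    atoms.append(
                        Atom(serial=serial, name=ring_name,
                             element=ring_name[0], residue_index=r,
                             residue_name=name3, residue_seq=r + 1)
                    )
                    coords.append(cg_origin + x * e1 + y * e2)
                    serial += 1
    return atoms, np.array(coords)


def make_toy_protein(
    n_residues: int = 30, with_sidechains: bool = True
) -> ToyProtein:
    """Deterministic toy α/β protein: one helix packed against a β-hairpin.

    Consecutive Cα-Cα distances are 3.8 ± 0.1 Å (ideal peptide geometry);
    the helix supplies H codes and i→i+4 H-bonds, the hairpin supplies E
    codes and long-range cross-strand contacts.  One strand residue is a
    tryptophan (bulky side chain for SASA tracking) and one loop residue
    is a glycine (no side-chain heavy atoms).
    """
    if not 12 <= n_residues <= 80:
        raise ValueError("n_residues must be in [12, 80]")
    helix, loop, strand1, turn, strand2 = _layout(n_residues)
    names = ["ALA"] * n_residues
    gly = loop[0]
    # even offset from the strand start puts the indole on the sheet-facing
    # side, so native/intermediate occlude it and unfolding exposes it
    offset = (strand1[1] - strand1[0]) // 2
    offset += offset % 2
    trp = min(strand1[0] + offset, strand1[1] - 1)
    names[gly] = "GLY"
    names[trp] = "TRP"
    phipsi = _phipsi_for(n_residues, unwind_helix=False, fully_extended=False)
    atoms, coords = _build_coords(n_residues, names, phipsi, with_sidechains)
    model = StructureModel(atoms)
    native = ConformerTemplate(
        label="native", coords=coords,
        description="helix + hairpin fold; defines the native contact set",
    )
    return ToyProtein(
        model=model, native=native, helix=helix, strand1=strand1,
        turn=turn, strand2=strand2, loop=loop, trp_residue=trp,
        gly_residue=gly, phipsi=phipsi, with_sidechains=with_sidechains,
    )


def make_templates(toy: ToyProtein) -> dict[str, ConformerTemplate]:
    """Native, intermediate and unfolded templates on the toy topology.

    The intermediate unwinds the helix to an extended arm while the
    hairpin keeps its exact native geometry, so it retains the hairpin's
    share of the native contacts (~half by construction).  The unfolded
    template is the fully extended chain: every contact at sequence
    separation ≥ 3 is broken by a wide margin.  Rg is strictly ordered
    native < intermediate < unfolded.
    """
    n = toy.model.n_residues
    names = [toy.model.residue_name(r) for r in range(n)]
    out = {"native": toy.native}
    for label, kwargs in (
        ("intermediate", dict(unwind_helix=True, fully_extended=False)),
        ("unfolded", dict(unwind_helix=False, fully_extended=True)),
    ):
        phipsi = _phipsi_for(n, **kwargs)
        _, coords = _build_coords(n, names, phipsi, toy.with_sidechains)
        out[label] = ConformerTemplate(
            label=label, coords=coords,
            description=(
                "helix unwound, hairpin intact" if label == "intermediate"
                else "fully extended chain, all long-range contacts broken"
            ),
        )
    return out


#: Default thermal-ladder occupancy schedule: occupancy mass moves
#: native → intermediate → unfolded as temperature rises, emulating
#: progressive thermal unfolding across a 300-500 K ladder.
DEFAULT_SCHEDULE: dict[float, dict[str, float]] = {
    300.0: {"native": 1.0},
    350.0: {"native": 0.80, "intermediate": 0.20},
    400.0: {"native": 0.40, "intermediate": 0.50, "unfolded": 0.10},
    450.0: {"native": 0.05, "intermediate": 0.35, "unfolded": 0.60},
    500.0: {"intermediate": 0.05, "unfolded": 0.95},
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; a fixed seed gives bit-identical output."""

    n_residues: int = 30
    n_frames: int = 2000
    occupancies: dict[str, float] = field(
        default_factory=lambda: {"native": 1.0}
    )
    jitter_sigma: float = 0.3        # Å per coordinate
    dwell: float = 25.0              # mean frames between switching events
    temperature_label: float = 300.0
    seed: int = 0
    dt_ps: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.occupancies.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.occupancies.values()):
            raise ValueError("occupancies must be non-negative and sum to 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.dwell < 1:
            raise ValueError("dwell must be >= 1 frame")


def simulate_trajectory(
    config: SyntheticConfig,
    toy: ToyProtein | None = None,
    templates: dict[str, ConformerTemplate] | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Markov-switching trajectory over conformer templates plus jitter.

    The hidden state resamples from the occupancy distribution with
    probability 1/dwell each frame (else it stays), which makes the
    occupancies the exact stationary distribution.  Each frame is its
    template plus i.i.d. Gaussian noise of sd ``jitter_sigma`` per
    coordinate.  Returns the trajectory and the ground-truth state path
    so recovery tests never re-infer it from coordinates.
    """
    if toy is None:
        toy = make_toy_protein(config.n_residues)
    if templates is None:
        templates = make_templates(toy)
    for label in config.occupancies:
        if label not in templates:
            raise ValueError(f"occupancy given for unbuilt template {label!r}")

    labels = sorted(config.occupancies)
    probs = np.array([config.occupancies[k] for k in labels])
    rng = np.random.default_rng(config.seed)

    states = np.empty(config.n_frames, dtype=object)
    state = labels[rng.choice(len(labels), p=probs)]
    p_switch = 1.0 / config.dwell
    for f in range(config.n_frames):
        if f > 0 and rng.random() < p_switch:
            state = labels[rng.choice(len(labels), p=probs)]
        states[f] = state

    n_atoms = toy.model.n_atoms
    coords = np.empty((config.n_frames, n_atoms, 3))
    for f in range(config.n_frames):
        coords[f] = templates[states[f]].coords
    if config.jitter_sigma > 0:
        coords += rng.normal(0.0, config.jitter_sigma, size=coords.shape)

    times = np.arange(config.n_frames, dtype=float) * config.dt_ps
    traj = Trajectory(toy.model, coords, times, config.temperature_label)
    return traj, states.astype(str)


def thermal_series(
    base: SyntheticConfig,
    schedule: dict[float, dict[str, float]] | None = None,
    toy: ToyProtein | None = None,
) -> list[tuple[Trajectory, np.ndarray]]:
    """One synthetic trajectory per temperature of an unfolding ladder.

    ``schedule`` maps temperature label (K) → occupancies; the default
    moves population native → intermediate → unfolded with temperature.
    Per-temperature seeds are derived deterministically from the base
    seed, so a fixed seed reproduces the whole ladder.
    """
    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    if toy is None:
        toy = make_toy_protein(base.n_residues)
    templates = make_templates(toy)
    ss = np.random.SeedSequence(base.seed)
    children = ss.spawn(len(schedule))
    out = []
    for child, (temp, occ) in zip(children, sorted(schedule.items())):
        config = SyntheticConfig(
            n_residues=base.n_residues,
            n_frames=base.n_frames,
            occupancies=dict(occ),
            jitter_sigma=base.jitter_sigma,
            dwell=base.dwell,
            temperature_label=temp,
            seed=int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)),
            dt_ps=base.dt_ps,
        )
        out.append(simulate_trajectory(config, toy=toy, templates=templates))
    return out
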