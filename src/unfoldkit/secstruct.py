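"""Per-residue secondary-structure assignment (simplified Kabsch-Sander).

Backbone hydrogen bonds are scored with the classic electrostatic model

    E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol, r in Å]

and declared below −0.5 kcal/mol.  Helices come from runs of i→i+3/4/5
turns, strands from parallel/antiparallel bridge patterns, plus turn (T)
and bend (S) assignments.  This is a simplified re-implementation of the
DSSP scheme: no β-bulges, no chirality-based disambiguation — adequate
for the coarse helix/strand/turn/bend/coil categories an unfolding
timeline tracks.

Code legend: H α-helix, G 3₁₀-helix, I π-helix, E extended strand,
B isolated β-bridge, T turn, S bend, C coil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .topology import StructureModel
from .trajectory import Trajectory

__all__ = [
    "SS_CODES",
    "SS_LEGEND",
    "SSTimeline",
    "backbone_hbond_energy",
    "assign_frame",
    "ss_timeline",
    "ss_content_series",
]

SS_CODES = "HGIEBTSC"
SS_LEGEND = {
    "H": "alpha-helix",
    "G": "3-10 helix",
    "I": "pi-helix",
    "E": "extended strand",
    "B": "isolated beta-bridge",
    "T": "turn",
    "S": "bend",
    "C": "coil",
}

_COUPLING = 27.888      # q1*q2*f in kcal·Å/mol
_BOND_CUTOFF = -0.5     # kcal/mol
_E_MIN = -9.9           # clamp for near-contact geometries
_NH_BOND = 1.01         # Å, reconstructed amide H distance from N


@dataclass
class SSTimeline:
    """Secondary-structure codes per frame per residue."""

    codes: np.ndarray           # (n_frames, n_residues) of single chars
    legend: dict[str, str]

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.codes.shape[1]


def backbone_hbond_energy(donor: dict, acceptor: dict) -> tuple[float, bool]:
    """Kabsch-Sander electrostatic H-bond energy between two backbones.

    ``donor`` must supply N and H coordinates (reconstruct H first if the
    structure has none); ``acceptor`` must supply C and O.  Returns
    (energy kcal/mol, bonded) with bonded = energy < −0.5.  A missing
    backbone atom yields (0, False) with a warning rather than a crash.
    """
    try:
        n, h = np.asarray(donor["N"]), np.asarray(donor["H"])
        c, o = np.asarray(acceptor["C"]), np.asarray(acceptor["O"])
    except KeyError as exc:
        warnings.warn(f"missing backbone atom {exc}; no bond", stacklevel=2)
        return 0.0, False
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return _E_MIN, True
    e = _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    e = max(e, _E_MIN)
    return float(e), e < _BOND_CUTOFF


def _backbone_arrays(model: StructureModel):
    """Per-residue backbone atom indices; -1 where an atom is missing."""
    idx = {}
    for name in ("N", "CA", "C", "O"):
        idx[name] = np.array(
            [
                (model.atom_index(r, name) if model.atom_index(r, name) is not None else -1)
                for r in range(model.n_residues)
            ],
            dtype=np.intp,
        )
    idx["H"] = np.array(
        [
            next(
                (model.atom_index(r, nm) for nm in ("H", "HN")
                 if model.atom_index(r, nm) is not None),
                -1,
            )
            for r in range(model.n_residues)
        ],
        dtype=np.intp,
    )
    return idx


def _hbond_matrix(model: StructureModel, coords: np.ndarray,
                  bb: dict) -> np.ndarray:
    """hb[d, a] True when N-H of residue d bonds to C=O of residue a."""
    n_res = model.n_residues
    complete = (bb["N"] >= 0) & (bb["CA"] >= 0) & (bb["C"] >= 0) & (bb["O"] >= 0)

    N = np.where(complete[:, None], coords[bb["N"]], np.nan)
    C = np.where(complete[:, None], coords[bb["C"]], np.nan)
    O = np.where(complete[:, None], coords[bb["O"]], np.nan)

    # Amide H: from topology when present, else 1.01 Å from N opposite the
    # carbonyl O of the preceding residue.  Residue 0 has no donor H.
    H = np.full((n_res, 3), np.nan)
    for r in range(n_res):
        if not complete[r]:
            continue
        if bb["H"][r] >= 0:
            H[r] = coords[bb["H"][r]]
        elif r > 0 and complete[r - 1]:
            direction = C[r - 1] - O[r - 1]
            nrm = np.linalg.norm(direction)
            if nrm > 1e-9:
                H[r] = N[r] + _NH_BOND * direction / nrm

    donor_ok = complete & ~np.isnan(H).any(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_on = np.linalg.norm(N[:, None, :] - O[None, :, :], axis=2)
        r_ch = np.linalg.norm(H[:, None, :] - C[None, :, :], axis=2)
        r_oh = np.linalg.norm(H[:, None, :] - O[None, :, :], axis=2)
        r_cn = np.linalg.norm(N[:, None, :] - C[None, :, :], axis=2)
        E = _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        too_close = np.fmin(np.fmin(r_on, r_ch), np.fmin(r_oh, r_cn)) < 0.5
        E = np.where(too_close, _E_MIN, E)
        E = np.where(np.isnan(E), 0.0, np.maximum(E, _E_MIN))

    hb = E < _BOND_CUTOFF
    hb &= donor_ok[:, None] & complete[None, :]
    di, ai = np.indices(hb.shape)
    hb &= np.abs(di - ai) >= 2
    return hb


def assign_frame(model: StructureModel, coords: np.ndarray) -> np.ndarray:
    """Assign one secondary-structure code per residue for one frame.

    Priority H > G > I > E > B > T > S > C.  Terminal residues are never
    H or E (a helix needs i→i+4 partners on both sides, a strand needs a
    flanking bridge), matching the structural definitions.
    """
    n_res = model.n_residues
    bb = _backbone_arrays(model)
    complete = (bb["N"] >= 0) & (bb["CA"] >= 0) & (bb["C"] >= 0) & (bb["O"] >= 0)
    codes = np.full(n_res, "C", dtype="<U1")
    if complete.sum() < 5:
        warnings.warn(
            "fewer than 5 residues with complete backbone; all coil",
            stacklevel=2,
        )
        return codes

    hb = _hbond_matrix(model, coords, bb)

    def turn(i: int, n: int) -> bool:
        return i + n < n_res and hb[i + n, i]

    # --- bend (S): Cα direction change > 70° -----------------------------
    for i in range(2, n_res - 2):
        ca = bb["CA"]
        if min(ca[i - 2], ca[i], ca[i + 2]) < 0:
            continue
        u = coords[ca[i]] - coords[ca[i - 2]]
        v = coords[ca[i + 2]] - coords[ca[i]]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        ang = np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))
        if ang > 70.0:
            codes[i] = "S"

    # --- turns (T): residues spanned by an isolated n-turn ---------------
    for n in (3, 4, 5):
        for i in range(n_res):
            if turn(i, n):
                codes[i + 1 : i + n] = "T"

    # --- bridges and strands (B / E) --------------------------------------
    bridges: set[tuple[int, int]] = set()
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                bridges.add((i, j))

    ladder: set[int] = set()
    bridge_res: set[int] = set()
    for (i, j) in bridges:
        bridge_res.update((i, j))
        for (p, q) in ((i + 1, j + 1), (i + 1, j - 1), (i - 1, j - 1), (i - 1, j + 1)):
            if (min(p, q), max(p, q)) in bridges:
                ladder.update((i, j))
    for r in bridge_res:
        # terminal residues stay B: a strand interior needs flanking bridges
        if r in ladder and 0 < r < n_res - 1:
            codes[r] = "E"
        else:
            codes[r] = "B"

    # --- helices (H/G/I): two consecutive n-turns ------------------------
    for n, code in ((5, "I"), (3, "G"), (4, "H")):
        for i in range(n_res - n - 1):
            if turn(i, n) and turn(i + 1, n):
                lo = max(i + 1, 1)
                hi = min(i + n + 1, n_res - 1)
                codes[lo:hi] = code
    return codes


def ss_timeline(traj: Trajectory) -> SSTimeline:
    """Secondary-structure codes for every frame of a trajectory."""
    codes = np.stack(
        [assign_frame(traj.model, traj.coords[f]) for f in range(traj.n_frames)]
    )
    return SSTimeline(codes=codes, legend=dict(SS_LEGEND))


def ss_content_series(timeline: SSTimeline) -> dict[str, np.ndarray]:
    """Per-frame fraction of residues in each code; fractions sum to 1."""
    n_res = timeline.n_residues
    return {
        code: (timeline.codes == code).sum(1) / n_res for code in SS_CODES
    }
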