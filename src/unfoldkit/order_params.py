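"""Per-frame and per-residue order parameters of an unfolding trajectory.

The scalars computed here summarise how far a conformation has moved from
the native state: Cα-RMSD after optimal superposition, radius of gyration
(compactness), solvent-accessible surface area (exposure), fraction of
native contacts Nc (tertiary-structure integrity), intraprotein hydrogen
bond count, and per-residue RMSF (local flexibility).

All lengths are Å internally; unit conversion to nm happens at the
pipeline/reporting level only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .topology import StructureModel, select_atoms
from .trajectory import Trajectory

__all__ = [
    "OrderParameterSeries",
    "SuperpositionResult",
    "NativeContactSet",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration_series",
    "rmsf_per_residue",
    "golden_spiral_points",
    "sasa_per_atom",
    "sasa_series",
    "residue_sidechain_sasa_series",
    "native_contacts",
    "nc_fraction_series",
    "hbond_count_series",
]


@dataclass
class OrderParameterSeries:
    """A named per-frame scalar with units and frame times (ps)."""

    name: str
    units: str
    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def mean_sd(self, discard_initial_fraction: float = 0.0) -> tuple[float, float]:
        """Mean and sample (n-1) SD, optionally discarding an initial burn-in."""
        n0 = int(round(discard_initial_fraction * len(self.values)))
        kept = self.values[n0:]
        if len(kept) < 2:
            raise ValueError("need at least 2 frames after discard")
        return float(np.mean(kept)), float(np.std(kept, ddof=1))


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray       # 3x3 proper rotation, det +1
    translation: np.ndarray    # applied after rotation: x' = R x + t
    rmsd: float                # Å, the global minimum over rigid motions
    unique: bool               # False for degenerate (collinear) point sets

    def __iter__(self):
        return iter((self.rotation, self.translation, self.rmsd))


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Solves the weighted orthogonal Procrustes problem by SVD of the
    cross-covariance matrix, with the reflection corrected so the returned
    rotation is proper (det = +1).  The returned RMSD is the global minimum
    of sqrt(Σ w_k |R x_k + t − y_k|² / Σ w_k) over all rigid motions.

    Collinear or otherwise degenerate point sets still yield the minimal
    RMSD but the rotation is not unique; the result is flagged.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.ndim != 2 or reference.shape[1] != 3:
        raise ValueError("reference must be (n, 3)")
    if reference.shape != mobile.shape:
        raise ValueError("reference and mobile must have equal shapes")
    n = reference.shape[0]
    if n < 1:
        raise ValueError("need at least one point")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be n non-negative values, not all zero")
    wsum = w.sum()

    ref_c = (w[:, None] * reference).sum(0) / wsum
    mob_c = (w[:, None] * mobile).sum(0) / wsum
    P = mobile - mob_c
    Q = reference - ref_c

    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    # Rank-deficient covariance => rotation not unique (collinear/planar-degenerate).
    unique = n >= 3 and S[1] > 1e-9 * max(S[0], 1.0)

    moved = P @ R.T
    rmsd = float(np.sqrt((w * ((moved - Q) ** 2).sum(1)).sum() / wsum))
    t = ref_c - R @ mob_c
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, unique=unique)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection: np.ndarray | str = "calpha",
) -> OrderParameterSeries:
    """Frame-by-frame minimal RMSD (Å) to a reference over a selection.

    ``reference`` may be a frame index into the trajectory or an explicit
    (n_atoms, 3) coordinate array on the full topology.
    """
    sel = _resolve(traj.model, selection)
    if len(sel) == 0:
        raise ValueError("empty selection")
    ref = (
        traj.coords[reference] if isinstance(reference, (int, np.integer)) else
        np.asarray(reference, dtype=float)
    )
    ref_sel = ref[sel]
    values = np.array(
        [kabsch_superpose(ref_sel, traj.coords[f][sel]).rmsd
         for f in range(traj.n_frames)]
    )
    return OrderParameterSeries("rmsd", "angstrom", values, traj.times)


def radius_of_gyration_series(
    traj: Trajectory,
    selection: np.ndarray | str = "heavy",
    mass_weighted: bool = True,
) -> OrderParameterSeries:
    """Radius of gyration Rg = sqrt(Σ m_k |x_k − x̄|² / Σ m_k) per frame, Å."""
    sel = _resolve(traj.model, selection)
    if len(sel) == 0:
        raise ValueError("empty selection")
    m = traj.model.masses[sel] if mass_weighted else np.ones(len(sel))
    msum = m.sum()
    if msum <= 0:
        raise ValueError("zero total mass")
    X = traj.coords[:, sel, :]
    center = (m[None, :, None] * X).sum(1) / msum
    dev2 = ((X - center[:, None, :]) ** 2).sum(2)
    values = np.sqrt((m[None, :] * dev2).sum(1) / msum)
    return OrderParameterSeries("rg", "angstrom", values, traj.times)


def rmsf_per_residue(
    traj: Trajectory,
    selection: np.ndarray | str = "calpha",
    align: bool = True,
    n_mean_passes: int = 2,
) -> np.ndarray:
    """Per-selected-atom RMSF (Å) about the (optionally aligned) mean.

    With ``align=True`` each frame is superposed onto the running mean
    structure, and the mean is re-estimated; two passes suffice for the
    fixed point to settle on well-behaved trajectories.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _resolve(traj.model, selection)
    if len(sel) == 0:
        raise ValueError("empty selection")
    X = traj.coords[:, sel, :].copy()
    if align:
        mean = X.mean(0)
        for _ in range(n_mean_passes):
            for f in range(X.shape[0]):
                res = kabsch_superpose(mean, X[f])
                X[f] = X[f] @ res.rotation.T + res.translation
            mean = X.mean(0)
    mean = X.mean(0)
    return np.sqrt(((X - mean[None]) ** 2).sum(2).mean(0))


# ---------------------------------------------------------------------------
# SASA: Shrake-Rupley quadrature on a deterministic golden-spiral point set
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points from the golden-spiral rule.

    Deterministic: k-th point at polar angle arccos(1 − 2(k+½)/n) and
    azimuth π(1+√5)k.  No seed involved.
    """
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * np.arange(n)
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley.

    Each atom's accessible sphere (radius r_i + probe) is sampled at
    ``n_sphere_points`` quadrature points; a point is exposed if it lies
    outside every neighbour's accessible sphere.  Area_i = exposed
    fraction × 4π(r_i + probe)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 0):
        raise ValueError("radii must be non-negative")
    if n_sphere_points < 50:
        raise ValueError("n_sphere_points must be >= 50")
    n = len(radii)
    unit = golden_spiral_points(n_sphere_points)
    R = radii + probe_radius
    areas = np.empty(n)
    d = cdist(coords, coords)
    for i in range(n):
        nb = np.where((d[i] < R[i] + R) & (np.arange(n) != i))[0]
        if len(nb) == 0:
            areas[i] = 4.0 * np.pi * R[i] ** 2
            continue
        pts = coords[i] + R[i] * unit
        diff = pts[:, None, :] - coords[nb][None, :, :]
        inside = (diff ** 2).sum(2) < (R[nb] ** 2)[None, :]
        exposed = ~inside.any(1)
        areas[i] = exposed.mean() * 4.0 * np.pi * R[i] ** 2
    return areas


def sasa_series(
    traj: Trajectory,
    selection: np.ndarray | str = "heavy",
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    stride: int = 1,
) -> OrderParameterSeries:
    """Total SASA (Å²) of a selection per frame.

    ``stride`` subsamples frames (quadrature is the most expensive
    analysis); the returned series carries the subsampled times.
    """
    sel = _resolve(traj.model, selection)
    if len(sel) == 0:
        raise ValueError("empty selection")
    radii = traj.model.radii[sel]
    frames = range(0, traj.n_frames, stride)
    values = np.array(
        [sasa_per_atom(traj.coords[f][sel], radii, probe_radius,
                       n_sphere_points).sum() for f in frames]
    )
    return OrderParameterSeries(
        "sasa", "angstrom^2", values, traj.times[::stride]
    )


def residue_sidechain_sasa_series(
    traj: Trajectory,
    residue_index: int,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    stride: int = 1,
) -> OrderParameterSeries:
    """Side-chain SASA (Å²) of one residue, in the context of all heavy atoms.

    The per-atom areas are computed over the full heavy-atom structure
    (occlusion by the rest of the protein counts), then summed over the
    residue's side-chain heavy atoms.  Glycine has none and is an error.
    """
    model = traj.model
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = select_atoms(model, ("sidechain_of", residue_index))
    if len(sc) == 0:
        raise ValueError(
            f"residue {residue_index} ({model.residue_name(residue_index)}) "
            "has no side-chain heavy atoms"
        )
    heavy = select_atoms(model, "heavy")
    pos_in_heavy = np.searchsorted(heavy, sc)
    radii = model.radii[heavy]
    frames = range(0, traj.n_frames, stride)
    values = np.array(
        [sasa_per_atom(traj.coords[f][heavy], radii, probe_radius,
                       n_sphere_points)[pos_in_heavy].sum() for f in frames]
    )
    return OrderParameterSeries(
        f"sidechain_sasa_res{residue_index}", "angstrom^2",
        values, traj.times[::stride],
    )


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

@dataclass
class NativeContactSet:
    """Reference-structure heavy-atom contact pairs defining Nc.

    A native contact is a pair of heavy atoms from residues at least
    ``min_sequence_separation`` apart in sequence whose distance in the
    reference frame is at most ``cutoff`` (Å).
    """

    reference_frame: int
    cutoff: float
    min_sequence_separation: int
    pairs: np.ndarray = field(repr=False)  # (n_pairs, 2) atom indices, i < j

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def native_contacts(
    model: StructureModel,
    reference_coords: np.ndarray,
    cutoff: float = 4.0,
    min_sequence_separation: int = 3,
    reference_frame: int = 0,
) -> NativeContactSet:
    """All heavy-atom pairs within ``cutoff`` in the reference structure.

    Only pairs spanning residues with |Δresidue| ≥ min_sequence_separation
    count; each pair is stored once with the lower atom index first.
    A structure yielding zero such pairs cannot define an Nc fraction and
    raises.
    """
    heavy = select_atoms(model, "heavy")
    X = np.asarray(reference_coords, dtype=float)[heavy]
    res = model.residue_of_atom[heavy]
    d = cdist(X, X)
    sep_ok = np.abs(res[:, None] - res[None, :]) >= min_sequence_separation
    hit = (d <= cutoff) & sep_ok
    ii, jj = np.where(np.triu(hit, k=1))
    if len(ii) == 0:
        raise ValueError(
            "no native contacts found: structure has no heavy-atom pairs "
            f"within {cutoff} Å at sequence separation "
            f">= {min_sequence_separation}"
        )
    pairs = np.column_stack([heavy[ii], heavy[jj]])
    return NativeContactSet(
        reference_frame=reference_frame,
        cutoff=cutoff,
        min_sequence_separation=min_sequence_separation,
        pairs=pairs,
    )


def nc_fraction_series(
    traj: Trajectory,
    native: NativeContactSet,
    tolerance_factor: float = 1.0,
) -> OrderParameterSeries:
    """Fraction of native contacts maintained per frame.

    A native pair counts as maintained when its distance is at most
    cutoff × tolerance_factor.  By definition the reference frame scores
    exactly 1 for tolerance_factor ≥ 1.
    """
    if native.n_pairs == 0:
        raise ValueError("native contact set is empty")
    i, j = native.pairs[:, 0], native.pairs[:, 1]
    diff = traj.coords[:, i, :] - traj.coords[:, j, :]
    dist = np.sqrt((diff ** 2).sum(2))
    thresh = native.cutoff * tolerance_factor
    values = (dist <= thresh).mean(1)
    return OrderParameterSeries("nc", "fraction", values, traj.times)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_count_series(
    traj: Trajectory,
    distance_cutoff: float = 3.5,
    angle_cutoff_deg: float = 120.0,
    min_sequence_separation: int = 2,
) -> OrderParameterSeries:
    """Per-frame count of intraprotein backbone hydrogen bonds.

    Geometric criterion: donor backbone N to acceptor backbone O distance
    ≤ ``distance_cutoff`` Å between residues with |Δresidue| ≥
    ``min_sequence_separation``, and D-H···A angle ≥ ``angle_cutoff_deg``.
    When the topology carries no amide hydrogen it is reconstructed
    geometrically (1.01 Å from N, anti to the preceding residue's carbonyl
    O); the angle test screens out the short-but-bent N···O approaches an
    α-helix packs at i→i+2 and i→i+3.  Residue 0 (no preceding carbonyl,
    no explicit H) cannot donate.
    """
    model = traj.model
    n_res = model.n_residues
    n_idx = np.array([
        -1 if model.atom_index(r, "N") is None else model.atom_index(r, "N")
        for r in range(n_res)
    ])
    o_idx = np.array([
        -1 if model.atom_index(r, "O") is None else model.atom_index(r, "O")
        for r in range(n_res)
    ])
    c_idx = np.array([
        -1 if model.atom_index(r, "C") is None else model.atom_index(r, "C")
        for r in range(n_res)
    ])
    h_idx = np.array([
        next((model.atom_index(r, nm) for nm in ("H", "HN")
              if model.atom_index(r, nm) is not None), -1)
        for r in range(n_res)
    ])
    if (n_idx < 0).all() or (o_idx < 0).all():
        raise ValueError("structure lacks backbone N and O atoms")

    # Per-frame hydrogen positions: explicit atom, else reconstructed.
    nF = traj.n_frames
    Hpos = np.full((nF, n_res, 3), np.nan)
    donor_ok = np.zeros(n_res, dtype=bool)
    for r in range(n_res):
        if n_idx[r] < 0:
            continue
        if h_idx[r] >= 0:
            Hpos[:, r] = traj.coords[:, h_idx[r]]
            donor_ok[r] = True
        elif r > 0 and c_idx[r - 1] >= 0 and o_idx[r - 1] >= 0:
            direction = (
                traj.coords[:, c_idx[r - 1]] - traj.coords[:, o_idx[r - 1]]
            )
            nrm = np.linalg.norm(direction, axis=1, keepdims=True)
            Hpos[:, r] = traj.coords[:, n_idx[r]] + 1.01 * direction / nrm
            donor_ok[r] = True

    pairs = [
        (rd, ra)
        for rd in range(n_res)
        for ra in range(n_res)
        if donor_ok[rd] and o_idx[ra] >= 0
        and abs(rd - ra) >= min_sequence_separation
    ]
    if not pairs:
        return OrderParameterSeries(
            "hbonds", "count", np.zeros(nF), traj.times
        )
    rd = np.array([p[0] for p in pairs])
    ra = np.array([p[1] for p in pairs])

    N = traj.coords[:, n_idx[rd], :]
    O = traj.coords[:, o_idx[ra], :]
    H = Hpos[:, rd, :]
    dist_ok = np.linalg.norm(N - O, axis=2) <= distance_cutoff
    v1 = N - H
    v2 = O - H
    cosang = (v1 * v2).sum(2) / (
        np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2) + 1e-30
    )
    # D-H...A angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
    angle_ok = cosang <= np.cos(np.deg2rad(angle_cutoff_deg))
    values = (dist_ok & angle_ok).sum(1).astype(float)
    return OrderParameterSeries("hbonds", "count", values, traj.times)


def _resolve(model: StructureModel, selection) -> np.ndarray:
    if isinstance(selection, (str, tuple)):
        return select_atoms(model, selection)
    return np.asarray(selection, dtype=np.intp)
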