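"""Dynamic cross-correlation matrices of residue motion.

C_ij = ⟨Δx_i·Δx_j⟩ / sqrt(⟨|Δx_i|²⟩⟨|Δx_j|²⟩), with Δx the displacement of
a residue's Cα from its window mean, optionally after superposing every
frame onto the window-mean structure (removing global rotation/translation
that would otherwise dominate the correlations).  +1 is fully correlated
motion, −1 fully anti-correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .order_params import kabsch_superpose
from .trajectory import Trajectory
from .topology import select_atoms

__all__ = ["DCCMatrix", "dccm_matrix", "dccm_windows"]


@dataclass
class DCCMatrix:
    """Residue-residue correlation matrix over one frame window."""

    values: np.ndarray            # (n_res, n_res) in [-1, 1]
    window: tuple[int, int]       # [start, stop) frame range
    labels: list[str] | None = None


def dccm_matrix(
    traj: Trajectory,
    selection: np.ndarray | str = "calpha",
    window: tuple[int, int] | None = None,
    align: bool = True,
) -> DCCMatrix:
    """Cross-correlation matrix of selected-atom displacements in a window.

    An atom with zero displacement variance in the window (immobile) gets
    zero off-diagonal correlation and a unit diagonal, with a warning —
    its correlation is undefined, not meaningful.
    """
    model = traj.model
    sel = (
        select_atoms(model, selection)
        if isinstance(selection, (str, tuple))
        else np.asarray(selection, dtype=np.intp)
    )
    if window is None:
        window = (0, traj.n_frames)
    start, stop = window
    if stop - start < 10:
        raise ValueError("window must contain at least 10 frames")
    X = traj.coords[start:stop, sel, :].copy()

    if align:
        mean = X.mean(0)
        for _ in range(2):
            for f in range(X.shape[0]):
                res = kabsch_superpose(mean, X[f])
                X[f] = X[f] @ res.rotation.T + res.translation
            mean = X.mean(0)

    D = X - X.mean(0)[None]                      # (frames, n, 3)
    cov = np.einsum("fik,fjk->ij", D, D) / D.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-12
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} atom(s) immobile in window {window}; "
            "their correlations are set to 0",
            stacklevel=2,
        )
        var[zero] = 1.0
    C = cov / np.sqrt(var[:, None] * var[None, :])
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)

    labels = [
        f"{model.residue_name(model.atoms[i].residue_index)}"
        f"{model.atoms[i].residue_index + 1}"
        for i in sel
    ]
    return DCCMatrix(values=C, window=(start, stop), labels=labels)


def dccm_windows(
    traj: Trajectory,
    windows: list[tuple[int, int]] | None = None,
    selection: np.ndarray | str = "calpha",
    align: bool = True,
) -> list[DCCMatrix]:
    """One DCCM per window; default windows = first and last 10% of frames.

    The defaults mirror comparing residue motion at the start and the end
    of a simulation.
    """
    if windows is None:
        tenth = max(10, traj.n_frames // 10)
        windows = [(0, tenth), (traj.n_frames - tenth, traj.n_frames)]
    out = []
    for start, stop in windows:
        if not (0 <= start < stop <= traj.n_frames):
            raise ValueError(f"window ({start}, {stop}) outside trajectory")
        out.append(dccm_matrix(traj, selection, (start, stop), align))
    return out
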