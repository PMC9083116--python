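"""Trajectory container: ordered coordinate frames over one fixed topology."""

from __future__ import annotations

import numpy as np

from .topology import StructureModel

__all__ = ["Trajectory"]


class Trajectory:
    """Coordinates (n_frames, n_atoms, 3) in Å over one :class:`StructureModel`.

    Frame times are in ps and must be strictly increasing.  The temperature
    label (K) identifies which member of a thermal ladder this trajectory
    is; it is a label, not a thermodynamic input, except where Boltzmann
    inversion needs RT.
    """

    def __init__(
        self,
        model: StructureModel,
        coords: np.ndarray,
        times: np.ndarray | None = None,
        temperature_label: float = 300.0,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[1] != model.n_atoms:
            raise ValueError(
                f"frames have {coords.shape[1]} atoms but topology has {model.n_atoms}"
            )
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if coords.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.model = model
        self.coords = coords
        self.times = times
        self.temperature_label = float(temperature_label)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over frames [start, stop)."""
        return Trajectory(
            self.model,
            self.coords[start:stop],
            self.times[start:stop],
            self.temperature_label,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Trajectory {self.n_frames} frames x {self.n_atoms} atoms "
            f"@ {self.temperature_label:g} K>"
        )
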