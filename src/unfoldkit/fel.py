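"""2-D free-energy landscapes by Boltzmann inversion of joint histograms.

F(x, y) = −RT ln P(x, y), where P is the empirical joint probability of two
order parameters over the trajectory and RT uses the gas constant in
kcal/(mol·K).  Unvisited bins are masked, never assigned −RT ln 0; the
surface is shifted so its minimum over visited bins is zero, which leaves
every free-energy difference unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .order_params import OrderParameterSeries

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FELGrid",
    "Basin",
    "fel_2d",
    "find_minima",
    "basin_delta_f",
]

#: Gas constant R in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass
class FELGrid:
    """Binned 2-D free-energy surface.

    ``F[i, j]`` is the free energy (kcal/mol) of bin (x-bin i, y-bin j);
    ``mask[i, j]`` is True for bins no frame visited.  The minimum of F
    over unmasked bins is 0 after construction.
    """

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    mask: np.ndarray
    RT: float
    n_frames: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.F.shape

    def probabilities(self) -> np.ndarray:
        """Recover the empirical joint probabilities from F.

        exp(−F/RT) over unmasked bins, renormalised; masked bins get 0.
        Inverse of the Boltzmann inversion up to the (probability-
        preserving) global shift of F.
        """
        p = np.where(self.mask, 0.0, np.exp(-self.F / self.RT))
        return p / p.sum()


@dataclass(frozen=True)
class Basin:
    """A local free-energy minimum: its bin coordinate and F value."""

    bin: tuple[int, int]
    f_value: float


def fel_2d(
    series_x: OrderParameterSeries,
    series_y: OrderParameterSeries,
    n_bins: tuple[int, int] = (60, 60),
    temperature: float = 300.0,
) -> FELGrid:
    """Boltzmann-invert the joint histogram of two order parameters.

    Parameters
    ----------
    series_x, series_y
        Equal-length per-frame series (≥ 100 frames for a meaningful
        histogram).
    n_bins
        Bins per axis (≥ 5 each).
    temperature
        Simulation temperature in K; sets RT for the inversion.
    """
    x = np.asarray(series_x.values, dtype=float)
    y = np.asarray(series_y.values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 100:
        raise ValueError("need at least 100 frames for a free-energy landscape")
    if n_bins[0] < 5 or n_bins[1] < 5:
        raise ValueError("need at least 5 bins per axis")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        flat = series_x.name if np.ptp(x) == 0 else series_y.name
        raise ValueError(
            f"order parameter {flat!r} is constant over the trajectory; "
            "choose a different order parameter for this axis"
        )
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins)
    n_frames = len(x)
    P = counts / n_frames
    mask = counts == 0
    RT = GAS_CONSTANT_KCAL * temperature
    F = np.zeros_like(P)
    F[~mask] = -RT * np.log(P[~mask])
    F[~mask] -= F[~mask].min()
    return FELGrid(
        x_name=series_x.name,
        y_name=series_y.name,
        x_edges=x_edges,
        y_edges=y_edges,
        F=F,
        mask=mask,
        RT=RT,
        n_frames=n_frames,
    )


def find_minima(grid: FELGrid, depth_threshold: float = 2.0) -> list[Basin]:
    """Locate free-energy basins: grid-local minima below a depth threshold.

    A basin is an unmasked bin whose F is ≤ every unmasked 8-neighbour and
    ≤ ``depth_threshold`` (kcal/mol above the global minimum).  A plateau
    of tied connected minima collapses to its first bin in row-major
    order.  Basins are returned sorted by F ascending, ties row-major.
    """
    F, mask = grid.F, grid.mask
    nx, ny = F.shape
    if mask.all():
        raise ValueError("grid has no visited bins")
    is_min = np.zeros_like(mask)
    for i in range(nx):
        for j in range(ny):
            if mask[i, j] or F[i, j] > depth_threshold:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and not mask[a, b]:
                        if F[a, b] < F[i, j]:
                            ok = False
                            break
                if not ok:
                    break
            is_min[i, j] = ok

    # Merge plateaus: connected (8-neighbour) equal-F minima -> first bin.
    seen = np.zeros_like(is_min)
    basins: list[Basin] = []
    for i in range(nx):
        for j in range(ny):
            if not is_min[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        p, q = a + di, b + dj
                        if (
                            0 <= p < nx and 0 <= q < ny
                            and is_min[p, q] and not seen[p, q]
                            and F[p, q] == F[i, j]
                        ):
                            seen[p, q] = True
                            stack.append((p, q))
            basins.append(Basin(bin=(i, j), f_value=float(F[i, j])))
    basins.sort(key=lambda b: (b.f_value, b.bin))
    return basins


def basin_delta_f(grid: FELGrid, basin_a: Basin, basin_b: Basin) -> float:
    """Free-energy difference F(b) − F(a) in kcal/mol; antisymmetric.

    Both basins must lie on unmasked bins of this grid; ΔF is invariant to
    the global min-shift applied at construction.
    """
    for basin in (basin_a, basin_b):
        i, j = basin.bin
        if not (0 <= i < grid.F.shape[0] and 0 <= j < grid.F.shape[1]):
            raise ValueError(f"basin bin {basin.bin} not on grid")
        if grid.mask[i, j]:
            raise ValueError(f"basin bin {basin.bin} is unvisited on this grid")
    return float(grid.F[basin_b.bin] - grid.F[basin_a.bin])
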