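"""End-to-end multi-temperature unfolding analysis.

Drives every analysis stage over a thermal ladder of trajectories (read
from multi-model PDB files or generated synthetically) and emits a
machine-readable output bundle: per-temperature order-parameter CSVs, a
per-temperature mean ± SD summary table, free-energy grids for the
configured order-parameter pairs, start/end-window DCC matrices, a
secondary-structure timeline, and a tracked side-chain-SASA-vs-RMSD
scatter table.

Lengths are Å internally; reported RMSD/Rg are converted to nm and SASA
to nm² at this level only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ukio
from .fel import fel_2d, find_minima
from .dccm import dccm_windows
from .order_params import (
    OrderParameterSeries,
    hbond_count_series,
    native_contacts,
    nc_fraction_series,
    radius_of_gyration_series,
    rmsd_series,
)
from .secstruct import ss_timeline
from .synthetic import SyntheticConfig, make_toy_protein, thermal_series
from .trajectory import Trajectory

__all__ = ["RunConfig", "run_unfolding_analysis", "summarize_series"]

logger = logging.getLogger("unfoldkit.pipeline")

_A_TO_NM = 0.1
_A2_TO_NM2 = 0.01


def summarize_series(
    series: OrderParameterSeries, discard_initial_fraction: float = 0.0
) -> tuple[float, float]:
    """Mean and sample (n-1) SD of a series after an optional burn-in discard."""
    return series.mean_sd(discard_initial_fraction)


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``pdb_inputs`` (paths with temperature labels) or a synthetic
    ladder (``synthetic`` base config + optional ``schedule``) supplies
    the trajectories.  The native reference defaults to frame 0 of the
    coldest trajectory (for synthetic ladders: the native template) and
    can be overridden with an explicit single-model PDB path.
    """

    output_dir: str | Path = "unfold_out"
    pdb_inputs: list[tuple[str, float]] | None = None
    synthetic: SyntheticConfig | None = None
    schedule: dict[float, dict[str, float]] | None = None
    native_reference_path: str | None = None
    nc_cutoff: float = 4.0
    nc_min_separation: int = 3
    fel_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("nc", "rmsd"), ("nc", "rg"), ("hbonds", "nc")]
    )
    fel_bins: tuple[int, int] = (60, 60)
    dccm_window_fraction: float = 0.1
    tracked_residue: int | None = None
    sasa_points: int = 960
    sasa_stride: int = 1
    discard_initial_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pdb_inputs is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
            logger.warning("no inputs given; defaulting to synthetic ladder")


def _sasa_pair(
    traj: Trajectory,
    tracked_residue: int | None,
    n_sphere_points: int,
    stride: int,
) -> dict[str, OrderParameterSeries]:
    """Total heavy-atom SASA and tracked side-chain SASA in one pass.

    One Shrake-Rupley evaluation per (strided) frame serves both series;
    quadrature is the most expensive analysis so this avoids doing it
    twice.  Matches sasa_series / residue_sidechain_sasa_series exactly.
    """
    from .order_params import sasa_per_atom
    from .topology import select_atoms

    model = traj.model
    heavy = select_atoms(model, "heavy")
    radii = model.radii[heavy]
    pos_in_heavy = None
    if tracked_residue is not None:
        sc = select_atoms(model, ("sidechain_of", tracked_residue))
        if len(sc) == 0:
            raise ValueError(
                f"tracked residue {tracked_residue} has no side-chain "
                "heavy atoms"
            )
        pos_in_heavy = np.searchsorted(heavy, sc)
    frames = range(0, traj.n_frames, stride)
    totals, tracked = [], []
    for f in frames:
        per_atom = sasa_per_atom(
            traj.coords[f][heavy], radii, n_sphere_points=n_sphere_points
        )
        totals.append(per_atom.sum())
        if pos_in_heavy is not None:
            tracked.append(per_atom[pos_in_heavy].sum())
    times = traj.times[::stride]
    out = {
        "sasa": OrderParameterSeries(
            "sasa", "angstrom^2", np.array(totals), times
        )
    }
    if pos_in_heavy is not None:
        out["sidechain_sasa"] = OrderParameterSeries(
            f"sidechain_sasa_res{tracked_residue}", "angstrom^2",
            np.array(tracked), times,
        )
    return out


def _load_trajectories(config: RunConfig) -> tuple[list[Trajectory], np.ndarray | None]:
    if config.pdb_inputs is not None:
        trajs = []
        for path, temp in config.pdb_inputs:
            _, traj = ukio.read_multimodel_pdb(path, temperature_label=temp)
            trajs.append(traj)
        return trajs, None
    toy = make_toy_protein(config.synthetic.n_residues)
    pairs = thermal_series(config.synthetic, schedule=config.schedule, toy=toy)
    if config.tracked_residue is None:
        config.tracked_residue = toy.trp_residue
        logger.warning(
            "tracked_residue defaulted to the toy tryptophan (residue %d)",
            toy.trp_residue,
        )
    return [t for t, _ in pairs], toy.native.coords


def run_unfolding_analysis(config: RunConfig) -> dict:
    """Run the full analysis; returns the bundle and writes it to disk.

    Deterministic given config + seed: rerunning with the same inputs
    reproduces every output file byte for byte.  Any stage failure aborts
    with the stage name; a completed run leaves a COMPLETE marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "COMPLETE"
    if marker.exists():
        marker.unlink()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    bundle: dict = {"series": {}, "fel": {}, "dccm": {}, "ss": {}}
    stage = "load_inputs"
    try:
        logger.info("run config: %r", config)
        trajs, native_ref = _load_trajectories(config)
        trajs.sort(key=lambda t: t.temperature_label)
        model = trajs[0].model
        if config.native_reference_path is not None:
            _, ref_traj = ukio.read_multimodel_pdb(config.native_reference_path)
            native_ref = ref_traj.coords[0]
        elif native_ref is None:
            native_ref = trajs[0].coords[0]
            logger.warning(
                "native reference defaulted to frame 0 of the coldest "
                "trajectory (%g K)", trajs[0].temperature_label,
            )

        stage = "native_contacts"
        ncset = native_contacts(
            model, native_ref,
            cutoff=config.nc_cutoff,
            min_sequence_separation=config.nc_min_separation,
        )
        logger.info("native contact set: %d pairs (cutoff %.2f Å, |Δres| ≥ %d)",
                    ncset.n_pairs, config.nc_cutoff, config.nc_min_separation)

        summary_rows = []
        for traj in trajs:
            temp = traj.temperature_label
            tag = f"{temp:g}K"
            stage = f"order_parameters[{tag}]"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                series = {
                    "rmsd": rmsd_series(traj, native_ref, "calpha"),
                    "rg": radius_of_gyration_series(traj, "heavy"),
                    "nc": nc_fraction_series(traj, ncset),
                    "hbonds": hbond_count_series(traj),
                }
                series.update(
                    _sasa_pair(traj, config.tracked_residue,
                               config.sasa_points, config.sasa_stride)
                )
            bundle["series"][temp] = series
            for name, s in series.items():
                ukio.write_series_csv(out / f"{name}_{tag}.csv", s)

            stage = f"summary[{tag}]"
            row = {"temperature_K": temp}
            for name, scale, unit in (
                ("rmsd", _A_TO_NM, "nm"), ("rg", _A_TO_NM, "nm"),
                ("nc", 1.0, "fraction"), ("sasa", _A2_TO_NM2, "nm^2"),
            ):
                mean, sd = summarize_series(
                    series[name], config.discard_initial_fraction
                )
                row[f"{name}_mean_{unit}"] = mean * scale
                row[f"{name}_sd_{unit}"] = sd * scale
            summary_rows.append(row)

            stage = f"fel[{tag}]"
            for x_name, y_name in config.fel_pairs:
                try:
                    grid = fel_2d(
                        series[x_name], series[y_name],
                        n_bins=config.fel_bins, temperature=temp,
                    )
                except ValueError as err:
                    # e.g. an order parameter constant at this temperature
                    logger.warning("skipping FEL %s/%s @ %s: %s",
                                   x_name, y_name, tag, err)
                    continue
                bundle["fel"][(temp, x_name, y_name)] = grid
                ukio.write_grid(out / f"fel_{x_name}_{y_name}_{tag}.dat", grid)
                basins = find_minima(grid)
                logger.info("FEL %s/%s @ %s: %d basin(s)",
                            x_name, y_name, tag, len(basins))

            stage = f"dccm[{tag}]"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mats = dccm_windows(traj)
            bundle["dccm"][temp] = mats
            for mat, which in zip(mats, ("start", "end")):
                ukio.write_matrix(out / f"dccm_{which}_{tag}.csv", mat)

            stage = f"secstruct[{tag}]"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                timeline = ss_timeline(traj)
            bundle["ss"][temp] = timeline
            pd.DataFrame(timeline.codes).to_csv(
                out / f"ss_timeline_{tag}.csv", index_label="frame"
            )

            stage = f"scatter[{tag}]"
            if config.tracked_residue is not None:
                sc = series["sidechain_sasa"]
                rmsd_sub = series["rmsd"].values[:: config.sasa_stride]
                pd.DataFrame(
                    {
                        "time_ps": sc.times,
                        "rmsd_nm": rmsd_sub[: len(sc.values)] * _A_TO_NM,
                        "sidechain_sasa_A2": sc.values,
                    }
                ).to_csv(out / f"sasa_vs_rmsd_{tag}.csv", index=False)

        stage = "summary_table"
        summary = pd.DataFrame(summary_rows).set_index("temperature_K")
        summary.to_csv(out / "summary_table.csv", float_format="%.17g")
        bundle["summary"] = summary
        bundle["native_contacts"] = ncset

        marker.write_text("complete\n")
        logger.info("run complete: %s", out)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
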