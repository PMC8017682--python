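"""Serialization and provenance: trajectories to netCDF/CSV, parameter
tables to delimited text, and run manifests.

Every output carries the fully resolved configuration and root seed in its
metadata, so any published artifact can be reconstructed from its manifest
alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .config import ModelConfig, config_hash
from .consumption_matrix import ConsumptionMatrix
from .errors import ValidationError
from .parameters import ParameterSet
from .simulator import Trajectory

__all__ = [
    "RunManifest",
    "trajectory_to_dataset",
    "write_trajectory",
    "read_trajectory",
    "write_parameter_tables",
    "read_parameter_tables",
    "write_manifest",
]


@dataclass
class RunManifest:
    """Provenance record of one run: configuration hash, seed, outputs."""

    config_hash: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    budget_residual: float | None = None
    package_version: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def trajectory_to_dataset(trajectory: Trajectory) -> xr.Dataset:
    """Pack a :class:`Trajectory` into an annotated :class:`xarray.Dataset`."""
    ds = xr.Dataset(
        {
            "C": (("time", "pool"), trajectory.C),
            "B": (("time", "population"), trajectory.B),
            "cumulative_supply": (("pool",), trajectory.cumulative_supply),
            "cumulative_consumed": (("pool",), trajectory.cumulative_consumed),
            "C_bar": (("pool",), trajectory.C_bar),
            "consumption_rate": (("pool",), trajectory.consumption_rate),
            "B_bar": (("population",), trajectory.B_bar),
            "rho_bar": (("interaction",), trajectory.rho_bar),
        },
        coords={"time": trajectory.times},
        attrs={
            "cumulative_respired": trajectory.cumulative_respired,
            "cumulative_mortality": trajectory.cumulative_mortality,
            "initial_C_total": trajectory.initial_C_total,
            "initial_B_total": trajectory.initial_B_total,
            "window_start": trajectory.window[0],
            "window_end": trajectory.window[1],
            "budget_residual": trajectory.budget_residual,
        },
    )
    if trajectory.matrix is not None:
        ds["edge_pool"] = ("interaction",), trajectory.matrix.pool_index
        ds["edge_population"] = ("interaction",), trajectory.matrix.population_index
    if trajectory.params is not None:
        p = trajectory.params
        ds["rho_max"] = ("interaction",), p.rho_max
        ds["half_saturation"] = ("interaction",), p.k
        ds["yield"] = ("interaction",), p.yield_
        ds["supply_potential"] = ("pool",), p.supply_potential
        ds["supply_probability"] = ("pool",), p.supply_probability
        ds["presence"] = ("population",), p.presence
        ds["mortality_quadratic"] = ("population",), p.mortality_quadratic
        ds["mortality_linear"] = ("population",), p.mortality_linear
    if trajectory.config is not None:
        ds.attrs["config_json"] = json.dumps(trajectory.config.to_dict(), sort_keys=True)
        ds.attrs["seed"] = trajectory.config.seed
    return ds


def write_trajectory(trajectory: Trajectory, path: str) -> RunManifest:
    """Write a trajectory to netCDF plus a per-pool summary CSV alongside.

    Returns the manifest listing the files created.  Arrays round-trip
    bit-exactly through :func:`read_trajectory`.
    """
    ds = trajectory_to_dataset(trajectory)
    try:
        ds.to_netcdf(path, engine="scipy")
    except OSError as exc:
        raise ValidationError(f"cannot write trajectory to {path!r}: {exc}") from exc
    summary_path = os.path.splitext(path)[0] + "_pools.csv"
    pd.DataFrame(
        {
            "pool_id": np.arange(trajectory.C.shape[1]),
            "C_final": trajectory.C_final,
            "cumulative_supply": trajectory.cumulative_supply,
            "cumulative_consumed": trajectory.cumulative_consumed,
        }
    ).to_csv(summary_path, index=False)
    cfg = trajectory.config
    manifest = RunManifest(
        config_hash=config_hash(cfg) if cfg is not None else "",
        seed=cfg.seed if cfg is not None else -1,
        config=cfg.to_dict() if cfg is not None else {},
        outputs=[path, summary_path],
        budget_residual=trajectory.budget_residual,
    )
    return manifest


def read_trajectory(path: str) -> Trajectory:
    """Reconstruct a :class:`Trajectory` written by :func:`write_trajectory`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    config = None
    if "config_json" in ds.attrs:
        config = ModelConfig.from_dict(json.loads(ds.attrs["config_json"]))
    matrix = None
    if "edge_pool" in ds:
        matrix = ConsumptionMatrix(
            ds.sizes["pool"],
            ds.sizes["population"],
            ds["edge_pool"].values.astype(np.int64),
            ds["edge_population"].values.astype(np.int64),
        )
    params = None
    if "rho_max" in ds:
        params = ParameterSet(
            supply_potential=ds["supply_potential"].values,
            supply_probability=ds["supply_probability"].values,
            rho_max=ds["rho_max"].values,
            k=ds["half_saturation"].values,
            yield_=ds["yield"].values,
            presence=ds["presence"].values,
            mortality_quadratic=ds["mortality_quadratic"].values,
            mortality_linear=ds["mortality_linear"].values,
        )
    return Trajectory(
        times=ds["time"].values,
        C=ds["C"].values,
        B=ds["B"].values,
        cumulative_supply=ds["cumulative_supply"].values,
        cumulative_consumed=ds["cumulative_consumed"].values,
        cumulative_respired=float(ds.attrs["cumulative_respired"]),
        cumulative_mortality=float(ds.attrs["cumulative_mortality"]),
        rho_bar=ds["rho_bar"].values,
        B_bar=ds["B_bar"].values,
        C_bar=ds["C_bar"].values,
        consumption_rate=ds["consumption_rate"].values,
        window=(float(ds.attrs["window_start"]), float(ds.attrs["window_end"])),
        config=config,
        seed=int(ds.attrs["seed"]) if "seed" in ds.attrs else None,
        initial_C_total=float(ds.attrs["initial_C_total"]),
        initial_B_total=float(ds.attrs["initial_B_total"]),
        matrix=matrix,
        params=params,
    )


def write_parameter_tables(
    params: ParameterSet, matrix: ConsumptionMatrix, directory: str
) -> list[str]:
    """Write the three delimited parameter tables; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, frame in params.to_frames(matrix).items():
        p = os.path.join(directory, f"{name}.csv")
        frame.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_parameter_tables(directory: str) -> tuple[ParameterSet, ConsumptionMatrix]:
    frames = {
        name: pd.read_csv(os.path.join(directory, f"{name}.csv"), float_precision="round_trip")
        for name in ("interactions", "pools", "populations")
    }
    return ParameterSet.from_frames(frames)


def write_manifest(manifest: RunManifest, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(manifest.to_json())


def column_state_to_dataset(state, config) -> xr.Dataset:
    """Pack a water-column state into an annotated :class:`xarray.Dataset`
    with depth and pool dimensions."""
    from .water_column import ColumnGrid

    grid = ColumnGrid.from_config(config)
    return xr.Dataset(
        {
            "din": (("depth",), state.din),
            "dic": (("depth",), state.dic),
            "phyto": (("phytoplankton", "depth"), state.phyto),
            "doc": (("pool", "depth"), state.doc),
            "heterotrophs": (("pool", "depth"), state.het),
            "pom": (("depth",), state.pom),
            "rho_max": (("pool",), config.rho_ladder),
        },
        coords={"depth": grid.z},
        attrs={
            "t_days": state.t,
            "buried": state.buried,
            "config_json": json.dumps(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
            ),
        },
    )


def write_column_state(state, config, path: str) -> None:
    column_state_to_dataset(state, config).to_netcdf(path, engine="scipy")
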