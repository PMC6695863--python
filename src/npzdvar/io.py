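"""NetCDF/CSV/JSON output and provenance records.

All NetCDF files are written through xarray's scipy backend (NetCDF3
classic) with CF-style lon/lat/layer/time coordinates.  Dry cells are
stored as NaN fill values and restored as the mask on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import ModelGrid
from .model import Trajectory

__all__ = [
    "write_field_netcdf",
    "read_field_netcdf",
    "write_trajectory_netcdf",
    "write_provenance",
]

_ENGINE = "scipy"
FILL = np.nan


def _coords(grid: ModelGrid, with_layer: bool = False) -> dict:
    c = {
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
    }
    if with_layer:
        c["layer"] = ("layer", np.arange(grid.nz), {"long_name": "layer index, 0 = surface"})
    return {k: xr.DataArray(v[1], dims=v[0], attrs=v[2]) for k, v in c.items()}


def write_field_netcdf(field: np.ndarray, grid: ModelGrid, path, variable: str = "field",
                       units: str = "mmol N m-3") -> None:
    """Write a surface (ny, nx) or volume (nz, ny, nx) field with coordinates."""
    field = np.asarray(field, dtype=float)
    if field.shape == (grid.ny, grid.nx):
        data = np.where(grid.mask, field, FILL)
        da = xr.DataArray(data, dims=("lat", "lon"), attrs={"units": units})
        coords = _coords(grid)
    elif field.shape == grid.active.shape:
        data = np.where(grid.active, field, FILL)
        da = xr.DataArray(data, dims=("layer", "lat", "lon"), attrs={"units": units})
        coords = _coords(grid, with_layer=True)
    else:
        raise ValueError(f"field shape {field.shape} does not match grid")
    ds = xr.Dataset({variable: da}, coords=coords)
    ds.to_netcdf(Path(path), engine=_ENGINE)


def read_field_netcdf(path, variable: str):
    """Read one variable back; dry cells come out as a masked (NaN) array."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with xr.open_dataset(p, engine=_ENGINE) as ds:
        for coord in ("lon", "lat"):
            if coord not in ds.coords:
                raise ValueError(f"file {p} lacks required coordinate {coord!r}")
        if variable not in ds:
            raise KeyError(
                f"variable {variable!r} not in {p}; available: {sorted(ds.data_vars)}"
            )
        return ds[variable].values.copy()


def write_trajectory_netcdf(traj: Trajectory, path) -> None:
    """Write all four compartments over time/layer/lat/lon."""
    grid = traj.grid
    nt = traj.n_times
    hours = np.arange(nt) * traj.step_hours
    cube = np.full((nt, 4, grid.nz, grid.ny, grid.nx), FILL)
    for t in range(nt):
        for c in range(4):
            cube[t, c][grid.active] = traj.states[t, c]
    names = ["N", "P", "Z", "D"]
    ds = xr.Dataset(
        {
            name: xr.DataArray(cube[:, c], dims=("time", "layer", "lat", "lon"),
                               attrs={"units": "mmol N m-3"})
            for c, name in enumerate(names)
        },
        coords={**_coords(grid, with_layer=True),
                "time": xr.DataArray(hours, dims="time", attrs={"units": "hours"})},
    )
    ds.to_netcdf(Path(path), engine=_ENGINE)


def write_ncf_csv(ncf_history, path) -> None:
    pd.DataFrame({"iteration": np.arange(len(ncf_history)),
                  "ncf": np.asarray(ncf_history)}).to_csv(path, index=False)


def write_provenance(path, config_dict: dict, seed: int, extra: dict | None = None) -> None:
    """Record config hash, seed and package version next to the outputs."""
    from . import __version__

    blob = json.dumps(config_dict, sort_keys=True, default=str)
    record = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "version": __version__,
        "config": config_dict,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
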