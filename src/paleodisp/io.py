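"""Readers and writers for the standard on-disk formats.

Rasters travel as CF-style NetCDF (lon/lat coordinate variables, via
xarray's scipy backend) or as plain ``lon,lat,value`` CSV for small
fixtures; series and catalogues as CSV; fitted ensembles as JSON.  Every
writer embeds the configuration hash and seed for provenance (NetCDF global
attributes, ``#`` header comments in CSV, top-level JSON keys).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import GridMismatchError
from .grid import LandMask, LatLonGrid, ScalarField
from .layers import HepStack, IsotopeSeries, normalize_isotope
from .niche import NicheEnsemble
from .solver import RunResult

__all__ = [
    "save_field_netcdf",
    "load_field_netcdf",
    "save_field_csv",
    "load_field_csv",
    "load_rasters",
    "save_stack",
    "load_stack",
    "save_isotope_csv",
    "load_isotope_csv",
    "save_series_csv",
    "save_run_netcdf",
    "save_ensemble_json",
    "load_ensemble_json",
]


def _provenance_attrs(provenance: dict | None) -> dict:
    return {str(k): str(v) for k, v in (provenance or {}).items()}


def _grid_from_coords(lon: np.ndarray, lat: np.ndarray) -> LatLonGrid:
    res = float(np.round(np.diff(lon).mean(), 9)) if lon.size > 1 else float(
        np.round(np.diff(lat).mean(), 9)
    )
    return LatLonGrid(np.asarray(lon, float), np.asarray(lat, float), res)


def _to_dataarray(field: ScalarField, name: str = "value") -> xr.DataArray:
    return xr.DataArray(
        field.values,
        dims=("lat", "lon"),
        coords={"lat": field.grid.lat, "lon": field.grid.lon},
        name=name,
        attrs={"units": field.units},
    )


def save_field_netcdf(field: ScalarField, path, name: str = "value",
                      provenance: dict | None = None) -> None:
    ds = _to_dataarray(field, name).to_dataset()
    ds.attrs.update(_provenance_attrs(provenance))
    ds.to_netcdf(path, engine="scipy")


def load_field_netcdf(path, name: str | None = None) -> ScalarField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if name is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValueError(
                    f"{path} holds {data_vars}; specify the variable name"
                )
            name = data_vars[0]
        da = ds[name].load()
    grid = _grid_from_coords(da["lon"].values, da["lat"].values)
    return ScalarField(grid, da.values.astype(float),
                       units=da.attrs.get("units", "1"))


def save_field_csv(field: ScalarField, path, provenance: dict | None = None) -> None:
    lon2, lat2 = field.grid.mesh()
    df = pd.DataFrame(
        {"lon": lon2.ravel(), "lat": lat2.ravel(), "value": field.values.ravel()}
    )
    with open(path, "w") as fh:
        for k, v in _provenance_attrs(provenance).items():
            fh.write(f"# {k}={v}\n")
        fh.write(f"# units={field.units}\n")
        df.to_csv(fh, index=False)


def load_field_csv(path) -> ScalarField:
    units = "1"
    with open(path) as fh:
        header = []
        for line in fh:
            if line.startswith("#"):
                header.append(line)
                if "units=" in line:
                    units = line.split("units=", 1)[1].strip()
            else:
                break
    df = pd.read_csv(path, comment="#")
    lon = np.unique(df["lon"].to_numpy())
    lat = np.unique(df["lat"].to_numpy())
    grid = _grid_from_coords(lon, lat)
    values = np.full(grid.shape, np.nan)
    i = np.searchsorted(lat, df["lat"].to_numpy())
    j = np.searchsorted(lon, df["lon"].to_numpy())
    values[i, j] = df["value"].to_numpy()
    return ScalarField(grid, values, units=units)


def load_rasters(paths: dict, expect_grid: LatLonGrid | None = None) -> dict:
    """Load several rasters and require one shared grid.

    ``paths`` maps names to NetCDF (.nc) or CSV files.  A grid mismatch
    raises an error listing the offending files.
    """
    fields, bad = {}, []
    ref = expect_grid
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"raster file not found: {path}")
        field = (
            load_field_netcdf(path) if path.suffix in (".nc", ".cdf")
            else load_field_csv(path)
        )
        if ref is None:
            ref = field.grid
        elif field.grid.shape != ref.shape or not (
            np.allclose(field.grid.lon, ref.lon) and np.allclose(field.grid.lat, ref.lat)
        ):
            bad.append(str(path))
        fields[name] = field
    if bad:
        raise GridMismatchError(f"rasters on inconsistent grids: {bad}")
    return fields


def save_stack(stack: HepStack, path, provenance: dict | None = None) -> None:
    """HepStack as NetCDF with (phase, regime) dimensions."""
    phases, regimes = ("P1", "P2"), ("GS", "GI")
    data = np.stack(
        [[stack.fields[(p, r)] for r in regimes] for p in phases]
    )
    da = xr.DataArray(
        data,
        dims=("phase", "regime", "lat", "lon"),
        coords={"phase": list(phases), "regime": list(regimes),
                "lat": stack.grid.lat, "lon": stack.grid.lon},
        name="phi_ac",
    )
    ds = da.to_dataset()
    ds.attrs.update(_provenance_attrs(provenance))
    ds.attrs["phase_boundary_ka"] = stack.phase_boundary_ka
    ds.to_netcdf(path, engine="scipy")


def load_stack(path) -> HepStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds["phi_ac"].load()
        boundary = float(ds.attrs.get("phase_boundary_ka", 38.0))
    grid = _grid_from_coords(da["lon"].values, da["lat"].values)
    fields = {}
    for p in da["phase"].values:
        for r in da["regime"].values:
            key = (str(np.char.decode(p) if isinstance(p, bytes) else p),
                   str(np.char.decode(r) if isinstance(r, bytes) else r))
            fields[key] = da.sel(phase=p, regime=r).values.astype(float)
    return HepStack(grid, fields, phase_boundary_ka=boundary)


def save_isotope_csv(series: IsotopeSeries, path,
                     provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in _provenance_attrs(provenance).items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame({"age_ka": series.age_ka, "d18O": series.d18o}).to_csv(
            fh, index=False
        )


def load_isotope_csv(path) -> IsotopeSeries:
    df = pd.read_csv(path, comment="#")
    return normalize_isotope(df["age_ka"].to_numpy(), df["d18O"].to_numpy())


def save_series_csv(run: RunResult, path, provenance: dict | None = None) -> None:
    """Lambda(t) and M(t) at snapshot times."""
    with open(path, "w") as fh:
        for k, v in _provenance_attrs({**run.provenance, **(provenance or {})}).items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(
            {"age_ka": run.times_ka, "lambda_persons": run.lam, "mobility": run.mob}
        ).to_csv(fh, index=False)


def save_run_netcdf(run: RunResult, path, provenance: dict | None = None) -> None:
    """Density history as a (time, lat, lon) NetCDF cube."""
    da = xr.DataArray(
        run.rho,
        dims=("time", "lat", "lon"),
        coords={"time": run.times_ka, "lat": run.grid.lat, "lon": run.grid.lon},
        name="rho",
        attrs={"units": "P/100km2", "time_units": "ka BP"},
    )
    ds = da.to_dataset()
    ds["land"] = xr.DataArray(
        run.mask.land.astype(np.int8), dims=("lat", "lon")
    )
    ds.attrs.update(_provenance_attrs({**run.provenance, **(provenance or {})}))
    ds.to_netcdf(path, engine="scipy")


def save_ensemble_json(ens: NicheEnsemble, path,
                       provenance: dict | None = None) -> None:
    payload = ens.to_dict()
    payload["provenance"] = _provenance_attrs(provenance)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble_json(path) -> NicheEnsemble:
    with open(path) as fh:
        return NicheEnsemble.from_dict(json.load(fh))
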