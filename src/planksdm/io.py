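"""Reading and writing the package's gridded and tabular artifacts.

Gridded stacks travel as CF-style NetCDF (lon/lat/month dims, via xarray's
built-in NetCDF3 backend) with a long-format CSV fallback; occurrence
tables and training sets are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import xarray as xr

from .grids import GridSpec

__all__ = [
    "save_stack",
    "load_stack",
    "stack_to_csv",
    "stack_from_csv",
    "save_occurrences",
    "load_occurrences",
]


def _grid_attrs(spec: GridSpec) -> dict:
    return {
        "grid_lon_min": spec.lon_min,
        "grid_lon_max": spec.lon_max,
        "grid_lat_min": spec.lat_min,
        "grid_lat_max": spec.lat_max,
        "grid_cell_size": spec.cell_size,
        "grid_months": spec.months,
    }


def save_stack(stack: xr.Dataset, path) -> None:
    ds = stack.copy()
    spec = ds.attrs.pop("grid", None)
    ds.attrs.pop("seed", None)
    if spec is not None:
        ds.attrs.update(_grid_attrs(spec))
    ds.to_netcdf(path, engine="scipy")


def load_stack(path) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    keys = {k: ds.attrs.get(f"grid_{k}") for k in
            ("lon_min", "lon_max", "lat_min", "lat_max", "cell_size", "months")}
    if all(v is not None for v in keys.values()):
        keys["months"] = int(keys["months"])
        ds.attrs["grid"] = GridSpec(**keys)
    return ds


def stack_to_csv(stack: xr.Dataset, path) -> None:
    """Long-format gridded CSV fallback (month, lat, lon, variable columns)."""
    df = stack.to_dataframe().reset_index()
    df.to_csv(path, index=False)


def stack_from_csv(path, spec: GridSpec) -> xr.Dataset:
    df = pd.read_csv(path)
    idx_cols = [c for c in ("month", "lat", "lon") if c in df.columns]
    ds = df.set_index(idx_cols).to_xarray()
    ds.attrs["grid"] = spec
    return ds


def save_occurrences(occ: pd.DataFrame, path) -> None:
    occ.to_csv(path, index=False)


def load_occurrences(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
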