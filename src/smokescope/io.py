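"""File formats: NetCDF gridded fields, sensor/indicator CSV, tract GeoJSON.

NetCDF uses dims (time, lat, lon) with a CF-style ``units = "ug m-3"``
attribute, written as NetCDF3 classic through xarray's scipy engine. Dates
are ISO-8601 in CSV; tract ids are opaque strings. GeoJSON tracts carry a
``population`` property.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .grid import DailyField, GridSpec, make_grid
from .synth import Tract


def fields_to_dataset(fields: Sequence[DailyField], name: str = "pm25") -> xr.Dataset:
    """Stack day fields into an xarray Dataset with dims (time, lat, lon)."""
    grid = fields[0].grid
    data = np.stack([f.values for f in fields])
    times = pd.to_datetime([f.date for f in fields])
    ds = xr.Dataset(
        {name: (("time", "lat", "lon"), data)},
        coords={
            "time": times,
            "lat": grid.lat_centers(),
            "lon": grid.lon_centers(),
        },
    )
    ds[name].attrs["units"] = "ug m-3"
    ds[name].attrs["kind"] = fields[0].kind
    ds.attrs["dlon"] = grid.dlon
    ds.attrs["dlat"] = grid.dlat
    ds.attrs["lon0"] = grid.lon0
    ds.attrs["lat0"] = grid.lat0
    return ds


def dataset_to_fields(ds: xr.Dataset, name: str = "pm25") -> list[DailyField]:
    """Inverse of :func:`fields_to_dataset`."""
    da = ds[name]
    dlon = float(ds.attrs["dlon"])
    dlat = float(ds.attrs["dlat"])
    grid = make_grid(
        lon0=float(ds.attrs["lon0"]),
        lat0=float(ds.attrs["lat0"]),
        dlon=dlon,
        dlat=dlat,
        nx=ds.sizes["lon"],
        ny=ds.sizes["lat"],
    )
    kind = da.attrs.get("kind", "total")
    out = []
    for t in range(ds.sizes["time"]):
        date = pd.Timestamp(ds["time"].values[t]).date()
        out.append(DailyField(date, da.values[t], grid, kind))
    return out


def write_fields(fields: Sequence[DailyField], path: str | Path, name: str = "pm25") -> None:
    fields_to_dataset(fields, name).to_netcdf(path, engine="scipy")


def read_fields(path: str | Path, name: str = "pm25") -> list[DailyField]:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_fields(ds.load(), name)


def write_tracts(tracts: Sequence[Tract], path: str | Path) -> None:
    """Tract polygons + populations as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(t.polygon),
            "properties": {"tract_id": t.tract_id, "population": t.population},
        }
        for t in tracts
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_tracts(path: str | Path) -> list[Tract]:
    gj = json.loads(Path(path).read_text())
    return [
        Tract(
            tract_id=str(f["properties"]["tract_id"]),
            polygon=shape(f["geometry"]),
            population=int(f["properties"]["population"]),
        )
        for f in gj["features"]
    ]


def write_sensor_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_sensor_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = df["date"].map(dt.date.fromisoformat)
    return df


def write_cell_obs(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_cell_obs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = df["date"].map(dt.date.fromisoformat)
    return df
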