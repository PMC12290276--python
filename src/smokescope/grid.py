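"""Regular lon-lat grid geometry and date-stamped concentration fields.

The grid is cell-edge anchored: cell ``(i, j)`` covers the half-open box
``[lon0 + i*dlon, lon0 + (i+1)*dlon) x [lat0 + j*dlat, lat0 + (j+1)*dlat)``.
Array storage is row-major ``(ny, nx)`` so ``values[j, i]`` addresses cell
``(i, j)``; this matches the ``(lat, lon)`` dimension order used on disk.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Literal

import numpy as np

FieldKind = Literal["total", "nonsmoke", "smoke"]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A regular longitude-latitude grid.

    Parameters
    ----------
    lon0, lat0 : float
        Degrees of the lower-left cell edge (the grid origin).
    dlon, dlat : float
        Cell spacing in degrees; defaults mirror a 0.625 x 0.5 degree
        chemical-transport-model grid.
    nx, ny : int
        Cell counts along longitude and latitude.
    """

    lon0: float
    lat0: float
    dlon: float = 0.625
    dlat: float = 0.5
    nx: int = 1
    ny: int = 1

    def __post_init__(self) -> None:
        for name in ("dlon", "dlat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("nx", "ny"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``."""
        return (self.ny, self.nx)

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.nx * self.dlon

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.ny * self.dlat

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.nx) + 0.5) * self.dlon

    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.ny) + 0.5) * self.dlat

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        """Center ``(lon, lat)`` of cell ``(i, j)``: edge plus half-spacing."""
        return (self.lon0 + (i + 0.5) * self.dlon, self.lat0 + (j + 0.5) * self.dlat)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Index ``(i, j)`` of the half-open cell containing a point."""
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) lies outside the grid")
        i = int(np.floor((lon - self.lon0) / self.dlon))
        j = int(np.floor((lat - self.lat0) / self.dlat))
        return (min(i, self.nx - 1), min(j, self.ny - 1))

    def contains(self, lon: float, lat: float) -> bool:
        return (self.lon0 <= lon < self.lon_max) and (self.lat0 <= lat < self.lat_max)

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """``(lon_min, lat_min, lon_max, lat_max)`` edges of cell ``(i, j)``."""
        return (
            self.lon0 + i * self.dlon,
            self.lat0 + j * self.dlat,
            self.lon0 + (i + 1) * self.dlon,
            self.lat0 + (j + 1) * self.dlat,
        )

    def covers(self, other: "GridSpec") -> bool:
        """True if this grid's bounding box contains ``other``'s."""
        return (
            self.lon0 <= other.lon0
            and self.lat0 <= other.lat0
            and self.lon_max >= other.lon_max
            and self.lat_max >= other.lat_max
        )


def make_grid(
    lon0: float,
    lat0: float,
    dlon: float = 0.625,
    dlat: float = 0.5,
    nx: int = 1,
    ny: int = 1,
) -> GridSpec:
    """Build a :class:`GridSpec`, rejecting non-positive spacings or counts."""
    return GridSpec(lon0=lon0, lat0=lat0, dlon=dlon, dlat=dlat, nx=nx, ny=ny)


@dataclasses.dataclass
class DailyField:
    """One day of gridded PM2.5 (ug m-3) on a :class:`GridSpec`."""

    date: dt.date
    values: np.ndarray
    grid: GridSpec
    kind: FieldKind = "total"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("PM2.5 field contains negative values")

    def copy(self) -> "DailyField":
        return DailyField(self.date, self.values.copy(), self.grid, self.kind)
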