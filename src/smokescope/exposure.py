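"""Tract-level aggregation and long-term smoke exposure metrics.

The daily smoke field is summarized over census-tract polygons with an
area-fraction-weighted mean (zonal statistics), then rolled up into the
metric suite: AQI-based day categories, person-days of moderate and dense
smoke, seasonal / annual / top-10-day means, smoke-day counts, smoke waves
(runs of >= 2 consecutive moderate-or-dense days), period comparisons, and
pairwise Pearson correlations among metrics.

Category bounds follow the US EPA AQI breakpoints: "moderate" smoke is
9.1-35.4 ug m-3 and "dense" is >= 35.5 ug m-3 (the Unhealthy-for-Sensitive-
Groups floor and above). Daily values are rounded to one decimal before
comparison so these bounds form an exhaustive partition.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .grid import DailyField, GridSpec

EARTH_RADIUS_KM = 6371.0

MODERATE_LOW = 9.1
DENSE_LOW = 35.5

SEASON_START = (5, 1)  # May 1
SEASON_DAYS = 153  # through Sep 30


def _equal_area(geom):
    """Project lon-lat geometry to a Lambert cylindrical equal-area plane.

    x = R*lambda, y = R*sin(phi) (km) — an exact equal-area mapping of the
    sphere, appropriate for comparing polygon areas at high latitudes where
    raw geographic-degree areas overweight east-west extent.
    """

    def f(coords):
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        return np.column_stack(
            [EARTH_RADIUS_KM * lon, EARTH_RADIUS_KM * np.sin(lat)]
        )

    return shapely.transform(geom, f)


def tract_area_km2(polygon: Polygon) -> float:
    """Spherical-surface area of a lon-lat polygon in km^2."""
    return float(_equal_area(polygon).area)


def area_weights(tract_polygon: Polygon, grid: GridSpec) -> dict[tuple[int, int], float]:
    """Per-cell area fractions of a tract: weight = area(tract ∩ cell)/area.

    Areas are computed in an equal-area projection. Weights are normalized
    over the cells intersecting the tract, so they sum to one even if the
    polygon extends slightly beyond the grid. Empty intersection is an
    error.
    """
    if not tract_polygon.is_valid:
        raise ValueError("tract polygon is invalid")
    minx, miny, maxx, maxy = tract_polygon.bounds
    i0 = max(0, int(np.floor((minx - grid.lon0) / grid.dlon)))
    i1 = min(grid.nx - 1, int(np.floor((maxx - grid.lon0) / grid.dlon)))
    j0 = max(0, int(np.floor((miny - grid.lat0) / grid.dlat)))
    j1 = min(grid.ny - 1, int(np.floor((maxy - grid.lat0) / grid.dlat)))
    weights: dict[tuple[int, int], float] = {}
    for j in range(j0, j1 + 1):
        for i in range(i0, i1 + 1):
            cell = box(*grid.cell_bounds(i, j))
            inter = tract_polygon.intersection(cell)
            if not inter.is_empty:
                a = _equal_area(inter).area
                if a > 0:
                    weights[(i, j)] = a
    total = sum(weights.values())
    if total == 0:
        raise ValueError("tract polygon does not intersect the grid")
    return {c: a / total for c, a in weights.items()}


@dataclasses.dataclass
class TractSeries:
    """Daily tract-mean smoke PM2.5 with population and the weights used."""

    tract_id: str
    population: int
    dates: list[dt.date]
    smoke: np.ndarray
    weights: dict[tuple[int, int], float]


def tract_daily_smoke(
    smoke_fields: Sequence[DailyField],
    weights: dict[tuple[int, int], float],
    population: int,
    tract_id: str = "",
) -> TractSeries:
    """Area-weighted daily tract mean of the smoke field.

    The date sequence must be gap-free (consecutive days); exposure metrics
    assume a complete season.
    """
    dates = [f.date for f in smoke_fields]
    deltas = {(b - a).days for a, b in zip(dates, dates[1:])}
    if deltas - {1}:
        raise ValueError(f"date gaps in smoke fields for tract {tract_id}")
    cells = list(weights)
    w = np.array([weights[c] for c in cells])
    jj = np.array([c[1] for c in cells])
    ii = np.array([c[0] for c in cells])
    series = np.array([float(f.values[jj, ii] @ w) for f in smoke_fields])
    return TractSeries(
        tract_id=tract_id,
        population=population,
        dates=dates,
        smoke=series,
        weights=weights,
    )


def categorize_day(value: float, round_first: bool = True) -> str:
    """AQI smoke category of a daily mean: good, moderate, or dense.

    With ``round_first`` (default) the value is rounded to one decimal
    before comparison, making the bounds 9.1-35.4 / >= 35.5 an exhaustive
    partition of the line (the AQI breakpoint convention).
    """
    if value < 0:
        raise ValueError("daily mean must be non-negative")
    v = round(value, 1) if round_first else value
    if v >= DENSE_LOW:
        return "dense"
    if v >= MODERATE_LOW:
        return "moderate"
    return "good"


def categorize_series(values: np.ndarray, round_first: bool = True) -> np.ndarray:
    """Vectorized day categories for a tract series."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("daily means must be non-negative")
    if round_first:
        v = np.round(v, 1)
    out = np.full(v.shape, "good", dtype=object)
    out[v >= MODERATE_LOW] = "moderate"
    out[v >= DENSE_LOW] = "dense"
    return out


def smoke_waves(categories: Sequence[str]) -> tuple[int, int]:
    """(number of smoke waves, longest wave length) of a category sequence.

    A smoke wave is a maximal run of >= 2 consecutive moderate-or-dense
    days; the longest wave is 0 when there is none.
    """
    n_waves = 0
    longest = 0
    run = 0
    for cat in categories:
        if cat in ("moderate", "dense"):
            run += 1
        else:
            if run >= 2:
                n_waves += 1
                longest = max(longest, run)
            run = 0
    if run >= 2:
        n_waves += 1
        longest = max(longest, run)
    return n_waves, longest


def person_days(
    series_set: Iterable[TractSeries],
    category: str,
    period: tuple[dt.date, dt.date] | None = None,
    round_first: bool = True,
) -> float:
    """Total person-days in a category: sum over tracts of pop * #days.

    ``period`` restricts to dates in [start, end] inclusive; additive over
    tracts and days by construction.
    """
    total = 0.0
    for ts in series_set:
        mask = np.ones(len(ts.dates), dtype=bool)
        if period is not None:
            start, end = period
            mask = np.array([start <= d <= end for d in ts.dates])
        cats = categorize_series(ts.smoke[mask], round_first)
        total += ts.population * int(np.sum(cats == category))
    return total


def weekly_person_days(
    series_set: Iterable[TractSeries],
    category: str,
    round_first: bool = True,
) -> pd.DataFrame:
    """Person-days per 7-day bin anchored at the first series date (May 1).

    The final bin of a 153-day season holds 6 days; binning is exhaustive so
    weekly values sum exactly to the seasonal total.
    """
    rows = []
    for ts in series_set:
        cats = categorize_series(ts.smoke, round_first)
        anchor = ts.dates[0]
        weeks = np.array([(d - anchor).days // 7 for d in ts.dates])
        for wk in np.unique(weeks):
            n = int(np.sum((weeks == wk) & (cats == category)))
            rows.append((ts.tract_id, int(wk), ts.population * n))
    df = pd.DataFrame(rows, columns=["tract_id", "week", "person_days"])
    return df.groupby("week", as_index=False)["person_days"].sum()


@dataclasses.dataclass
class TractYearMetrics:
    tract_id: str
    year: int
    person_days_moderate: float
    person_days_dense: float
    mean_annual: float
    mean_season: float
    mean_top10: float
    days_moderate_or_dense: int
    days_dense: int
    n_smoke_waves: int
    longest_wave: int


def tract_year_metrics(
    series: TractSeries, year: int, round_first: bool = True
) -> TractYearMetrics:
    """Annual metric suite for one tract over one complete wildfire season.

    ``mean_season`` averages the 153 season days; ``mean_annual`` spreads
    the season sum over the calendar year (smoke set to zero outside the
    season); ``mean_top10`` averages the 10 highest daily values.
    """
    season_start = dt.date(year, *SEASON_START)
    idx = [k for k, d in enumerate(series.dates) if d.year == year and d >= season_start]
    if len(idx) < SEASON_DAYS:
        raise ValueError(
            f"tract {series.tract_id}: season {year} incomplete "
            f"({len(idx)}/{SEASON_DAYS} days)"
        )
    vals = series.smoke[idx][:SEASON_DAYS]
    cats = categorize_series(vals, round_first)
    smoky = (cats == "moderate") | (cats == "dense")
    n_waves, longest = smoke_waves(cats)
    days_in_year = 366 if dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365
    n_mod = int(np.sum(cats == "moderate"))
    n_dense = int(np.sum(cats == "dense"))
    return TractYearMetrics(
        tract_id=series.tract_id,
        year=year,
        person_days_moderate=series.population * n_mod,
        person_days_dense=series.population * n_dense,
        mean_annual=float(vals.sum() / days_in_year),
        mean_season=float(vals.mean()),
        mean_top10=float(np.sort(vals)[-10:].mean()),
        days_moderate_or_dense=int(smoky.sum()),
        days_dense=n_dense,
        n_smoke_waves=n_waves,
        longest_wave=longest,
    )


def metrics_table(metrics: Iterable[TractYearMetrics]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in metrics])


def period_change(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-tract person-day change flags between two periods.

    Input frames are tract-year metric tables for each period; per tract,
    person-days are summed within period and a flag per category marks an
    increase (period b exceeds period a). The summary gives the share of
    tracts increasing per category.
    """
    cols = ["person_days_moderate", "person_days_dense"]
    a = metrics_a.groupby("tract_id")[cols].sum()
    b = metrics_b.groupby("tract_id")[cols].sum()
    if set(a.index) != set(b.index):
        raise ValueError("periods cover different tract sets")
    b = b.loc[a.index]
    flags = (b > a).rename(
        columns={c: c.replace("person_days", "increase") for c in cols}
    )
    flags = flags.reset_index()
    summary = {
        "share_increasing_moderate": float(flags["increase_moderate"].mean()),
        "share_increasing_dense": float(flags["increase_dense"].mean()),
    }
    return flags, summary


def metric_correlations(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among the numeric exposure metrics.

    Pairwise-complete over missing values; a zero-variance metric yields
    missing correlations with a warning.
    """
    num = metrics.drop(columns=["tract_id", "year"], errors="ignore").astype(float)
    if len(num) < 3:
        raise ValueError("need at least 3 tracts for correlations")
    degenerate = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    if degenerate:
        warnings.warn(
            f"zero-variance metrics, correlations undefined: {degenerate}",
            stacklevel=2,
        )
    return num.corr(method="pearson")
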