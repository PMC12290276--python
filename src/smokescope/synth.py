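"""Synthetic scene generator with known ground truth.

Emulates the four inputs of the hybrid exposure pipeline — true and
model-distorted gridded PM2.5 fields, noisy sensor streams, census-tract
polygons with populations, and tract vulnerability indicators — so every
downstream stage can be tested against a planted truth without any external
data. The plume model is a drifting isotropic Gaussian kernel, not physical
transport: it only needs to produce spatially coherent, heavy-tailed smoke
with configurable quiet and extreme seasons.

All randomness flows from one master seed through named substreams
(``fields``, ``model``, ``sensors``, ``tracts``, ``indicators``), so each
scene component can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .grid import DailyField, GridSpec, make_grid

# Fixed tags keep substreams stable across releases.
_SUBSTREAMS = {"fields": 1, "model": 2, "sensors": 3, "tracts": 4, "indicators": 5}

# Low-cost calibration coefficients; the generator inverts this affine form
# so that applying the calibration to its raw output recovers truth exactly.
CAL_SLOPE = 0.524
CAL_RH = 0.0862
CAL_INTERCEPT = 5.75

#: 7 health-sensitivity indicator columns.
SENSITIVITY_INDICATORS = [
    "age_le_17",
    "age_ge_65",
    "asthma",
    "copd",
    "cardiovascular",
    "women_childbearing",
    "outdoor_workers",
]
#: 8 adaptive-capacity indicator columns.
ADAPTIVE_INDICATORS = [
    "disability",
    "single_parent",
    "limited_english",
    "below_150_poverty",
    "housing_cost_burden",
    "unemployed",
    "uninsured",
    "no_hs_diploma",
]
ALL_INDICATORS = SENSITIVITY_INDICATORS + ADAPTIVE_INDICATORS


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the master seed."""
    return np.random.default_rng([int(seed), _SUBSTREAMS[name]])


def season_dates(year: int) -> list[dt.date]:
    """Wildfire-season days, May 1 through Sep 30 (153 days)."""
    start = dt.date(year, 5, 1)
    return [start + dt.timedelta(days=k) for k in range(153)]


@dataclasses.dataclass(frozen=True)
class FireEvent:
    """One synthetic fire: a drifting Gaussian plume source.

    ``peak_emission`` is the smoke concentration (ug m-3) at the plume
    center; ``decay_length`` is the Gaussian sigma in degrees; ``drift`` is
    the daily center displacement (dlon/day, dlat/day).
    """

    center: tuple[float, float]
    start: int  # day index into the date list
    duration: int
    peak_emission: float
    decay_length: float
    drift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1 day")
        if self.peak_emission <= 0:
            raise ValueError("peak_emission must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclasses.dataclass
class Tract:
    tract_id: str
    polygon: Polygon
    population: int


@dataclasses.dataclass
class SceneTruth:
    """Complete synthetic scene: truth, distorted model, sensors, tracts."""

    grid: GridSpec
    dates: list[dt.date]
    truth_total: list[DailyField]
    truth_nonsmoke: list[DailyField]
    truth_smoke: list[DailyField]
    model_total_fine: list[DailyField]
    model_nonsmoke_coarse: list[DailyField]
    sensors: pd.DataFrame  # hourly table
    tracts: list[Tract]
    vuln_indicators: pd.DataFrame
    vuln_truth: list[str]  # planted high-vulnerability tract ids


def simulate_truth(
    grid: GridSpec,
    dates: Sequence[dt.date],
    fires: Sequence[FireEvent],
    mu_b: float = float(np.log(2.0)),
    sigma_b: float = 0.3,
    seed: int = 0,
) -> tuple[list[DailyField], list[DailyField], list[DailyField]]:
    """Generate (truth_total, truth_nonsmoke, truth_smoke) day fields.

    Non-smoke background is lognormal LN(mu_b, sigma_b) per cell-day,
    emulating low summer background PM2.5 (median 2 ug m-3 by default).
    Each active fire adds ``peak * exp(-d^2 / (2 L^2))`` around its drifting
    center; smoke is the plume sum and total = nonsmoke + smoke exactly.
    """
    if len(dates) == 0:
        raise ValueError("dates must be non-empty")
    rng = substream(seed, "fields")
    lon_c = grid.lon_centers()[None, :]  # (1, nx)
    lat_c = grid.lat_centers()[:, None]  # (ny, 1)

    totals, nonsmokes, smokes = [], [], []
    for t, date in enumerate(dates):
        nonsmoke = rng.lognormal(mean=mu_b, sigma=sigma_b, size=grid.shape)
        smoke = np.zeros(grid.shape)
        for fire in fires:
            if not (fire.start <= t < fire.start + fire.duration):
                continue
            age = t - fire.start
            cx = fire.center[0] + age * fire.drift[0]
            cy = fire.center[1] + age * fire.drift[1]
            d2 = (lon_c - cx) ** 2 + (lat_c - cy) ** 2
            smoke += fire.peak_emission * np.exp(-d2 / (2.0 * fire.decay_length**2))
        total = nonsmoke + smoke
        nonsmokes.append(DailyField(date, nonsmoke, grid, "nonsmoke"))
        smokes.append(DailyField(date, smoke, grid, "smoke"))
        totals.append(DailyField(date, total, grid, "total"))
    return totals, nonsmokes, smokes


def default_fires(
    grid: GridSpec, n_days: int, n_fires: int, seed: int
) -> list[FireEvent]:
    """Random fire events sized for a heavy-tailed smoke season.

    ``n_fires`` controls the season character: 1-2 emulates a quiet year,
    4+ a high-fire year with overlapping plumes and dense-smoke days.
    """
    rng = substream(seed, "fields").spawn(1)[0]
    fires = []
    for _ in range(n_fires):
        center = (
            rng.uniform(grid.lon0, grid.lon_max),
            rng.uniform(grid.lat0, grid.lat_max),
        )
        duration = int(rng.integers(5, max(6, n_days // 3)))
        start = int(rng.integers(0, max(1, n_days - duration)))
        fires.append(
            FireEvent(
                center=center,
                start=start,
                duration=duration,
                peak_emission=float(rng.lognormal(np.log(60.0), 0.5)),
                decay_length=float(rng.uniform(0.8, 2.0)),
                drift=(float(rng.normal(0, 0.15)), float(rng.normal(0, 0.1))),
            )
        )
    return fires


def _smoothstep_ramp(x: np.ndarray, high_bias: float, knee: float = 35.0) -> np.ndarray:
    """Inflation factor rising smoothly from 1 at 0 to ``high_bias`` at ``knee``."""
    s = np.clip(x / knee, 0.0, 1.0)
    s = s * s * (3.0 - 2.0 * s)
    return 1.0 + (high_bias - 1.0) * s


def coarse_grid_for(grid: GridSpec, dlon: float = 2.5, dlat: float = 2.0) -> GridSpec:
    """Smallest coarse grid at the given spacing that covers ``grid``."""
    nx = int(np.ceil(grid.nx * grid.dlon / dlon))
    ny = int(np.ceil(grid.ny * grid.dlat / dlat))
    return make_grid(grid.lon0, grid.lat0, dlon, dlat, nx, ny)


def block_mean_to_coarse(field: DailyField, coarse: GridSpec) -> np.ndarray:
    """Mean of fine-cell values whose centers fall in each coarse cell."""
    grid = field.grid
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    ci = np.clip(((lon_c - coarse.lon0) / coarse.dlon).astype(int), 0, coarse.nx - 1)
    cj = np.clip(((lat_c - coarse.lat0) / coarse.dlat).astype(int), 0, coarse.ny - 1)
    out = np.zeros(coarse.shape)
    cnt = np.zeros(coarse.shape)
    CI, CJ = np.meshgrid(ci, cj)
    np.add.at(out, (CJ, CI), field.values)
    np.add.at(cnt, (CJ, CI), 1.0)
    return np.where(cnt > 0, out / np.maximum(cnt, 1), 0.0)


def distort_to_model(
    truth_total: Sequence[DailyField],
    truth_nonsmoke: Sequence[DailyField],
    coarse_grid: GridSpec | None = None,
    high_bias: float = 1.8,
    noise_sigma: float = 0.2,
    coarse_noise_sigma: float = 0.1,
    seed: int = 0,
) -> tuple[list[DailyField], list[DailyField]]:
    """Distort truth into a biased "model": the error the blending must fix.

    Fine total is inflated by a smooth ramp reaching ``high_bias`` above
    35 ug m-3 (emulating model overestimation during heavy smoke) times
    multiplicative lognormal noise LN(0, noise_sigma). The non-smoke field
    is block-averaged onto ``coarse_grid`` (default 2 x 2.5 degrees) with
    its own lognormal noise.
    """
    if high_bias < 1.0:
        warnings.warn("high_bias < 1 produces a deflation scenario", stacklevel=2)
    grid = truth_total[0].grid
    if coarse_grid is None:
        coarse_grid = coarse_grid_for(grid)
    if not coarse_grid.covers(grid):
        raise ValueError("coarse grid must cover the fine grid")
    rng = substream(seed, "model")
    model_fine, model_coarse = [], []
    for ft, fn in zip(truth_total, truth_nonsmoke):
        eps = (
            rng.lognormal(0.0, noise_sigma, size=grid.shape)
            if noise_sigma > 0
            else np.ones(grid.shape)
        )
        vals = ft.values * _smoothstep_ramp(ft.values, high_bias) * eps
        model_fine.append(DailyField(ft.date, np.maximum(vals, 0.0), grid, "total"))

        cvals = block_mean_to_coarse(fn, coarse_grid)
        ceps = (
            rng.lognormal(0.0, coarse_noise_sigma, size=coarse_grid.shape)
            if coarse_noise_sigma > 0
            else np.ones(coarse_grid.shape)
        )
        model_coarse.append(
            DailyField(fn.date, np.maximum(cvals * ceps, 0.0), coarse_grid, "nonsmoke")
        )
    return model_fine, model_coarse


def place_sensors(
    grid: GridSpec,
    truth_total: Sequence[DailyField],
    n_regulatory: int = 3,
    n_lowcost: int = 6,
    hourly_noise_sigma: float = 0.05,
    missingness: float = 0.0,
    n_clusters: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly sensor table emulating regulatory and low-cost networks.

    Sensors cluster in a few "population" cells to mimic monitor siting near
    towns. Regulatory hourly value = truth at the sensor cell times
    LN(0, hourly_noise_sigma). Low-cost sensors report the raw cf1 channel
    obtained by inverting the affine calibration at an hourly RH drawn from
    Uniform(20, 80), plus the same hourly noise, so that calibrating their
    stream recovers truth when noise is off. ``missingness`` drops each
    hourly row independently.

    Returns a DataFrame with columns sensor_id, lon, lat, type, date, hour,
    value, cf1, rh (value is NaN for low-cost rows; cf1/rh NaN for
    regulatory rows).
    """
    n_total = n_regulatory + n_lowcost
    if n_total < 1:
        raise ValueError("need at least one sensor")
    if not 0.0 <= missingness < 1.0:
        raise ValueError("missingness must be in [0, 1)")
    rng = substream(seed, "sensors")

    n_clusters = max(1, min(n_clusters, grid.nx * grid.ny))
    flat = rng.choice(grid.nx * grid.ny, size=n_clusters, replace=False)
    cluster_cells = [(int(f % grid.nx), int(f // grid.nx)) for f in flat]

    records = []
    for s in range(n_total):
        stype = "regulatory" if s < n_regulatory else "lowcost"
        ci, cj = cluster_cells[int(rng.integers(0, n_clusters))]
        lon = grid.lon0 + (ci + rng.uniform(0.1, 0.9)) * grid.dlon
        lat = grid.lat0 + (cj + rng.uniform(0.1, 0.9)) * grid.dlat
        sid = f"{stype[:3]}-{s:03d}"
        for fld in truth_total:
            truth = fld.values[cj, ci]
            keep = (
                rng.uniform(size=24) >= missingness
                if missingness > 0
                else np.ones(24, bool)
            )
            noise = (
                rng.lognormal(0.0, hourly_noise_sigma, size=24)
                if hourly_noise_sigma > 0
                else np.ones(24)
            )
            rh = rng.uniform(20.0, 80.0, size=24)
            for h in range(24):
                if not keep[h]:
                    continue
                if stype == "regulatory":
                    records.append(
                        (sid, lon, lat, stype, fld.date, h, truth * noise[h], np.nan, np.nan)
                    )
                else:
                    cf1 = (truth * noise[h] - CAL_INTERCEPT + CAL_RH * rh[h]) / CAL_SLOPE
                    records.append((sid, lon, lat, stype, fld.date, h, np.nan, cf1, rh[h]))
    return pd.DataFrame(
        records,
        columns=["sensor_id", "lon", "lat", "type", "date", "hour", "value", "cf1", "rh"],
    )


def make_tracts(
    grid: GridSpec,
    n_tracts: int = 40,
    urban_fraction: float = 0.6,
    pop_mu: float = float(np.log(2000.0)),
    pop_sigma: float = 0.8,
    seed: int = 0,
) -> list[Tract]:
    """Census-tract stand-ins: a mix of small urban and large rural boxes.

    About ``urban_fraction`` of tracts are sub-cell rectangles inside single
    grid cells (urban, more populous); the rest span several cells (rural).
    This mimics the real mixture where most tracts overlap only 1-2 model
    cells while a few rural tracts cover many.
    """
    if n_tracts < 2:
        raise ValueError("n_tracts must be >= 2")
    rng = substream(seed, "tracts")
    tracts = []
    n_urban = int(round(urban_fraction * n_tracts))
    for k in range(n_tracts):
        if k < n_urban:
            i = int(rng.integers(0, grid.nx))
            j = int(rng.integers(0, grid.ny))
            x0, y0, x1, y1 = grid.cell_bounds(i, j)
            fx0, fx1 = np.sort(rng.uniform(0.05, 0.95, size=2))
            fy0, fy1 = np.sort(rng.uniform(0.05, 0.95, size=2))
            if fx1 - fx0 < 0.1:
                fx0, fx1 = 0.2, 0.8
            if fy1 - fy0 < 0.1:
                fy0, fy1 = 0.2, 0.8
            poly = box(
                x0 + fx0 * (x1 - x0),
                y0 + fy0 * (y1 - y0),
                x0 + fx1 * (x1 - x0),
                y0 + fy1 * (y1 - y0),
            )
            pop = int(np.ceil(rng.lognormal(pop_mu + 0.7, pop_sigma)))
        else:
            w = rng.uniform(1.2, min(4.0, grid.nx)) * grid.dlon
            h = rng.uniform(1.2, min(4.0, grid.ny)) * grid.dlat
            x0 = rng.uniform(grid.lon0, max(grid.lon0, grid.lon_max - w))
            y0 = rng.uniform(grid.lat0, max(grid.lat0, grid.lat_max - h))
            poly = box(x0, y0, min(x0 + w, grid.lon_max), min(y0 + h, grid.lat_max))
            pop = int(np.ceil(rng.lognormal(pop_mu - 0.5, pop_sigma)))
        tracts.append(Tract(tract_id=f"T{k:03d}", polygon=poly, population=max(pop, 1)))
    return tracts


# Base mean proportion per indicator; rough magnitudes for tract-level shares.
_BASE_MEANS = {
    "age_le_17": 0.24,
    "age_ge_65": 0.13,
    "asthma": 0.10,
    "copd": 0.06,
    "cardiovascular": 0.07,
    "women_childbearing": 0.21,
    "outdoor_workers": 0.15,
    "disability": 0.13,
    "single_parent": 0.06,
    "limited_english": 0.04,
    "below_150_poverty": 0.18,
    "housing_cost_burden": 0.20,
    "unemployed": 0.08,
    "uninsured": 0.14,
    "no_hs_diploma": 0.08,
}


def make_vuln_indicators(
    tracts: Sequence[Tract],
    planted_high_ids: Sequence[str] = (),
    effect: float = 0.10,
    sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Tract vulnerability-indicator proportions with planted structure.

    Each of the 15 indicators is Beta-distributed with standard deviation
    ``sd``; tracts in ``planted_high_ids`` have every indicator mean shifted
    up by ``effect``, creating a known high-vulnerability subset the index
    construction should recover.
    """
    ids = [t.tract_id for t in tracts]
    unknown = set(planted_high_ids) - set(ids)
    if unknown:
        raise ValueError(f"planted ids not in tract set: {sorted(unknown)}")
    rng = substream(seed, "indicators")
    out = {"tract_id": ids}
    planted = np.array([tid in set(planted_high_ids) for tid in ids])
    for col in ALL_INDICATORS:
        mean = np.full(len(ids), _BASE_MEANS[col])
        mean[planted] += effect
        if np.any((mean <= 0) | (mean >= 1)):
            warnings.warn(f"shifted mean for {col} clipped into (0, 1)", stacklevel=2)
            mean = np.clip(mean, 0.01, 0.99)
        # Match the Beta variance m(1-m)/(kappa+1) to sd^2 per tract.
        kappa = np.maximum(mean * (1 - mean) / sd**2 - 1.0, 0.5)
        vals = rng.beta(mean * kappa, (1 - mean) * kappa)
        out[col] = np.clip(vals, 0.0, 1.0)
    return pd.DataFrame(out)


def make_scene(
    grid: GridSpec | None = None,
    year: int = 2019,
    n_days: int | None = None,
    n_fires: int = 3,
    n_regulatory: int = 3,
    n_lowcost: int = 6,
    n_tracts: int = 40,
    high_bias: float = 1.8,
    model_noise_sigma: float = 0.2,
    sensor_noise_sigma: float = 0.05,
    missingness: float = 0.0,
    planted_fraction: float = 0.2,
    vuln_effect: float = 0.10,
    seed: int = 0,
) -> SceneTruth:
    """Build a full scene with one call; the downstream pipeline's test bed.

    Defaults describe one 153-day wildfire season (May 1 - Sep 30) on a
    16 x 10 cell grid at 0.625 x 0.5 degree spacing with three fires —
    a moderately smoky season. ``n_days`` truncates the season for speed.
    """
    if grid is None:
        grid = make_grid(-160.0, 55.0, 0.625, 0.5, 16, 10)
    dates = season_dates(year)
    if n_days is not None:
        dates = dates[:n_days]
    fires = default_fires(grid, len(dates), n_fires, seed)
    truth_total, truth_nonsmoke, truth_smoke = simulate_truth(
        grid, dates, fires, seed=seed
    )
    model_fine, model_coarse = distort_to_model(
        truth_total,
        truth_nonsmoke,
        high_bias=high_bias,
        noise_sigma=model_noise_sigma,
        seed=seed,
    )
    sensors = place_sensors(
        grid,
        truth_total,
        n_regulatory=n_regulatory,
        n_lowcost=n_lowcost,
        hourly_noise_sigma=sensor_noise_sigma,
        missingness=missingness,
        seed=seed,
    )
    tracts = make_tracts(grid, n_tracts=n_tracts, seed=seed)
    n_planted = max(1, int(round(planted_fraction * n_tracts)))
    planted_rng = substream(seed, "indicators").spawn(1)[0]
    planted = sorted(
        planted_rng.choice([t.tract_id for t in tracts], size=n_planted, replace=False)
    )
    indicators = make_vuln_indicators(tracts, planted, effect=vuln_effect, seed=seed)
    return SceneTruth(
        grid=grid,
        dates=list(dates),
        truth_total=truth_total,
        truth_nonsmoke=truth_nonsmoke,
        truth_smoke=truth_smoke,
        model_total_fine=model_fine,
        model_nonsmoke_coarse=model_coarse,
        sensors=sensors,
        tracts=tracts,
        vuln_indicators=indicators,
        vuln_truth=list(planted),
    )
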