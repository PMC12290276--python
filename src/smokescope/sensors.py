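"""Sensor quality control, low-cost calibration, and grid collocation.

Raw hourly streams come from two networks: regulatory monitors reporting
calibrated PM2.5 directly, and low-cost sensors reporting a raw cf1 channel
plus relative humidity that must pass through the affine US calibration

    PM2.5 = 0.524 * cf1 - 0.0862 * RH + 5.75   (ug m-3)

before use. Days with fewer than 75% of hourly records, or implausible
(<= 0 ug m-3) daily means, are dropped. Retained daily means are averaged
onto model grid cells (unweighted mean when a cell holds several sensors).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grid import GridSpec
from .synth import CAL_INTERCEPT, CAL_RH, CAL_SLOPE

logger = logging.getLogger(__name__)

COMPLETENESS_THRESHOLD = 0.75


def calibrate_lowcost(cf1, rh):
    """Calibrated PM2.5 (ug m-3) from raw cf1 and relative humidity (%).

    Vectorized affine form ``0.524*cf1 - 0.0862*RH + 5.75``. RH outside
    [0, 100] is rejected; results <= 0 are returned as-is and flagged
    implausible by the daily QC step.
    """
    cf1 = np.asarray(cf1, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100]%")
    out = CAL_SLOPE * cf1 - CAL_RH * rh + CAL_INTERCEPT
    return float(out) if out.ndim == 0 else out


def daily_average(hourly_values):
    """Daily mean and completeness from (hour, value) pairs, or None.

    Returns ``(daily_mean, completeness)`` when at least 75% of the 24
    hourly records are present ("fewer than 75%" excludes, so exactly 18 of
    24 hours is retained); otherwise None. Duplicate or out-of-range hours
    are rejected. The implausibility rule (mean <= 0) is applied by the
    caller so that the drop can be logged per sensor.
    """
    hours = [h for h, _ in hourly_values]
    if any(not 0 <= h <= 23 for h in hours):
        raise ValueError("hours must lie in 0..23")
    if len(set(hours)) != len(hours):
        raise ValueError("duplicate hourly records for the same day")
    completeness = len(hours) / 24.0
    if completeness < COMPLETENESS_THRESHOLD:
        return None
    values = np.array([v for _, v in hourly_values], dtype=float)
    return float(values.mean()), completeness


def qc_daily(raw: pd.DataFrame, calibration: str = "hourly") -> pd.DataFrame:
    """Hourly sensor table -> retained daily records (SensorDay rows).

    Low-cost rows are calibrated from (cf1, rh); ``calibration`` selects
    whether the form is applied to each hourly pair ("hourly", default) or
    to the daily means of cf1 and RH ("daily"). Because the calibration is
    affine, the two agree exactly on the same set of present hours; the flag
    exists so a nonlinear calibration could be swapped in without changing
    the QC path.

    Applies the 75% completeness rule, then drops daily means <= 0 ug m-3
    as implausible. Returns columns sensor_id, lon, lat, type, date,
    daily_mean, completeness.
    """
    if calibration not in ("hourly", "daily"):
        raise ValueError("calibration must be 'hourly' or 'daily'")
    records = []
    n_incomplete = n_implausible = 0
    for (sid, date), g in raw.groupby(["sensor_id", "date"], sort=True):
        if g["hour"].duplicated().any():
            raise ValueError(f"duplicate hours for sensor {sid} on {date}")
        completeness = len(g) / 24.0
        if completeness < COMPLETENESS_THRESHOLD:
            n_incomplete += 1
            continue
        stype = g["type"].iloc[0]
        if stype == "lowcost":
            if calibration == "hourly":
                mean = float(np.mean(calibrate_lowcost(g["cf1"], g["rh"])))
            else:
                mean = float(calibrate_lowcost(g["cf1"].mean(), g["rh"].mean()))
        else:
            mean = float(g["value"].mean())
        if mean <= 0:
            n_implausible += 1
            continue
        records.append(
            (sid, g["lon"].iloc[0], g["lat"].iloc[0], stype, date, mean, completeness)
        )
    logger.info(
        "qc_daily: retained %d sensor-days, dropped %d incomplete, %d implausible",
        len(records),
        n_incomplete,
        n_implausible,
    )
    return pd.DataFrame(
        records,
        columns=["sensor_id", "lon", "lat", "type", "date", "daily_mean", "completeness"],
    )


def collocate(sensor_days: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Average retained daily records onto grid cells.

    One record per (cell, date) with at least one reporting sensor; the
    value is the unweighted mean over sensors whose location falls in that
    cell. A sensor outside the grid is an error naming the sensor.

    Returns columns i, j, date, value, n_sensors.
    """
    if sensor_days.empty:
        return pd.DataFrame(columns=["i", "j", "date", "value", "n_sensors"])
    df = sensor_days.copy()
    cells = []
    for sid, lon, lat in df[["sensor_id", "lon", "lat"]].itertuples(index=False):
        if not grid.contains(lon, lat):
            raise ValueError(f"sensor {sid} at ({lon}, {lat}) lies outside the grid")
        cells.append(grid.cell_of(lon, lat))
    df["i"] = [c[0] for c in cells]
    df["j"] = [c[1] for c in cells]
    out = (
        df.groupby(["i", "j", "date"], sort=True)["daily_mean"]
        .agg(value="mean", n_sensors="size")
        .reset_index()
    )
    out["n_sensors"] = out["n_sensors"].astype(int)
    return out
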