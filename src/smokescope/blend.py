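"""Model-observation blending and smoke-fraction attribution.

The calibration chain, applied day by day in a fixed order:

1. **Quantile mapping** — a monotone empirical transform fitted on pooled
   (model, observed) day pairs at sensor cells aligns the model's total
   PM2.5 distribution with the observed one; extreme model values are
   capped at the observed 100th quantile.
2. **Observation substitution** — sensor-cell values are replaced by the
   observations themselves; the residual (quantile-mapped minus observed)
   is recorded as that cell's bias.
3. **Successive correction (SCM)** — each bias is spread to surrounding
   cells with Cressman distance weights ``(R^2 - d^2)/(R^2 + d^2)`` over a
   schedule of shrinking radii (default 3 then 2 cells), removing local
   steps around sensors while leaving remote cells untouched.
4. **Smoke fraction** — the with/without-fire model pair gives a smoke
   fraction ``1 - nonsmoke/total`` per cell; multiplying the calibrated
   total by this fraction yields the final smoke PM2.5 field.

Cross-validation (leave-one-cell-out or k-fold over sensor-days) refits the
chain without held-out observations and scores predictions at them.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import DailyField, GridSpec

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class QuantileMap:
    """Monotone empirical map from model quantiles to observed quantiles."""

    probs: np.ndarray
    model_q: np.ndarray
    obs_q: np.ndarray

    @property
    def cap(self) -> float:
        """Observed 100th quantile; the ceiling for any mapped value."""
        return float(self.obs_q[-1])

    def __call__(self, x):
        """Map model values; linear between knots, capped above the model max."""
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.model_q, self.obs_q)
        return np.maximum(out, 0.0)


@dataclasses.dataclass(frozen=True)
class CorrectionSchedule:
    """SCM pass radii in cell units, one pass per radius, non-increasing."""

    radii: tuple[float, ...] = (3.0, 2.0)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if any(a < b for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be non-increasing")


@dataclasses.dataclass
class ValidationReport:
    scheme: str
    k: int
    fold_rmse: list[float]
    fold_r2: list[float]
    pooled_rmse: float
    pooled_r2: float
    n_pairs: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_quantile_map(
    matched_pairs: Sequence[tuple[float, float]] | np.ndarray,
    n_probs: int = 101,
) -> QuantileMap:
    """Fit an empirical quantile map from pooled (model, observed) pairs.

    Quantiles of each margin are taken at ``n_probs`` evenly spaced
    probabilities in [0, 1] (linear interpolation between order statistics);
    the map interpolates linearly between matched knots and returns the
    observed maximum (the cap) for queries above the model maximum.
    """
    pairs = np.asarray(matched_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("matched_pairs must be an (n, 2) array of (model, obs)")
    if len(pairs) < 10:
        raise ValueError(
            f"need >= 10 matched pairs to fit a quantile map, got {len(pairs)}; "
            "consider pooling more sensor cells or days"
        )
    probs = np.linspace(0.0, 1.0, n_probs)
    model_q = np.quantile(pairs[:, 0], probs)
    obs_q = np.quantile(pairs[:, 1], probs)
    # np.quantile guarantees monotone output; enforce against fp jitter.
    model_q = np.maximum.accumulate(model_q)
    obs_q = np.maximum.accumulate(obs_q)
    return QuantileMap(probs=probs, model_q=model_q, obs_q=obs_q)


def apply_quantile_map(field: DailyField, qmap: QuantileMap) -> DailyField:
    """Cell-wise monotone transform of a total-PM2.5 field; output <= cap."""
    return DailyField(field.date, qmap(field.values), field.grid, field.kind)


def substitute_observations(
    field: DailyField, cell_obs: pd.DataFrame
) -> tuple[DailyField, pd.DataFrame]:
    """Replace sensor-cell values by observations and record their biases.

    ``cell_obs`` holds rows (i, j, date, value) for the field's date. The
    bias per sensor cell is (quantile-mapped model value - observation);
    positive bias means the mapped model still overestimates there.
    Returns the substituted field and a (i, j, bias) frame.
    """
    obs = cell_obs[cell_obs["date"] == field.date] if "date" in cell_obs else cell_obs
    out = field.copy()
    rows = []
    for i, j, value in obs[["i", "j", "value"]].itertuples(index=False):
        i, j = int(i), int(j)
        bias = float(out.values[j, i] - value)
        out.values[j, i] = value
        rows.append((i, j, bias))
    return out, pd.DataFrame(rows, columns=["i", "j", "bias"])


def successive_correction(
    field: DailyField,
    biases: pd.DataFrame,
    schedule: CorrectionSchedule = CorrectionSchedule(),
) -> DailyField:
    """Spread sensor-cell biases to nearby cells with Cressman weights.

    Each pass with radius R sees every non-sensor cell c within Euclidean
    distance d < R (cell-index units) of at least one sensor cell and uses
    Cressman weights ``w(d) = (R^2 - d^2)/(R^2 + d^2)``. The accumulated
    correction A at a cell relaxes toward the local weighted bias mean
    ``T = sum w*bias / sum w`` at a rate set by the weight mass,

        A <- A + min(sum w, 1) * (T - A),    A = 0 initially,

    so a lone sensor's influence decays continuously to zero at the radius
    (for one sensor two passes give ``1 - (1-w_1)(1-w_2)`` of its bias, a
    single pass exactly ``w*bias``) and the correction converges toward the
    observed level instead of over-subtracting when passes stack. Sensor
    cells are already exact and are never re-adjusted; cells beyond every
    radius are untouched; the corrected field is floored at zero.
    """
    out = field.copy()
    if biases.empty:
        return out
    si = biases["i"].to_numpy(int)
    sj = biases["j"].to_numpy(int)
    b = biases["bias"].to_numpy(float)
    ny, nx = field.grid.shape
    II, JJ = np.meshgrid(np.arange(nx), np.arange(ny))
    # (cell, sensor) squared distances, in cell units
    d2 = (II[..., None] - si[None, None, :]) ** 2 + (
        JJ[..., None] - sj[None, None, :]
    ) ** 2
    sensor_mask = np.zeros((ny, nx), dtype=bool)
    sensor_mask[sj, si] = True
    applied = np.zeros((ny, nx))
    for R in schedule.radii:
        within = d2 < R**2
        w = np.where(within, (R**2 - d2) / (R**2 + d2), 0.0)
        wsum = w.sum(axis=-1)
        target = np.where(wsum > 0, (w * b).sum(axis=-1) / np.maximum(wsum, 1e-300), 0.0)
        gain = np.minimum(wsum, 1.0)
        applied += gain * (target - applied)
    applied[sensor_mask] = 0.0
    out.values = np.maximum(out.values - applied, 0.0)
    return out


def interpolate_nonsmoke(coarse: DailyField, fine_grid: GridSpec) -> DailyField:
    """Bilinear interpolation of coarse cell-center values onto a fine grid.

    Fine cell centers outside the coarse center lattice are clamped to the
    nearest edge (with a warning); output is floored at zero.
    """
    cg = coarse.grid
    if not cg.covers(fine_grid):
        raise ValueError("coarse grid must cover the fine grid")
    lat_c = cg.lat_centers()
    lon_c = cg.lon_centers()
    interp = RegularGridInterpolator(
        (lat_c, lon_c), coarse.values, method="linear", bounds_error=False
    )
    flon = fine_grid.lon_centers()
    flat = fine_grid.lat_centers()
    qlon = np.clip(flon, lon_c[0], lon_c[-1])
    qlat = np.clip(flat, lat_c[0], lat_c[-1])
    if not (np.array_equal(qlon, flon) and np.array_equal(qlat, flat)):
        warnings.warn(
            "fine cell centers outside coarse center lattice; nearest-edge extension",
            stacklevel=2,
        )
    LON, LAT = np.meshgrid(qlon, qlat)
    vals = interp(np.stack([LAT.ravel(), LON.ravel()], axis=1)).reshape(fine_grid.shape)
    return DailyField(coarse.date, np.maximum(vals, 0.0), fine_grid, "nonsmoke")


def compute_smoke(
    calibrated_total: DailyField,
    model_total: DailyField,
    nonsmoke_fine: DailyField,
    use_calibrated_denominator: bool = False,
) -> DailyField:
    """Final smoke PM2.5: calibrated total times the model smoke fraction.

    The fraction ``1 - nonsmoke/total`` comes from the paired with/without-
    fire simulations and by default uses the uncalibrated model total in the
    denominator (a model-internal quantity); set
    ``use_calibrated_denominator`` to use the calibrated total instead. The
    fraction is clamped to [0, 1] (zero where the denominator is zero), so
    smoke never exceeds the calibrated total.
    """
    if not (calibrated_total.date == model_total.date == nonsmoke_fine.date):
        raise ValueError("fields must share a date")
    denom = (
        calibrated_total.values if use_calibrated_denominator else model_total.values
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - nonsmoke_fine.values / denom
    frac = np.where(denom > 0, np.clip(frac, 0.0, 1.0), 0.0)
    return DailyField(
        calibrated_total.date,
        calibrated_total.values * frac,
        calibrated_total.grid,
        "smoke",
    )


def calibrate_fields(
    model_total: Sequence[DailyField],
    cell_obs: pd.DataFrame,
    qmap: QuantileMap | None = None,
    schedule: CorrectionSchedule = CorrectionSchedule(),
    n_probs: int = 101,
) -> tuple[list[DailyField], QuantileMap]:
    """Full total-PM2.5 calibration: quantile map -> substitute -> SCM.

    Fits the pooled quantile map from all (model, observed) sensor-cell day
    pairs in ``cell_obs`` unless a prefitted ``qmap`` is given, then applies
    the three-step chain to every day. Returns the calibrated day fields and
    the map used.
    """
    if qmap is None:
        pairs = matched_pairs(model_total, cell_obs)
        qmap = fit_quantile_map(pairs, n_probs=n_probs)
    out = []
    for fld in model_total:
        mapped = apply_quantile_map(fld, qmap)
        substituted, biases = substitute_observations(mapped, cell_obs)
        out.append(successive_correction(substituted, biases, schedule))
    return out, qmap


def matched_pairs(
    model_total: Sequence[DailyField], cell_obs: pd.DataFrame
) -> np.ndarray:
    """Pooled (model value, observed value) pairs at sensor cells."""
    by_date = {f.date: f for f in model_total}
    rows = []
    for i, j, date, value in cell_obs[["i", "j", "date", "value"]].itertuples(
        index=False
    ):
        fld = by_date.get(date)
        if fld is not None:
            rows.append((fld.values[int(j), int(i)], value))
    return np.asarray(rows, dtype=float)


def _score(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return rmse, r2


def cross_validate(
    model_total: Sequence[DailyField],
    cell_obs: pd.DataFrame,
    scheme: str = "loocv",
    k: int = 20,
    schedule: CorrectionSchedule = CorrectionSchedule(),
    n_probs: int = 101,
    seed: int = 0,
) -> ValidationReport:
    """Score the calibration chain on held-out observations.

    ``loocv`` holds out one sensor cell at a time (all its days); ``kfold``
    partitions sensor-day records into k random folds. For each fold the
    quantile map is refit and substitution + SCM run with training
    observations only; predictions at held-out cells are compared with the
    held-out observed values. RMSE and R^2 are reported per fold and pooled
    over all held-out pairs.
    """
    obs = cell_obs.copy()
    obs["cell"] = list(zip(obs["i"].astype(int), obs["j"].astype(int)))
    cells = sorted(obs["cell"].unique())
    if len(cells) < 2:
        raise ValueError("cross-validation needs at least 2 sensor cells")

    if scheme == "loocv":
        folds = [obs["cell"] == c for c in cells]
    elif scheme == "kfold":
        if k > len(obs):
            raise ValueError(f"k={k} exceeds {len(obs)} sensor-day records")
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(len(obs)) % k
        folds = [assignment == f for f in range(k)]
    else:
        raise ValueError("scheme must be 'loocv' or 'kfold'")

    by_date = {f.date: f for f in model_total}
    fold_rmse, fold_r2 = [], []
    pooled_pred, pooled_obs = [], []
    for held_mask in folds:
        train = obs[~held_mask]
        test = obs[held_mask]
        if test.empty:
            continue
        calibrated, _ = calibrate_fields(
            model_total, train, schedule=schedule, n_probs=n_probs
        )
        cal_by_date = {f.date: f for f in calibrated}
        pred = np.array(
            [
                cal_by_date[d].values[int(j), int(i)]
                for i, j, d in test[["i", "j", "date"]].itertuples(index=False)
                if d in by_date
            ]
        )
        truth = test["value"].to_numpy(float)
        rmse, r2 = _score(pred, truth)
        fold_rmse.append(rmse)
        fold_r2.append(r2)
        pooled_pred.append(pred)
        pooled_obs.append(truth)
    pooled_pred = np.concatenate(pooled_pred)
    pooled_obs = np.concatenate(pooled_obs)
    pooled_rmse, pooled_r2 = _score(pooled_pred, pooled_obs)
    logger.info(
        "cross_validate(%s): pooled RMSE %.3f, R2 %.3f over %d pairs",
        scheme,
        pooled_rmse,
        pooled_r2,
        len(pooled_obs),
    )
    return ValidationReport(
        scheme=scheme,
        k=len(folds),
        fold_rmse=fold_rmse,
        fold_r2=fold_r2,
        pooled_rmse=pooled_rmse,
        pooled_r2=pooled_r2,
        n_pairs=int(len(pooled_obs)),
    )
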