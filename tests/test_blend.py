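"""Blending chain: quantile mapping, substitution, SCM, smoke fraction, CV."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokescope import make_grid
from smokescope.blend import (
    CorrectionSchedule,
    apply_quantile_map,
    calibrate_fields,
    compute_smoke,
    cross_validate,
    fit_quantile_map,
    interpolate_nonsmoke,
    matched_pairs,
    substitute_observations,
    successive_correction,
)
from smokescope.grid import DailyField
from smokescope.sensors import collocate, qc_daily
from smokescope.synth import make_scene
from tests.conftest import field_like

DATE = dt.date(2019, 6, 1)


class TestQuantileMap:
    def test_identical_samples_give_identity_map(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2, 1, 500)
        qm = fit_quantile_map(np.column_stack([x, x]))
        np.testing.assert_allclose(qm.model_q, qm.obs_q)
        probe = rng.lognormal(2, 1, 50)
        probe = probe[(probe >= x.min()) & (probe <= x.max())]
        np.testing.assert_allclose(qm(probe), probe, rtol=1e-10)

    def test_doubled_model_maps_back_to_half(self):
        # model margin = 2 * obs margin implies the fitted transform is x/2
        # throughout the model range (empirical-CDF matching oracle).
        rng = np.random.default_rng(2)
        obs = rng.lognormal(1.5, 0.8, 1000)
        model = 2.0 * obs
        qm = fit_quantile_map(np.column_stack([model, obs]))
        probe = np.linspace(model.min(), model.max(), 200)
        np.testing.assert_allclose(qm(probe), probe / 2.0, rtol=1e-9)

    def test_query_above_model_max_returns_cap(self):
        rng = np.random.default_rng(3)
        obs = rng.lognormal(1, 1, 200)
        model = rng.lognormal(2, 1, 200)
        qm = fit_quantile_map(np.column_stack([model, obs]))
        assert qm(model.max() * 10) == pytest.approx(qm.cap)
        assert qm.cap == pytest.approx(obs.max())

    def test_too_few_pairs_suggests_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            fit_quantile_map([(1.0, 1.0)] * 9)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_mapping_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.lognormal(1, 1, 100)
        model = rng.lognormal(1.5, 1.2, 100)
        qm = fit_quantile_map(np.column_stack([model, obs]))
        x = np.sort(rng.lognormal(1.5, 1.5, 300))
        y = qm(x)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y <= qm.cap + 1e-12)

    def test_training_sample_reproduces_observed_quantiles(self):
        # Mapped model training values must match the observed empirical
        # quantiles at every knot, within the local order-statistic spacing.
        rng = np.random.default_rng(4)
        obs = rng.lognormal(1.2, 0.9, 1000)
        model = rng.lognormal(1.8, 1.1, 1000)
        qm = fit_quantile_map(np.column_stack([model, obs]), n_probs=101)
        mapped = qm(model)
        got = np.quantile(mapped, qm.probs)
        spacing = np.max(np.diff(np.sort(obs)))
        np.testing.assert_allclose(got, qm.obs_q, atol=spacing)


class TestApplyMap:
    def test_constant_field_at_model_median_maps_to_obs_median(self, grid):
        rng = np.random.default_rng(5)
        obs = rng.lognormal(1, 0.7, 1001)
        model = rng.lognormal(2, 0.7, 1001)
        qm = fit_quantile_map(np.column_stack([model, obs]))
        fld = field_like(grid, np.full(grid.shape, np.median(model)))
        out = apply_quantile_map(fld, qm)
        np.testing.assert_allclose(out.values, np.median(obs), rtol=1e-9)

    def test_output_never_exceeds_cap(self, grid):
        rng = np.random.default_rng(6)
        obs = rng.lognormal(1, 1, 300)
        model = rng.lognormal(1, 1, 300)
        qm = fit_quantile_map(np.column_stack([model, obs]))
        fld = field_like(grid, rng.lognormal(3, 2, grid.shape))
        out = apply_quantile_map(fld, qm)
        assert out.values.max() <= qm.cap + 1e-12


class TestSubstitution:
    def test_observed_value_installed_and_bias_recorded(self, grid):
        fld = field_like(grid, np.full(grid.shape, 16.0))
        obs = pd.DataFrame({"i": [4], "j": [2], "date": [DATE], "value": [12.0]})
        out, biases = substitute_observations(fld, obs)
        assert out.values[2, 4] == 12.0
        assert biases["bias"].iloc[0] == pytest.approx(4.0)

    def test_no_observations_is_a_noop(self, grid):
        fld = field_like(grid, np.full(grid.shape, 16.0))
        obs = pd.DataFrame({"i": [], "j": [], "date": [], "value": []})
        out, biases = substitute_observations(fld, obs)
        np.testing.assert_array_equal(out.values, fld.values)
        assert biases.empty

    def test_zero_bias_makes_scm_a_noop(self, grid):
        fld = field_like(grid, np.full(grid.shape, 12.0))
        obs = pd.DataFrame({"i": [4], "j": [2], "date": [DATE], "value": [12.0]})
        out, biases = substitute_observations(fld, obs)
        corrected = successive_correction(out, biases)
        np.testing.assert_array_equal(corrected.values, out.values)


class TestSuccessiveCorrection:
    def test_single_sensor_cressman_weight_hand_example(self, grid):
        # bias +4 at (8,5), R=2, neighbor at d=1: w=(4-1)/(4+1)=0.6,
        # adjustment 0.6*4 = 2.4 on that pass.
        fld = field_like(grid, np.full(grid.shape, 20.0))
        biases = pd.DataFrame({"i": [8], "j": [5], "bias": [4.0]})
        out = successive_correction(fld, biases, CorrectionSchedule(radii=(2.0,)))
        assert out.values[5, 9] == pytest.approx(20.0 - 2.4)
        assert out.values[6, 8] == pytest.approx(20.0 - 2.4)

    def test_cells_beyond_radius_untouched(self, grid):
        fld = field_like(grid, np.full(grid.shape, 20.0))
        biases = pd.DataFrame({"i": [8], "j": [5], "bias": [4.0]})
        out = successive_correction(fld, biases, CorrectionSchedule(radii=(3.0, 2.0)))
        assert out.values[5, 12] == 20.0  # d=4 > max radius
        assert out.values[0, 0] == 20.0

    def test_sensor_cell_not_readjusted(self, grid):
        fld = field_like(grid, np.full(grid.shape, 20.0))
        fld.values[5, 8] = 12.0  # already substituted
        biases = pd.DataFrame({"i": [8], "j": [5], "bias": [8.0]})
        out = successive_correction(fld, biases)
        assert out.values[5, 8] == 12.0

    def test_result_floored_at_zero(self, grid):
        fld = field_like(grid, np.full(grid.shape, 1.0))
        biases = pd.DataFrame({"i": [8], "j": [5], "bias": [50.0]})
        out = successive_correction(fld, biases)
        assert np.all(out.values >= 0)

    def test_decreasing_radii_required(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CorrectionSchedule(radii=(2.0, 3.0))

    @pytest.mark.parametrize(
        "sensors",
        [
            [(8, 5, 8.0)],                      # one interior sensor, large step
            [(5, 4, 6.0), (10, 6, 6.0)],        # two separated sensors
            [(5, 4, 5.0), (7, 4, -4.0)],        # nearby sensors, mixed signs
        ],
    )
    def test_scm_smooths_substitution_steps_at_ring_cells(self, grid, sensors):
        # Smooth-transition property: substituting an observation into a
        # smooth field leaves a step around the sensor cell; SCM must reduce
        # the mean |discrete Laplacian| at the ring-1 cells, not sharpen it.
        base = 30.0
        fld = field_like(grid, np.full(grid.shape, base))
        for i, j, b in sensors:
            fld.values[j, i] = base - b  # substitution installed obs = base - bias
        biases = pd.DataFrame(
            {"i": [s[0] for s in sensors], "j": [s[1] for s in sensors],
             "bias": [s[2] for s in sensors]}
        )
        out = successive_correction(fld, biases)

        def ring_lap(v):
            acc = []
            for (i, j, _) in sensors:
                for di, dj in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
                    ii, jj = i + di, j + dj
                    lap = (
                        v[jj, ii + 1] + v[jj, ii - 1]
                        + v[jj + 1, ii] + v[jj - 1, ii] - 4 * v[jj, ii]
                    )
                    acc.append(abs(lap))
            return np.mean(acc)

        assert ring_lap(out.values) <= ring_lap(fld.values)


class TestInterpolateNonsmoke:
    fine = make_grid(-160, 55, 0.625, 0.5, 16, 10)

    def _coarse_field(self, values, nx=5, ny=4):
        coarse = make_grid(-160, 55, 2.5, 2.0, nx, ny)
        return field_like(coarse, values, kind="nonsmoke")

    def test_constant_coarse_gives_constant_fine(self):
        with pytest.warns(UserWarning, match="nearest-edge"):
            out = interpolate_nonsmoke(self._coarse_field(np.full((4, 5), 2.5)), self.fine)
        np.testing.assert_allclose(out.values, 2.5)

    def test_longitude_ramp_preserved_in_interior(self):
        coarse = make_grid(-160, 55, 2.5, 2.0, 5, 4)
        lon_c = coarse.lon_centers()
        vals = np.tile(2.0 * (lon_c - lon_c[0]), (4, 1))
        with pytest.warns(UserWarning, match="nearest-edge"):
            out = interpolate_nonsmoke(field_like(coarse, vals, kind="nonsmoke"), self.fine)
        flon = self.fine.lon_centers()
        interior = (flon >= lon_c[0]) & (flon <= lon_c[-1])
        expected = 2.0 * (flon[interior] - lon_c[0])
        np.testing.assert_allclose(out.values[5, interior], expected, atol=1e-10)

    def test_coincident_centers_are_exact(self):
        # a fine grid whose centers include coarse centers
        fine = make_grid(-160, 55, 1.25, 1.0, 8, 6)
        coarse = make_grid(-160, 55, 2.5, 2.0, 4, 3)
        rng = np.random.default_rng(8)
        vals = rng.lognormal(1, 0.5, (3, 4))
        with pytest.warns(UserWarning, match="nearest-edge"):
            out = interpolate_nonsmoke(field_like(coarse, vals, kind="nonsmoke"), fine)
        # coarse center (k) lands on fine center (2k+1 - 0.5)... check direct
        for cj in range(3):
            for ci in range(4):
                lon, lat = coarse.cell_center(ci, cj)
                fi, fj = fine.cell_of(lon, lat)
                # center coincidence only when offsets align
                flon, flat = fine.cell_center(fi, fj)
                if abs(flon - lon) < 1e-9 and abs(flat - lat) < 1e-9:
                    assert out.values[fj, fi] == pytest.approx(vals[cj, ci])

    def test_coarse_must_cover_fine(self):
        small = make_grid(-158, 56, 2.5, 2.0, 1, 1)
        fld = field_like(small, np.array([[1.0]]), kind="nonsmoke")
        with pytest.raises(ValueError, match="cover"):
            interpolate_nonsmoke(fld, self.fine)


class TestComputeSmoke:
    def test_fraction_arithmetic(self, grid):
        cal = field_like(grid, np.full(grid.shape, 16.0))
        model = field_like(grid, np.full(grid.shape, 20.0))
        nonsmoke = field_like(grid, np.full(grid.shape, 5.0), kind="nonsmoke")
        smoke = compute_smoke(cal, model, nonsmoke)
        np.testing.assert_allclose(smoke.values, 12.0)  # fraction 0.75

    def test_nonsmoke_exceeding_total_clamps_to_zero(self, grid):
        cal = field_like(grid, np.full(grid.shape, 16.0))
        model = field_like(grid, np.full(grid.shape, 4.0))
        nonsmoke = field_like(grid, np.full(grid.shape, 5.0), kind="nonsmoke")
        smoke = compute_smoke(cal, model, nonsmoke)
        np.testing.assert_array_equal(smoke.values, 0.0)

    def test_zero_nonsmoke_attributes_everything(self, grid):
        cal = field_like(grid, np.full(grid.shape, 16.0))
        model = field_like(grid, np.full(grid.shape, 20.0))
        nonsmoke = field_like(grid, np.zeros(grid.shape), kind="nonsmoke")
        smoke = compute_smoke(cal, model, nonsmoke)
        np.testing.assert_array_equal(smoke.values, cal.values)

    def test_zero_model_total_gives_zero_fraction(self, grid):
        cal = field_like(grid, np.full(grid.shape, 1.0))
        model = field_like(grid, np.zeros(grid.shape))
        nonsmoke = field_like(grid, np.zeros(grid.shape), kind="nonsmoke")
        smoke = compute_smoke(cal, model, nonsmoke)
        np.testing.assert_array_equal(smoke.values, 0.0)


class TestExactnessAndLocality:
    def test_sensor_cells_exact_after_substitution_and_scm(self, noisy_scene):
        scene = noisy_scene
        obs = collocate(qc_daily(scene.sensors), scene.grid)
        calibrated, _ = calibrate_fields(scene.model_total_fine, obs)
        by_date = {f.date: f for f in calibrated}
        for i, j, date, value in obs[["i", "j", "date", "value"]].itertuples(index=False):
            assert by_date[date].values[int(j), int(i)] == pytest.approx(value, abs=1e-12)

    def test_cells_far_from_all_sensors_keep_mapped_values(self, noisy_scene):
        scene = noisy_scene
        obs = collocate(qc_daily(scene.sensors), scene.grid)
        calibrated, qm = calibrate_fields(scene.model_total_fine, obs)
        mapped = [apply_quantile_map(f, qm) for f in scene.model_total_fine]
        cells = obs[["i", "j"]].drop_duplicates().to_numpy()
        max_r = 3.0
        ny, nx = scene.grid.shape
        for cal, mp in zip(calibrated, mapped):
            for j in range(ny):
                for i in range(nx):
                    d = np.sqrt(((cells - [i, j]) ** 2).sum(axis=1)).min()
                    if d >= max_r:
                        assert cal.values[j, i] == mp.values[j, i]


def uniform_undistorted_setup(grid, n_days=25, n_cells=5, seed=13):
    """Model == obs with a spatially uniform field each day.

    Spatial uniformity keeps every fold's held-out values inside the
    training range, so the capped quantile map is exactly the identity and
    the cross-validation sanity contract (RMSE 0, R^2 1) is exact. With a
    spatially varying field the cap at the observed 100th quantile censors a
    held-out cell that carries the global maximum — inherent to quantile
    mapping, not an implementation defect.
    """
    rng = np.random.default_rng(seed)
    daily = rng.lognormal(1.0, 0.6, n_days)
    fields, rows = [], []
    flat = rng.choice(16 * 10, size=n_cells, replace=False)
    cells = [(int(f % 16), int(f // 16)) for f in flat]
    for k in range(n_days):
        date = DATE + dt.timedelta(days=k)
        fields.append(field_like(grid, np.full(grid.shape, daily[k]), date=date))
        for (i, j) in cells:
            rows.append((i, j, date, daily[k]))
    obs = pd.DataFrame(rows, columns=["i", "j", "date", "value"])
    return fields, obs


class TestCrossValidation:
    def test_undistorted_uniform_scene_scores_perfectly(self, grid):
        fields, obs = uniform_undistorted_setup(grid)
        report = cross_validate(fields, obs, scheme="loocv")
        assert report.pooled_rmse == pytest.approx(0.0, abs=1e-9)
        assert report.pooled_r2 == pytest.approx(1.0, abs=1e-9)

    def test_loocv_fold_count_equals_sensor_cells(self, noisy_scene):
        obs = collocate(qc_daily(noisy_scene.sensors), noisy_scene.grid)
        n_cells = len(obs[["i", "j"]].drop_duplicates())
        report = cross_validate(noisy_scene.model_total_fine, obs, scheme="loocv")
        assert report.k == n_cells

    def test_kfold_k_exceeding_records_rejected(self, noisy_scene):
        obs = collocate(qc_daily(noisy_scene.sensors), noisy_scene.grid)
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(
                noisy_scene.model_total_fine, obs, scheme="kfold", k=len(obs) + 1
            )

    def test_kfold_reproducible_for_seed(self, noisy_scene):
        obs = collocate(qc_daily(noisy_scene.sensors), noisy_scene.grid)
        a = cross_validate(noisy_scene.model_total_fine, obs, scheme="kfold", k=4, seed=3)
        b = cross_validate(noisy_scene.model_total_fine, obs, scheme="kfold", k=4, seed=3)
        assert a.pooled_rmse == b.pooled_rmse
        assert a.fold_rmse == b.fold_rmse


def test_matched_pairs_aligns_model_and_observation(noisy_scene):
    obs = collocate(qc_daily(noisy_scene.sensors), noisy_scene.grid)
    pairs = matched_pairs(noisy_scene.model_total_fine, obs)
    assert pairs.shape == (len(obs), 2)
    assert np.all(pairs > 0)
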