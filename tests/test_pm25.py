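"""Collocation, PM2.5 prediction, LOSO CV and histogram comparison."""

import numpy as np
import pandas as pd
import pytest

from aodfuse.grid import DailyGridField, GridSpec
from aodfuse.mixedlm import IdentifiabilityError, MixedModelFit
from aodfuse.pm25 import (CollocatedPanel, collocate, compare_histograms,
                          fit_mixed_model, loso_cross_validate, predict_pm)


@pytest.fixture()
def grid4():
    return GridSpec(116.0, 116.4, 39.8, 40.2, 0.1)  # 4 x 4


def _field(date, grid, value=0.5, missing_cells=()):
    vals = np.full(grid.shape, float(value))
    for rc in missing_cells:
        vals[rc] = np.nan
    return DailyGridField(date, vals)


class TestCollocate:
    def test_monitors_sharing_cell_average(self, grid4):
        lat, lon = grid4.cell_center(1, 1)
        coords = pd.DataFrame({
            "site_id": ["a", "b"],
            "lat": [lat, lat + 0.01],
            "lon": [lon, lon - 0.01],
        })
        pm = pd.DataFrame({
            "date": [0, 0], "site_id": ["a", "b"], "pm25": [80.0, 120.0]
        })
        panel = collocate(pm, coords, [_field(0, grid4)], grid4)
        assert len(panel) == 1
        assert panel.records["pm"].iloc[0] == pytest.approx(100.0)
        assert panel.records["site"].iloc[0] == "r1c1"

    def test_pseudo_site_count_equals_occupied_cells(self, grid4, rng):
        # 12 monitors over 5 distinct cells
        cells = [(0, 0), (0, 1), (1, 1), (2, 3), (3, 2)]
        assign = [cells[i % 5] for i in range(12)]
        coords = pd.DataFrame({
            "site_id": [f"m{i}" for i in range(12)],
            "lat": [grid4.cell_center(r, c)[0] + rng.uniform(-0.03, 0.03)
                    for r, c in assign],
            "lon": [grid4.cell_center(r, c)[1] + rng.uniform(-0.03, 0.03)
                    for r, c in assign],
        })
        pm = pd.DataFrame({
            "date": [0] * 12,
            "site_id": [f"m{i}" for i in range(12)],
            "pm25": rng.uniform(20, 150, 12),
        })
        panel = collocate(pm, coords, [_field(0, grid4)], grid4)
        assert panel.sites.size == len(set(assign))

    def test_missing_aod_drops_record(self, grid4):
        lat, lon = grid4.cell_center(2, 2)
        coords = pd.DataFrame({"site_id": ["a"], "lat": [lat], "lon": [lon]})
        pm = pd.DataFrame({"date": [0, 1], "site_id": ["a", "a"],
                           "pm25": [50.0, 60.0]})
        fields = [_field(0, grid4, missing_cells=[(2, 2)]), _field(1, grid4)]
        panel = collocate(pm, coords, fields, grid4)
        assert list(panel.records["day"]) == [1]

    def test_monitor_outside_domain_excluded(self, grid4):
        coords = pd.DataFrame({
            "site_id": ["in", "out"],
            "lat": [grid4.cell_center(0, 0)[0], 45.0],
            "lon": [grid4.cell_center(0, 0)[1], 116.1],
        })
        pm = pd.DataFrame({"date": [0, 0], "site_id": ["in", "out"],
                           "pm25": [50.0, 70.0]})
        panel = collocate(pm, coords, [_field(0, grid4)], grid4)
        assert panel.sites.tolist() == ["r0c0"]

    def test_source_flag_propagated(self, grid4):
        from aodfuse.grid import FILLED, RETRIEVED
        vals = np.full(grid4.shape, 0.5)
        flags = np.full(grid4.shape, RETRIEVED, dtype=np.int8)
        flags[3, 3] = FILLED
        fld = DailyGridField(0, vals, flags)
        coords = pd.DataFrame({
            "site_id": ["a", "b"],
            "lat": [grid4.cell_center(3, 3)[0], grid4.cell_center(0, 0)[0]],
            "lon": [grid4.cell_center(3, 3)[1], grid4.cell_center(0, 0)[1]],
        })
        pm = pd.DataFrame({"date": [0, 0], "site_id": ["a", "b"],
                           "pm25": [50.0, 60.0]})
        panel = collocate(pm, coords, [fld], grid4)
        src = dict(zip(panel.records["site"], panel.records["source"]))
        assert src == {"r3c3": "filled", "r0c0": "retrieved"}


def _manual_fit(alpha=30.0, beta=90.0, u=None, v=None, s=None,
                day_labels=None, site_cells=None):
    n_days = len(u) if u is not None else 1
    n_sites = len(s) if s is not None else 1
    return MixedModelFit(
        alpha=alpha, beta=beta, alpha_se=1.0, beta_se=1.0,
        Sigma=np.zeros((2, 2)), sigma_s_sq=0.0, sigma_sq=1.0,
        u=np.asarray(u if u is not None else [0.0]),
        v=np.asarray(v if v is not None else [0.0]),
        s=np.asarray(s if s is not None else [0.0]),
        day_labels=np.asarray(day_labels if day_labels is not None else [0]),
        site_labels=np.asarray([f"s{i}" for i in range(n_sites)]),
        n_days=n_days, n_sites=n_sites, n_obs=10,
        converged=True, loglik=0.0, site_cells=site_cells,
    )


class TestPredictPm:
    def test_fixed_effects_line(self, grid4):
        fit = _manual_fit()
        pm = predict_pm(fit, _field(0, grid4, value=1.0))
        np.testing.assert_allclose(pm, 120.0)

    def test_day_effects_applied(self, grid4):
        # (30+10) + (90-5)*0.5 = 82.5
        fit = _manual_fit(u=[10.0], v=[-5.0])
        pm = predict_pm(fit, _field(0, grid4, value=0.5))
        np.testing.assert_allclose(pm, 82.5)

    def test_site_intercept_only_at_site_cell(self, grid4):
        fit = _manual_fit(u=[10.0], v=[-5.0], s=[7.0], site_cells=[(2, 2)])
        pm = predict_pm(fit, _field(0, grid4, value=0.5))
        assert pm[2, 2] == pytest.approx(89.5)
        assert pm[0, 0] == pytest.approx(82.5)

    def test_missing_aod_propagates(self, grid4):
        fit = _manual_fit()
        pm = predict_pm(fit, _field(0, grid4, missing_cells=[(1, 2)]))
        assert np.isnan(pm[1, 2])
        assert np.isfinite(pm).sum() == grid4.n_cells - 1

    def test_unknown_day_needs_explicit_new_day_mode(self, grid4):
        fit = _manual_fit(u=[10.0], v=[-5.0])
        with pytest.raises(KeyError):
            predict_pm(fit, _field(99, grid4))
        pm = predict_pm(fit, _field(99, grid4, value=1.0), new_day=True)
        np.testing.assert_allclose(pm, 120.0)  # population-level day

    def test_negative_predictions_floored(self, grid4):
        fit = _manual_fit(alpha=-50.0, beta=10.0)
        pm = predict_pm(fit, _field(0, grid4, value=0.5))
        np.testing.assert_allclose(pm, 0.0)


def _noise_free_panel_df(I=5, J=25):
    rng = np.random.default_rng(4)
    rows = []
    for i in range(I):
        for j in range(J):
            aod = float(rng.uniform(0.1, 1.5))
            rows.append((f"s{i}", j, 30.0 + 90.0 * aod, aod, "retrieved"))
    return CollocatedPanel(
        pd.DataFrame(rows, columns=["site", "day", "pm", "aod", "source"])
    )


class TestLosoCrossValidate:
    def test_noise_free_panel_predicts_perfectly(self):
        res = loso_cross_validate(_noise_free_panel_df())
        assert res.metrics.r == pytest.approx(1.0, abs=1e-6)
        assert res.metrics.rmse == pytest.approx(0.0, abs=1e-4)
        assert not res.failed_folds

    def test_fold_count_matches_sites(self):
        panel = _noise_free_panel_df(I=3)
        res = loso_cross_validate(panel)
        assert sorted(res.predictions["fold"].unique().tolist()) == [0, 1, 2]
        assert res.site_summary.shape[0] == 3

    def test_shifted_site_error_stays_in_its_fold(self):
        """+50 on one site's PM appears as ~50 MPE in that fold only."""
        panel = _noise_free_panel_df(I=6, J=30)
        df = panel.records.copy()
        df.loc[df["site"] == "s0", "pm"] += 50.0
        shifted = CollocatedPanel(df)
        res = loso_cross_validate(shifted)
        summ = res.site_summary.set_index("site")
        assert summ.loc["s0", "mpe"] == pytest.approx(50.0, abs=2.0)
        for other in ("s1", "s2", "s3", "s4", "s5"):
            assert summ.loc[other, "mpe"] < 15.0

    def test_needs_three_sites(self):
        with pytest.raises(IdentifiabilityError):
            loso_cross_validate(_noise_free_panel_df(I=2))


class TestCompareHistograms:
    def test_identical_samples(self):
        obs = np.array([5.0, 15.0, 25.0, 35.0, 45.0, 55.0])
        r, mad = compare_histograms(obs, obs.copy())
        assert r == pytest.approx(1.0)
        assert mad == pytest.approx(0.0)

    def test_one_bin_shift_matches_naive_count(self):
        obs = np.array([5.0] * 6 + [15.0] * 4)
        pred = obs + 10.0  # everything moves exactly one bin up
        r, mad = compare_histograms(obs, pred, bin_width=10.0)
        # naive: shared range [0,30), bins [0,10),[10,20),[20,30]
        f_obs = np.array([6, 4, 0]) / 10 * 100
        f_pred = np.array([0, 6, 4]) / 10 * 100
        assert mad == pytest.approx(np.mean(np.abs(f_obs - f_pred)))

    def test_disjoint_support(self):
        obs = np.array([5.0] * 10)       # all in bin 0
        pred = np.array([95.0] * 10)     # all in last bin
        r, mad = compare_histograms(obs, pred, bin_width=10.0)
        # 10 bins over [0,100]; |100-0| + |0-100| over 10 bins = 20
        assert mad == pytest.approx(200.0 / 10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compare_histograms([], [1.0])
        with pytest.raises(ValueError):
            compare_histograms([1.0], [1.0], bin_width=0.0)
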