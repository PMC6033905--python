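"""Regression map fitting, correlation-gated filling, sampling, metrics."""

import numpy as np
import pandas as pd
import pytest

from aodfuse.fusion import (FusionConfig, evaluate_against_reference,
                            fill_missing, fit_regression_map, sampling_ratio)
from aodfuse.grid import FILLED, MISSING, RETRIEVED, DailyGridField
from aodfuse.synthetic import default_scene_config, generate_scene


def _const_season(_):
    return "winter"


CFG = FusionConfig(r_threshold=0.5, min_pairs=10, season_of=_const_season)


def _fields_from_matrix(Y):
    """(n_days, nr, nc) array with NaN -> list of DailyGridField."""
    return [DailyGridField(t, Y[t]) for t in range(Y.shape[0])]


def _ols_oracle(x, y):
    """Textbook normal equations, computed the long way."""
    xb, yb = np.mean(x), np.mean(y)
    sxx = sum((xi - xb) ** 2 for xi in x)
    sxy = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    syy = sum((yi - yb) ** 2 for yi in y)
    slope = sxy / sxx
    return slope, yb - slope * xb, sxy / np.sqrt(sxx * syy)


class TestFitRegressionMap:
    def test_noise_free_line_recovered_exactly(self, rng):
        site = pd.Series(rng.uniform(0.1, 1.5, 20), index=range(20))
        Y = (1.2 * site.to_numpy() + 0.05)[:, None, None] * np.ones((1, 2, 2))
        rmap = fit_regression_map(site, _fields_from_matrix(Y), CFG)
        fit = rmap.seasons["winter"]
        np.testing.assert_allclose(fit.slope, 1.2, rtol=1e-9)
        np.testing.assert_allclose(fit.intercept, 0.05, atol=1e-9)
        np.testing.assert_allclose(fit.r, 1.0, rtol=1e-9)
        assert (fit.n_pairs == 20).all()

    def test_independent_cell_has_small_r(self, rng):
        n = 2000
        site = pd.Series(rng.uniform(0.1, 1.5, n), index=range(n))
        Y = rng.uniform(0.1, 1.5, (n, 1, 1))
        rmap = fit_regression_map(site, _fields_from_matrix(Y), CFG)
        assert abs(rmap.seasons["winter"].r[0, 0]) < 0.1

    def test_matches_normal_equations_oracle(self, rng):
        """Random 50-day strata agree with brute-force OLS to 1e-10."""
        n = 50
        site = pd.Series(rng.uniform(0.05, 2.0, n), index=range(n))
        Y = rng.uniform(0.0, 2.0, (n, 3, 4))
        rmap = fit_regression_map(site, _fields_from_matrix(Y), CFG)
        fit = rmap.seasons["winter"]
        x = site.to_numpy()
        for r in range(3):
            for c in range(4):
                slope, intercept, rr = _ols_oracle(x, Y[:, r, c])
                assert fit.slope[r, c] == pytest.approx(slope, abs=1e-10)
                assert fit.intercept[r, c] == pytest.approx(intercept, abs=1e-10)
                assert fit.r[r, c] == pytest.approx(rr, abs=1e-10)

    def test_min_pairs_suppresses_fit_but_keeps_count(self, rng):
        site = pd.Series(rng.uniform(0.1, 1.0, 5), index=range(5))
        Y = rng.uniform(0.1, 1.0, (5, 1, 1))
        rmap = fit_regression_map(site, _fields_from_matrix(Y), CFG)
        fit = rmap.seasons["winter"]
        assert np.isnan(fit.slope[0, 0])
        assert fit.n_pairs[0, 0] == 5

    def test_only_retrieved_cells_form_pairs(self, rng):
        """Filled cells must not feed the regression."""
        n = 30
        site = pd.Series(rng.uniform(0.1, 1.5, n), index=range(n))
        Y = (1.0 * site.to_numpy())[:, None, None] * np.ones((1, 1, 1))
        fields = _fields_from_matrix(Y.copy())
        # mark half the days as filled with corrupted values
        for t in range(0, n, 2):
            fields[t].flags[0, 0] = FILLED
            fields[t].values[0, 0] = 99.0
        rmap = fit_regression_map(site, fields, CFG)
        fit = rmap.seasons["winter"]
        assert fit.n_pairs[0, 0] == n // 2
        assert fit.slope[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_zero_variance_site_stratum_gives_no_fit(self):
        site = pd.Series(0.5, index=range(15))
        Y = np.random.default_rng(0).uniform(0.1, 1.0, (15, 1, 1))
        rmap = fit_regression_map(site, _fields_from_matrix(Y), CFG)
        assert np.isnan(rmap.seasons["winter"].slope[0, 0])


class TestFillMissing:
    def _map_with(self, slope, intercept, r, shape=(2, 2)):
        from aodfuse.fusion import SeasonalRegressionMap, SeasonFit
        from aodfuse.grid import GridSpec

        rmap = SeasonalRegressionMap(GridSpec(0, 0.2, 0, 0.2, 0.1))
        rmap.seasons["winter"] = SeasonFit(
            slope=np.full(shape, float(slope)),
            intercept=np.full(shape, float(intercept)),
            r=np.full(shape, float(r)),
            n_pairs=np.full(shape, 50),
        )
        return rmap

    def test_complete_field_unchanged(self):
        fld = DailyGridField(0, np.full((2, 2), 0.4))
        out = fill_missing(fld, 0.8, self._map_with(1.0, 0.0, 0.9), CFG)
        np.testing.assert_array_equal(out.values, fld.values)
        assert (out.flags == RETRIEVED).all()

    def test_identity_regression_fills_site_value(self):
        vals = np.array([[0.4, np.nan], [np.nan, 0.2]])
        fld = DailyGridField(0, vals)
        out = fill_missing(fld, 0.8, self._map_with(1.0, 0.0, 0.9), CFG)
        assert out.values[0, 1] == pytest.approx(0.8)
        assert out.flags[0, 1] == FILLED
        assert out.values[1, 0] == pytest.approx(0.8)
        # retrieved cells bit-identical
        assert out.values[0, 0] == vals[0, 0]
        assert out.flags[0, 0] == RETRIEVED

    def test_negative_prediction_floored_to_zero(self):
        fld = DailyGridField(0, np.full((2, 2), np.nan))
        out = fill_missing(fld, 0.5, self._map_with(-0.2, 0.01, 0.9), CFG)
        # -0.2*0.5 + 0.01 = -0.09 -> floored
        assert (out.values == 0.0).all()
        assert (out.flags == FILLED).all()

    def test_low_correlation_gates_fill(self):
        fld = DailyGridField(0, np.full((2, 2), np.nan))
        out = fill_missing(fld, 0.5, self._map_with(1.0, 0.0, 0.49), CFG)
        assert not out.present.any()

    def test_absent_site_value_is_noop(self):
        fld = DailyGridField(0, np.array([[0.3, np.nan]]))
        rmap = self._map_with(1.0, 0.0, 0.9, shape=(1, 2))
        for missing_site in (None, float("nan")):
            out = fill_missing(fld, missing_site, rmap, CFG)
            np.testing.assert_array_equal(out.flags, fld.flags)


class TestSamplingRatio:
    def test_count_ratio(self):
        fields = [DailyGridField(t, np.array([[0.5 if t < 5 else np.nan]]))
                  for t in range(10)]
        assert sampling_ratio(fields)[0, 0] == pytest.approx(0.5)
        assert sampling_ratio(fields[:5])[0, 0] == pytest.approx(1.0)

    def test_fill_monotonicity_on_scene(self, small_scene):
        """Fused coverage >= retrieved-only coverage in every cell, and
        strictly greater where fills occurred."""
        site = small_scene.site_aod
        fields = small_scene.observed_grid_aod
        cfg = FusionConfig(r_threshold=0.5, min_pairs=10,
                           season_of=small_scene.season_of)
        rmap = fit_regression_map(site, fields, cfg)
        fused = [fill_missing(f, site.get(f.date, None), rmap, cfg)
                 for f in fields]
        before = sampling_ratio(fields, include_filled=False)
        after = sampling_ratio(fused, include_filled=True)
        assert (after >= before - 1e-15).all()
        n_fills = sum(int(f.filled.sum()) for f in fused)
        assert n_fills > 0
        assert after.mean() > before.mean()
        # retrieved-only ratio unchanged by filling
        np.testing.assert_array_equal(
            sampling_ratio(fused, include_filled=False), before
        )


class TestEvalMetrics:
    def test_identity_prediction(self):
        ref = np.array([0.2, 0.5, 1.1, 0.7])
        m = evaluate_against_reference(ref, ref)
        assert (m.r, m.mpe, m.rmse, m.envelope_fraction) == (1.0, 0.0, 0.0, 1.0)

    def test_envelope_boundary_inclusive(self):
        # offset of exactly +0.05 lies inside the band for positive AOD
        ref = np.array([0.5, 1.0, 0.2])
        m = evaluate_against_reference(ref + 0.05, ref)
        assert m.envelope_fraction == 1.0
        # exactly on the band edge counts as inside; just beyond does not
        ref1 = np.array([1.0, 1.0])
        edge = 0.05 + 0.20 * 1.0
        m_edge = evaluate_against_reference(ref1 + edge, ref1)
        assert m_edge.envelope_fraction == 1.0
        m_out = evaluate_against_reference(ref1 + edge + 1e-6, ref1)
        assert m_out.envelope_fraction == 0.0

    def test_matches_naive_loop_oracle(self, rng):
        pred = rng.uniform(0, 1.5, 100)
        ref = rng.uniform(0, 1.5, 100)
        m = evaluate_against_reference(pred, ref)
        n = len(pred)
        mpe = sum(abs(p - r) for p, r in zip(pred, ref)) / n
        rmse = (sum((p - r) ** 2 for p, r in zip(pred, ref)) / n) ** 0.5
        env = sum(abs(p - r) <= 0.05 + 0.2 * r for p, r in zip(pred, ref)) / n
        pb, rb = np.mean(pred), np.mean(ref)
        r_num = sum((p - pb) * (q - rb) for p, q in zip(pred, ref))
        r_den = (sum((p - pb) ** 2 for p in pred)
                 * sum((q - rb) ** 2 for q in ref)) ** 0.5
        assert m.mpe == pytest.approx(mpe, abs=1e-12)
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.envelope_fraction == pytest.approx(env, abs=1e-12)
        assert m.r == pytest.approx(r_num / r_den, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            evaluate_against_reference([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            evaluate_against_reference([1.0], [1.0])
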