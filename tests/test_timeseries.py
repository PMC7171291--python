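"""Preprocessing, window planning and connectivity estimation."""

import numpy as np
import pytest

import restmodes as rm
from restmodes.exceptions import InvalidParameterError, RankDeficientError
from restmodes.timeseries import _window_weights, _weighted_corr


def make_ts(data, tr=0.72, **kw):
    return rm.RoiTimeSeries(data=data, tr=tr, **kw)


class TestRegressConfounds:
    def test_orthogonal_confounds_leave_series_unchanged(self, rng):
        t = 200
        base = rng.standard_normal((t, 5))
        # center and detrend so the intercept/trend columns have nothing to remove
        trend = np.linspace(-1, 1, t)
        X = np.column_stack([np.ones(t), trend])
        base -= X @ np.linalg.lstsq(X, base, rcond=None)[0]
        conf = rng.standard_normal((t, 3))
        conf -= np.column_stack([X, base]) @ np.linalg.lstsq(
            np.column_stack([X, base]), conf, rcond=None
        )[0]
        out = rm.regress_confounds(make_ts(base), conf)
        assert np.allclose(out.data, base, atol=1e-8)

    def test_exact_confound_column_is_annihilated(self, rng):
        t = 100
        conf = rng.standard_normal((t, 2))
        data = np.column_stack([conf[:, 0], rng.standard_normal(t)])
        out = rm.regress_confounds(make_ts(data), conf)
        assert np.max(np.abs(out.data[:, 0])) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        t = 150
        data = rng.standard_normal((t, 4))
        conf = rng.standard_normal((t, 3))
        X = np.column_stack([np.ones(t), np.linspace(-1, 1, t), conf])
        beta = np.linalg.solve(X.T @ X, X.T @ data)
        expected = data - X @ beta
        out = rm.regress_confounds(make_ts(data), conf)
        assert np.max(np.abs(out.data - expected)) < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        t = 80
        conf = rng.standard_normal((t, 2))
        out = rm.regress_confounds(make_ts(rng.standard_normal((t, 3))), conf)
        assert np.max(np.abs(conf.T @ out.data)) < 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        t = 60
        c0 = rng.standard_normal(t)
        conf = np.column_stack([c0, 2.0 * c0])
        with pytest.raises(RankDeficientError) as err:
            rm.regress_confounds(make_ts(rng.standard_normal((t, 2))), conf)
        assert err.value.columns


class TestTaskRegressors:
    def test_empty_block_list_gives_zero_columns(self):
        out = rm.build_task_regressors([], [], tr=0.72, n_volumes=100)
        assert out.shape == (100, 2)
        assert np.all(out == 0)

    def test_single_block_peaks_near_six_seconds(self):
        tr = 0.5
        out = rm.build_task_regressors([10.0], [1.0], tr=tr, n_volumes=200)
        peak_t = np.argmax(out[:, 0]) * tr
        assert abs(peak_t - (10.0 + 6.0)) <= tr + 0.5  # double-gamma peak ~6 s post onset

    def test_derivative_column_telescopes(self):
        out = rm.build_task_regressors([5.0, 30.0], [10.0, 5.0], tr=1.0, n_volumes=60)
        assert np.isclose(out[:, 1].sum(), out[-1, 0] - out[0, 0], atol=1e-10)

    def test_block_past_run_end_rejected(self):
        with pytest.raises(InvalidParameterError):
            rm.build_task_regressors([50.0], [30.0], tr=1.0, n_volumes=60)


class TestBandpass:
    def _sine_ts(self, freq, tr=0.72, n=1200):
        t = np.arange(n) * tr
        return make_ts(np.sin(2 * np.pi * freq * t)[:, None], tr=tr)

    def test_in_band_sinusoid_passes(self):
        ts = self._sine_ts(0.03)
        out = rm.bandpass_filter(ts, 0.008, 0.09)
        assert out.data.std() >= 0.9 * ts.data.std()

    def test_stop_band_sinusoid_suppressed(self):
        ts = self._sine_ts(0.2)
        out = rm.bandpass_filter(ts, 0.008, 0.09)
        assert out.data.std() <= 0.1 * ts.data.std()

    def test_white_noise_matches_fft_mask_oracle(self, rng):
        from scipy.signal import detrend

        tr, n = 2.0, 400
        x = rng.standard_normal((n, 3))
        out = rm.bandpass_filter(make_ts(x, tr=tr), 0.008, 0.09)
        xd = detrend(x, axis=0)
        freqs = np.fft.rfftfreq(n, d=tr)
        spec = np.fft.rfft(xd, axis=0)
        spec[(freqs <= 0.008) | (freqs >= 0.09)] = 0
        oracle = np.fft.irfft(spec, n=n, axis=0)
        rms = np.sqrt(np.mean(oracle**2))
        assert np.sqrt(np.mean((out.data - oracle) ** 2)) < 0.05 * rms

    def test_f_hi_at_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            rm.bandpass_filter(self._sine_ts(0.03, tr=2.0, n=100), 0.008, 0.25)


class TestPlanWindows:
    def test_hcp_geometry_yields_1548_windows(self):
        plan = rm.plan_windows({f"run-{i}": 1200 for i in range(4)}, 41, 3)
        assert plan.n_windows == 1548
        assert all(len(plan.windows_in_run(r)) == 387 for r in plan.run_ids)

    def test_window_exactly_spanning_run(self):
        plan = rm.plan_windows({"r": 100}, 100, 3)
        assert plan.n_windows == 1
        assert plan.windows[0] == ("r", 0, 100)

    def test_short_run_contributes_nothing_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            plan = rm.plan_windows({"r": 50}, 60, 3)
        assert plan.n_windows == 0

    @pytest.mark.parametrize("trial", range(5))
    def test_counts_match_brute_force_enumeration(self, rng, trial):
        lengths = {f"r{i}": int(rng.integers(5, 400)) for i in range(4)}
        wl = int(rng.integers(2, 60))
        hop = int(rng.integers(1, 10))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = rm.plan_windows(lengths, wl, hop)
        expected = sum(
            (L - wl) // hop + 1 for L in lengths.values() if L >= wl
        )
        assert plan.n_windows == expected


class TestWindowConnectivity:
    def test_identical_roi_columns_hit_clip_bound(self, rng):
        x = rng.standard_normal(30)
        ts = make_ts(np.column_stack([x, x, rng.standard_normal(30)]))
        plan = rm.plan_windows({ts.run_id: 30}, 30, 1)
        (mat,) = rm.window_connectivity(ts, plan)
        assert np.isclose(mat.values[0, 1], np.arctanh(0.999999))
        assert np.allclose(mat.values, mat.values.T)

    def test_uniform_weighting_reduces_to_pearson(self, rng):
        data = rng.standard_normal((41, 6))
        ts = make_ts(data)
        plan = rm.plan_windows({ts.run_id: 41}, 41, 1, weighting="uniform")
        (mat,) = rm.window_connectivity(ts, plan)
        expected = np.arctanh(np.clip(np.corrcoef(data, rowvar=False), -0.999999, 0.999999))
        np.fill_diagonal(expected, 0.0)
        assert np.max(np.abs(mat.values - expected)) < 1e-12

    def test_hann_weights_match_explicit_sums_oracle(self, rng):
        data = rng.standard_normal((41, 5))
        ts = make_ts(data)
        plan = rm.plan_windows({ts.run_id: 41}, 41, 1)
        (mat,) = rm.window_connectivity(ts, plan)
        w = np.hanning(41)
        w = w / w.sum()
        r = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                xi, xj = data[:, i], data[:, j]
                mi, mj = np.sum(w * xi), np.sum(w * xj)
                cov = np.sum(w * (xi - mi) * (xj - mj))
                vi = np.sum(w * (xi - mi) ** 2)
                vj = np.sum(w * (xj - mj) ** 2)
                r[i, j] = cov / np.sqrt(vi * vj)
        expected = np.arctanh(np.clip(r, -0.999999, 0.999999))
        np.fill_diagonal(expected, 0.0)
        assert np.max(np.abs(mat.values - expected)) < 1e-10

    def test_correlation_invariant_to_roi_rescaling(self, rng):
        data = rng.standard_normal((41, 4))
        scaled = data * np.array([1.0, 5.0, 0.2, 100.0])
        plan = rm.plan_windows({"run-1": 41}, 41, 1)
        (a,) = rm.window_connectivity(make_ts(data), plan)
        (b,) = rm.window_connectivity(make_ts(scaled), plan)
        assert np.max(np.abs(a.values - b.values)) < 1e-10

    def test_zero_variance_roi_warns_and_zeroes(self, rng):
        data = rng.standard_normal((20, 3))
        data[:, 1] = 7.0
        plan = rm.plan_windows({"run-1": 20}, 20, 1)
        with pytest.warns(UserWarning, match="zero weighted variance"):
            (mat,) = rm.window_connectivity(make_ts(data), plan)
        assert np.all(mat.values[1] == 0)


class TestStaticConnectivity:
    def test_equals_uniform_window_over_single_run(self, rng):
        data = rng.standard_normal((60, 5))
        ts = make_ts(data)
        plan = rm.plan_windows({ts.run_id: 60}, 60, 1, weighting="uniform")
        (win,) = rm.window_connectivity(ts, plan)
        stat = rm.static_connectivity([ts])
        assert np.max(np.abs(win.values - stat.values)) < 1e-12

    def test_duplicated_run_changes_nothing(self, rng):
        ts = make_ts(rng.standard_normal((50, 4)))
        single = rm.static_connectivity([ts])
        double = rm.static_connectivity([ts, ts])
        assert np.max(np.abs(single.values - double.values)) < 1e-12

    def test_two_run_concatenation_oracle(self, rng):
        a = rng.standard_normal((40, 4))
        b = rng.standard_normal((55, 4))
        stat = rm.static_connectivity([make_ts(a), make_ts(b, run_id="run-2")])
        za = (a - a.mean(0)) / a.std(0)
        zb = (b - b.mean(0)) / b.std(0)
        cat = np.vstack([za, zb])
        n = cat.shape[0]
        r = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                xi = cat[:, i] - cat[:, i].mean()
                xj = cat[:, j] - cat[:, j].mean()
                r[i, j] = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
        expected = np.arctanh(np.clip(r, -0.999999, 0.999999))
        np.fill_diagonal(expected, 0.0)
        assert np.max(np.abs(stat.values - expected)) < 1e-10

    def test_connectivity_outputs_are_symmetric_zero_diagonal_finite(self, rng):
        ts = make_ts(rng.standard_normal((30, 6)))
        mat = rm.static_connectivity([ts])
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)
        assert np.all(np.isfinite(mat.values))
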