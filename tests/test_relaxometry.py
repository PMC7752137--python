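"""Signal models, gradient-descent fitting, and the independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zfmri.errors import DomainError, ValidationError
from zfmri.io import AcquisitionSeries, Volume
from zfmri.relaxometry import (FitHyperparams, default_mask, fit_map,
                               fit_voxel_gd, nls_oracle_fit, t1_signal,
                               t2_signal)

from conftest import T1_TIMES, T2_TIMES


class TestSignalModels:
    def test_t1_closed_form_values(self):
        assert t1_signal(8000, 150, 0) == 0.0
        np.testing.assert_allclose(t1_signal(8000, 150, 150),
                                   8000 * (1 - math.exp(-1)), rtol=1e-15)
        # saturation: approaches M0 from below
        assert t1_signal(8000, 150, 1e7) == pytest.approx(8000, rel=1e-12)
        assert t1_signal(8000, 150, 5000) < 8000

    def test_t2_closed_form_values(self):
        assert t2_signal(8000, 75, 0) == 8000.0
        np.testing.assert_allclose(t2_signal(8000, 75, 75), 8000 / math.e, rtol=1e-15)
        np.testing.assert_allclose(t2_signal(8000, 75, 36.6),
                                   8000 * math.exp(-36.6 / 75), rtol=1e-15)

    @pytest.mark.parametrize("fn", [t1_signal, t2_signal])
    def test_nonpositive_time_constant_rejected(self, fn):
        with pytest.raises(DomainError):
            fn(8000, 0, 50)
        with pytest.raises(DomainError):
            fn(8000, -10, 50)

    @given(t=st.floats(10, 500), dt=st.floats(0.1, 200), start=st.floats(0, 500))
    def test_monotonicity(self, t, dt, start):
        assert t1_signal(8000, t, start + dt) >= t1_signal(8000, t, start)
        assert t2_signal(8000, t, start + dt) <= t2_signal(8000, t, start)


class TestFitVoxel:
    @pytest.mark.parametrize("model,times,truth", [
        ("T2", T2_TIMES, (8000.0, 75.0)),
        ("T2", T2_TIMES, (8000.0, 45.0)),
        ("T1", T1_TIMES, (8000.0, 150.0)),
        ("T1", T1_TIMES, (8000.0, 110.0)),
    ])
    def test_noiseless_roundtrip_within_half_percent(self, model, times, truth):
        m0, t = truth
        s = t1_signal(m0, t, times) if model == "T1" else t2_signal(m0, t, times)
        res = fit_voxel_gd(s, times, model)
        assert abs(res.t_value - t) / t < 0.005
        assert abs(res.m0 - m0) / m0 < 0.005

    def test_all_zero_signal_degenerates_without_raising(self):
        res = fit_voxel_gd(np.zeros(3), T2_TIMES, "T2")
        assert res.m0 == 0.0
        assert math.isnan(res.t_value)
        assert not res.converged

    def test_nonfinite_signal_rejected(self):
        with pytest.raises(DomainError):
            fit_voxel_gd([1.0, np.nan, 2.0], T2_TIMES, "T2")

    def test_loss_trajectory_is_nonincreasing(self):
        rng = np.random.default_rng(3)
        s = t2_signal(8000, 60, T2_TIMES) + rng.normal(0, 100, 3)
        res = fit_voxel_gd(np.abs(s), T2_TIMES, "T2", record_loss=True)
        traj = res.loss_trajectory
        assert traj is not None and len(traj) == res.iterations
        assert np.all(np.diff(traj) <= 1e-9 * traj[:-1] + 1e-12)

    def test_scale_invariance(self):
        times = T2_TIMES
        s = t2_signal(8000, 60, times)
        base = fit_voxel_gd(s, times, "T2")
        c = 3.7
        scaled = fit_voxel_gd(c * s, times, "T2",
                              FitHyperparams(m0_init=8000 * c))
        assert abs(scaled.t_value - base.t_value) / base.t_value < 1e-3
        assert abs(scaled.m0 - c * base.m0) / (c * base.m0) < 1e-3

    def test_wide_grid_roundtrip_scaled_mode(self):
        """Diagonally preconditioned mode recovers (M0, T) across the full
        physiologic grid where raw descent cannot traverse the flat M0
        direction within the loop budget."""
        hp = FitHyperparams(step_mode="scaled", learning_rate=0.5,
                            loop_limit=20000)
        for m0 in (2000.0, 8000.0, 16000.0):
            for t1 in (50.0, 150.0, 600.0):
                res = fit_voxel_gd(t1_signal(m0, t1, T1_TIMES), T1_TIMES, "T1", hp)
                assert abs(res.t_value - t1) / t1 < 0.005
                assert abs(res.m0 - m0) / m0 < 0.005
            for t2 in (20.0, 75.0, 200.0):
                res = fit_voxel_gd(t2_signal(m0, t2, T2_TIMES), T2_TIMES, "T2", hp)
                assert abs(res.t_value - t2) / t2 < 0.005
                assert abs(res.m0 - m0) / m0 < 0.005


class TestOracle:
    def test_two_point_closed_form(self):
        te = np.array([10.0, 60.0])
        s = np.array([100.0, 100.0 / math.e])
        m0, t2 = nls_oracle_fit(s, te, "T2")
        assert t2 == pytest.approx(50.0, rel=1e-12)  # (TE2-TE1)/ln(S1/S2)
        te2 = np.array([12.2, 36.6])
        s2 = t2_signal(5000, 80, te2)
        _, t = nls_oracle_fit(s2, te2, "T2")
        assert t == pytest.approx((te2[1] - te2[0]) / math.log(s2[0] / s2[1]),
                                  rel=1e-12)

    def test_gd_agrees_with_nls_on_converged_voxels(self):
        """Where the descent has converged (early stop hit), it finds the same
        optimum as the independent least-squares solver to < 1%."""
        rng = np.random.default_rng(11)
        hp_scaled = FitHyperparams(step_mode="scaled", learning_rate=0.5,
                                   loop_limit=20000)
        for model, times, t_true in (("T2", T2_TIMES, 60.0), ("T1", T1_TIMES, 130.0)):
            clean = (t2_signal(8000, t_true, times) if model == "T2"
                     else t1_signal(8000, t_true, times))
            # noiseless, default settings
            gd = fit_voxel_gd(clean, times, model)
            _, t_nls = nls_oracle_fit(clean, times, model)
            assert abs(gd.t_value - t_nls) / t_nls < 0.01
            # noisy, preconditioned mode (reaches convergence within budget)
            s = np.abs(clean + rng.normal(0, 80, len(times)))
            gd_n = fit_voxel_gd(s, times, model, hp_scaled)
            assert gd_n.converged
            _, t_nls_n = nls_oracle_fit(s, times, model)
            assert abs(gd_n.t_value - t_nls_n) / t_nls_n < 0.01


def _uniform_series(times, m0, t, model, shape=(6, 5, 4)):
    signal = (t1_signal(m0, t, np.asarray(times)) if model == "T1"
              else t2_signal(m0, t, np.asarray(times)))
    vols = [Volume(np.full(shape, s), (1, 1, 1)) for s in signal]
    return AcquisitionSeries(vols, model, times)


class TestFitMap:
    def test_uniform_phantom_gives_constant_plane(self):
        series = _uniform_series(T2_TIMES, 8000, 60.0, "T2")
        pmap = fit_map(series)
        assert pmap.mask.all()
        tvals = pmap.t_value[pmap.mask]
        np.testing.assert_allclose(tvals, tvals[0])  # dedup: identical fits
        assert abs(tvals[0] - 60.0) / 60.0 < 0.005

    def test_mask_excludes_background_with_sentinels(self):
        series = _uniform_series(T2_TIMES, 8000, 60.0, "T2")
        mask = np.zeros(series.shape, bool)
        mask[2:4, 2:4, 1:3] = True
        pmap = fit_map(series, mask=mask)
        assert not pmap.mask[0, 0, 0]
        assert pmap.m0[0, 0, 0] == 0.0 and pmap.t_value[0, 0, 0] == 0.0
        assert pmap.t_value[pmap.mask].min() > 0

    def test_disabled_early_stop_runs_full_loop(self):
        hp = FitHyperparams(loop_limit=200, early_stop_tol=0.0)
        series = _uniform_series(T2_TIMES, 8000, 60.0, "T2")
        pmap = fit_map(series, hp=hp)
        assert np.all(pmap.iterations[pmap.mask] == 200)
        assert not pmap.converged[pmap.mask].any()

    def test_mask_shape_mismatch_rejected(self):
        series = _uniform_series(T2_TIMES, 8000, 60.0, "T2")
        with pytest.raises(ValidationError):
            fit_map(series, mask=np.ones((2, 2, 2), bool))

    def test_repetitions_averaged_before_fitting(self):
        rng = np.random.default_rng(5)
        times = T2_TIMES
        signal = t2_signal(8000, 60.0, times)
        shape = (4, 4, 3)
        reps = [[Volume(np.abs(np.full(shape, s) + rng.normal(0, 300, shape)), (1, 1, 1))
                 for _ in range(8)] for s in signal]
        vols = [Volume(np.full(shape, s), (1, 1, 1)) for s in signal]
        series = AcquisitionSeries(vols, "T2", times, repetitions=reps)
        pmap = fit_map(series, mask=np.ones(shape, bool), deduplicate=False)
        # the fit must consume the repetition average, not `volumes`
        avg = series.averaged()
        pmap_avg = fit_map(avg, mask=np.ones(shape, bool), deduplicate=False)
        np.testing.assert_array_equal(pmap.t_value, pmap_avg.t_value)

    def test_default_mask_thresholds_at_5_percent(self):
        shape = (4, 4, 2)
        data = np.full(shape, 1000.0)
        data[0, 0, 0] = 10.0  # below 5% of max
        vols = [Volume(data * s, (1, 1, 1)) for s in (1.0, 0.5, 0.2)]
        series = AcquisitionSeries(vols, "T2", T2_TIMES)
        mask = default_mask(series)
        assert not mask[0, 0, 0]
        assert mask.sum() == data.size - 1
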