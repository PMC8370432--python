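import numpy as np
import pytest

from dcmerf.dynamics import default_time_grid, integrate
from dcmerf.erf import ERFDataset, erfs_to_frame, load_erfs, save_erfs
from dcmerf.microcircuit import POPULATIONS
from dcmerf.observation import (ObservationSpec, condition_erf, fit_statistics,
                                pearson, project_erf, summarize_correlations,
                                tukey_window)
from dcmerf.params import ParameterSet


def _dataset(erf, time_ms, sources=("lA1",), **kw):
    defaults = dict(subject="s1", group="control", session="placebo",
                    condition="deviant")
    defaults.update(kw)
    return ERFDataset(time_ms=time_ms, erf=erf, sources=sources, **defaults)


class TestProjection:
    def test_one_hot_weights_select_population(self, single_source_net):
        traj, _ = integrate(single_source_net, None)
        obs = ObservationSpec(contributions={"sp": 1.0})
        erf = project_erf(traj, obs, None, single_source_net)
        sp = traj[:, POPULATIONS.index("sp"), 0] - single_source_net.microcircuit.v_leak
        np.testing.assert_allclose(erf[0], sp)

    def test_zero_deviation_gives_zero_erf(self, single_source_net):
        t = default_time_grid()
        traj = np.zeros((t.size, 6, 4))
        traj[..., 0] = single_source_net.microcircuit.v_leak
        erf = project_erf(traj, ObservationSpec(), None, single_source_net)
        np.testing.assert_array_equal(erf, 0.0)

    def test_linearity(self, single_source_net):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 6, 4))
        y = rng.normal(size=(50, 6, 4))
        obs = ObservationSpec()
        net = single_source_net
        vl = net.microcircuit.v_leak

        def proj_dev(traj):
            # measure deviations only: offset the leak so depolarization
            # equals the raw array
            t = traj.copy()
            t[..., 0] += vl
            return project_erf(t, obs, None, net)

        a, b = 2.3, -0.7
        np.testing.assert_allclose(
            proj_dev(a * x + b * y), a * proj_dev(x) + b * proj_dev(y),
            rtol=1e-10, atol=1e-12,
        )

    def test_gain_parameter_scales_output(self, single_source_net):
        traj, _ = integrate(single_source_net, None)
        obs = ObservationSpec()
        base = project_erf(traj, obs, None, single_source_net)
        ps = ParameterSet(("obs:gain",), np.array([0.3]))
        scaled = project_erf(traj, obs, ps, single_source_net)
        np.testing.assert_allclose(scaled, np.exp(0.3) * base)

    def test_shape_mismatch_raises(self, single_source_net):
        with pytest.raises(ValueError):
            project_erf(np.zeros((10, 7, 4)), ObservationSpec(), None,
                        single_source_net)


class TestConditioning:
    def test_window_is_exactly_one_in_flat_region(self):
        t = default_time_grid()
        w = tukey_window(t)
        flat = (t >= 50) & (t <= 350)
        assert np.all(w[flat] == 1.0)
        assert np.all(w[~flat] < 1.0) or np.all(w[~flat] <= 1.0)
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[-1] == pytest.approx(0.0, abs=1e-12)

    def test_flat_region_outside_epoch_raises(self):
        t = default_time_grid()
        with pytest.raises(ValueError, match="flat region"):
            tukey_window(t, flat=(50, 500))

    def test_60hz_suppressed_by_20db(self):
        t = default_time_grid()
        sig = np.sin(2 * np.pi * 60e-3 * t)[None, :]
        ds = _dataset(sig, t)
        out = condition_erf(ds)
        mid = (t >= 100) & (t <= 300)  # avoid taper, measure filter alone
        p_in = np.mean(sig[0, mid] ** 2)
        p_out = np.mean(out.erf[0, mid] ** 2)
        assert p_out < 0.01 * p_in  # > 20 dB amplitude attenuation

    def test_constant_signal_unchanged_in_flat_region(self):
        t = default_time_grid()
        ds = _dataset(np.ones((1, t.size)), t)
        out = condition_erf(ds)
        flat = (t >= 60) & (t <= 340)
        np.testing.assert_allclose(out.erf[0, flat], 1.0, rtol=1e-6)

    def test_conditioning_is_idempotent(self):
        t = default_time_grid()
        rng = np.random.default_rng(1)
        ds = _dataset(rng.normal(size=(1, t.size)), t)
        once = condition_erf(ds)
        twice = condition_erf(once)
        np.testing.assert_allclose(twice.erf, once.erf, atol=1e-6)
        assert twice.conditioned

    def test_zero_group_delay_preserves_peak_latency(self):
        t = default_time_grid()
        # band-limited pulse centred at 150 ms
        pulse = np.exp(-0.5 * ((t - 150) / 25.0) ** 2)[None, :]
        out = condition_erf(_dataset(pulse, t))
        assert abs(t[np.argmax(out.erf[0])] - t[np.argmax(pulse[0])]) <= 1.0

    def test_nyquist_precondition(self):
        t = np.arange(-100, 401, 20.0)  # 50 Hz sampling < 2 x 48
        ds = _dataset(np.zeros((1, t.size)), t)
        with pytest.raises(ValueError, match="sampling rate"):
            condition_erf(ds)


class TestFitStatistics:
    def test_perfect_and_inverted_prediction(self):
        t = default_time_grid()
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, t.size))
        obs = _dataset(x, t, sources=("lA1", "rA1"), conditioned=True)
        assert fit_statistics(obs, obs)["per_source"]["lA1"] == pytest.approx(1.0)
        neg = obs.with_erf(-x)
        assert fit_statistics(obs, neg)["per_source"]["rA1"] == pytest.approx(-1.0)

    def test_hand_computed_five_point_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand calculation: cov = 1.6, sd_x = sd_y = sqrt(2)
        assert pearson(x, y) == pytest.approx(1.6 / 2.0)

    def test_zero_variance_reported_missing(self):
        t = default_time_grid()
        flat = _dataset(np.zeros((1, t.size)), t, conditioned=True)
        wig = flat.with_erf(np.sin(t)[None, :] )
        stats = fit_statistics(flat, wig)
        assert stats["per_source"]["lA1"] is None
        assert stats["median_r"] is None

    def test_pooled_summary_median_iqr(self):
        s = summarize_correlations([0.2, 0.4, 0.6, 0.8, None])
        assert s["median_r"] == pytest.approx(0.5)
        assert s["iqr_r"] == pytest.approx(0.3)
        assert s["n"] == 4


class TestERFDatasetIO:
    def test_hdf5_roundtrip(self, tmp_path):
        t = default_time_grid()
        rng = np.random.default_rng(3)
        ds = _dataset(rng.normal(size=(1, t.size)), t, gaba=1.3, n_trials=150)
        path = tmp_path / "erfs.h5"
        save_erfs(path, [ds])
        back = load_erfs(path)[0]
        np.testing.assert_array_equal(back.erf, ds.erf)
        assert back.gaba == pytest.approx(1.3)
        assert back.n_trials == 150
        assert back.key() == ds.key()

    def test_flat_csv_export(self):
        t = default_time_grid()
        ds = _dataset(np.zeros((1, t.size)), t)
        frame = erfs_to_frame([ds])
        assert set(frame.columns) == {"subject", "group", "session",
                                      "condition", "source", "time_ms", "value"}
        assert len(frame) == t.size

    def test_nonuniform_time_axis_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            _dataset(np.zeros((1, 3)), np.array([0.0, 1.0, 3.0]))
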