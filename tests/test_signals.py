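"""Environmental signal generators, benign windows and signal statistics."""

import math

import numpy as np
import pytest
import scipy.stats

import woo


class TestRegularDichotomous:
    def test_symmetric_square_wave_samples(self):
        p = woo.RegularDichotomousParams(E_low=0, E_high=1, tau_low=1, tau_high=1)
        traj = woo.generate_regular_dichotomous(p, duration=4, dt=0.5)
        assert traj.values.tolist() == [0, 0, 1, 1, 0, 0, 1, 1]
        assert traj.values.mean() == pytest.approx(0.5)

    def test_asymmetric_time_average_matches_closed_form(self):
        # duty-cycle mean (E_low*tau_low + E_high*tau_high) / period
        p = woo.RegularDichotomousParams(E_low=0, E_high=1, tau_low=2, tau_high=1)
        expected = (0 * 2 + 1 * 1) / 3
        traj = woo.generate_regular_dichotomous(p, duration=3000, dt=0.01)
        assert traj.values.mean() == pytest.approx(expected, abs=1e-3)
        assert woo.dichotomous_moments(p).mean == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(E_low=1, E_high=0, tau_low=1, tau_high=1),
            dict(E_low=0, E_high=1, tau_low=-1, tau_high=1),
            dict(E_low=0, E_high=1, tau_low=1, tau_high=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(woo.ParameterError):
            woo.RegularDichotomousParams(**kwargs)

    def test_non_positive_duration_rejected(self):
        p = woo.RegularDichotomousParams(E_low=0, E_high=1, tau_low=1, tau_high=1)
        with pytest.raises(woo.ParameterError):
            woo.generate_regular_dichotomous(p, duration=0, dt=0.5)


class TestDMN:
    def test_seeded_reproducibility(self, fig3_dmn):
        a = woo.generate_dmn(fig3_dmn, seed=7)
        b = woo.generate_dmn(fig3_dmn, seed=7)
        c = woo.generate_dmn(fig3_dmn, seed=8)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_two_level_support(self, long_dmn_trajectory, fig3_dmn):
        assert set(np.unique(long_dmn_trajectory.values)) == {
            fig3_dmn.E_low, fig3_dmn.E_high
        }

    def test_stationary_low_fraction(self, long_dmn_trajectory, fig3_dmn):
        # time in the low state converges to k_high/(k_low+k_high) = 2/3;
        # 3 standard errors from the telegraph autocovariance:
        # var = 2*p*q*tau_c/T with tau_c = 1/(k_low+k_high)
        frac = (long_dmn_trajectory.values == fig3_dmn.E_low).mean()
        p = fig3_dmn.p_low
        T = long_dmn_trajectory.duration
        se = math.sqrt(2 * p * (1 - p) / (fig3_dmn.k_low + fig3_dmn.k_high) / T)
        assert abs(frac - p) < 3 * se

    def test_completed_window_lengths_are_exponential(
        self, long_dmn_trajectory, fig3_dmn
    ):
        ws = woo.extract_benign_windows(long_dmn_trajectory, threshold=0.5)
        d = ws.durations()
        assert d.size > 1000
        mean = 1.0 / fig3_dmn.k_low
        assert d.mean() == pytest.approx(mean, rel=0.05)
        assert d.std() / d.mean() == pytest.approx(1.0, rel=0.10)
        # high-state residences follow the complementary rate
        ws_high = woo.extract_benign_windows(long_dmn_trajectory, threshold=0.5)
        assert ws_high.threshold == 0.5

    def test_coarse_step_rejected_and_warned(self):
        with pytest.raises(woo.ParameterError, match="too coarse"):
            woo.DMNParams(E_low=0, E_high=1, k_low=10.0, k_high=0.2,
                          dt=0.1, n_steps=100)
        with pytest.warns(UserWarning, match="exponential"):
            woo.DMNParams(E_low=0, E_high=1, k_low=5.0, k_high=0.2,
                          dt=0.05, n_steps=100)

    def test_near_absorbing_low_rate_stays_low(self):
        # k_low -> 0 limit: a trajectory that starts low never leaves
        p = woo.DMNParams(E_low=0, E_high=1, k_low=1e-12, k_high=1e-12,
                          dt=0.01, n_steps=10_000)
        traj = woo.generate_dmn(p, seed=3)
        assert np.all(traj.values == traj.values[0])


class TestScaleEpsilon:
    def test_zero_variance_gives_zero_amplitude(self):
        assert woo.scale_epsilon(0.0, 2.0, 0.01) == 0.0

    def test_ar1_formula(self):
        # a = 1 - (1 - 1/2)*0.01 = 0.995; eps = sqrt(0.5*(1-a^2))
        eps = woo.scale_epsilon(0.5, 2.0, 0.01)
        assert eps == pytest.approx(math.sqrt(0.5 * (1 - 0.995**2)))
        assert eps == pytest.approx(0.0706, abs=2e-4)

    def test_nonstationary_combination_rejected(self):
        with pytest.raises(woo.ParameterError, match="stationary"):
            woo.scale_epsilon(0.5, 1.0, 0.01)  # printed drift: random walk
        with pytest.raises(woo.ParameterError, match="stationary"):
            woo.scale_epsilon(0.5, 0.5, 0.01)  # printed drift: explosive

    def test_simulated_variance_matches_target(self):
        params = woo.OUNParams(mu=1.0, tau_approx=2.0, dt=0.01,
                               n_steps=100_000, target_variance=0.5)
        traj = woo.generate_oun(params, seed=11, burn_in="auto")
        assert traj.values.var() == pytest.approx(0.5, rel=0.10)


class TestOUN:
    def test_noise_free_geometric_decay(self):
        # eps=0, tau=2: per-step decay factor of the deviation is 0.995
        params = woo.OUNParams(mu=1.0, tau_approx=2.0, dt=0.01,
                               n_steps=100, epsilon=0.0)
        traj = woo.generate_oun(params, seed=0, E0=2.0)
        dev = traj.values - 1.0
        np.testing.assert_allclose(dev, 0.995 ** np.arange(100), rtol=1e-12)

    def test_noise_free_from_mean_is_constant(self):
        params = woo.OUNParams(mu=1.0, tau_approx=2.0, dt=0.01,
                               n_steps=50, epsilon=0.0)
        traj = woo.generate_oun(params, seed=0)
        assert np.all(traj.values == 1.0)

    def test_default_settings_stationary_moments(self):
        # default study conditions (mu=1, tau=1, var=0.5, dt=0.01) are only
        # stationary under the mean-reverting drift convention
        params = woo.OUNParams(mu=1.0, tau_approx=1.0, dt=0.01,
                               n_steps=100_000, target_variance=0.5,
                               drift="reverting")
        traj = woo.generate_oun(params, seed=5, burn_in="auto")
        assert traj.values.mean() == pytest.approx(1.0, abs=0.1)
        assert traj.values.var() == pytest.approx(0.5, rel=0.10)

    def test_printed_drift_unstationary_at_unit_period(self):
        params = woo.OUNParams(mu=1.0, tau_approx=1.0, dt=0.01,
                               n_steps=100, target_variance=0.5)
        with pytest.raises(woo.ParameterError):
            woo.generate_oun(params, seed=0)

    def test_seeded_reproducibility_and_drift_modes_differ(self):
        base = dict(mu=1.0, tau_approx=5.0, dt=0.01, n_steps=1000,
                    target_variance=0.5)
        a = woo.generate_oun(woo.OUNParams(**base), seed=9)
        b = woo.generate_oun(woo.OUNParams(**base), seed=9)
        c = woo.generate_oun(woo.OUNParams(**base, drift="reverting"), seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_missing_seed_rejected(self):
        params = woo.OUNParams(mu=1.0, tau_approx=5.0, dt=0.01, n_steps=100,
                               epsilon=0.1)
        with pytest.raises(woo.ParameterError, match="seed"):
            woo.generate_oun(params)


class TestWindows:
    def test_no_benign_samples_gives_empty_set(self):
        traj = woo.SignalTrajectory(t0=0, dt=1, values=np.ones(10))
        ws = woo.extract_benign_windows(traj, threshold=0.5)
        assert len(ws) == 0
        assert ws.durations().size == 0

    def test_run_length_bookkeeping_and_censoring(self):
        traj = woo.SignalTrajectory(t0=0, dt=1, values=np.array([1, 0, 0, 1, 0, 1]))
        ws = woo.extract_benign_windows(traj, threshold=0.5)
        assert ws.duration.tolist() == [2.0, 1.0]
        assert ws.censored.tolist() == [False, False]
        assert [w.duration for w in ws.windows()] == [2.0, 1.0]
        # windows touching either series boundary are censored
        traj2 = woo.SignalTrajectory(t0=0, dt=1, values=np.array([0, 1, 0, 1, 0]))
        ws2 = woo.extract_benign_windows(traj2, threshold=0.5)
        assert ws2.censored.tolist() == [True, False, True]
        assert ws2.durations().tolist() == [1.0]

    def test_windows_disjoint_and_ordered(self, long_dmn_trajectory):
        ws = woo.extract_benign_windows(long_dmn_trajectory, threshold=0.5)
        assert np.all(ws.end[:-1] <= ws.start[1:])
        assert np.all(ws.duration > 0)


class TestSignalStatistics:
    def test_alternating_series_moments(self):
        traj = woo.SignalTrajectory(t0=0, dt=1,
                                    values=np.tile([0.0, 1.0], 50))
        stats = woo.signal_statistics(traj)
        assert stats.mean == pytest.approx(0.5)
        assert stats.variance == pytest.approx(0.25)

    def test_constant_series_warns(self):
        traj = woo.SignalTrajectory(t0=0, dt=1, values=np.ones(10))
        with pytest.warns(UserWarning, match="constant"):
            stats = woo.signal_statistics(traj)
        assert stats.variance == 0.0
        assert stats.correlation_time == 0.0

    def test_white_noise_correlation_time_is_one_step(self):
        # reverting drift with tau = dt gives AR coefficient a = 0
        params = woo.OUNParams(mu=0.0, tau_approx=0.01, dt=0.01,
                               n_steps=20_000, target_variance=1.0,
                               drift="reverting")
        traj = woo.generate_oun(params, seed=1)
        assert woo.signal_statistics(traj).correlation_time == pytest.approx(0.01)

    def test_longer_period_gives_longer_correlation_time(self):
        out = {}
        for tau in (0.5, 5.0):
            params = woo.OUNParams(mu=0.0, tau_approx=tau, dt=0.01,
                                   n_steps=100_000, target_variance=0.5,
                                   drift="reverting")
            traj = woo.generate_oun(params, seed=2, burn_in="auto")
            out[tau] = woo.signal_statistics(traj).correlation_time
        assert out[5.0] > out[0.5]


class TestDichotomousMoments:
    def test_symmetric_regular_moments(self):
        p = woo.RegularDichotomousParams(E_low=0, E_high=1, tau_low=3, tau_high=3)
        stats = woo.dichotomous_moments(p)
        assert stats.mean == pytest.approx(0.5)
        assert stats.variance == pytest.approx(0.25)

    def test_dmn_two_point_moments(self, fig3_dmn):
        stats = woo.dichotomous_moments(fig3_dmn)
        assert stats.mean == pytest.approx(1.0 / 3.0)
        assert stats.variance == pytest.approx(2.0 / 9.0)
        assert stats.correlation_time == pytest.approx(1.0 / 0.3)

    def test_degenerate_levels_give_zero_variance(self):
        p = woo.DMNParams(E_low=0.5, E_high=0.5 + 1e-12, k_low=0.1, k_high=0.1,
                          dt=0.01, n_steps=10)
        assert woo.dichotomous_moments(p).variance == pytest.approx(0.0, abs=1e-20)

    def test_agrees_with_sample_statistics(self, long_dmn_trajectory, fig3_dmn):
        analytic = woo.dichotomous_moments(fig3_dmn)
        sample = woo.signal_statistics(long_dmn_trajectory)
        assert sample.mean == pytest.approx(analytic.mean, abs=0.03)
        assert sample.variance == pytest.approx(analytic.variance, rel=0.05)
        assert sample.correlation_time == pytest.approx(
            analytic.correlation_time, rel=0.2
        )


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        p = woo.DMNParams(E_low=0, E_high=1, k_low=0.1, k_high=0.2,
                          dt=0.01, n_steps=500)
        traj = woo.generate_dmn(p, seed=4)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = woo.SignalTrajectory.from_csv(path)
        np.testing.assert_allclose(back.values, traj.values)
        assert back.dt == traj.dt
        assert back.params["kind"] == "dmn"
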