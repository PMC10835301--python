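"""Phase extraction, period detection, spectra, synchrony and smoothing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import circstd as scipy_circstd

import redoxclocks as rc
from redoxclocks.metrics import autocorrelation


class TestPhaseAmplitude:
    def test_cardinal_points(self):
        ps = rc.instantaneous_phase_amplitude([1.0, 0.0, -1.0], [0.0, 1.0, 0.0])
        assert ps.phase == pytest.approx([0.0, np.pi / 2, np.pi])
        assert ps.amplitude == pytest.approx([1.0, 1.0, 1.0])

    def test_origin_phase_undefined_and_counted(self):
        ps = rc.instantaneous_phase_amplitude([0.0, 1.0], [0.0, 0.0])
        assert np.isnan(ps.phase[0]) and ps.n_undefined == 1

    def test_noiseless_oscillator_phase_is_linear_in_time(self):
        spec = rc.EnsembleSpec(n=1, tau_sd=0.0, seed=1,
                               shared=rc.OscillatorParams(sigma_x=0.0, sigma_y=0.0,
                                                          twist=0.0))
        grid = rc.SimulationGrid(dt=0.01, t_end=100.0, transient=0.0)
        tr = rc.simulate_ensemble(spec, grid)
        ph = rc.instantaneous_phase_amplitude(tr.x[0], tr.y[0]).unwrapped()
        fit = np.polyfit(tr.times, ph, 1)
        assert fit[0] == pytest.approx(2 * np.pi / 24.23, rel=1e-3)
        assert np.max(np.abs(ph - np.polyval(fit, tr.times))) < 1e-3


class TestZeroCrossingPeriod:
    def test_pure_cosine(self):
        t = np.arange(0, 240, 0.01)
        zc = rc.period_zero_crossings(np.cos(2 * np.pi * t / 24.0), t)
        assert zc.period == pytest.approx(24.0, abs=1e-3)

    def test_constant_series_raises(self):
        t = np.arange(0, 100, 0.1)
        with pytest.raises(ValueError, match="no rhythm"):
            rc.period_zero_crossings(np.ones_like(t), t)

    def test_hysteresis_rejects_noise_jitter_crossings(self):
        """Additive sample noise creates crossing clusters near each zero;
        the Schmitt-trigger rule must keep the period unbiased."""
        rng = np.random.default_rng(4)
        t = np.arange(0, 2400, 0.1)
        s = np.sin(2 * np.pi * t / 24.0) + 0.05 * rng.standard_normal(t.size)
        naive = rc.period_zero_crossings(s, t, hysteresis=0.0).period
        robust = rc.period_zero_crossings(s, t).period
        assert abs(robust - 24.0) < 0.05
        assert abs(robust - 24.0) < abs(naive - 24.0)

    def test_offset_invariance(self):
        t = np.arange(0, 240, 0.01)
        s = np.cos(2 * np.pi * t / 24.0)
        a = rc.period_zero_crossings(s, t).period
        b = rc.period_zero_crossings(s + 3.7, t).period
        assert a == pytest.approx(b, abs=1e-9)


class TestPeriodogram:
    def test_pure_sine_within_spectral_resolution(self):
        t = np.arange(0, 2400, 0.1)
        pg = rc.periodogram_dominant_period(np.sin(2 * np.pi * t / 24.0), t)
        assert pg.period == pytest.approx(24.0, abs=0.25)
        assert not pg.arrhythmic

    def test_two_tone_dominance_and_secondary_peak(self):
        """2:1 amplitude mix of 23.6 h and 26.2 h: the stronger tone wins
        and the weaker one is reported as a secondary peak."""
        t = np.arange(0, 2400, 0.1)
        s = 2 * np.sin(2 * np.pi * t / 23.6) + np.sin(2 * np.pi * t / 26.2)
        pg = rc.periodogram_dominant_period(s, t)
        assert pg.period == pytest.approx(23.6, abs=0.25)
        secondary = [p for p, h in pg.peaks if abs(p - 26.2) < 0.3]
        assert secondary, f"no secondary peak near 26.2 h in {pg.peaks}"

    def test_agrees_with_zero_crossings_on_noiseless_signal(self):
        t = np.arange(0, 2400, 0.1)
        s = np.sin(2 * np.pi * t / 25.3)
        zc = rc.period_zero_crossings(s, t).period
        pg = rc.periodogram_dominant_period(s, t).period
        assert abs(zc - pg) < 0.25

    def test_white_noise_flagged_arrhythmic(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 2400, 0.1)
        pg = rc.periodogram_dominant_period(rng.standard_normal(t.size), t)
        assert pg.arrhythmic

    def test_single_noisy_oscillator_peaks_near_intrinsic_period(self):
        """A free-running noisy oscillator at tau = 24.23 h over 100 days
        shows its spectral peak at ~24.2 h."""
        spec = rc.EnsembleSpec(n=1, tau_sd=0.0, seed=21)
        grid = rc.SimulationGrid()
        tr = rc.simulate_ensemble(spec, grid)
        pg = rc.periodogram_dominant_period(tr.x[0], tr.times, transient=480.0)
        assert pg.period == pytest.approx(24.2, abs=0.5)


class TestAutocorrelation:
    def test_pure_sine_envelope_does_not_decay(self):
        t = np.arange(0, 480, 0.1)
        ac = autocorrelation(np.sin(2 * np.pi * t / 24.0), dt=0.1)
        assert abs(ac.envelope_decay_rate) < 1e-3
        assert ac.acf[0] == pytest.approx(1.0)

    def test_white_noise_acf_vanishes(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(20_000)
        ac = autocorrelation(s, max_lag=1000)
        assert np.max(np.abs(ac.acf[1:])) < 3.0 / np.sqrt(s.size) * 1.5

    def test_noisy_oscillator_envelope_decays(self):
        """Phase diffusion makes the oscillator decorrelate from itself; a
        single record's empirical ACF fluctuates, so the envelope decay is
        asserted on the ACF averaged over an identical ensemble."""
        spec = rc.EnsembleSpec(n=10, tau_sd=0.0, seed=6)
        tr = rc.simulate_ensemble(spec, rc.SimulationGrid())
        acfs = [autocorrelation(x, dt=0.1, max_lag=8_000).acf for x in tr.x]
        mean_acf = np.mean(acfs, axis=0)
        lags = np.arange(8_001) * 0.1
        from scipy.signal import find_peaks
        from scipy.stats import linregress

        pk, _ = find_peaks(mean_acf)
        pk = pk[mean_acf[pk] > 0.01]
        rate = -linregress(lags[pk], np.log(mean_acf[pk])).slope
        assert rate > 0


class TestOrderParameter:
    def test_analytic_values(self):
        assert rc.order_parameter(np.zeros(7)) == pytest.approx(1.0)
        assert rc.order_parameter(np.linspace(0, 2 * np.pi, 8, endpoint=False)) \
            == pytest.approx(0.0, abs=1e-12)
        assert rc.order_parameter(np.array([0.0, np.pi / 2])) \
            == pytest.approx(np.sqrt(2) / 2)

    def test_single_oscillator_is_always_coherent(self):
        assert rc.order_parameter(np.array([1.234])) == pytest.approx(1.0)

    @given(arrays(float, st.integers(2, 30),
                  elements=st.floats(-np.pi, np.pi)))
    def test_bounded_between_zero_and_one(self, phases):
        r = rc.order_parameter(phases)
        assert -1e-12 <= r <= 1.0 + 1e-12

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            rc.order_parameter(np.array([np.nan, np.nan]))


class TestCircularStd:
    def test_analytic_values(self):
        assert rc.circular_std(np.zeros(5)) == pytest.approx(0.0, abs=1e-12)
        assert rc.circular_std(np.array([0.0, np.pi / 2])) \
            == pytest.approx(np.sqrt(-2 * np.log(np.sqrt(2) / 2)))

    def test_antipodal_pair_is_infinite_with_flag(self):
        with pytest.warns(UserWarning, match="resultant"):
            assert rc.circular_std(np.array([0.0, np.pi])) == np.inf

    def test_matches_scipy_circstd(self):
        rng = np.random.default_rng(2)
        ph = rng.normal(1.0, 0.4, 500)
        assert rc.circular_std(ph) == pytest.approx(
            scipy_circstd(ph, high=np.pi, low=-np.pi), rel=1e-10
        )

    def test_hours_rescaling(self):
        ph = np.random.default_rng(3).normal(0, 0.3, 100)
        assert rc.circular_std(ph, to_hours=True) == pytest.approx(
            rc.circular_std(ph) * 24 / (2 * np.pi)
        )

    @given(st.floats(-10, 10), st.integers(0, 5))
    def test_rotation_invariance(self, offset, seed):
        ph = np.random.default_rng(seed).uniform(-2, 2, 40)
        assert rc.circular_std(ph + offset) == pytest.approx(
            rc.circular_std(ph), abs=1e-9
        )


class TestPhaseDispersion:
    def test_noiseless_identical_ensemble_has_zero_dispersion(self):
        spec = rc.EnsembleSpec(n=5, tau_sd=0.0, seed=1,
                               shared=rc.OscillatorParams(sigma_x=0.0, sigma_y=0.0))
        grid = rc.SimulationGrid(dt=0.01, t_end=100.0, transient=0.0)
        trajs = [rc.simulate_ensemble(spec, grid)]
        d = rc.phase_dispersion_timecourse(trajs)
        assert np.allclose(d.mean_curve, 0.0, atol=1e-6)

    def test_relabeling_invariance(self):
        spec = rc.EnsembleSpec(n=8, tau_sd=0.0, seed=9)
        grid = rc.SimulationGrid(dt=0.01, t_end=200.0, transient=0.0)
        tr = rc.simulate_ensemble(spec, grid)
        d1 = rc.phase_dispersion_timecourse([tr]).mean_curve
        perm = np.random.default_rng(0).permutation(8)
        tr.x, tr.y = tr.x[perm], tr.y[perm]
        d2 = rc.phase_dispersion_timecourse([tr]).mean_curve
        assert np.allclose(d1, d2)

    def test_mismatched_grids_rejected(self):
        spec = rc.EnsembleSpec(n=2, seed=1)
        a = rc.simulate_ensemble(spec, rc.SimulationGrid(dt=0.01, t_end=50, transient=0))
        b = rc.simulate_ensemble(spec, rc.SimulationGrid(dt=0.01, t_end=60, transient=0))
        with pytest.raises(ValueError, match="time grid"):
            rc.phase_dispersion_timecourse([a, b])


class TestMeanFieldAmplitude:
    def test_sine_amplitude_recovered(self):
        t = np.arange(0, 2400, 0.1)
        a = 0.83
        assert rc.mean_field_amplitude(a * np.sin(2 * np.pi * t / 24), t) \
            == pytest.approx(a, abs=1e-3)

    def test_offset_invariance(self):
        t = np.arange(0, 2400, 0.1)
        s = 0.5 * np.sin(2 * np.pi * t / 24)
        assert rc.mean_field_amplitude(s + 2.0, t) == pytest.approx(
            rc.mean_field_amplitude(s, t), abs=1e-9
        )

    def test_few_cycles_warns(self):
        t = np.arange(0, 100, 0.1)
        with pytest.warns(UserWarning, match="cycles"):
            rc.mean_field_amplitude(np.sin(2 * np.pi * t / 24), t)


class TestBootstrapLowess:
    def test_line_recovered_with_negligible_band(self):
        x = np.linspace(0, 1, 200)
        y = 2.0 * x + 0.5
        bl = rc.bootstrap_lowess(x, y, seed=1)
        assert np.max(np.abs(bl.mean - (2.0 * bl.grid + 0.5))) < 1e-6
        assert np.max(bl.hi - bl.lo) < 1e-6

    def test_constant_y(self):
        x = np.linspace(0, 1, 50)
        bl = rc.bootstrap_lowess(x, np.full(50, 1.3), seed=1)
        assert np.allclose(bl.mean, 1.3)

    def test_smooth_curve_consistency_on_low_noise_quadratic(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 1, 300)
        y = x**2 + rng.normal(0, 0.01, x.size)
        bl = rc.bootstrap_lowess(x, y, seed=2)
        assert np.max(np.abs(bl.mean - bl.grid**2)) < 0.05

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rc.bootstrap_lowess(np.ones(20), np.arange(20.0), seed=1)
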