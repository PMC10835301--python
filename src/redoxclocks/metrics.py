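"""Rhythm analysis: phases, periods, spectra, synchrony and dispersion.

Conventions used throughout:

* instantaneous phase phi = atan2(y, x), wrapped to (-pi, pi]; amplitude
  r = sqrt(x^2 + y^2); the phase is undefined at the origin and such samples
  are excluded from circular statistics (with a logged count);
* periods come either from negative-slope zero crossings of the
  mean-removed signal (with linear interpolation between samples and a
  noise-rejecting hysteresis) or from a zero-padded FFT periodogram with
  parabolic peak interpolation;
* the Kuramoto order parameter R0 is the modulus of the mean unit phasor,
  0 = incoherent, 1 = fully phase-locked;
* circular standard deviation is sqrt(-2 ln Rbar) with Rbar the mean
  resultant length (the standard definition, identical to
  ``scipy.stats.circstd``), optionally rescaled to hours on a 24 h cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "PhaseSeries",
    "ZeroCrossingPeriod",
    "Periodogram",
    "SyncMetrics",
    "DispersionCurve",
    "BootstrapLowess",
    "instantaneous_phase_amplitude",
    "period_zero_crossings",
    "periodogram_dominant_period",
    "autocorrelation",
    "order_parameter",
    "circular_std",
    "phase_dispersion_timecourse",
    "mean_field_amplitude",
    "bootstrap_lowess",
    "sync_metrics",
]

RAD_TO_H24 = 24.0 / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# phases and amplitudes


@dataclass
class PhaseSeries:
    """Instantaneous phase (wrapped to (-pi, pi]) and amplitude.

    ``phase`` and ``amplitude`` have the same shape as the input (N, T) or
    (T,). Samples at the origin, where the phase is undefined, are NaN and
    counted in ``n_undefined``.
    """

    times: np.ndarray | None
    phase: np.ndarray
    amplitude: np.ndarray
    n_undefined: int = 0

    def unwrapped(self) -> np.ndarray:
        """Continuous phase along the time axis (last axis)."""
        return np.unwrap(self.phase, axis=-1)


def instantaneous_phase_amplitude(x, y, times=None) -> PhaseSeries:
    """Quadrant-aware phase atan2(y, x) and amplitude sqrt(x^2 + y^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    amp = np.hypot(x, y)
    phase = np.arctan2(y, x)
    phase = np.where(phase == -np.pi, np.pi, phase)  # wrap to (-pi, pi]
    undefined = amp == 0.0
    n_undef = int(undefined.sum())
    if n_undef:
        phase = np.where(undefined, np.nan, phase)
    return PhaseSeries(times=times, phase=phase, amplitude=amp, n_undefined=n_undef)


# ---------------------------------------------------------------------------
# periods


@dataclass
class ZeroCrossingPeriod:
    period: float
    crossing_times: np.ndarray
    period_sd: float = np.nan


def period_zero_crossings(
    series,
    times,
    transient: float = 0.0,
    hysteresis: float = 0.25,
) -> ZeroCrossingPeriod:
    """Mean interval between negative-slope zeros of the mean-removed signal.

    Crossings are located by linear interpolation between the bracketing
    samples. A Schmitt-trigger re-arm rule suppresses the spurious crossing
    pairs that measurement/dynamical noise produces near a zero: after a
    downward crossing is accepted, the next one only counts once the signal
    has risen above ``hysteresis`` times the standard deviation of the
    mean-removed series (0 disables the rule; smooth signals are
    unaffected either way).

    Raises ``ValueError`` ("no rhythm detected") with fewer than two
    accepted crossings.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = times >= transient
    s = series[keep]
    t = times[keep]
    if s.size < 3:
        raise ValueError("no rhythm detected: series too short")
    s = s - s.mean()

    cand = np.where((s[:-1] > 0) & (s[1:] <= 0))[0]
    if cand.size < 2:
        raise ValueError("no rhythm detected: fewer than 2 negative-slope zeros")

    thr = hysteresis * s.std()
    accepted = []
    prev_end = 0
    seg_max = -np.inf
    for i in cand:
        seg_max = max(seg_max, s[prev_end : i + 1].max())
        if seg_max > thr:
            accepted.append(i)
            seg_max = -np.inf
        prev_end = i + 1
    if len(accepted) < 2:
        raise ValueError("no rhythm detected: fewer than 2 negative-slope zeros")

    idx = np.asarray(accepted)
    frac = s[idx] / (s[idx] - s[idx + 1])
    tc = t[idx] + frac * (t[idx + 1] - t[idx])
    intervals = np.diff(tc)
    sd = float(intervals.std(ddof=1)) if intervals.size > 1 else np.nan
    return ZeroCrossingPeriod(
        period=float(intervals.mean()), crossing_times=tc, period_sd=sd
    )


@dataclass
class Periodogram:
    """FFT periodogram summarized on the period axis.

    ``period`` is the parabolic-interpolated period of the maximal power;
    ``peaks`` lists (period_h, relative_power) for every local maximum above
    ``peak_threshold`` of the global maximum (useful to spot beating between
    coexisting frequencies); ``arrhythmic`` flags a spectrum whose maximum
    is indistinguishable from its noise floor.
    """

    period: float
    periods: np.ndarray
    power: np.ndarray  # normalized to max = 1 within the analysis band
    peaks: list[tuple[float, float]]
    arrhythmic: bool = False


def _parabolic_refine(f: np.ndarray, p: np.ndarray, j: int) -> float:
    """Refine a spectral peak frequency by a parabola through 3 bins."""
    if j <= 0 or j >= p.size - 1:
        return f[j]
    a, b, c = p[j - 1], p[j], p[j + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return f[j]
    delta = 0.5 * (a - c) / denom
    return f[j] + delta * (f[1] - f[0])


def periodogram_dominant_period(
    series,
    times,
    transient: float = 0.0,
    min_period: float | None = None,
    max_period: float | None = None,
    pad_factor: int = 4,
    peak_threshold: float = 0.2,
    arrhythmic_ratio: float = 20.0,
) -> Periodogram:
    """Dominant period from a zero-padded FFT periodogram.

    The mean-removed, transient-trimmed series is zero-padded to at least
    ``pad_factor`` times its length (rounded up to a power of two) and the
    spectrum restricted to the period band [min_period, max_period]
    (defaults: 4 sample intervals to one fifth of the analyzed span). The
    spectrum is flagged arrhythmic when the maximal power is below
    ``arrhythmic_ratio`` times the band median — the max/median ratio of a
    featureless (white) spectrum stays near ~12 while genuine rhythms reach
    orders of magnitude more.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = times >= transient
    s = series[keep]
    t = times[keep]
    if s.size < 16:
        raise ValueError("series too short for a periodogram")
    dt = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    if min_period is None:
        min_period = 4.0 * dt
    if max_period is None:
        max_period = span / 5.0

    s = s - s.mean()
    nfft = 1 << int(np.ceil(np.log2(pad_factor * s.size)))
    power = np.abs(np.fft.rfft(s, nfft)) ** 2
    freq = np.fft.rfftfreq(nfft, dt)
    band = (freq >= 1.0 / max_period) & (freq <= 1.0 / min_period)
    fb = freq[band]
    pb = power[band]
    if pb.size < 3 or pb.max() <= 0:
        return Periodogram(np.nan, 1.0 / fb[::-1] if fb.size else fb,
                           pb[::-1], [], arrhythmic=True)

    arrhythmic = pb.max() < arrhythmic_ratio * np.median(pb)
    pn = pb / pb.max()
    j = int(np.argmax(pb))
    f0 = _parabolic_refine(fb, pb, j)
    dominant = 1.0 / f0 if f0 > 0 else np.nan

    pk, props = find_peaks(pn, height=peak_threshold)
    peaks = []
    for i, h in zip(pk, props["peak_heights"]):
        fi = _parabolic_refine(fb, pb, int(i))
        peaks.append((1.0 / fi, float(h)))
    if not any(abs(p - dominant) < 1e-9 for p, _ in peaks):
        peaks.append((dominant, 1.0))
    peaks.sort(key=lambda ph: -ph[1])

    return Periodogram(
        period=float(dominant),
        periods=1.0 / fb[::-1],
        power=pn[::-1],
        peaks=peaks,
        arrhythmic=bool(arrhythmic),
    )


# ---------------------------------------------------------------------------
# autocorrelation


@dataclass
class Autocorrelation:
    lags: np.ndarray  # in time units of `dt`
    acf: np.ndarray
    envelope_decay_rate: float  # per time unit; ~0 for a pure sine


def autocorrelation(series, dt: float = 1.0, max_lag: int | None = None) -> Autocorrelation:
    """Normalized autocorrelation and the decay rate of its envelope.

    The ACF of a noisy self-sustained oscillator is an exponentially
    damped cosine; the decay rate is fitted log-linearly to the ACF's
    positive cycle maxima (rate ~0 for a noiseless periodic signal).
    """
    s = np.asarray(series, dtype=float)
    s = s - s.mean()
    n = s.size
    if max_lag is None:
        max_lag = n // 2
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(s, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    # unbiased estimator: without the 1/(n-k) correction a finite periodic
    # signal shows a spurious linear (triangular-window) envelope decay
    ac = ac / (n - np.arange(max_lag + 1))
    ac = ac / ac[0]
    lags = np.arange(max_lag + 1) * dt

    pk, _ = find_peaks(ac)
    pk = pk[ac[pk] > 0.01]
    if pk.size >= 3:
        fit = linregress(lags[pk], np.log(ac[pk]))
        rate = -float(fit.slope)
    else:
        rate = np.nan
    return Autocorrelation(lags=lags, acf=ac, envelope_decay_rate=rate)


# ---------------------------------------------------------------------------
# synchrony and circular statistics


def order_parameter(phases, axis: int = 0):
    """Kuramoto order parameter R0 = |mean_j exp(i phi_j)|.

    NaN phases (undefined at the origin) are excluded; if all phases along
    a slice are undefined a ``ValueError`` is raised. For a (N, T) phase
    matrix with ``axis=0`` this returns the R0 time series.
    """
    ph = np.asarray(phases, dtype=float)
    z = np.exp(1j * ph)
    z = np.where(np.isnan(ph), 0, z)
    counts = (~np.isnan(ph)).sum(axis=axis)
    if np.any(counts == 0):
        raise ValueError("all phases undefined in at least one time slice")
    r = np.abs(z.sum(axis=axis)) / counts
    return float(r) if np.ndim(r) == 0 else r


def circular_std(phases, to_hours: bool = False, axis=None):
    """Circular standard deviation sqrt(-2 ln Rbar) of wrapped phases.

    ``Rbar`` is the mean resultant length; Rbar = 0 (e.g. an antipodal
    pair) gives +inf, reported with a warning flag. With ``to_hours`` the
    result is rescaled to hours on a 24 h cycle (24/2pi h per radian).
    """
    ph = np.asarray(phases, dtype=float)
    valid = ~np.isnan(ph)
    if valid.sum(axis=axis if axis is not None else None).min() < 2:
        raise ValueError("need at least 2 defined phases")
    z = np.where(valid, np.exp(1j * ph), 0)
    rbar = np.abs(z.sum(axis=axis)) / valid.sum(axis=axis)
    rbar = np.where(rbar < 1e-12, 0.0, rbar)  # exact cancellation up to fp noise
    rbar = np.minimum(rbar, 1.0)  # |mean phasor| can exceed 1 by fp rounding
    with np.errstate(divide="ignore"):
        out = np.sqrt(-2.0 * np.log(rbar))
    if np.any(rbar == 0):
        warnings.warn("mean resultant length is 0; circular std is +inf")
    if to_hours:
        out = out * RAD_TO_H24
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class SyncMetrics:
    """Summary of one ensemble run's synchrony and rhythm."""

    r0_series: np.ndarray
    r0_mean: float
    period_per_oscillator: np.ndarray
    mean_field_period: float
    mean_field_amplitude: float


def sync_metrics(traj, transient: float | None = None, n_cycles: int = 8) -> SyncMetrics:
    """R0 time course and averaged rhythm statistics of one ensemble run.

    ``r0_mean`` and the mean-field amplitude are averaged over the last
    ``n_cycles`` mean-field oscillations (falling back to the final third
    of the record when the mean field has no detectable rhythm);
    per-oscillator periods use the zero-crossing method on x after the
    transient.
    """
    if transient is None:
        transient = traj.meta.get("transient_h", 0.0)
    ps = instantaneous_phase_amplitude(traj.x, traj.y, traj.times)
    r0 = order_parameter(ps.phase, axis=0)

    periods = np.full(traj.n_oscillators, np.nan)
    for i in range(traj.n_oscillators):
        try:
            periods[i] = period_zero_crossings(
                traj.x[i], traj.times, transient=transient
            ).period
        except ValueError:
            pass

    try:
        mf_period = periodogram_dominant_period(
            traj.mean_field, traj.times, transient=transient
        ).period
        zc = period_zero_crossings(traj.mean_field, traj.times, transient=transient)
        window_start = zc.crossing_times[max(0, len(zc.crossing_times) - 1 - n_cycles)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf_amp = mean_field_amplitude(
                traj.mean_field, traj.times, n_cycles=n_cycles, transient=transient
            )
    except ValueError:
        mf_period = np.nan
        mf_amp = np.nan
        window_start = traj.times[0] + 2.0 * (traj.times[-1] - traj.times[0]) / 3.0

    window = traj.times >= window_start
    return SyncMetrics(
        r0_series=r0,
        r0_mean=float(r0[window].mean()),
        period_per_oscillator=periods,
        mean_field_period=mf_period,
        mean_field_amplitude=mf_amp,
    )


# ---------------------------------------------------------------------------
# phase dispersion across realizations


@dataclass
class DispersionCurve:
    """Ensemble phase dispersion over time, averaged across realizations.

    ``exponent`` is the slope of log(dispersion) vs log(t) fitted between
    ``fit_window`` bounds — the pre-saturation growth law (0.5 = pure phase
    diffusion, the Fickian square root of time).
    """

    times: np.ndarray
    mean_curve: np.ndarray  # radians
    per_realization: np.ndarray  # (n_realizations, T)
    exponent: float
    fit_window: tuple[float, float]
    saturated: bool = False


def phase_dispersion_timecourse(
    realizations,
    fit_tmin: float = 12.0,
    saturation_rad: float = 1.5,
) -> DispersionCurve:
    """Circular std of ensemble phases vs time, averaged over realizations.

    All realizations must share a time grid. The power-law exponent is
    fitted on the realization-averaged curve from ``fit_tmin`` up to the
    first time the dispersion exceeds ``saturation_rad`` (beyond which the
    circular std saturates toward its uniform-distribution plateau and no
    growth law is identifiable). Curves saturated from the start are
    flagged and get a NaN exponent.
    """
    times = realizations[0].times
    for tr in realizations[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError("realizations do not share a time grid")

    curves = np.empty((len(realizations), times.size))
    for k, tr in enumerate(realizations):
        ps = instantaneous_phase_amplitude(tr.x, tr.y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves[k] = circular_std(ps.phase, axis=0)
    mean_curve = curves.mean(axis=0)

    sel = times >= fit_tmin
    above = np.where(sel & (mean_curve >= saturation_rad))[0]
    t_hi = times[above[0]] if above.size else times[-1]
    window = sel & (times < t_hi) & (mean_curve > 0)
    if window.sum() < 5:
        return DispersionCurve(
            times=times,
            mean_curve=mean_curve,
            per_realization=curves,
            exponent=np.nan,
            fit_window=(fit_tmin, float(t_hi)),
            saturated=True,
        )
    fit = linregress(np.log(times[window]), np.log(mean_curve[window]))
    return DispersionCurve(
        times=times,
        mean_curve=mean_curve,
        per_realization=curves,
        exponent=float(fit.slope),
        fit_window=(fit_tmin, float(t_hi)),
    )


# ---------------------------------------------------------------------------
# mean-field amplitude and sweep smoothing


def mean_field_amplitude(
    mean_field,
    times,
    n_cycles: int = 8,
    transient: float = 0.0,
) -> float:
    """Half peak-to-trough distance averaged over the last ``n_cycles`` cycles.

    Cycles are delimited by consecutive negative-slope zero crossings of the
    mean-removed signal; each cycle contributes (max - min) / 2 of the raw
    signal, making the measure invariant to constant offsets. With fewer
    than ``n_cycles`` full cycles available the mean is taken over what is
    there, with a warning.
    """
    mf = np.asarray(mean_field, dtype=float)
    times = np.asarray(times, dtype=float)
    zc = period_zero_crossings(mf, times, transient=transient)
    tc = zc.crossing_times
    n_avail = len(tc) - 1
    if n_avail < n_cycles:
        warnings.warn(
            f"only {n_avail} full cycles available; averaging amplitude over those"
        )
        n_use = n_avail
    else:
        n_use = n_cycles
    amps = []
    for a, b in zip(tc[-n_use - 1 : -1], tc[-n_use:]):
        seg = mf[(times >= a) & (times < b)]
        amps.append((seg.max() - seg.min()) / 2.0)
    return float(np.mean(amps))


@dataclass
class BootstrapLowess:
    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray  # 2.5th percentile
    hi: np.ndarray  # 97.5th percentile


def bootstrap_lowess(
    x,
    y,
    n_boot: int = 100,
    frac_points: float = 0.5,
    span: float = 0.4,
    n_grid: int = 100,
    seed: int | None = None,
) -> BootstrapLowess:
    """Bootstrap-averaged lowess smooth of a scatter with a 95% band.

    Each of ``n_boot`` iterations fits a lowess smoother (window fraction
    ``span``) to a random ``frac_points`` subsample drawn without
    replacement and evaluates it on a common x grid; the pointwise mean and
    2.5-97.5 percentile band summarize the fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x values: all equal")
    rng = np.random.default_rng(seed)
    grid = np.linspace(x.min(), x.max(), n_grid)
    m = max(2, int(round(frac_points * x.size)))
    fits = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        idx = rng.choice(x.size, size=m, replace=False)
        fits[b] = _sm_lowess(y[idx], x[idx], frac=span, xvals=grid)
    return BootstrapLowess(
        grid=grid,
        mean=fits.mean(axis=0),
        lo=np.percentile(fits, 2.5, axis=0),
        hi=np.percentile(fits, 97.5, axis=0),
    )
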