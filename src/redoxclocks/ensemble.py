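"""Ensembles of stochastic amplitude-phase (Poincaré) oscillators with twist.

A single oscillator in Cartesian coordinates (x, y), with radial coordinate
r = sqrt(x^2 + y^2), follows

    dx = [ lam * x * (A - r) - y * (2*pi/tau + twist * (A - r)) ] dt + sigma_x dW1
    dy = [ lam * y * (A - r) + x * (2*pi/tau + twist * (A - r)) ] dt + sigma_y dW2

so the limit cycle is the circle r = A, radial perturbations relax at rate
lam * A, and the twist term makes the instantaneous frequency depend on the
amplitude deviation (r > A runs slow for positive twist — the
period-amplitude correlation seen in redox and other circadian oscillators).

A population of N such units, heterogeneous in intrinsic period tau_i,
interacts all-to-all through the mean field M(t) = mean_i x_i(t) (modelling
fast-diffusing cytosolic H2O2), which enters each x-equation as Kc * M.
An optional transcription-translation feedback loop (TTFL) signal enters
each y-equation as K_TTFL * drive(t), with ``drive`` the mean-normalized
CLOCK:BMAL1 series of :mod:`redoxclocks.goodwin`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .integrate import IntegrationResult, NoiseSpec, SimulationGrid, integrate_sde

__all__ = [
    "OscillatorParams",
    "EnsembleSpec",
    "EnsembleTrajectory",
    "make_ensemble",
    "ensemble_drift",
    "simulate_ensemble",
]

TAU_FLOOR_H = 1.0  # redraw guard for pathological period draws


@dataclass(frozen=True)
class OscillatorParams:
    """Constants of one amplitude-phase oscillator.

    amplitude : limit-cycle radius A (dimensionless signal units)
    lam       : amplitude relaxation rate lambda (h^-1)
    twist     : amplitude-period coupling epsilon (h^-1)
    tau       : intrinsic period (h)
    sigma_x, sigma_y : white-noise intensities on x and y (signal * h^-1/2)
    """

    amplitude: float = 1.0
    lam: float = 0.05
    twist: float = 0.05
    tau: float = 24.23
    sigma_x: float = 0.05
    sigma_y: float = 0.05

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("noise intensities must be >= 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Population description.

    ``n`` oscillators share every constant of the ``shared`` template except
    the intrinsic period, drawn i.i.d. Normal(tau_mean, tau_sd) per
    oscillator (tau_sd = 0 gives an identical population). ``kc`` is the
    mean-field coupling strength, ``k_ttfl`` the TTFL input strength, and
    ``seed`` makes the period draws and every noise stream reproducible.
    """

    n: int = 100
    tau_mean: float = 24.23
    tau_sd: float = 1.5
    shared: OscillatorParams = field(default_factory=OscillatorParams)
    kc: float = 0.0
    k_ttfl: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be an integer >= 1")
        if self.tau_sd < 0:
            raise ValueError("tau_sd must be >= 0")
        if self.kc < 0 or self.k_ttfl < 0:
            raise ValueError("kc and k_ttfl must be >= 0")


@dataclass
class EnsembleTrajectory:
    """Recorded ensemble solution.

    ``x`` and ``y`` have shape (N, T); ``mean_field[t]`` is exactly the
    arithmetic mean of ``x[:, t]``. ``tau`` holds the drawn intrinsic
    periods and ``meta`` the full parameter set of the run.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tau: np.ndarray
    mean_field: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_oscillators(self) -> int:
        return self.x.shape[0]

    def radial(self) -> np.ndarray:
        """Instantaneous amplitude r_i(t) = sqrt(x^2 + y^2), shape (N, T)."""
        return np.hypot(self.x, self.y)


def _seed_children(seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    """Independent sub-seeds for (period draws, noise streams)."""
    draws, noise = np.random.SeedSequence(seed).spawn(2)
    return draws, noise


def make_ensemble(spec: EnsembleSpec, seed: int | None = None) -> list[OscillatorParams]:
    """Draw the N oscillator parameter sets of an ensemble.

    Periods are i.i.d. Normal(tau_mean, tau_sd); draws at or below 1 h are
    redrawn (a guard for pathological specs — at the canonical
    24.23 +/- 1.5 h distribution this essentially never triggers). All other
    constants are copied from the shared template. The draw stream is
    derived from ``spec.seed`` (or the ``seed`` override) and is independent
    of the simulation noise streams, so the same spec always yields the same
    periods.
    """
    draws, _ = _seed_children(spec.seed if seed is None else seed)
    rng = np.random.default_rng(draws)
    taus = np.empty(spec.n)
    for i in range(spec.n):
        t = rng.normal(spec.tau_mean, spec.tau_sd)
        while t <= TAU_FLOOR_H:
            t = rng.normal(spec.tau_mean, spec.tau_sd)
        taus[i] = t
    return [replace(spec.shared, tau=float(t)) for t in taus]


def _param_arrays(params: Sequence[OscillatorParams]):
    A = np.array([p.amplitude for p in params])
    lam = np.array([p.lam for p in params])
    eps = np.array([p.twist for p in params])
    tau = np.array([p.tau for p in params])
    return A, lam, eps, tau


def _drift_core(state, A, lam, eps, tau, kc, force):
    n = state.size // 2
    x = state[:n]
    y = state[n:]
    r = np.hypot(x, y)
    rel = lam * (A - r)
    omega = 2.0 * np.pi / tau + eps * (A - r)
    out = np.empty_like(state)
    np.multiply(x, rel, out=out[:n])
    out[:n] -= y * omega
    out[:n] += kc * x.mean()
    np.multiply(y, rel, out=out[n:])
    out[n:] += x * omega
    out[n:] += force
    return out


def ensemble_drift(
    state: np.ndarray,
    params: Sequence[OscillatorParams],
    kc: float = 0.0,
    k_ttfl: float = 0.0,
    drive_value: float = 0.0,
) -> np.ndarray:
    """Deterministic part of the ensemble vector field at one instant.

    ``state`` is the concatenated vector (x_1..x_N, y_1..y_N). The
    mean-field coupling term Kc * M appears only in the x-equations; the
    TTFL forcing K_TTFL * drive_value only in the y-equations. The drift is
    finite everywhere, including at the origin (where only the *phase* is
    undefined, an analysis-level concern).
    """
    A, lam, eps, tau = _param_arrays(params)
    return _drift_core(
        np.asarray(state, dtype=float), A, lam, eps, tau, kc, k_ttfl * drive_value
    )


def _drive_on_steps(drive, grid: SimulationGrid) -> np.ndarray:
    """Align an external forcing series to the integration step grid."""
    if hasattr(drive, "times") and hasattr(drive, "drive"):
        return np.interp(grid.step_times, drive.times, drive.drive)
    if isinstance(drive, tuple) and len(drive) == 2:
        t, v = drive
        return np.interp(grid.step_times, np.asarray(t, float), np.asarray(v, float))
    arr = np.asarray(drive, dtype=float)
    if arr.ndim != 1 or arr.size != grid.n_steps + 1:
        raise ValueError(
            f"drive series has {arr.size} samples but the grid has "
            f"{grid.n_steps + 1} integration steps; pass (times, values) "
            "to have it interpolated"
        )
    return arr


def simulate_ensemble(
    spec: EnsembleSpec,
    grid: SimulationGrid,
    drive=None,
) -> EnsembleTrajectory:
    """Integrate the coupled ensemble by Euler-Maruyama.

    Every oscillator starts at the common on-cycle point (x, y) = (A, 0);
    with zero noise and a homogeneous population the ensemble then stays on
    the limit cycle regardless of twist. ``drive`` is required when
    ``spec.k_ttfl > 0`` and may be a 1-D array aligned to the integration
    steps, a ``(times, values)`` pair, or any object with ``times`` and
    ``drive`` attributes (e.g. a ``GoodwinTrajectory``); off-grid series are
    linearly interpolated.
    """
    params = make_ensemble(spec)
    A, lam, eps, tau = _param_arrays(params)
    n = spec.n

    if spec.k_ttfl > 0:
        if drive is None:
            raise ValueError("k_ttfl > 0 requires a precomputed drive series")
        drive_steps = _drive_on_steps(drive, grid)
    elif drive is not None:
        drive_steps = _drive_on_steps(drive, grid)
    else:
        drive_steps = None

    kf = spec.k_ttfl
    kc = spec.kc
    dt = grid.dt

    if drive_steps is None:

        def drift(t: float, s: np.ndarray) -> np.ndarray:
            return _drift_core(s, A, lam, eps, tau, kc, 0.0)

    else:

        def drift(t: float, s: np.ndarray) -> np.ndarray:
            k = int(t / dt + 0.5)
            return _drift_core(s, A, lam, eps, tau, kc, kf * drive_steps[k])

    _, noise_seq = _seed_children(spec.seed)
    noise = NoiseSpec(
        sigma_per_coordinate=np.r_[
            np.full(n, spec.shared.sigma_x), np.full(n, spec.shared.sigma_y)
        ],
        seed=int(noise_seq.generate_state(1)[0] & 0x7FFFFFFF),
        stream_groups=tuple((i, n + i) for i in range(n)),
    )
    state0 = np.r_[A, np.zeros(n)]
    res: IntegrationResult = integrate_sde(drift, noise, state0, grid)

    x = res.states[:, :n].T.copy()
    y = res.states[:, n:].T.copy()
    meta = {
        "n_oscillators": n,
        "tau_mean_h": spec.tau_mean,
        "tau_sd_h": spec.tau_sd,
        "amplitude": spec.shared.amplitude,
        "lambda_per_h": spec.shared.lam,
        "twist_per_h": spec.shared.twist,
        "sigma_x": spec.shared.sigma_x,
        "sigma_y": spec.shared.sigma_y,
        "kc": kc,
        "k_ttfl": kf,
        "seed": spec.seed,
        "dt_h": grid.dt,
        "t_end_h": grid.t_end,
        "transient_h": grid.transient,
        "record_stride": grid.record_stride,
        "solver": "euler-maruyama",
    }
    return EnsembleTrajectory(
        times=res.times,
        x=x,
        y=y,
        tau=tau,
        mean_field=x.mean(axis=0),
        meta=meta,
    )
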