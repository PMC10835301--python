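"""Fixed-step stochastic (Euler-Maruyama) and deterministic reference integrators.

The Euler-Maruyama scheme advances a state vector ``s`` by

    s <- s + f(t, s) * dt + sigma * sqrt(dt) * xi

with ``xi`` an independent standard normal draw per coordinate and per step.
Noise streams are seeded explicitly and, when a stream partition is given,
each group of coordinates draws from its own child generator so that adding
oscillators to an ensemble never changes the noise seen by existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SimulationGrid",
    "NoiseSpec",
    "IntegrationResult",
    "integrate_sde",
    "integrate_ode",
]

_NOISE_CHUNK = 8192  # steps of pre-drawn noise held in memory at once


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid for a simulation.

    Parameters
    ----------
    dt : float
        Integration step (hours).
    t_end : float
        Total simulated time (hours).
    transient : float
        Initial span (hours) that downstream analyses discard. The
        integrators themselves record it; trimming is an analysis concern.
    record_stride : int
        Store every ``record_stride``-th step (step 0 is always stored).
        The default keeps one sample per 0.1 h at the canonical dt = 0.01 h,
        bounding memory for 100-day ensemble runs.
    """

    dt: float = 0.01
    t_end: float = 2400.0
    transient: float = 480.0
    record_stride: int = 10

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.t_end > self.transient >= 0:
            raise ValueError(
                f"need t_end > transient >= 0, got t_end={self.t_end}, "
                f"transient={self.transient}"
            )
        if int(self.record_stride) != self.record_stride or self.record_stride < 1:
            raise ValueError(f"record_stride must be an integer >= 1")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)

    @property
    def recorded_times(self) -> np.ndarray:
        """Time stamps of recorded samples: exactly k * record_stride * dt."""
        n_rec = self.n_steps // self.record_stride
        return np.arange(n_rec + 1) * (self.record_stride * self.dt)

    @property
    def step_times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian white-noise description for :func:`integrate_sde`.

    ``sigma_per_coordinate`` holds the noise intensity of each state
    coordinate in units of signal * h^-1/2 (a scalar broadcasts to all
    coordinates). ``stream_groups``, when given, partitions coordinate
    indices into independently seeded sub-streams (one child generator per
    group, spawned from ``seed``); by default a single stream covers the
    whole state.
    """

    sigma_per_coordinate: Sequence[float] | float
    seed: int = 0
    stream_groups: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma_per_coordinate, dtype=float) < 0):
            raise ValueError("noise standard deviations must be >= 0")

    def sigmas(self, dim: int) -> np.ndarray:
        sig = np.broadcast_to(
            np.asarray(self.sigma_per_coordinate, dtype=float), (dim,)
        )
        return np.array(sig)

    def generators(self, dim: int) -> list[tuple[np.ndarray, np.random.Generator]]:
        groups = self.stream_groups
        if groups is None:
            groups = (tuple(range(dim)),)
        seqs = np.random.SeedSequence(self.seed).spawn(len(groups))
        return [
            (np.asarray(g, dtype=np.intp), np.random.default_rng(s))
            for g, s in zip(groups, seqs)
        ]


@dataclass
class IntegrationResult:
    """Recorded solution: ``states[k]`` is the state at ``times[k]``."""

    times: np.ndarray
    states: np.ndarray  # shape (n_recorded, dim)

    def column(self, j: int) -> np.ndarray:
        return self.states[:, j]


def integrate_sde(
    drift: Callable[[float, np.ndarray], np.ndarray],
    noise: NoiseSpec,
    state0: Sequence[float],
    grid: SimulationGrid,
) -> IntegrationResult:
    """Integrate ``ds = drift(t, s) dt + sigma dW`` by Euler-Maruyama.

    The same ``NoiseSpec`` (same seed, same stream partition) yields a
    bit-identical noise stream and therefore bit-identical output.

    Raises
    ------
    FloatingPointError
        If a non-finite state is produced; the message reports the recorded
        step index at which the divergence was detected.
    """
    state = np.array(state0, dtype=float)
    dim = state.size
    dt = grid.dt
    stride = grid.record_stride
    n_steps = grid.n_steps
    sq = noise.sigmas(dim) * math.sqrt(dt)
    gens = noise.generators(dim)

    n_rec = n_steps // stride
    out = np.empty((n_rec + 1, dim))
    out[0] = state
    buf = np.empty((dim, _NOISE_CHUNK))

    k = 0
    while k < n_steps:
        span = min(_NOISE_CHUNK, n_steps - k)
        for idx, gen in gens:
            buf[idx, :span] = gen.standard_normal((idx.size, span))
        for j in range(span):
            step = k + j
            state = state + drift(step * dt, state) * dt + sq * buf[:, j]
            nxt = step + 1
            if nxt % stride == 0:
                rec = nxt // stride
                out[rec] = state
                # cheap non-finite guard: the sum is non-finite iff any
                # element is (inf - inf yields nan, never a finite value)
                if not math.isfinite(float(state.sum())):
                    raise FloatingPointError(
                        f"non-finite state at integration step {nxt} "
                        f"(t = {nxt * dt:.4g} h)"
                    )
        k += span

    return IntegrationResult(times=grid.recorded_times, states=out)


def integrate_ode(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    state0: Sequence[float],
    grid: SimulationGrid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> IntegrationResult:
    """Deterministic reference solution on the same recorded grid.

    Adaptive integration (scipy ``solve_ivp``) evaluated at the grid's
    recorded times; serves as the oracle for :func:`integrate_sde` with all
    sigmas set to zero.
    """
    times = grid.recorded_times
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        np.asarray(state0, dtype=float),
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method=method,
    )
    if not sol.success:
        raise FloatingPointError(f"ODE integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise FloatingPointError("non-finite state in ODE solution")
    return IntegrationResult(times=times, states=sol.y.T.copy())
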