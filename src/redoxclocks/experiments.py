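"""Reproducible multi-run experiments: desynchronization, coupling sweeps,
TTFL entrainment sweeps and the minimum-input-for-entrainment curve.

Every cell of every sweep gets its own child seed spawned from the base
spec's seed, so any cell can be re-run in isolation from the recorded
manifest. Entrainment of the mean field to the TTFL is decided spectrally:
the dominant periodogram peak must sit within a tolerance of the forcing
period and no comparable secondary peak may lie outside it (which rejects
the "beating" states where ensemble and TTFL frequencies coexist).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ensemble import EnsembleSpec, simulate_ensemble
from .integrate import SimulationGrid
from .metrics import (
    DispersionCurve,
    bootstrap_lowess,
    periodogram_dominant_period,
    phase_dispersion_timecourse,
    sync_metrics,
)

__all__ = [
    "SweepResult",
    "EntrainmentResult",
    "run_desynchronization",
    "run_coupling_sweep",
    "entrainment_test",
    "run_ttfl_sweep",
    "max_entrained_coupling",
    "min_ttfl_for_entrainment",
]

logger = logging.getLogger(__name__)

TTFL_PERIOD_H = 23.6  # free-running period of the default Goodwin TTFL


def _cell_seeds(base_seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds for sweep cells/realizations."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


# ---------------------------------------------------------------------------
# desynchronization (uncoupled ensembles)


def run_desynchronization(
    spec: EnsembleSpec,
    grid: SimulationGrid,
    n_realizations: int = 50,
) -> dict[str, DispersionCurve]:
    """Phase-dispersion curves for identical vs period-heterogeneous ensembles.

    Runs ``n_realizations`` uncoupled ensembles twice — once with tau_sd
    forced to 0 ("identical") and once with the spec's own tau_sd
    ("heterogeneous") — and returns the realization-averaged circular-std
    curve and fitted growth exponent for each condition.
    """
    if spec.kc != 0 or spec.k_ttfl != 0:
        raise ValueError("desynchronization protocol requires kc = k_ttfl = 0")
    seeds = _cell_seeds(spec.seed, 2 * n_realizations)
    out: dict[str, DispersionCurve] = {}
    for cond, (label, tau_sd) in enumerate(
        [("identical", 0.0), ("heterogeneous", spec.tau_sd)]
    ):
        trajs = []
        for r in range(n_realizations):
            s = replace(spec, tau_sd=tau_sd, seed=seeds[cond * n_realizations + r])
            trajs.append(simulate_ensemble(s, grid))
            logger.info("desync %s realization %d/%d done", label, r + 1, n_realizations)
        out[label] = phase_dispersion_timecourse(trajs)
    return out


# ---------------------------------------------------------------------------
# coupling sweep (Kc, no TTFL)


@dataclass
class SweepResult:
    """One row of ``cells`` per (grid value, realization).

    ``periods`` maps (grid value, realization index) to the per-oscillator
    period array of that run — the raw material of period histograms.
    ``r0_smooth`` / ``amplitude_smooth`` are bootstrap-lowess summaries of
    the scatter (None when there are too few points to smooth).
    """

    grid_name: str
    cells: pd.DataFrame
    periods: dict = field(default_factory=dict)
    r0_smooth: object = None
    amplitude_smooth: object = None
    n_realizations: int = 0


def run_coupling_sweep(
    kc_grid,
    spec: EnsembleSpec,
    grid: SimulationGrid,
    n_realizations: int = 5,
) -> SweepResult:
    """Sweep the mean-field coupling strength with seeded realizations.

    Per cell: time-averaged order parameter R0, per-oscillator
    zero-crossing periods (mean, sd and the full histogram material),
    mean-field dominant period and mean-field amplitude (half
    peak-to-trough over the last 8 cycles).
    """
    if spec.k_ttfl != 0:
        raise ValueError("coupling sweep runs without TTFL input")
    kc_grid = np.asarray(kc_grid, dtype=float)
    seeds = _cell_seeds(spec.seed, kc_grid.size * n_realizations)
    rows = []
    periods: dict = {}
    for i, kc in enumerate(kc_grid):
        for r in range(n_realizations):
            seed = seeds[i * n_realizations + r]
            traj = simulate_ensemble(replace(spec, kc=float(kc), seed=seed), grid)
            m = sync_metrics(traj, transient=grid.transient)
            periods[(float(kc), r)] = m.period_per_oscillator
            rows.append(
                {
                    "kc": float(kc),
                    "realization": r,
                    "seed": seed,
                    "r0_mean": m.r0_mean,
                    "mean_field_period": m.mean_field_period,
                    "mean_field_amplitude": m.mean_field_amplitude,
                    "period_mean": float(np.nanmean(m.period_per_oscillator)),
                    "period_sd": float(np.nanstd(m.period_per_oscillator, ddof=1)),
                }
            )
            logger.info("sweep kc=%.3g realization %d/%d done", kc, r + 1, n_realizations)
    cells = pd.DataFrame(rows)
    r0_smooth = amp_smooth = None
    if len(cells) >= 10:
        r0_smooth = bootstrap_lowess(cells["kc"], cells["r0_mean"], seed=spec.seed)
        amp_smooth = bootstrap_lowess(
            cells["kc"], cells["mean_field_amplitude"], seed=spec.seed
        )
    return SweepResult(
        grid_name="kc",
        cells=cells,
        periods=periods,
        r0_smooth=r0_smooth,
        amplitude_smooth=amp_smooth,
        n_realizations=n_realizations,
    )


# ---------------------------------------------------------------------------
# entrainment


@dataclass
class EntrainmentResult:
    entrained: bool
    period: float
    reason: str
    peaks: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.entrained


def entrainment_test(
    mean_field,
    times,
    target_period: float = TTFL_PERIOD_H,
    tol: float = 0.3,
    transient: float = 0.0,
    secondary_threshold: float = 0.5,
) -> EntrainmentResult:
    """Spectral test: has the mean field adopted the forcing period?

    Entrained iff the dominant periodogram period lies within ``tol`` hours
    of ``target_period`` *and* no secondary peak at or above
    ``secondary_threshold`` of the maximal power lies outside that band —
    the latter rejects beating states where the free-running ensemble
    frequency survives alongside the forcing.
    """
    pg = periodogram_dominant_period(mean_field, times, transient=transient)
    if pg.arrhythmic:
        return EntrainmentResult(False, pg.period, "arrhythmic spectrum", pg.peaks)
    if abs(pg.period - target_period) > tol:
        return EntrainmentResult(
            False,
            pg.period,
            f"dominant period {pg.period:.2f} h outside "
            f"{target_period} +/- {tol} h",
            pg.peaks,
        )
    off_target = [
        (p, h)
        for p, h in pg.peaks
        if h >= secondary_threshold and abs(p - target_period) > tol
    ]
    if off_target:
        return EntrainmentResult(
            False,
            pg.period,
            f"beating: secondary peak at {off_target[0][0]:.2f} h "
            f"({off_target[0][1]:.0%} of max)",
            pg.peaks,
        )
    return EntrainmentResult(True, pg.period, "entrained", pg.peaks)


def _entrainment_cells(
    param_name: str,
    values,
    spec: EnsembleSpec,
    grid: SimulationGrid,
    drive,
    n_realizations: int,
    tol: float,
    target_period: float,
) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    seeds = _cell_seeds(spec.seed, values.size * n_realizations)
    rows = []
    for i, v in enumerate(values):
        for r in range(n_realizations):
            seed = seeds[i * n_realizations + r]
            s = replace(spec, **{param_name: float(v)}, seed=seed)
            traj = simulate_ensemble(s, grid, drive=drive)
            res = entrainment_test(
                traj.mean_field,
                traj.times,
                target_period=target_period,
                tol=tol,
                transient=grid.transient,
            )
            rows.append(
                {
                    param_name: float(v),
                    "realization": r,
                    "seed": seed,
                    "mean_field_period": res.period,
                    "entrained": res.entrained,
                    "reason": res.reason,
                }
            )
            logger.info(
                "entrainment %s=%.3g realization %d/%d: %s",
                param_name, v, r + 1, n_realizations, res.reason,
            )
    return pd.DataFrame(rows)


def run_ttfl_sweep(
    kttfl_grid,
    spec: EnsembleSpec,
    grid: SimulationGrid,
    drive,
    n_realizations: int = 3,
    tol: float = 0.3,
    target_period: float = TTFL_PERIOD_H,
) -> SweepResult:
    """Sweep the TTFL input strength at fixed coupling ``spec.kc``.

    Per cell: mean-field dominant period and the entrainment flag (majority
    vote material lives in the per-realization rows).
    """
    cells = _entrainment_cells(
        "k_ttfl", kttfl_grid, spec, grid, drive, n_realizations, tol, target_period
    )
    return SweepResult(grid_name="k_ttfl", cells=cells, n_realizations=n_realizations)


def max_entrained_coupling(
    kc_grid,
    spec: EnsembleSpec,
    grid: SimulationGrid,
    drive,
    n_realizations: int = 3,
    tol: float = 0.3,
    target_period: float = TTFL_PERIOD_H,
) -> tuple[float, SweepResult]:
    """Largest Kc on the grid still entrained at the spec's K_TTFL.

    A Kc cell counts as entrained when the majority of its realizations
    pass :func:`entrainment_test`. Returns NaN when no cell entrains.
    """
    cells = _entrainment_cells(
        "kc", kc_grid, spec, grid, drive, n_realizations, tol, target_period
    )
    vote = cells.groupby("kc")["entrained"].mean() >= 0.5
    entrained_kcs = vote[vote].index
    largest = float(entrained_kcs.max()) if len(entrained_kcs) else float("nan")
    return largest, SweepResult(
        grid_name="kc", cells=cells, n_realizations=n_realizations
    )


def min_ttfl_for_entrainment(
    kc_grid,
    kttfl_grid,
    spec: EnsembleSpec,
    grid: SimulationGrid,
    drive,
    n_realizations: int = 3,
    tol: float = 0.3,
    target_period: float = TTFL_PERIOD_H,
) -> pd.DataFrame:
    """Minimal entraining TTFL input per coupling strength (onset curve).

    For each Kc, ascends the K_TTFL search grid until a cell passes the
    majority-vote entrainment test; Kc values that never entrain within
    the grid are recorded as censored (NaN minimum), not as errors.
    Returns a frame with columns kc, min_kttfl, censored.
    """
    kc_grid = np.asarray(kc_grid, dtype=float)
    kttfl_grid = np.sort(np.asarray(kttfl_grid, dtype=float))
    seeds = _cell_seeds(spec.seed, kc_grid.size * kttfl_grid.size * n_realizations)
    rows = []
    si = 0
    for kc in kc_grid:
        found = np.nan
        for kttfl in kttfl_grid:
            votes = 0
            for r in range(n_realizations):
                s = replace(spec, kc=float(kc), k_ttfl=float(kttfl), seed=seeds[si])
                si += 1
                traj = simulate_ensemble(s, grid, drive=drive)
                votes += entrainment_test(
                    traj.mean_field,
                    traj.times,
                    target_period=target_period,
                    tol=tol,
                    transient=grid.transient,
                ).entrained
            logger.info(
                "arnold kc=%.3g kttfl=%.3g votes=%d/%d", kc, kttfl, votes, n_realizations
            )
            if votes / n_realizations >= 0.5:
                found = float(kttfl)
                break
        rows.append({"kc": float(kc), "min_kttfl": found, "censored": np.isnan(found)})
    return pd.DataFrame(rows)
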