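"""Simulate a small heterogeneous ensemble of noisy redox oscillators.

Builds 20 uncoupled stochastic amplitude-phase oscillators with periods
drawn from Normal(24.23, 1.5) h, integrates 30 days by Euler-Maruyama and
prints how far the population has desynchronized.
"""

import numpy as np

import redoxclocks as rc

spec = rc.EnsembleSpec(n=20, kc=0.0, seed=1)
grid = rc.SimulationGrid(dt=0.01, t_end=720.0, transient=120.0)
traj = rc.simulate_ensemble(spec, grid)

m = rc.sync_metrics(traj)
print(f"drawn intrinsic periods : {traj.tau.mean():.2f} +/- {traj.tau.std(ddof=1):.2f} h")
print(f"measured periods (x zero crossings): "
      f"{np.nanmean(m.period_per_oscillator):.2f} +/- "
      f"{np.nanstd(m.period_per_oscillator, ddof=1):.2f} h")
print(f"order parameter R0, averaged over the last cycles: {m.r0_mean:.3f}")
print()
print("Without coupling the noisy, heterogeneous clocks drift apart: the")
print("measured period spread tracks the drawn distribution and R0 falls")
print("well below 1 (1 = perfect phase synchrony, 0 = incoherence).")
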