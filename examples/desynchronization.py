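"""Desynchronization of identical vs period-heterogeneous ensembles.

Repeats a 20-day simulation of 30 uncoupled noisy oscillators a few times,
measures the circular standard deviation of their phases over time, and
compares how fast the two population types lose phase order.
"""

import numpy as np

import redoxclocks as rc

spec = rc.EnsembleSpec(n=30, kc=0.0, seed=7)
grid = rc.SimulationGrid(dt=0.02, t_end=480.0, transient=0.0)
curves = rc.run_desynchronization(spec, grid, n_realizations=3)

for label, c in curves.items():
    idx = np.where(c.mean_curve >= 1.0)[0]
    t1 = c.times[idx[0]] if idx.size else float("inf")
    print(f"{label:14s}: dispersion reaches 1 rad at t = {t1:6.1f} h, "
          f"growth exponent {c.exponent:.2f}")

print()
print("Heterogeneous periods (sd 1.5 h) desynchronize the population much")
print("faster than noise alone; an exponent near 0.5 would be pure Fickian")
print("phase diffusion, and the default plastic oscillators exceed it.")
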