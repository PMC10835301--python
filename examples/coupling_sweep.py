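"""Mean-field coupling sweep: synchrony and amplitude grow with Kc.

Sweeps the coupling strength of a reduced ensemble (30 oscillators,
50 days) and prints the order parameter, the mean-field amplitude and the
collective period per coupling value.
"""

import redoxclocks as rc

spec = rc.EnsembleSpec(n=30, seed=11)
grid = rc.SimulationGrid(dt=0.02, t_end=1200.0, transient=240.0)
res = rc.run_coupling_sweep([0.0, 0.05, 0.10, 0.15], spec, grid, n_realizations=2)

summary = res.cells.groupby("kc")[
    ["r0_mean", "mean_field_amplitude", "mean_field_period"]
].mean()
print(summary.round(3).to_string())
print()
print("Coupling through the shared H2O2 mean field synchronizes the")
print("population (R0 up) and expands the collective amplitude; the")
print("positive twist turns that amplitude expansion into a slower")
print("collective period.")
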