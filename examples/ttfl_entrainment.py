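"""TTFL forcing of a weakly coupled redox ensemble: entrainment test.

Runs a reduced weakly coupled ensemble (Kc = 0.05) with and without the
Goodwin CLOCK:BMAL1 drive and checks which collective period the mean
field adopts.
"""

import redoxclocks as rc

grid = rc.SimulationGrid(dt=0.02, t_end=1200.0, transient=240.0)
goodwin = rc.simulate_goodwin(grid=grid)
print(f"TTFL period: {goodwin.period:.2f} h")

for k_ttfl in (0.0, 0.25):
    spec = rc.EnsembleSpec(n=30, kc=0.05, k_ttfl=k_ttfl, seed=23)
    traj = rc.simulate_ensemble(spec, grid, drive=goodwin if k_ttfl else None)
    res = rc.entrainment_test(traj.mean_field, traj.times,
                              transient=grid.transient)
    print(f"K_TTFL = {k_ttfl:4.2f}: mean-field period {res.period:5.2f} h, "
          f"{'entrained' if res.entrained else 'not entrained'} ({res.reason})")

print()
print("Without the TTFL the weakly coupled ensemble free-runs slow (~26 h,")
print("twist-lengthened); a strong enough TTFL input imposes its own")
print("~23.6 h period on the whole network.")
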