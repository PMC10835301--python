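"""Recover oscillator constants from simulated observables.

1. amplitude relaxation rate lambda, from the exponential decay of pulse
   perturbations applied at random phases;
2. twist, from the period-amplitude correlation of a population varied in
   amplitude, plus the first-order phase-shift formula that links both.
"""

import numpy as np

import redoxclocks as rc

params = rc.OscillatorParams()  # lambda = 0.05/h, twist = 0.05/h

est = rc.estimate_relaxation_rate(params, delta0=-0.3, n_perturbations=25, seed=1)
print(f"lambda recovery: {est.lam:.4f} +/- {est.sd:.4f} /h "
      f"(true 0.05, {est.n_used} runs used)")

# synthetic period-amplitude scatter with the model's own twist slope
rng = np.random.default_rng(2)
amp = rng.uniform(0.9, 1.1, 40)
per = 24.23 + params.twist * (amp - 1.0) * 24.23**2 / (2 * np.pi) \
    + rng.normal(0, 0.05, 40)
fit = rc.estimate_twist(amp, per)
print(f"twist regression: slope {fit.slope:+.2f} h per amplitude unit, "
      f"r = {fit.correlation:+.2f} (p = {fit.pvalue:.1e})")

shift = rc.predicted_twist_phase_shift(params, delta0=-0.2)
print(f"predicted phase shift for a -0.2 radial kick: {shift:+.2f} rad")
print()
print("The pulse protocol recovers lambda to a few percent; the regression")
print("slope classifies the twist sign; and the -twist*delta0/(lambda*A)")
print("formula predicts how amplitude kicks advance or delay the clock.")
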