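# Methods

## The oscillator model and its assumptions

A single redox clock is reduced to a planar amplitude-phase (Poincaré)
oscillator: a circular limit cycle of radius `A` (dimensionless, default 1)
that attracts radial perturbations at rate `lam * A` (`lam`, default
0.05 h⁻¹) and rotates at angular velocity `2π/tau + twist * (A − r)`. The
twist term (default 0.05 h⁻¹) encodes the empirical period-amplitude
correlation of redox oscillations: above-cycle amplitudes run slow,
below-cycle amplitudes run fast. Gaussian white noise of intensity
`sigma_x = sigma_y = 0.05` (signal · h^−1/2) enters both Cartesian
velocities, modelling intrinsic molecular noise. The model is
phenomenological — it abstracts away the underlying peroxiredoxin/
sulfiredoxin kinetics and keeps only amplitude, phase, rigidity, twist and
noise as interpretable knobs.

A population of `N` such units (default 100, roughly a cell's mitochondrial
count scale) is heterogeneous **only** in its intrinsic periods,
`tau_i ~ Normal(24.23 h, 1.5 h)` (draws ≤ 1 h are redrawn as a guard;
at the default distribution this is a ~10⁻⁵³ event). All-to-all coupling
acts through the mean field `M(t) = mean_i x_i(t)` — the biological picture
is cytosolic H₂O₂ diffusing fast relative to the circadian timescale — and
enters each `x`-equation as `Kc * M`. TTFL forcing enters each
`y`-equation as `K_TTFL * (CB/⟨CB⟩ − 1)`, treating the Goodwin model as an
exogenous, one-way drive (no redox→TTFL feedback). The asymmetry —
coupling in `x` only, forcing in `y` only — is part of the model
definition and is implemented exactly as stated.

Every oscillator starts at the common on-cycle point `(A, 0)`. Any common
on-cycle point is equivalent up to a global rotation, so nothing depends
on this choice.

## The Goodwin TTFL model

Three variables (CLOCK:BMAL1 `CB`, cytoplasmic and nuclear PER:CRY `PCc`,
`PCn`) close a negative-feedback loop with a Hill-4 repression and
Michaelis-Menten degradation; all rate constants default to the standard
set (v1 = v3 = v5 = 0.7, v2 = v4 = v6 = 0.35, all K = 1, h = 4). At these
values the limit cycle is globally attracting, free-runs at ≈ 23.6 h, and
its cycle-averaged `CB` is ≈ 0.123. Initial conditions (default
(0.1, 0.1, 0.1)) only shape the discarded transient. The normalization
mean is always **computed** over an integer number of detected cycles
after the transient — never hard-coded — and a warning fires if it strays
more than 5% from the reference value of the default parameter set.

## Numerical integration

Stochastic runs use fixed-step Euler–Maruyama:
`s ← s + f(s) dt + sigma √dt ξ`, default `dt = 0.01 h` over 100 days with
a 20-day transient, recording every 10th step (0.1 h). Each oscillator
owns an independently spawned child RNG stream, so enlarging `N` never
changes the noise of existing oscillators, and a seed fully determines a
run bit-for-bit. Non-finite states abort with the offending step index
(checked at recording points). Deterministic references (Goodwin model,
perturbation protocols, σ = 0 oracles) use adaptive LSODA at relative
tolerance 1e-8 (1e-10 for the relaxation-rate protocol, whose envelope
spans many decades).

Known discretization bias: explicit EM inflates the radius by
`≈ ω² dt / (2 lam)` (0.007 at the defaults), which through the twist
shifts noiseless periods by ≈ +0.03 h. This is inherent to the scheme at
the canonical `dt` and is below every tolerance used; tests that probe
twist-sensitive quantities at high twist use a finer step or the adaptive
solver on both arms of a comparison.

## Rhythm analysis conventions

* **Phase/amplitude**: `phi = atan2(y, x)` wrapped to (−π, π],
  `r = √(x²+y²)`; the phase is undefined at the origin and such samples
  are excluded from circular statistics with a logged count. Unwrapped
  phases are used only for dispersion/diffusion analyses.
* **Zero-crossing period**: mean interval between negative-slope zeros of
  the mean-removed signal, located by linear interpolation. A
  Schmitt-trigger re-arm rule (the signal must rise above 0.25 sd of the
  detrended series before the next downward crossing counts) suppresses
  the spurious crossing pairs that white noise creates near zeros; without
  it, raw EM samples bias per-oscillator periods low by ~1 h. Smooth
  signals are unaffected.
* **Periodogram**: FFT of the mean-removed, transient-trimmed series,
  zero-padded ≥ 4× to a power of two, restricted to periods between 4
  sample intervals and one fifth of the span, with parabolic interpolation
  of the peak. All local maxima above 20% of the global maximum are
  reported, which is how beating (coexisting frequencies) is detected. A
  spectrum whose maximum is below 20× its band median is flagged
  arrhythmic (a featureless spectrum's max/median ratio stays near ~12).
* **Order parameter / circular std**: standard Kuramoto modulus of the
  mean phasor (the defining formula is implemented as the modulus, which
  is what makes statements like "R0 < 1 despite period locking"
  meaningful) and `√(−2 ln R̄)`, matching `scipy.stats.circstd`;
  `R̄ = 0` reports +∞ with a warning. Hours-rescaling uses 24 h per 2π.
* **Dispersion growth law**: per realization, circular std across the
  ensemble at each time; curves averaged across realizations; the
  power-law exponent is a log-log fit from t = 12 h until the mean curve
  first exceeds 1.5 rad (beyond which the circular std saturates toward
  its uniform plateau and no growth law exists).
* **Mean-field amplitude**: half peak-to-trough per cycle, averaged over
  the last 8 cycles (offset-invariant by construction); fewer cycles are
  used with a warning.
* **Summary window**: sweep metrics (time-averaged R0, amplitude) use the
  last 8 mean-field cycles; mean-field periods use the full post-transient
  record.
* **Bootstrap-lowess**: 100 lowess fits (span 0.4) to random 50%
  subsamples without replacement, evaluated on a common grid; pointwise
  mean and 2.5–97.5% band. The span is a package choice; the bootstrap
  protocol is fixed.

## Entrainment criterion

The mean field counts as entrained to the TTFL when its dominant
periodogram period lies within 0.3 h of 23.6 h **and** no secondary peak
≥ 50% of the maximum lies outside that band. The 0.3 h tolerance exceeds
the ~0.24 h spectral resolution of an 80-day analysis window near 24 h;
the secondary-peak rule rejects beating states. Sweep cells are decided by
majority vote over 3 independently seeded realizations. In the
minimum-input curve, couplings that never entrain within the search grid
are reported as censored rather than as errors.

## Parameter-estimation protocols

* **Relaxation rate**: the on-cycle oscillator is kicked radially by
  `delta0` at a uniformly random phase and integrated deterministically;
  the envelope `|r − A|` is sampled at the kick instant and at subsequent
  cycle maxima of `x`, points below 1e-8·A (solver accuracy floor) are
  dropped, and the log-envelope slope is fitted and divided by `A`
  (the linearized decay rate is `lam * A`). Including the kick instant is
  what keeps the protocol workable for rigid oscillators (`lam = 1 h⁻¹`),
  whose envelope sinks below the floor within a single cycle; runs left
  with fewer than two usable points, or with a non-decaying envelope, are
  excluded with a warning. The residual bias of the estimator is the
  logistic (second-order) correction to exponential decay and shrinks
  with `|delta0|`.
* **Twist**: least-squares regression of period on amplitude; the slope's
  sign classifies the twist. Mapping the slope back to the twist
  parameter depends on how amplitudes were varied and is left to the
  caller.
* **Phase-shift oracle**: to first order, a radial kick `delta0` produces
  an asymptotic phase shift `−twist · delta0 / (lam · A)` (integrate the
  twist term along the exponential relaxation). Simulations agree within
  ~15% at `|delta0| = 0.2`.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions themselves (parameter
values, ensemble sizes, noise, grids); it is not fitted to experimental
recordings. Passing tests therefore demonstrate internal consistency of
the model and analysis chain — emergent period lengthening under coupling,
rigidity-dependent phase diffusion, entrainment windows — not agreement
with any particular wet-lab dataset. Real redox rhythms add features the
model omits by design: amplitude heterogeneity, non-Gaussian and
correlated noise, spatial structure of mitochondria, and bidirectional
TTFL-redox feedback.

## Problem sizes and reproducibility choices

Full-scale experiments (acceptance script, ensemble-level tests) use the
canonical N = 100, 100 days, dt = 0.01 h. Multi-realization analyses are
sized for a desk run as a package choice: 5 realizations per coupling-sweep
cell, 3 per entrainment cell with majority voting, 16 realizations for
dispersion-exponent measurements, and reduced ensembles (20–30 oscillators,
20–50 days) in the qualitative experiment tests and examples, whose
assertions are orderings that are robust at that scale. All sweeps spawn
one child seed per cell from the base seed, so any cell is reproducible in
isolation from its manifest.

## Known limitations

* Explicit EM radius bias at coarse `dt` (quantified above).
* Periodogram peaks of stochastic mean fields carry finite-record
  variability; entrainment near the transition can flip between
  realizations, which the majority vote absorbs but does not eliminate.
* The dispersion exponent depends on the fitted window; the chosen window
  (12 h to 1.5 rad) excludes the saturation plateau but retains the
  early-time transient for strongly plastic ensembles.
* Only period heterogeneity is supported within an ensemble; `lam`,
  `twist` and `sigma` are population-wide constants by design.
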