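# Methods

This note records the model, the numerical choices, and the assumptions
behind `pacesim`. It is the place to look when a default looks arbitrary
or a result needs to be traced back to a modelling decision.

## 1. Model

### 1.1 Membrane equation

A single pacemaker cell is modelled as one isopotential compartment with
four currents — leak, calcium, sodium, potassium:

    C dv/dt = -( I_Leak + I_Ca + I_Na + I_K )

    I_Leak = G_Leak (v - E_Leak)
    I_Ca   = G_Ca  b^2 g^2 (v - E_Ca)
    I_Na   = G_Na  m   h   (v - E_Na)
    I_K    = G_K   n^2 q^2 (v - E_K)

The membrane capacitance is fixed at C = 1 and absorbed into the
conductances, which therefore carry units of ms⁻¹ (conductance density
per capacitance density). Voltages are in mV, time in ms.

Each current has one activation gate (`b`, `m`, `n`) and one
inactivation gate (`g`, `h`, `q`). Activation gates have positive
steady-state slope, inactivation gates negative; `ModelParams`
validation enforces the sign convention and gate bounds.

### 1.2 Gate kinetics

Every gate `x` relaxes first-order toward a Boltzmann steady state with a
Gaussian voltage-dependent time constant:

    dx/dt   = (x_inf(v) - x) / tau_x(v)
    x_inf   = 1 / (1 + exp((v_half - v) / k))
    tau_x   = tau_base + tau_amp * exp(-((v - tau_vmid) / tau_width)^2)

`k > 0` gives an activation gate, `k < 0` an inactivation gate.
`tau_base > 0` keeps every time constant strictly positive. The full
parameter vector has 44 scalars: 8 conductances/reversals plus 6 gates x
6 kinetic constants.

### 1.3 Jacobian

The 7x7 Jacobian is coded analytically (`pacesim.model.jacobian`), using

    d x_inf / dv = x_inf (1 - x_inf) / k
    d tau / dv   = tau_amp * exp(-u^2) * (-2u / tau_width),  u = (v - tau_vmid)/tau_width

and is verified against central finite differences in the test suite.
The analytic form matters twice: it makes stiff integration with LSODA
cheap, and it makes eigenvalue-based bifurcation detection exact rather
than dependent on differencing step choices.

## 2. Canonical parameter set

The package ships one canonical parameter set
(`pacesim/data/canonical_params.json`, loaded by
`pacesim.synth.canonical_params`). It was constructed by choosing
physiologically shaped gate curves (fast Na activation, slower K
kinetics, small slow Ca current) and then polishing seven scalars
(G_Na, G_K, G_Leak, two kinetic scale factors and two half-voltage
offsets) with a Nelder–Mead search (`scripts/make_canonical.py`) against
four qualitative targets typical of the *Apteronotus* pacemaker
literature:

- control firing near 380 Hz at E_Na = 58 mV (the Nernst value for
  148 mM external / 15 mM internal sodium at 22 °C),
- spike peak-to-peak amplitude near 25 mV,
- loss of oscillation (Hopf bifurcation) near E_Na = -12.8 mV,
- onset frequency near 260 Hz at the bifurcation.

The shipped set realizes control 391.5 Hz, amplitude 25.8 mV, Hopf at
-12.26 mV, onset 248.7 Hz, supercritical, with G_Ca/G_Na ≈ 0.05 so that
full calcium block leaves the oscillation intact. The fixture is a
*plausible instance*, not a fit to any particular recorded cell.

## 3. Simulation and feature extraction

- **Integrator.** `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
  atol 1e-10, analytic Jacobian, dense output sampled on a uniform grid
  (default dt = 0.01 ms, i.e. 100 kHz). Tests confirm convergence under
  dt halving and agreement with a closed-form leak-only solution.
- **Spikes.** Local maxima above the min/max midpoint
  (`scipy.signal.find_peaks`); frequency is 1000 / mean inter-peak
  interval (ms → Hz). Rest is encoded as frequency 0.
- **Sustained-oscillation screen.** Near a Hopf bifurcation, transients
  ring for hundreds of milliseconds while decaying (critical slowing
  down) and would be miscounted as limit cycles. `sustained_features`
  splits the post-transient window in half and requires the second half
  to keep ≥ 0.5 mV peak-to-peak *and* ≥ 70 % of the first half's
  amplitude. All branch sweeps, block curves and washout series use this
  screen.
- **Spectral tools.** Dominant frequency is the argmax of the one-sided
  FFT power spectrum (mean removed, rectangular window, DC excluded),
  requiring ≥ 1 s of data for 1 Hz resolution. The cessation classifier
  declares firing ceased when dominant power < 1.5x the 60 Hz power, and
  rejects the recording as too noisy when a ceased verdict's dominant
  frequency sits within 5 Hz of any 60 Hz harmonic.

## 4. Bifurcation analysis

- **Fixed points.** The 7-D equilibrium problem reduces exactly to a
  scalar current-balance root in v with all gates at steady state; roots
  are bracketed on a 1201-point scan and polished with Brent's method.
- **Branches.** `sweep_parameter` walks a parameter grid, warm-starting
  both the fixed-point guess and the limit-cycle initial condition from
  the previous point, so the sweep tracks one attractor (the numerical
  analogue of a slow experimental ramp).
- **Hopf detection.** A stability change between adjacent branch points
  is refined by bisection on the sign of the maximal eigenvalue real
  part (relative tolerance 1e-6). The onset frequency is |Im λ| / 2π
  (rad/ms → Hz).
- **Criticality.** Decided empirically by two independent tests that
  must agree: (i) quasi-static forward/backward sweeps across the
  bifurcation — a supercritical Hopf switches at the same value in both
  directions, a subcritical one shows a bistable window; (ii) squared
  cycle amplitude linear in parameter distance past onset
  (R² > 0.99, intercept near zero) — the square-root law. Each
  quasi-static step adds a small voltage kick (0.2 mV by default)
  standing in for biological noise; without it the sweep can track the
  unstable fixed point past a supercritical onset and fake hysteresis.
  Closed-form planar normal forms (`HopfNormalForm`: dr/dt = μr + a₃r³ +
  a₅r⁵) serve as oracles; the subcritical variant has a saddle-node of
  cycles at μ = -1/4, giving an exact hysteresis width of 0.25.

## 5. Fitting

`fit_waveform` estimates all 44 parameters from a short target waveform
with `scipy.optimize.differential_evolution` (rand1bin, mutation
(0.5, 1.0), recombination 0.7, no polishing, seeded initial population,
deferred updating). The objective is the RMS voltage difference after
aligning candidate and target at their first spike peaks and resampling
onto the target grid; the normalized error is 100 · RMS / peak-to-peak.
Candidates are integrated with a vectorized fixed-step RK4 that advances
the whole population simultaneously (the integration cost, not the DE
bookkeeping, dominates); divergent candidates are flagged with NaN and
receive a flat penalty above any physical RMS. The population
integrator is validated against the LSODA reference in the tests.

## 6. Experiments in silico

- **Channel block.** G → (1-β) G for one channel; block curves are
  warm-started in β like a slow wash-in. `equivalent_block_level`
  inverts a feature-vs-β curve by linear interpolation to express a
  measured percent change as an equivalent blocked fraction, warning
  when the curve is non-monotone (partial Na block transiently *raises*
  spike amplitude in the canonical model before collapse).
- **Low-sodium washout.** Bath sodium decays exponentially, so the
  Nernst E_Na falls linearly in time (RT/F at 22 °C = 25.44 mV). The
  frequency time course is computed quasi-statically at frozen E_Na
  values; cessation time is the first zero-frequency grid point, and
  normalized time places cessation at exactly 1. Consistency with the
  independently detected Hopf value is an acceptance check.

## 7. Synthetic data realism

`make_recording` builds 1 s extracellular-style records at 100 kHz: a
periodic spike train of difference-of-exponentials pulses (0.2 ms rise,
0.8 ms decay), additive 60 Hz line interference, and white Gaussian
noise, all seeded. The generator's knobs (spike amplitude, line
amplitude, noise SD) map directly onto the SNR quantities the cessation
classifier consumes. `make_target_waveform` cuts an integer number of
steady-state cycles positioned so spike peaks are interior to the
segment (the cut is anchored half a period before a spike).

## 8. Limitations

- Single-compartment, single-cell: no gap-junction coupling, no relay
  cells, no network CV predictions.
- The canonical set is a constructed plausible instance; quantities
  derived from it (frequencies, Hopf location) characterize the shipped
  fixture, not a specific biological cell.
- Quasi-static protocols ignore the rate of parameter change; a fast
  washout would show dynamic bifurcation delays not modelled here.
- The criticality classifier is empirical (simulation-based), not a
  first-Lyapunov-coefficient computation; it reports `undetermined`
  when its two tests disagree rather than guessing.
- Temperature enters only through the Nernst constant (22 °C); channel
  kinetics are not temperature-scaled.
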