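# Methods

This note documents the models and numerical procedures implemented in
`synglu`, the assumptions behind them, and what the synthetic-data tests do
and do not demonstrate about recorded data.

## 1. Vesicle glutamate-loading model (`synglu.vesicle`)

### Model structure

A single spherical synaptic vesicle (radius 20 nm, specific membrane
capacitance 1 µF/cm²) is simulated from the moment of endocytosis, when its
lumen still resembles the extracellular solution (pH 7.2, Cl⁻ 110 mM,
K⁺ 5 mM, Na⁺ 145 mM, glutamate 1 µM). The dynamic luminal states are
glutamate, pH, Cl⁻ and (by default) K⁺. The membrane potential Δψ is not a
state: it follows algebraically from the net luminal charge over the
capacitance,

    Δψ = (F·V/C) · ([H⁺]_L + [K⁺]_L + [Na⁺]_L − [Cl⁻]_L − [Glut⁻]_L − B),

with the impermeant background charge B fixed once from charge conservation
at t = 0, including the surface-potential term (C/(F·V))·(ψ_in − ψ_out).
With the default leaflet potentials (ψ_in = 0, ψ_out = −50 mV) this makes
Δψ(0) = +50 mV exactly; for the 20 nm vesicle one mM of net charge
corresponds to 64.3 mV and the surface term to 0.777 mM.

Protons are buffered: the single proton state is pH_L, driven by the net
proton molecule flux divided by N_A·V·β_pH with buffering capacity
β_pH = 40 mM per pH unit. The free luminal [H⁺] entering the charge balance
and the flux laws is 10^(−pH_L). Concentrations adjacent to each membrane
leaflet carry a Boltzmann correction exp(−zFψ/RT) with the leaflet's surface
potential; these corrected concentrations enter the flux laws only, never
the bulk charge balance.

### Flux laws

The transporter flux laws are a pluggable contract (`FluxModel`); the
shipped default uses thermodynamically consistent mass-action/Eyring forms —
each flux is continuous and vanishes exactly at its own electrochemical
equilibrium:

- **VGLUT** (glutamate⁻ in, one H⁺ out per cycle): zero when
  [Glut]_L/[Glut]_c,m = ([H]_L/[H]_c,m)·e^{2FΔψ/RT}; the factor 2 reflects
  the two elementary charges moved per cycle. This makes loading driven
  mainly by Δψ, with a ΔpH contribution.
- **Cl⁻ conductance** through the transporter and a **passive H⁺ leak**:
  symmetric-barrier forms, zero at the respective Nernst potentials.
- **V-ATPase**: a saturating pump, J = k·scale·(1 − e^{Δμ_H − Δμ_max}), which
  runs near capacity at physiological proton-motive force and stalls at
  Δμ_max = 11.5 RT (≈ 2 H⁺ per ATP at a cytosolic ATP free energy of
  ~23 RT). It scales linearly with the `atpase_scale` knob used for the
  metabolic-failure scenario.
- **Cation (K⁺) conductance**: a vesicular cation channel that lets luminal
  K⁺ equilibrate with its electrochemical gradient. This pathway is
  essential: with luminal cations frozen at their endocytotic values
  (K⁺ + Na⁺ = 150 mM) the charge balance caps luminal glutamate near 110 mM
  (≈ 2 240 molecules for this geometry), so a steady state of ~3 500
  molecules (≈ 173 mM) is only reachable if cations accumulate alongside
  glutamate. Luminal K⁺ is therefore dynamic by default
  (`FluxModel(dynamic_k=False)` restores the strictly clamped variant).
- **Na⁺/H⁺ exchanger**: electroneutral, with luminal Na⁺ treated as a
  clamped reservoir. It couples cytosolic Na⁺ to the luminal proton budget,
  so that raised cytosolic Na⁺ drains luminal protons and lowers loading.

### Calibration

Rate constants are in molecules/s at unit normalized drive. The passive
rates (k_vglut = 0.2, k_vglut_cl = 0.5, k_hleak = 1.0, k_kchan = 0.05,
k_nhe = 0.005) were chosen once for a loading time course that plateaus
within a few hundred seconds; the pump rate k_vatpase = 10.38642488…
was then calibrated by root finding so that the control steady state is
exactly 3 500 glutamate molecules. At that point the lumen sits at
pH 6.39 (acidified below the cytosolic 7.2), Δψ = +63 mV, Cl⁻ 16 mM and
K⁺ 85 mM — all within the physiological range reported for secretory
vesicles. The calibration is a package constant; it is not refit at run
time.

### Scenarios and steady-state handling

`run_scenarios` applies single-parameter overrides (defaults: cytosolic
pH 7.2→6.8, Na⁺ 10→30 mM, Cl⁻ 10→20 mM, K⁺ 140→100 mM, initial luminal
pH 7.2→6.9, ATPase ×0.5, and the alkalinization control pH 7.2→7.4). The
magnitudes are package defaults representative of energy-failure conditions,
not measured values; the model's claims are about signs, and every
ischemia-like perturbation lowers the steady-state count while
alkalinization raises it.

The integration uses LSODA with rtol 1e−8 / atol 1e−10 to t_end = 3000 s;
steady state is declared when the relative drift of the molecule count is
below 1e−6 per second over a trailing 10 s window, and
`steady_state_glutamate` reports the trailing-window average. For scenario
comparisons the endpoint is additionally polished with a damped Newton solve
of the right-hand side in log-concentration coordinates: the
initial-luminal-pH scenario acts only through the impermeant-charge term B
and shifts the steady state by ~10⁻⁷ relative, which integration tolerances
alone would not resolve.

The luminal-cation insensitivity question: with the shipped flux forms,
making K⁺ dynamic is what enables the 3 500-molecule plateau, so the default
model is *not* insensitive to the luminal cation treatment. The clamped mode
exists for comparison and saturates near 2 200 molecules.

## 2. ECS diffusion / RTI fitting (`synglu.ecs`)

The forward model is the constant point source in a porous medium with
optional first-order clearance k′ (erfc solution; post-pulse by exact
superposition of the on-solution). Source strength Q = I·n_t/(zF) with
transport number n_t = 0.3 by default; absolute volume-fraction accuracy
depends on the generator and fitter agreeing on n_t, which is a documented
bias source for real pipettes. The free-medium TMA⁺ diffusion coefficient
defaults to 1.31×10⁻⁵ cm²/s at recording temperature (34–35 °C) and is a
configuration value; tortuosity is λ = √(D_free/D*). Clearance defaults to
zero and is excluded from fitting unless requested.

Fitting uses trust-region least squares with bounds 0 < α ≤ 1,
0 < D* ≤ D_free, multi-started from three coarse grid points with ties
broken by residual norm. Distances are µm at the interface and cm
internally; all diffusion math is CGS.

An independent backward-Euler finite-difference solver of the radial
diffusion equation (tests/fd_oracle.py; flux boundary condition on a 2 µm
inner sphere, v = rC substitution, 0.5 µm grid, 20 ms steps) agrees with the
closed form to better than 0.1% in sup-norm across α ∈ {0.1, 0.2, 1},
λ ∈ {1, 1.6, 2}, k′ ∈ {0, 0.005/s}; the test suite asserts 1%.

## 3. Ion-selective electrodes (`synglu.electrodes`)

Nernst (V = E0 + s·log₁₀c) and Nicolsky–Eisenman calibration; the
sub-millimolar departure from Nernstian behavior is lumped into a single
apparent interfering-background concentration (V = E0 + s·log₁₀(c + c_int))
rather than per-ion selectivity coefficients — one knob, matching the
single observed departure mode. Activities are approximated by
concentrations (calibration standards are concentration-defined); no
junction-potential model. Inversion is analytic and exact; the NE inverse is
clamped at zero concentration with a warning when a voltage falls below the
interference floor. The QC rule is strict: a ten-fold concentration step
must produce ΔV strictly greater than 50 mV. Peak transient extraction
(`max_delta`) uses the mean over the 60 s preceding the analysis window as
baseline.

## 4. Field-potential analysis (`synglu.ephys`)

Per stimulus, the first 0.5 ms is treated as artifact; the fiber volley is
the first negative deflection in a 0.5–3 ms window (trough must exceed
3× the robust pre-stimulus noise, estimated as 1.4826×MAD); half width at
half maximum is half the linearly interpolated full width at half
amplitude; delay is stimulus onset to trough. The fEPSP slope is a straight
line fitted over the samples of the negative-going phase between 20% and
80% of the trough amplitude (window 2.5–20 ms post-stimulus); the exact
window and fractions are configurable because published analyses rarely
state them. PPR is pulse-2 over pulse-1 of the chosen metric.

Time courses are normalized to the 0–10 min baseline-epoch mean; the end
epoch defaults to the final 10 min of the timeline and comes from
configuration. The outcome rule is deliberately minimal: an episode is
classified as postsynaptic failure iff the end-epoch mean of the normalized
fEPSP slope is ≤ 0.5 (the response did not recover to strictly above 50% of
baseline).

## 5. iGluSnFR analysis (`synglu.iglusnfr`)

Repeats (4–6) are averaged before background subtraction; F0 is the
pre-stimulus mean of the background-corrected ROI signal, and a
non-positive F0 marks the scan unusable. Peaks are maxima of the averaged
ΔF/F0 within 30 ms of each stimulus. The decay fit is a single exponential
A·e^{−t/τ} + c from the post-peak sample of the chosen pulse (default: the
second) over a 500 ms window; the offset is fitted rather than fixed at
zero, because a fixed zero biases τ whenever the transient rides on a slow
pedestal. The second pulse's amplitude for the PPR is measured after
subtracting the first pulse's extrapolated exponential tail (the 50 ms
interstimulus interval makes the transients overlap by e^{−50/τ}).

## 6. Synthetic data (`synglu.synth`)

Generators emit data plus the exact ground truth, with one seeded RNG per
call. Signal structure: electrode voltages get additive Gaussian noise; TMA
curves multiplicative Gaussian noise (2% default) on top of a 1 mM bath
baseline; line scans per-pixel Gaussian noise. Sweeps are a biphasic
artifact + Gaussian fiber-volley trough + alpha-function fEPSP (the
generator also publishes the dense-analytic rising-phase slope as an
independent oracle). Experiments follow scenario templates — control:
stable; ischemia: transient suppression, recovery, potentiation to 1.3×;
ischemia-failure: suppression with full fiber-volley recovery and the fEPSP
pinned at 0.05× — with 3% per-sweep amplitude jitter. The template
magnitudes are package defaults chosen well inside the classifier margins
and are explicitly not claims about experimentally measured effect sizes.
K⁺ transients rise saturatingly inside the ischemia window (τ_rise 20 s) and
decay exponentially after it; the failure scenario uses a larger peak
(12 vs 8 mM) to reproduce the severity trend.

What the synthetic tests show: that every analyzer recovers the parameters
of data with the structure it assumes, at the stated tolerances, and that
the classification rule is exact on cleanly separated scenarios. What they
do not show: robustness to real-recording pathologies (drift, line noise,
movement, overlapping population spikes, indicator saturation,
non-exponential clearance), none of which the generators emulate.

## 7. Problem sizes

Default problem sizes keep the whole suite light: one vesicle integration is
~3 000 output points and runs in well under a second; RTI fits use 480-point
curves; experiments are 180 sweeps of 3 000 samples; line scans are
64×568 pixel frames, five repeats. The acceptance script runs the control
vesicle integration, five slice-like RTI fits and one free-medium fit.

## 8. Known limitations

- The flux laws are this package's own calibrated forms satisfying the
  stated contracts; no claim is made to reproduce any previously published
  vesicle model coefficient-for-coefficient.
- Osmotic balance and vesicle volume changes are not modeled.
- Luminal Na⁺ is a clamped reservoir; the Na⁺/H⁺ exchanger therefore
  exchanges against a fixed pool.
- The RTI model assumes an ideal point source (no electrode geometry or
  finite-source corrections) and isotropic diffusion.
- Electrode activities are approximated by concentrations; no drift
  correction beyond what a user applies externally.
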