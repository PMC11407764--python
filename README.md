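# synglu

Analysis and modeling toolkit for synaptic glutamate signaling under
transient metabolic failure ("chemical ischemia") in acute hippocampal
slices. It is written for experimenters who combine extracellular field
recordings, ion-selective microelectrodes, TMA⁺ iontophoresis and iGluSnFR
glutamate imaging, and for modelers who want a compact, calibrated
single-vesicle glutamate-loading model to probe how energy failure changes
presynaptic vesicle filling.

## What it computes

**Vesicle loading** (`synglu.vesicle`). A stiff ODE model of glutamate
accumulation in a single 20 nm synaptic vesicle. Luminal glutamate, pH, Cl⁻
and K⁺ evolve under VGLUT (glutamate⁻/H⁺ antiport), a Cl⁻ conductance, a
passive H⁺ leak, the V-ATPase, a cation conductance and an Na⁺/H⁺
exchanger; the membrane potential follows algebraically from the luminal
charge, Δψ = (F·V/C)(Σ z·c − B), with the impermeant charge B fixed by
charge conservation at endocytosis. Under control conditions the calibrated
model plateaus at ≈3500 glutamate molecules (≈173 mM); a scenario runner
compares ischemia-like perturbations against control.

**ECS diffusion** (`synglu.ecs`). The real-time iontophoresis (RTI) method:
a constant TMA⁺ point source (100 nA × 30 s) in a porous medium gives

C(r,t) = Q/(8πD*αr)·[e^{r√(k′/D*)}erfc(r/(2√(D*t)) + √(k′t)) + e^{−r√(k′/D*)}erfc(r/(2√(D*t)) − √(k′t))]

during the pulse and the on-solution difference afterwards. Nonlinear least
squares on a recorded transient returns the extracellular volume fraction α,
the effective diffusion coefficient D* and the tortuosity λ = √(D_free/D*).

**Ion-selective electrodes** (`synglu.electrodes`). Nernst and
Nicolsky–Eisenman calibration (V = E0 + s·log₁₀(c + c_int)), exact analytic
inversion of voltage traces to concentrations, the >50 mV-per-decade
electrode QC rule, and peak ΔK⁺ extraction during ischemia windows.

**Field potentials** (`synglu.ephys`). Paired-pulse sweep metrics — fiber
volley amplitude / half width at half maximum / delay, fEPSP initial slope
(20–80% rising phase), paired-pulse ratio — baseline normalization of
experiment time courses, and the postsynaptic-outcome rule (failure iff the
normalized fEPSP slope does not recover to strictly above 50% of baseline in
the end epoch).

**iGluSnFR transients** (`synglu.iglusnfr`). Line-scan averaging, background
subtraction, F₀ and ΔF/F₀, per-pulse peak amplitudes with overlap
correction, and mono-exponential decay time constants (the readout of
glutamate clearance).

**Synthetic data** (`synglu.synth`). Seeded generators for every signal
class above, each emitting its exact ground truth, so the full pipeline is
testable without any recorded data.

## Worked example

```python
from synglu import vesicle

table = vesicle.run_scenarios()
print(table[["name", "steady_state_n_glut", "pH_L", "relative_change"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4g}"))
```

```
                      name  steady_state_n_glut  pH_L  relative_change
                   control                 3500 6.393                0
   cytosolic_acidification                 2989 6.296           -0.146
       raised_cytosolic_na                 3344 6.481         -0.04447
       raised_cytosolic_cl                 3275 6.384         -0.06434
       lowered_cytosolic_k                 3129 6.377           -0.106
lowered_initial_luminal_ph                 3500 6.393       -2.602e-07
            reduced_atpase                 3093 6.631          -0.1163
  cytosolic_alkalinization                 3858 6.408           0.1023
```

The control vesicle loads 3500 glutamate molecules with an acidified lumen
(pH 6.39, Δψ ≈ +63 mV). Every condition expected during metabolic failure —
cytosolic acidification, raised Na⁺ or Cl⁻, lowered K⁺, a more acidic
endocytosed lumen, reduced V-ATPase activity — lowers the steady-state
count, while the alkalinization control (pH 7.2→7.4) raises it by ~10%:
impaired energy supply cannot explain *increased* vesicular glutamate
content.

Fitting a synthetic slice-like TMA⁺ transient:

```python
from synglu import ecs
from synglu.synth import TISSUE_SCENARIOS, gen_tma_curve

curve, truth = gen_tma_curve(TISSUE_SCENARIOS["slice_like"], seed=1)
fit = ecs.fit_rti(curve)
print(f"alpha={fit.alpha:.3f}  lambda={fit.lam:.3f}")   # alpha=0.190  lambda=1.540
```

which recovers the slice-tissue ground truth (α = 0.19, λ = 1.54) from a
2%-noise transient.

A CLI mirrors the main operations (`synglu vesicle-scenarios`,
`synglu rti-fit`, `synglu electrode-qc`, `synglu synth-experiment`, …).

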