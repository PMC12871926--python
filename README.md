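# phlux — surface-pH CO₂ flux assay toolkit

`phlux` implements the quantitative pipeline behind a classic membrane-
transport assay: measuring transmembrane CO₂ fluxes across a *Xenopus*
oocyte's plasma membrane from simultaneous microelectrode recordings of
extracellular **surface pH (pH_S)** and **intracellular pH (pH_i)** during
CO₂/HCO₃⁻ addition and removal. It is written for electrophysiologists and
modellers who run (or want to simulate) gas-channel experiments: candidate
CO₂ channels such as aquaporins raise membrane permeability `P_M,CO2`, while
carbonic anhydrases (CA) on either side of the membrane steepen the
transmembrane CO₂ gradient — and the two effects multiply.

## The science in brief

Fick's law for the membrane, written with the thin fluid films at the two
membrane faces, is

    J_CO2 = P_M,CO2 · ([CO₂]_outer-surface − [CO₂]_inner-surface).

When CO₂/HCO₃⁻ is applied, CO₂ influx depletes surface CO₂; the surface
reaction HCO₃⁻ + H⁺ → CO₂ + H₂O replenishes it and consumes protons, so
pH_S spikes upward by ΔpH_S — a semiquantitative flux index read *trans* to
any cytosolic CA manipulation. Meanwhile cytosolic hydration of entering CO₂
acidifies the cell at rate (dpH_i/dt)_Max. The package provides:

* **`phlux.sim`** — a reduced 1-D radial reaction–diffusion forward model
  (cell shells + extracellular unconvected film + bulk reservoir) with
  CO₂ ⇌ H⁺ + HCO₃⁻ kinetics, instantaneous-equilibrium buffers, CA
  acceleration factors on each side, and Fick's-law membrane permeation.
* **`phlux.instrument`** — the electrode forward model (Nernstian slope,
  offset, drift, noise, CO₂ sensitivity) and the inversion chain: channel
  subtraction, two-point slope calibration (≥ 55 mV/pH acceptance), and
  segment-wise one-point recalibration from the three bulk retraction
  windows.
* **`phlux.metrics`** — per-oocyte metrics: ΔpH_S up/down, the maximal
  relaxation rate as the derivative of a double-exponential fit at the
  local time origin, (dpH_i/dt)_Max from a running-slope + 10-s linear fit,
  and intrinsic buffering power β_I = −Δ[HCO₃⁻]_i / ΔpH_i.
* **`phlux.pf`** — osmotic water permeability from swelling assays:
  P_f = V₀·d(V/V₀)/dt / (S·ΔOsm·V_W).
* **`phlux.stats`** — mean ± SD summaries, one-way ANOVA with Tukey–Kramer
  post hoc tests, and the ΔΔ/ΔΔΔ synergy construction that diagnoses
  candidate CO₂ channels by how much they amplify the CA-induced ΔΔpH_S.

## Worked example

```python
from phlux.experiment import CO2FluxExperiment
from phlux.metrics import OocyteCondition

cond = OocyteCondition(hAQP5=True, hCAII_ng=10.0)
exp = CO2FluxExperiment.from_synthetic(cond, seed=3, noisy=False)
print(exp.fit().summary())
```

prints

```
CO2 flux assay results - condition +hAQP5/+hCAII10/-bCA  [Vm gate: ok]
----------------------------------------------------------------------
dpHS_up (pH)              +0.043846
dpHS_down (pH)            -0.052559
(dpHS/dt)_Max add (pH/s)  -0.00013193
(dpHS/dt)_Max rem (pH/s)  +0.00011416
(dpHi/dt)_Max add (pH/s)  -0.00084354
(dpHi/dt)_Max rem (pH/s)  +0.0006159
pHi initial (pH)          +7.3
dpHi (pH)                 -0.26574
beta_I (mM/pH)            +12.876
```

Read: the channel-plus-cytosolic-CA oocyte shows a 0.044 pH upward surface
transient on CO₂ addition (vs ≈ 0.013 for a control oocyte), its surface pH
relaxes at up to 0.13 mpH/s, the cytosol acidifies by 0.27 pH at up to
0.84 mpH/s, and the CO₂-induced acid load implies an intrinsic buffering
power of ≈ 13 mM per pH unit.

The same pipeline runs from the shell on recording bundles:

```bash
phlux --seed 1 simulate --out bundle/ --haqp5 --hcaii-ng 10
phlux calibrate bundle/
phlux metrics bundle/ --out cohort.csv
phlux groupstats cohort.csv --metric dpHS_up --ca-axis hCAII
```

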