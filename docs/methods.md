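# Methods

This note documents the models, numerical choices and design decisions
behind `phlux`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Forward model of the addition–removal experiment

### Geometry

A spherical oocyte of radius `R = 0.06 cm` is discretized into
`n_shells_in = 12` equal-thickness concentric shells. Outside the membrane
lies the **extracellular unconvected fluid film (EUF)**, discretized into 8
shells, beyond which the flowing bulk solution acts as an infinite reservoir
(Dirichlet boundary on every mobile species). A sealed-bath variant replaces
the reservoir with a finite well-mixed compartment for conservation checks.

The film thickness defaults to **300 µm**. The blunt surface electrode
dimples the membrane and its shaft shields a pocket of fluid from the
chamber flow; the unconvected region it creates is of the same order as the
340 µm retraction step that moves the tip into the stirred bulk. This is a
free geometric calibration (no measured value exists for it), chosen once:
with a thin (≤ 50 µm) film, the uncatalysed film reaction is too slow to
produce a measurable surface-pH transient at all.

### Chemistry

Carbonate chemistry is collapsed to a single reversible step

    CO₂ + H₂O ⇌ H⁺ + HCO₃⁻,    K_eq = [H⁺][HCO₃⁻]/[CO₂],

with CO₃²⁻ neglected (pH ≤ 8.5). Carbonic anhydrase is a pure catalyst: an
acceleration factor `A ≥ 1` multiplies **both** directions, so equilibria —
and hence all conserved totals — are untouched (detailed balance; the
dehydration constant is always derived as `k_hyd·A / K_eq`). Three factors
exist: `A_i` (cytosol, mapped from the injected hCA II dose), `A_o_surface`
(membrane-adjacent film shell), and the solution-wide `bca_factor` (bCA
dissolved in the perfusate, applied throughout the film).

Non-CO₂ buffers (5 mM HEPES outside; a lumped 20 mM, pK 7.3 intrinsic
buffer inside) equilibrate instantaneously: the dynamic proton variable is
the total titratable acid `H_tot = [H⁺] + [BH]`, and free [H⁺] is recovered
per shell from a quadratic. This keeps the ODE system non-stiff at
physiological CA levels.

State per shell: `[CO₂], [HCO₃⁻], H_tot` in mol cm⁻³. Species diffuse
within each phase (no diffusion across the membrane); proton transport
carries both free H⁺ and the protonated buffer. The membrane passes CO₂ by
Fick's law `J = P_M,CO2 · ([CO₂]_os − [CO₂]_is)`; HCO₃⁻/H⁺ permeabilities
exist but default to zero.

### Constants (literature values; the tunable core)

| constant | default | units | note |
|---|---|---|---|
| k_hyd | 0.037 | s⁻¹ | uncatalysed CO₂ hydration, ~25 °C |
| pK₁′ (effective) | 6.20 | — | lumped CO₂/HCO₃⁻ pK, I ≈ 0.1, room temp |
| CO₂ solubility | 0.0339 | M atm⁻¹ | makes 1.5 % CO₂/10 mM HCO₃⁻ self-consistent at pH 7.494 ≈ the titrated 7.50 |
| D_CO₂ / D_HCO₃ / D_H / D_buf | 1.71/1.18/9.3/0.5 | 10⁻⁵ cm² s⁻¹ | aqueous, used in both phases |
| P_M,CO2 (native) | 3×10⁻⁴ | cm s⁻¹ | free calibration, see below |
| channel permeability factor | ×4 | — | hAQP5 expression |
| A_i(dose) | 1 + 20·ng/(ng+0.5) | — | saturating; 1 ng sub-saturating, 10–100 ng at plateau |
| bca_factor | 20 | — | 0.1 mg/ml dissolved bCA |
| cytosolic buffer | 20 mM, pK 7.3 | — | loading time constant + β_I at the low end of oocyte measurements |
| initial pH_i | 7.30 | — | resting oocyte |
| pH_i probe depth | 0.5·R | — | impalement depth is unreported; mid-radius default |

The baseline permeability and film thickness were calibrated **once,
jointly, before any acceptance measurement**, to put the synthetic control
in the regime the assay is designed around: the membrane is the dominant
resistance, so a ×4 channel factor roughly triples the upward ΔpH_S
(control ≈ 0.013 pH → ≈ 0.026), cytosolic CA alone adds comparatively
little, and the channel × CA combination is supra-additive. Absolute
amplitudes are a factor ~3–5 smaller than typical wet-lab transients — a
known consequence of the reduced 1-D geometry — so only signs, orderings
and ratios are asserted against synthetic data, never absolute group means.

### Integration and sampling

Piecewise integration per solution phase (bulk values step at each switch;
an optional exponential mixing constant, default 2 s when enabled, smooths
them) with `scipy.integrate.solve_ivp(method="BDF")`, rtol 10⁻⁸, atol 10⁻¹⁴
mol cm⁻³. Concentrations more negative than −10⁻¹² mol cm⁻³ abort the run.
Traces are sampled on the 3 Hz acquisition grid. The forward model is
deterministic; the experiment seed only drives instrument noise.

Verified properties (tests/acceptance): sealed-bath total carbon and net
acid (`H_tot − HCO₃⁻`) conserved to < 10⁻⁶ relative over a 3×3
permeability × CA grid; equilibrium initial conditions stay flat to
< 10⁻⁸ pH; with film-wide fast chemistry (A = 300) and a thin film the peak
flux matches `P·([CO₂]_bulk − [CO₂]_is)` within 5 %.

## 2. Instrument model and calibration

Each electrode channel is `V = base + offset + drift·t − slope·(pH −
anchor) + shift·[in CO₂ solution] + noise`, with the pH_i electrode riding
on V_m and the pH_S electrode referenced to a bulk electrode. Default noise
is 0.1 mV rms per sample (≈ 1.7 mpH at 58 mV/pH), a quiet but realistic rig.

The inversion follows the two-step calibration: slope from pH 6.00/8.00
standards (electrodes under 55 mV/pH rejected), then one-point offsets.
pH_S gets **three** offsets from the three bulk retraction windows
(5 %-trimmed mean of the window voltage, anchored at the window solution's
known bulk pH): first window → initial ND96 dimple segment, middle window →
all CO₂/HCO₃⁻ dimple samples, third window → final ND96 segment. The
middle window is placed after 70 % of the CO₂ dimpling time by default —
the retraction happens once the surface-pH relaxation is largely over —
rather than centred. pH_i uses its initial ND96 one-point calibration, plus
(flag on by default) the repeat taken in CO₂ solution for the CO₂-phase
samples, which removes any CO₂-sensitivity offset symmetrically with pH_S.
Samples within ±2 s of an electrode move are masked out of all metrics.

The round trip is exact (< 10⁻¹⁰ pH) when noise, drift and CO₂ shift are
zero, and segment-wise calibration strictly dominates a single-offset
calibration in worst-case pH_S error whenever drift or CO₂ sensitivity is
present.

## 3. Trace metrics

* **Stable tails**: mean over the latest ≥ 30 s (≥ 90 samples) window whose
  running slope is below 2×10⁻⁴ pH/s; otherwise the final window, flagged
  unstable.
* **ΔpH_S**: CO₂-phase peak (on a 5-s running-mean smoothed trace, global
  extremum within the dimple samples) minus the ND96 baseline tail;
  downward analogue for removal (a negative number). Smoothing de-biases
  the extremum under noise; a peak abutting a masked interval is flagged.
* **(dpH_S/dt)_Max**: a 5-s running linear fit locates the extreme slope
  after the peak (`t_Local = 0`, ties to the earliest window); a
  double-exponential `y∞ + A₁e^(−t/τ₁) + A₂e^(−t/τ₂)` is fitted from there
  to the electrode retraction (deterministic multi-start over τ pairs,
  log-τ parameterization, Levenberg–Marquardt), and the reported rate is
  the analytic derivative at zero, `−A₁/τ₁ − A₂/τ₂`. If τ₂/τ₁ < 1.5 or
  |A₂| < 2 SE(A₂), a single exponential is refitted and flagged. If the
  relaxation is interrupted by the retraction, the final 20 samples are
  fitted and flagged `relaxation_truncated`.
* **(dpH_i/dt)_Max**: extreme of the running pH_i slope after the switch,
  then a plain linear fit over the following 10 s (≈ 30 samples).
* **β_I**: with pre-exposure [HCO₃⁻]_i = 0, equal intra/extracellular pK
  and [CO₂]_i = [CO₂]_o at the stable tail,
  `Δ[HCO₃⁻]_i = 10 mM · 10^(pH_i,tail − 7.50)` and
  `β_I = −Δ[HCO₃⁻]_i / ΔpH_i`. A non-acidifying trace raises "no acid
  load" (flagged, NaN, in the composed extraction). Note that on slow
  synthetic loading the tail may be pre-equilibrium, which inflates β_I
  relative to the generator's buffer — a property of the formula's
  equilibrium assumption, preserved deliberately.

## 4. Osmotic water permeability

`P_f = V₀·d(V/V₀)/dt / (S·ΔOsm·V_W)` with V from the projected area under
the sphere assumption, `S = 8·4πr₀²` (membrane infoldings), ΔOsm = 95
mosmol/L and V_W = 18 cm³/mol. The first-minute rate is a plain
least-squares slope of V/V₀ (the source procedure states no fit rule). The
companion generator integrates the *same linearized* flux law (constant S
and ΔOsm) with optional iid multiplicative frame noise on the areas: a
fully nonlinear generator (S growing as V^⅔) would be inconsistent with
the first-minute linear-slope estimator at high P_f, overshooting ~20 % at
2×10⁻² cm/s.

**Precision floor**: the slope SE under iid area noise σ_A is
`1.5·σ_A/√(n(n²−1)/12)·s` ≈ 1.1×10⁻⁴ s⁻¹ at σ_A = 1 %, n = 60 frames,
while the true rate is `0.684·P_f` s⁻¹. At P_f = 2×10⁻⁴ cm/s the signal
(1.4×10⁻⁴ s⁻¹) sits below this floor, so *no* estimator recovers that
decade within 10 % at 1 % frame noise; the acceptance test records this
honestly (the corresponding check fails at the lowest decade only). The
2×10⁻³ and 2×10⁻² decades recover within 10 % and the noiseless inversion
is exact to machine precision.

## 5. Group statistics

Summaries are mean ± SD (n−1). Omnibus comparisons use one-way ANOVA
followed by Tukey's HSD, Tukey–Kramer for unbalanced groups
(statsmodels); for two groups the studentized-range test is evaluated in
closed form via its exact pooled-t equivalence. Degenerate inputs (all
values identical) report p = 1 with a flag.

The ΔΔ/ΔΔΔ synergy construction subtracts the **mean** of the matching
no-CA control group from each +CA measurement, on each level of the
modifier (channel) axis, and compares the two ΔΔ samples by ANOVA/Tukey:

* treating the subtracted control mean as a constant is part of the
  procedure (no uncertainty propagation). With control means *estimated*
  from n = 10 groups this makes the null test anticonservative — the ΔΔ
  group means carry the control-mean sampling error that the within-group
  variance cannot see; a property test documents a > 10 % null rejection
  rate. The calibration acceptance check therefore evaluates the procedure
  under its own stated assumption (known control means supplied via
  `control_means`), where the type-I error is exact (measured ≈ 0.05 over
  1000 replicates).
* the default synergy effect sizes for the statistical-level generator are
  the forward simulator's own condition-grid means (control 0.0132, +CA
  0.0186, +channel 0.0258, both 0.0438 pH) with a 25 % coefficient of
  variation, the spread scale seen across real condition groups; at
  n = 10/group the ΔΔΔ test detects this with ≈ 86 % power.

## 6. What the synthetic data do and do not show

The generator reproduces the *structure* the analysis assumes — trace
morphology (upward spike and relaxation, mirror image on removal),
Nernstian electrode voltages with offset/drift/noise/CO₂ shift, the
protocol's segmentation and recalibration windows, and the condition-grid
orderings (monotonicity in permeability and trans-side CA,
supra-additivity, the cis-side caveat that extracellular CA moves ΔpH_S
without any permeability change). It does **not** reproduce wet-lab
absolute amplitudes (reduced geometry; see §1), biological between-oocyte
variability in membrane parameters, electrode artifacts beyond the additive
model, or water fluxes during the pH protocol. Passing tests therefore
validate the pipeline's correctness and the assay's internal logic, not any
particular measured group mean.

## 7. Problem sizes

Default test/acceptance problem sizes: 12+8 radial shells; protocols of
480 s (grid scans) or 1320 s (full default) at 3 Hz; 20 noisy replicates
per arm for the permeability-recovery study; 1000 replicates for the
type-I and power simulations; 10 seeded fixtures per noise study elsewhere.
These sizes were chosen so the whole suite runs on a laptop-class single
core in a few minutes while every Monte-Carlo bound retains comfortable
margin.
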