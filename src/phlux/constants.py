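"""Physical and kinetic constants used throughout the package.

All values are standard literature numbers for dilute saline near room
temperature (~22 degC, ionic strength ~0.1). None of them is fitted to data;
they are centralized here so that every module draws from one source.

Unit conventions
----------------
Concentrations handled by the simulator core are in mol cm^-3 (so that
membrane permeabilities in cm s^-1 and diffusivities in cm^2 s^-1 combine
without conversion factors); user-facing solution specifications are in
mol L^-1 and are converted at the boundary (1 mol L^-1 = 1e-3 mol cm^-3).
"""

# --- CO2 / carbonic acid system -------------------------------------------
#: CO2 solubility (Henry) coefficient in saline, mol L^-1 atm^-1.
#: Weiss (1974)-type value for ~22 degC, S ~ 0.1 M NaCl.
K_H_CO2 = 0.0339

#: Effective apparent first dissociation pK of the lumped reaction
#: CO2 + H2O <=> H+ + HCO3- (hydration and H2CO3 dissociation collapsed),
#: room temperature, I ~ 0.1 (Harned & Bonner-type corrected value).
PK1_CARBONIC = 6.20

#: Uncatalysed CO2 hydration rate constant, s^-1 (Khalifah 1971: 0.035-0.04
#: at 25 degC).
K_HYD = 0.037

# --- Diffusivities (cm^2 s^-1, aqueous, ~22 degC) --------------------------
D_CO2 = 1.71e-5
D_HCO3 = 1.18e-5
D_H = 9.3e-5
#: Effective diffusivity of mobile non-CO2 buffer (HEPES-sized zwitterion in
#: the extracellular film; crowded cytosolic protein/small-molecule mix is
#: taken at the same order).
D_BUFFER = 5.0e-6

# --- Solutions --------------------------------------------------------------
#: pH to which ND96 and the CO2/HCO3- solution are titrated.
PH_ND96 = 7.50
#: HEPES buffer in ND96, mol L^-1 (5 mM) and its pK near room temperature.
HEPES_CONC = 5.0e-3
HEPES_PK = 7.5
#: CO2/HCO3- solution: 1.5% CO2 (0.015 atm) and 10 mM NaHCO3.
PCT_CO2 = 1.5
HCO3_CONC = 10.0e-3

# --- Oocyte -----------------------------------------------------------------
#: Oocyte radius, cm (stage V-VI, ~1.2 mm diameter).
OOCYTE_RADIUS = 0.06
#: Initial intracellular pH of a healthy oocyte in nominally CO2-free saline.
PH_I_INIT = 7.30
#: Lumped intrinsic (non-CO2) cytosolic buffer: total concentration (mol L^-1)
#: and pK. 20 mM at pK 7.3 gives an open-system buffering power at the low
#: end of oocyte measurements and a CO2-loading time constant short enough
#: that the surface-pH relaxation completes within the exposure.
CYTOSOL_BUFFER_CONC = 20.0e-3
CYTOSOL_BUFFER_PK = 7.30

# --- Membrane ---------------------------------------------------------------
#: Baseline membrane CO2 permeability of a native (water-injected) oocyte,
#: cm s^-1. Free calibration: chosen (jointly with the unconvected-film
#: thickness) so that the synthetic control is membrane-limited: a x4
#: channel factor roughly triples the surface-pH transient while cytosolic
#: CA alone adds little, the pattern the assay is designed around.
PM_CO2_BASE = 3.0e-4
#: Multiplicative permeability factor contributed by hAQP5 expression.
AQP5_PERM_FACTOR = 4.0

# --- Carbonic anhydrase acceleration ---------------------------------------
#: Saturating map from injected hCA II dose (ng/oocyte) to the cytosolic
#: acceleration factor A_i: A_i(ng) = 1 + A_MAX * ng / (ng + K_HALF_NG).
#: 1 ng is sub-saturating; 10-100 ng sit near the plateau.
CA_A_MAX = 20.0
CA_K_HALF_NG = 0.5
#: Acceleration factor applied throughout the extracellular film when bCA
#: (0.1 mg/ml) is dissolved in the flowing solutions.
BCA_FACTOR = 20.0

# --- Protocol / acquisition --------------------------------------------------
SAMPLE_RATE_HZ = 3.0
#: Electrode retraction distance into the bulk fluid for recalibration, cm.
RETRACTION_CM = 0.034
#: One-point calibration anchor pH.
PH_ANCHOR = 7.50
#: Minimum acceptable electrode slope, mV per pH unit.
MIN_SLOPE_MV = 55.0

# --- Osmotic water permeability ---------------------------------------------
#: Osmotic gradient in the swelling assay, mosmol L^-1 (195 - 100).
DELTA_OSM_MOSM = 95.0
#: Molar volume of water, cm^3 mol^-1.
V_W = 18.0
#: True membrane area is taken as eightfold the idealized sphere area
#: (membrane infoldings).
AREA_FACTOR = 8.0


def hca2_dose_to_Ai(ng: float) -> float:
    """Map an injected hCA II dose (ng/oocyte) to the cytosolic CA
    acceleration factor ``A_i`` via the saturating calibration above."""
    if ng < 0:
        raise ValueError("hCA II dose must be non-negative")
    return 1.0 + CA_A_MAX * ng / (ng + CA_K_HALF_NG) if ng > 0 else 1.0
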