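"""Reduced radial reaction-diffusion model of the CO2/HCO3- addition-removal
experiment.

A spherical cell of radius ``R`` is discretized into concentric intracellular
shells; outside the membrane an extracellular unconvected fluid film (EUF) is
discretized likewise, and beyond the film lies the flowing bulk solution,
treated either as an infinite reservoir (Dirichlet boundary, the standard
perfusion chamber) or as a sealed finite bath (conservation checks).

Chemistry is collapsed to the single reversible step

    CO2 + H2O  <=>  H+ + HCO3-        (effective constant K_eq)

with carbonic anhydrase represented as a catalyst multiplying BOTH directions
by an acceleration factor ``A`` (cytosolic ``A_i``; ``A_o_surface`` in the
EUF shell touching the membrane; the solution-wide ``bca_factor`` throughout
the film), so equilibria are untouched. Non-CO2 buffers (HEPES outside, a
lumped intrinsic buffer inside) equilibrate instantaneously: the dynamic
proton variable is the total titratable acid H_tot = [H+] + [BH], and free
[H+] is recovered algebraically at every evaluation.

State per shell: [CO2], [HCO3-], H_tot, all in mol cm^-3. Transmembrane
fluxes follow Fick's law J = P * ([X]_outer_surface - [X]_inner_surface),
which is exactly the thin-film permeability law the assay is built around;
only CO2 is membrane-permeant by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import constants as C
from .protocol import ProtocolTimeline, build_protocol
from .solutions import SolutionSpec

MOLAR_TO_CM3 = 1e-3  # mol L^-1 -> mol cm^-3

# negative-concentration tolerance (mol cm^-3): beyond this the run errors
NEG_CONC_TOL = 1e-12


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class OocyteGeometry:
    radius: float = C.OOCYTE_RADIUS          # cm
    n_shells_in: int = 12
    #: unconvected-film thickness, cm. 300 um: the dimpling electrode shaft
    #: shields a pocket of fluid from convection, of the same order as the
    #: 340 um retraction step that moves the tip into the stirred bulk.
    euf_thickness: float = 0.03
    n_shells_euf: int = 8
    pHi_probe_fraction: float = 0.5          # radial position reported as pH_i

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.euf_thickness <= 0:
            raise ValueError("radius and euf_thickness must be positive")
        if self.n_shells_in < 3:
            raise ValueError("need at least 3 intracellular shells")
        if not 0.0 < self.pHi_probe_fraction < 1.0:
            raise ValueError("pHi_probe_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class MembraneParams:
    pm_co2: float = C.PM_CO2_BASE            # cm s^-1
    pm_hco3: float = 0.0
    pm_h: float = 0.0
    pf_water: float = 0.0                    # condition tag only; not simulated

    def __post_init__(self) -> None:
        for a in ("pm_co2", "pm_hco3", "pm_h", "pf_water"):
            if getattr(self, a) < 0:
                raise ValueError(f"{a} must be >= 0")


@dataclass(frozen=True)
class ChemKinetics:
    k_hyd: float = C.K_HYD                   # s^-1, uncatalysed hydration
    pk_eq: float = C.PK1_CARBONIC            # effective carbonate pK
    A_i: float = 1.0                         # cytosolic CA acceleration
    A_o_surface: float = 1.0                 # membrane-surface extracellular CA
    D_co2: float = C.D_CO2
    D_hco3: float = C.D_HCO3
    D_h: float = C.D_H
    D_buffer: float = C.D_BUFFER
    cytosol_buffer_conc: float = C.CYTOSOL_BUFFER_CONC   # mol L^-1
    cytosol_buffer_pk: float = C.CYTOSOL_BUFFER_PK
    pH_i_init: float = C.PH_I_INIT

    def __post_init__(self) -> None:
        for a in ("k_hyd", "D_co2", "D_hco3", "D_h", "D_buffer"):
            if getattr(self, a) <= 0:
                raise ValueError(f"{a} must be > 0")
        if self.A_i < 1.0 or self.A_o_surface < 1.0:
            raise ValueError("CA acceleration factors must be >= 1")

    @property
    def K_eq(self) -> float:
        """Effective equilibrium constant [H][HCO3]/[CO2] in mol cm^-3.
        The dehydration rate is always k_hyd/K_eq (detailed balance)."""
        return 10.0 ** (-self.pk_eq) * MOLAR_TO_CM3


@dataclass(frozen=True)
class SimConfig:
    geometry: OocyteGeometry = field(default_factory=OocyteGeometry)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    chem: ChemKinetics = field(default_factory=ChemKinetics)
    timeline: ProtocolTimeline = field(default_factory=build_protocol)
    sample_rate: float = C.SAMPLE_RATE_HZ
    seed: int = 0
    #: None = instantaneous bulk switch; a float = exponential mixing tau (s)
    mixing_tau: float | None = None
    rtol: float = 1e-8
    atol: float = 1e-14

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class TrueTraces:
    """Ground-truth traces on the acquisition grid."""
    time: np.ndarray           # s
    pH_S: np.ndarray           # EUF shell adjacent to the membrane
    pH_i: np.ndarray           # shell at pHi_probe_fraction * radius
    J_co2: np.ndarray          # mol cm^-2 s^-1, positive into the cell
    config: SimConfig
    #: CO2 at the outer / inner membrane face, mol cm^-3 (diagnostics)
    co2_surf_out: np.ndarray | None = None
    co2_surf_in: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "pH_S": self.pH_S,
            "pH_i": self.pH_i, "J_co2": self.J_co2,
        })


class SimulationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# core machinery
# --------------------------------------------------------------------------
def _free_h(H_tot: np.ndarray, B: np.ndarray, Ka: np.ndarray) -> np.ndarray:
    """Free [H+] from total titratable acid with one instantaneous buffer:
    H_tot = h + B*h/(h+Ka)  ->  quadratic in h."""
    p = Ka + B - H_tot
    h = 0.5 * (-p + np.sqrt(p * p + 4.0 * Ka * H_tot))
    return np.maximum(h, 1e-30)


class _RadialModel:
    """Precomputed geometry/parameters and the ODE right-hand side."""

    def __init__(self, cfg: SimConfig, closed_bath_volume: float | None = None):
        g, chem = cfg.geometry, cfg.chem
        self.cfg = cfg
        self.closed = closed_bath_volume is not None

        r_in = np.linspace(0.0, g.radius, g.n_shells_in + 1)
        r_euf = np.linspace(g.radius, g.radius + g.euf_thickness,
                            g.n_shells_euf + 1)
        edges = np.concatenate([r_in, r_euf[1:]])
        self.n_in = g.n_shells_in
        self.n_euf = g.n_shells_euf
        n = self.n_in + self.n_euf + (1 if self.closed else 0)
        self.n = n

        vol = 4.0 / 3.0 * math.pi * np.diff(edges ** 3)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if self.closed:
            vol = np.append(vol, closed_bath_volume)
        self.vol = vol
        self.A_mem = 4.0 * math.pi * g.radius ** 2

        # geometry factor area/dist for each adjacent-shell edge; the
        # membrane edge is zeroed (coupled via permeabilities instead)
        n_shell = self.n_in + self.n_euf
        gfac = np.zeros(n - 1)
        for i in range(n_shell - 1):
            area = 4.0 * math.pi * edges[i + 1] ** 2
            gfac[i] = area / (centers[i + 1] - centers[i])
        gfac[self.n_in - 1] = 0.0
        self.area_out = 4.0 * math.pi * edges[-1] ** 2
        self.dr_euf_half = 0.5 * g.euf_thickness / g.n_shells_euf
        if self.closed:
            # last edge couples the outer film shell to the well-mixed bath
            gfac[n_shell - 1] = self.area_out / self.dr_euf_half
        self.gfac = gfac

        # buffers per shell
        B = np.empty(n)
        Ka = np.empty(n)
        B[: self.n_in] = chem.cytosol_buffer_conc * MOLAR_TO_CM3
        Ka[: self.n_in] = 10.0 ** (-chem.cytosol_buffer_pk) * MOLAR_TO_CM3
        sol0 = cfg.timeline.segments[0].solution
        B[self.n_in:] = sol0.non_co2_buffer_conc * MOLAR_TO_CM3
        Ka[self.n_in:] = 10.0 ** (-sol0.non_co2_buffer_pk) * MOLAR_TO_CM3
        self.B, self.Ka = B, Ka

        self.k_hyd = chem.k_hyd
        self.K_eq = chem.K_eq
        self.pHi_probe_idx = int(np.argmin(
            np.abs(centers[: self.n_in] - g.pHi_probe_fraction * g.radius)))
        self.pHS_idx = self.n_in  # EUF shell adjacent to the membrane

    # -- per-phase reaction acceleration ------------------------------------
    def accel(self, solution: SolutionSpec) -> np.ndarray:
        a = np.ones(self.n)
        a[: self.n_in] = self.cfg.chem.A_i
        a[self.n_in:] = solution.bca_factor
        a[self.n_in] *= self.cfg.chem.A_o_surface
        return a

    # -- state helpers -------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        chem = self.cfg.chem
        sol0 = self.cfg.timeline.segments[0].solution
        c = np.zeros(self.n)
        b = np.zeros(self.n)
        H = np.zeros(self.n)
        # cytosol: carbon-free, at the initial intracellular pH
        h_i = 10.0 ** (-chem.pH_i_init) * MOLAR_TO_CM3
        H[: self.n_in] = h_i + self.B[0] * h_i / (h_i + self.Ka[0])
        # film (and bath): equilibrated with the first solution
        c[self.n_in:] = sol0.co2_conc * MOLAR_TO_CM3
        b[self.n_in:] = sol0.hco3_conc * MOLAR_TO_CM3
        h_o = sol0.h_conc * MOLAR_TO_CM3
        H[self.n_in:] = h_o + self.B[-1] * h_o / (h_o + self.Ka[-1])
        return np.concatenate([c, b, H])

    def split(self, y: np.ndarray):
        n = self.n
        return y[:n], y[n: 2 * n], y[2 * n:]

    def free_h(self, H: np.ndarray) -> np.ndarray:
        return _free_h(H, self.B, self.Ka)

    def membrane_flux(self, c: np.ndarray) -> float:
        """CO2 flux across the membrane, positive into the cell."""
        return self.cfg.membrane.pm_co2 * (c[self.n_in] - c[self.n_in - 1])

    # -- RHS -----------------------------------------------------------------
    def rhs(self, a_fac: np.ndarray,
            bulk_fn: Callable[[float], tuple[float, float, float, float]] | None):
        """Build the ODE right-hand side for one protocol phase.

        ``bulk_fn(t)`` returns (c, b, h, BH)_bulk in mol cm^-3; None for the
        sealed-bath variant.
        """
        chem, mem = self.cfg.chem, self.cfg.membrane
        n, n_in = self.n, self.n_in
        vol, gfac = self.vol, self.gfac
        zero = np.zeros(1)

        def _diffuse(x: np.ndarray, D: float) -> np.ndarray:
            flux = D * gfac * (x[1:] - x[:-1])  # positive: into lower shell
            return (np.concatenate([flux, zero])
                    - np.concatenate([zero, flux])) / vol

        def f(t: float, y: np.ndarray) -> np.ndarray:
            c, b, H = self.split(y)
            h = self.free_h(H)
            BH = self.B * h / (h + self.Ka)

            # reaction CO2 <-> H+ + HCO3- (detailed balance)
            R = a_fac * self.k_hyd * (c - h * b / self.K_eq)
            dc = -R + _diffuse(c, chem.D_co2)
            db = R + _diffuse(b, chem.D_hco3)
            dH = R + _diffuse(h, chem.D_h) + _diffuse(BH, chem.D_buffer)

            # transmembrane permeation (outer-surface minus inner-surface)
            j_in = n_in - 1
            J_c = mem.pm_co2 * (c[n_in] - c[j_in])
            dc[j_in] += J_c * self.A_mem / vol[j_in]
            dc[n_in] -= J_c * self.A_mem / vol[n_in]
            if mem.pm_hco3 > 0.0:
                J_b = mem.pm_hco3 * (b[n_in] - b[j_in])
                db[j_in] += J_b * self.A_mem / vol[j_in]
                db[n_in] -= J_b * self.A_mem / vol[n_in]
            if mem.pm_h > 0.0:
                J_h = mem.pm_h * (h[n_in] - h[j_in])
                dH[j_in] += J_h * self.A_mem / vol[j_in]
                dH[n_in] -= J_h * self.A_mem / vol[n_in]

            if bulk_fn is not None:
                cb, bb, hb, BHb = bulk_fn(t)
                g_out = self.area_out / self.dr_euf_half / vol[-1]
                dc[-1] += chem.D_co2 * g_out * (cb - c[-1])
                db[-1] += chem.D_hco3 * g_out * (bb - b[-1])
                dH[-1] += (chem.D_h * g_out * (hb - h[-1])
                           + chem.D_buffer * g_out * (BHb - BH[-1]))
            return np.concatenate([dc, db, dH])

        return f


def _bulk_values(model: _RadialModel, sol: SolutionSpec):
    c = sol.co2_conc * MOLAR_TO_CM3
    b = sol.hco3_conc * MOLAR_TO_CM3
    h = sol.h_conc * MOLAR_TO_CM3
    B, Ka = model.B[-1], model.Ka[-1]
    BH = B * h / (h + Ka)
    return np.array([c, b, h, BH])


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------
def simulate(config: SimConfig) -> TrueTraces:
    """Integrate the radial model over the protocol timeline and sample the
    ground-truth pH_S, pH_i and transmembrane CO2 flux at the acquisition
    rate. Deterministic: no randomness enters the forward model."""
    model = _RadialModel(config)
    tl = config.timeline
    times = tl.times()

    # merge contiguous segments sharing a solution into integration phases
    phases: list[tuple[float, float, SolutionSpec]] = []
    for seg in tl.segments:
        if phases and phases[-1][2].name == seg.solution.name:
            phases[-1] = (phases[-1][0], seg.t1, phases[-1][2])
        else:
            phases.append((seg.t0, seg.t1, seg.solution))

    y = model.initial_state()
    Y = np.empty((y.size, times.size))
    filled = np.zeros(times.size, dtype=bool)
    prev_bulk = _bulk_values(model, phases[0][2])

    for k, (t0, t1, sol) in enumerate(phases):
        target = _bulk_values(model, sol)
        if config.mixing_tau is not None and k > 0:
            start, tau = prev_bulk.copy(), config.mixing_tau

            def bulk_fn(t, _t0=t0, _start=start, _target=target, _tau=tau):
                w = math.exp(-(t - _t0) / _tau)
                return _target + (_start - _target) * w
        else:
            def bulk_fn(t, _target=target):
                return _target
        prev_bulk = target

        sel = (times >= t0) & (times <= t1) & ~filled
        t_eval = times[sel]
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
            extra = True
        else:
            extra = False
        f = model.rhs(model.accel(sol), bulk_fn)
        res = solve_ivp(f, (t0, t1), y, method="BDF", t_eval=t_eval,
                        rtol=config.rtol, atol=config.atol)
        if not res.success:
            raise SimulationError(
                f"integrator failed in phase '{sol.name}' "
                f"[{t0:.0f}, {t1:.0f}] s: {res.message}")
        ysol = res.y[:, :-1] if extra else res.y
        Y[:, sel] = ysol
        filled |= sel
        y = res.y[:, -1]
        nneg = y[: 2 * model.n].min()
        if nneg < -NEG_CONC_TOL:
            raise SimulationError(
                f"negative concentration {nneg:.3e} mol/cm^3 in phase "
                f"'{sol.name}'")

    n = model.n
    cS = Y[: n, :]
    H = Y[2 * n:, :]
    h = _free_h(H, model.B[:, None], model.Ka[:, None])
    pH = -np.log10(h / MOLAR_TO_CM3)
    J = config.membrane.pm_co2 * (cS[model.pHS_idx] - cS[model.n_in - 1])
    return TrueTraces(time=times, pH_S=pH[model.pHS_idx].copy(),
                      pH_i=pH[model.pHi_probe_idx].copy(),
                      J_co2=J.copy(), config=config,
                      co2_surf_out=cS[model.pHS_idx].copy(),
                      co2_surf_in=cS[model.n_in - 1].copy())


@dataclass
class ConservationReport:
    carbon_drift_rel: float
    acid_drift_rel: float
    tol: float
    passed: bool
    totals: pd.DataFrame

    def __str__(self) -> str:  # failure report names per-species drift
        status = "PASS" if self.passed else "FAIL"
        return (f"closed-system conservation {status}: "
                f"carbon drift {self.carbon_drift_rel:.2e}, "
                f"acid drift {self.acid_drift_rel:.2e} (tol {self.tol:.0e})")


def closed_system_check(config: SimConfig, bath_volume: float = 0.1,
                        duration: float = 200.0,
                        tol: float = 1e-6) -> ConservationReport:
    """Sealed-bath variant: replace the infinite reservoir by a finite,
    well-mixed bath and verify that total carbon (CO2 + HCO3-, volume
    weighted over every compartment) and total net acid (H_tot - HCO3-,
    conserved by the reaction stoichiometry) stay constant.

    The initial condition is deliberately out of equilibrium (cell at its
    resting state, film and bath filled with the first timeline solution
    or, if carbon-free, with the first CO2-bearing solution found) so the
    check exercises the full reaction-diffusion-permeation dynamics.
    """
    model = _RadialModel(config, closed_bath_volume=bath_volume)
    sol = config.timeline.segments[0].solution
    if sol.co2_conc == 0:
        for seg in config.timeline.segments:
            if seg.solution.co2_conc > 0:
                sol = seg.solution
                break
    # refill film+bath with the chosen solution
    y = model.initial_state()
    c, b, H = (a.copy() for a in model.split(y))
    c[model.n_in:] = sol.co2_conc * MOLAR_TO_CM3
    b[model.n_in:] = sol.hco3_conc * MOLAR_TO_CM3
    h_o = sol.h_conc * MOLAR_TO_CM3
    H[model.n_in:] = h_o + model.B[-1] * h_o / (h_o + model.Ka[-1])
    y = np.concatenate([c, b, H])

    t_eval = np.linspace(0.0, duration, 101)
    f = model.rhs(model.accel(sol), bulk_fn=None)
    res = solve_ivp(f, (0.0, duration), y, method="BDF", t_eval=t_eval,
                    rtol=config.rtol, atol=config.atol)
    if not res.success:
        raise SimulationError(f"integrator failed in sealed-bath run: {res.message}")

    n = model.n
    cY, bY, HY = res.y[:n], res.y[n:2 * n], res.y[2 * n:]
    carbon = model.vol @ (cY + bY)
    acid = model.vol @ (HY - bY)
    scale_c = max(abs(carbon[0]), 1e-30)
    scale_a = max(abs(acid[0]), 1e-30)
    cd = float(np.max(np.abs(carbon - carbon[0])) / scale_c)
    ad = float(np.max(np.abs(acid - acid[0])) / scale_a)
    totals = pd.DataFrame({"time_s": res.t, "carbon_mol": carbon,
                           "net_acid_mol": acid})
    return ConservationReport(cd, ad, tol, passed=(cd < tol and ad < tol),
                              totals=totals)


# --------------------------------------------------------------------------
# condition plumbing and the synergy grid
# --------------------------------------------------------------------------
def config_for_condition(hAQP5: bool = False, hCAII_ng: float = 0.0,
                         bCA: bool = False,
                         base: SimConfig | None = None,
                         perm_factor: float | None = None,
                         timeline: ProtocolTimeline | None = None) -> SimConfig:
    """Build a SimConfig for an experimental condition.

    hAQP5 multiplies the membrane CO2 permeability by the calibrated channel
    factor (or an explicit ``perm_factor``); the injected hCA II dose maps to
    ``A_i`` through the saturating dose curve; bCA dissolves CA in every
    perfusion solution (film-wide acceleration).
    """
    base = base if base is not None else SimConfig()
    if timeline is None:
        timeline = base.timeline
    if bCA:
        from .protocol import with_bca
        timeline = with_bca(timeline)
    pf = perm_factor if perm_factor is not None else (
        C.AQP5_PERM_FACTOR if hAQP5 else 1.0)
    mem = replace(base.membrane, pm_co2=C.PM_CO2_BASE * pf,
                  pf_water=(2e-2 if hAQP5 else 1e-3))
    chem = replace(base.chem, A_i=C.hca2_dose_to_Ai(hCAII_ng))
    return replace(base, membrane=mem, chem=chem, timeline=timeline)


def short_protocol() -> ProtocolTimeline:
    """A trimmed addition/removal timeline for grid scans (same structure,
    shorter phases)."""
    return build_protocol(init_cal_s=30.0, nd96_dimple_s=60.0,
                          co2_total_s=270.0, mid_cal_s=30.0,
                          nd96_final_s=120.0, final_cal_s=30.0)


def trace_dphs_up(tr: TrueTraces) -> float:
    """Upward surface-pH excursion straight off ground-truth traces:
    CO2-phase peak minus the pre-switch ND96 baseline."""
    tl = tr.config.timeline
    t_on = tl.segment("co2_dimple_a").t0
    t_off = tl.segment("nd96_dimple_final").t0
    pre = (tr.time >= t_on - 10.0) & (tr.time < t_on)
    dur = (tr.time >= t_on) & (tr.time < t_off)
    return float(tr.pH_S[dur].max() - tr.pH_S[pre].mean())


def trace_peak_dphidt(tr: TrueTraces, smooth_s: float = 5.0) -> float:
    """Most negative smoothed dpH_i/dt after the CO2 switch (pH s^-1)."""
    tl = tr.config.timeline
    t_on = tl.segment("co2_dimple_a").t0
    t_off = tl.segment("nd96_dimple_final").t0
    sel = (tr.time >= t_on) & (tr.time < t_off)
    t, p = tr.time[sel], tr.pH_i[sel]
    w = max(3, int(round(smooth_s * tr.config.sample_rate)))
    kern = np.ones(w) / w
    dp = np.convolve(np.gradient(p, t), kern, mode="valid")
    return float(dp.min())


def synergy_table(base: SimConfig | None = None,
                  perm_factors=(1.0, 2.0),
                  ai_levels=(1.0, 20.0),
                  ao_levels=(1.0,),
                  timeline: ProtocolTimeline | None = None) -> pd.DataFrame:
    """Grid of simulated flux metrics over membrane permeability and cis/
    trans CA activity.

    Returns one row per (perm_factor, A_i, A_o) combination with the upward
    surface-pH excursion and the peak intracellular acidification rate, both
    measured on ground-truth traces. Feeding the grid into ordering tests is
    how supra-additivity (synergy) is established.
    """
    if len(perm_factors) < 1 or len(ai_levels) < 1 or len(ao_levels) < 1:
        raise ValueError("each axis needs at least one level")
    base = base if base is not None else SimConfig()
    tl = timeline if timeline is not None else short_protocol()
    rows = []
    for pf in perm_factors:
        for ai in ai_levels:
            for ao in ao_levels:
                cfg = replace(
                    base,
                    membrane=replace(base.membrane, pm_co2=C.PM_CO2_BASE * pf),
                    chem=replace(base.chem, A_i=ai, A_o_surface=ao),
                    timeline=tl)
                tr = simulate(cfg)
                rows.append({
                    "perm_factor": pf, "A_i": ai, "A_o": ao,
                    "dphs_up": trace_dphs_up(tr),
                    "peak_dphidt": trace_peak_dphidt(tr),
                })
    return pd.DataFrame(rows)
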