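"""Osmotic water permeability (P_f) from oocyte swelling.

An oocyte moved into hypotonic saline swells; from a 1 frame/s series of
projected areas the volume (sphere assumption) gives

    P_f = V0 * d(V/V0)/dt / (S * DeltaOsm * V_W)

with V0 the initial volume, d(V/V0)/dt the relative volume slope over the
first minute, S the membrane area taken as eightfold the idealized sphere
area (membrane infoldings), DeltaOsm the osmotic gradient (195 - 100 mOsm)
and V_W = 18 cm^3/mol the molar volume of water.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C

MOSM_TO_OSM_CM3 = 1e-6  # mosmol L^-1 -> osmol cm^-3


@dataclass
class VolumeSeries:
    time: np.ndarray                 # s, 1 frame/s
    area: np.ndarray                 # cm^2 projected
    radius: np.ndarray | None = None
    volume: np.ndarray | None = None
    #: scalar area-scale calibration (reference steel sphere), metadata only
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.area.size < 10:
            raise ValueError("need at least 10 frames")
        if np.any(self.area <= 0):
            raise ValueError("projected areas must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "area_cm2": self.area})


@dataclass
class PfResult:
    Pf: float          # cm s^-1
    V0: float          # cm^3
    rel_rate: float    # s^-1
    S: float           # cm^2 (= area_factor * 4 pi r0^2)
    dOsm: float        # osmol cm^-3
    Vw: float          # cm^3 mol^-1
    r0: float          # cm
    shrinking: bool = False

    def summary(self) -> str:
        return (f"P_f = {self.Pf:.3e} cm/s  (V0 = {self.V0:.3e} cm^3, "
                f"d(V/V0)/dt = {self.rel_rate:.3e} /s, S = {self.S:.4f} cm^2)"
                + ("  [shrinking series]" if self.shrinking else ""))

    def to_row(self) -> pd.Series:
        return pd.Series({"Pf_cm_per_s": self.Pf, "V0_cm3": self.V0,
                          "rel_rate_per_s": self.rel_rate, "S_cm2": self.S,
                          "dOsm_osm_cm3": self.dOsm, "Vw_cm3_mol": self.Vw,
                          "r0_cm": self.r0, "shrinking": self.shrinking})


def areas_to_volumes(series: VolumeSeries) -> VolumeSeries:
    """Fill radii and volumes from projected areas (sphere assumption):
    r = sqrt(A/pi), V = 4/3 pi r^3."""
    r = np.sqrt(series.area / math.pi)
    series.radius = r
    series.volume = 4.0 / 3.0 * math.pi * r ** 3
    return series


def compute_pf(series: VolumeSeries,
               dOsm_mosm: float = C.DELTA_OSM_MOSM,
               Vw: float = C.V_W,
               area_factor: float = C.AREA_FACTOR,
               span_s: float = 60.0) -> PfResult:
    """Estimate P_f from the first-minute relative volume slope.

    d(V/V0)/dt is the plain least-squares slope of V/V0 against time over
    the first ``span_s`` seconds (or whatever is available, >= 30 s); V0 is
    the first-frame volume and S = area_factor * 4 pi r0^2. A negative
    slope (shrinking oocyte) is flagged, not an error.
    """
    if series.volume is None:
        areas_to_volumes(series)
    t, V = series.time, series.volume
    span = t[-1] - t[0]
    if span < 30.0:
        raise ValueError(f"need >= 30 s of frames (got {span:.0f} s)")
    sel = t <= t[0] + span_s
    V0 = float(V[0])
    r0 = float(series.radius[0])
    rel_rate = float(np.polyfit(t[sel] - t[0], V[sel] / V0, 1)[0])
    S = area_factor * 4.0 * math.pi * r0 ** 2
    dOsm = dOsm_mosm * MOSM_TO_OSM_CM3
    Pf = V0 * rel_rate / (S * dOsm * Vw)
    return PfResult(Pf=Pf, V0=V0, rel_rate=rel_rate, S=S, dOsm=dOsm, Vw=Vw,
                    r0=r0, shrinking=rel_rate < 0)


def generate_swelling_series(Pf_true: float,
                             r0: float = C.OOCYTE_RADIUS,
                             dOsm_mosm: float = C.DELTA_OSM_MOSM,
                             noise_sd: float = 0.0,
                             seed: int = 0,
                             n_frames: int = 60,
                             area_factor: float = C.AREA_FACTOR) -> VolumeSeries:
    """Forward model for the swelling assay.

    Integrates dV/dt = Pf * S * Vw * DeltaOsm with the same (fixed) membrane
    area convention S = area_factor * 4 pi r0^2 the estimator uses and a
    constant osmotic gradient, i.e. the linearized first-minute regime; the
    projected areas then carry iid multiplicative noise of ``noise_sd``
    relative sd per frame. Deterministic under the seed.
    """
    if Pf_true < 0:
        raise ValueError("Pf_true must be >= 0")
    t = np.arange(n_frames, dtype=float)
    V0 = 4.0 / 3.0 * math.pi * r0 ** 3
    S = area_factor * 4.0 * math.pi * r0 ** 2
    rate = Pf_true * S * Vw_dOsm(dOsm_mosm) / V0
    V = V0 * (1.0 + rate * t)
    r = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    A = math.pi * r ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A * (1.0 + rng.normal(0.0, noise_sd, A.size))
    return VolumeSeries(time=t, area=A)


def Vw_dOsm(dOsm_mosm: float) -> float:
    """V_W * DeltaOsm in cm^3 water per cm^3 flux units (cm s^-1 * cm^2 ->
    cm^3 s^-1 scaling factor)."""
    return C.V_W * dOsm_mosm * MOSM_TO_OSM_CM3
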