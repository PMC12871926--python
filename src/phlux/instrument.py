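"""Electrode forward model and the two-step calibration/inversion chain.

Liquid-membrane pH microelectrodes report a voltage that falls linearly with
pH (Nernstian slope, ideally ~58 mV/pH at room temperature). The intracellular
electrode senses membrane potential plus the pH signal, so the recorded pH_i
channel is corrected by digitally subtracting the V_m channel; the surface
electrode is referenced against a broken-tip bulk electrode, subtracted
likewise.

Calibration is two-step: the slope comes from certified pH 6.00 / 8.00
standards (electrodes below 55 mV/pH are rejected), after which a one-point
calibration in a physiological solution of known pH fixes the offset.
Because these electrodes can respond to CO2 itself, the offset is re-measured
in bulk solution during the experiment (three retraction windows) and each
protocol segment is inverted with the offset of its own solution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import constants as C
from .protocol import ProtocolTimeline

DEFAULT_VM_MV = -60.0


@dataclass(frozen=True)
class ElectrodeModel:
    """Additive measurement-chain model for one electrode channel.

    ``co2_sensitivity_shift`` is an extra offset (mV) active whenever the
    tip sits in CO2/HCO3- -containing solution.
    """
    slope: float = 58.0            # mV per pH unit, positive magnitude
    offset: float = 0.0            # mV
    drift_rate: float = 0.0        # mV s^-1
    noise_sd: float = 0.1          # mV rms per sample
    co2_sensitivity_shift: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("electrode slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ElectrodeSet:
    """The four channels of the rig."""
    pHS: ElectrodeModel = field(default_factory=ElectrodeModel)
    pHi: ElectrodeModel = field(default_factory=ElectrodeModel)
    vm: ElectrodeModel = field(default_factory=lambda: ElectrodeModel(
        slope=58.0, noise_sd=0.05))
    ref: ElectrodeModel = field(default_factory=lambda: ElectrodeModel(
        slope=58.0, noise_sd=0.05))

    @staticmethod
    def noiseless() -> "ElectrodeSet":
        quiet = ElectrodeModel(noise_sd=0.0)
        return ElectrodeSet(pHS=quiet, pHi=quiet, vm=quiet, ref=quiet)


@dataclass
class CalPoint:
    """A one-point calibration reading: the differential voltage measured
    with the electrode in a bulk solution of known pH."""
    time: float
    solution: str
    diff_mV: float
    anchor_pH: float


@dataclass
class RawRecording:
    time: np.ndarray
    V_m: np.ndarray
    V_pHi_raw: np.ndarray
    V_pHS_raw: np.ndarray
    V_ref: np.ndarray
    timeline: ProtocolTimeline
    #: one-point calibrations of the pH_i electrode (initial ND96, and the
    #: repeat in CO2/HCO3- solution)
    pHi_cal: list[CalPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("V_m", "V_pHi_raw", "V_pHS_raw", "V_ref"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("sampling must be uniform")


@dataclass
class CalibrationResult:
    slope: float
    accepted: bool
    offsets: tuple[float, float, float]   # initial-ND96, CO2, final-ND96 (mV)
    anchors: tuple[float, float, float]   # pH assigned in each window
    applied_pH_anchor: float = C.PH_ANCHOR

    def report(self) -> str:
        status = ("accepted" if self.accepted
                  else f"REJECTED, < {C.MIN_SLOPE_MV:.0f} mV/pH")
        lines = [f"electrode slope: {self.slope:.2f} mV/pH ({status})"]
        for name, off, anc in zip(("initial ND96", "CO2/HCO3-", "final ND96"),
                                  self.offsets, self.anchors):
            lines.append(f"  window {name}: offset {off:+.3f} mV "
                         f"at anchor pH {anc:.3f}")
        return "\n".join(lines)


@dataclass
class CalibratedTraces:
    time: np.ndarray
    pH_S: np.ndarray
    pH_i: np.ndarray
    V_m: np.ndarray
    segment_label: np.ndarray
    mask: np.ndarray                      # True near electrode moves
    timeline: ProtocolTimeline
    calibration: CalibrationResult | None = None


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# forward synthesis
# ---------------------------------------------------------------------------
def synthesize_voltages(true, electrodes: ElectrodeSet, seed: int,
                        vm_resting_mV: float = DEFAULT_VM_MV,
                        anchor_pH: float = C.PH_ANCHOR) -> RawRecording:
    """Generate the four raw voltage channels from ground-truth traces.

    The pH_S electrode reads the true surface pH while dimpling and the bulk
    solution pH while retracted; the pH_i electrode rides on top of V_m. The
    CO2-sensitivity shift switches on whenever the ambient solution carries
    CO2/HCO3-. A one-point pH_i calibration is taken at t = 0 in ND96 and
    repeated at the centre of the mid-exposure window in CO2/HCO3- solution.
    Deterministic for a given seed.
    """
    if electrodes is None:
        raise ValueError("missing electrode model set")
    tl: ProtocolTimeline = true.config.timeline
    t = true.time
    rng = np.random.default_rng(seed)

    idx = tl.segment_index(t)
    segs = tl.segments
    in_co2 = np.array([segs[i].solution.co2_conc > 0 for i in idx])
    in_bulk = np.array([segs[i].position == "bulk" for i in idx])
    bulk_pH = np.array([segs[i].solution.pH_bulk for i in idx])

    pH_read_S = np.where(in_bulk, bulk_pH, true.pH_S)

    e = electrodes
    vm_true = np.full_like(t, vm_resting_mV)
    V_m = vm_true + rng.normal(0.0, e.vm.noise_sd, t.size)
    ref_true = e.ref.offset + e.ref.drift_rate * t
    V_ref = ref_true + rng.normal(0.0, e.ref.noise_sd, t.size)

    def channel(model: ElectrodeModel, pH: np.ndarray, base: np.ndarray):
        return (base + model.offset + model.drift_rate * t
                - model.slope * (pH - anchor_pH)
                + model.co2_sensitivity_shift * in_co2
                + rng.normal(0.0, model.noise_sd, t.size))

    V_pHi = channel(e.pHi, true.pH_i, vm_true)
    V_pHS = channel(e.pHS, pH_read_S, ref_true)

    # one-point pH_i calibrations (differential voltage at the anchor pH)
    cal_nd96 = CalPoint(0.0, "ND96", e.pHi.offset, anchor_pH)
    mid = tl.segment("co2_cal")
    t_mid = 0.5 * (mid.t0 + mid.t1)
    cal_co2 = CalPoint(t_mid, "CO2/HCO3-",
                       e.pHi.offset + e.pHi.drift_rate * t_mid
                       + e.pHi.co2_sensitivity_shift, anchor_pH)
    return RawRecording(time=t, V_m=V_m, V_pHi_raw=V_pHi, V_pHS_raw=V_pHS,
                        V_ref=V_ref, timeline=tl,
                        pHi_cal=[cal_nd96, cal_co2])


# ---------------------------------------------------------------------------
# calibration pipeline
# ---------------------------------------------------------------------------
@dataclass
class SlopeFit:
    slope: float
    accepted: bool


def fit_slope(v_low_pH: float, v_high_pH: float,
              pH_low: float = 6.00, pH_high: float = 8.00) -> SlopeFit:
    """Electrode slope from the two certified buffers; accepted only if at
    least 55 mV/pH."""
    if pH_low == pH_high:
        raise ValueError("calibration buffers must have distinct pH")
    slope = abs(v_low_pH - v_high_pH) / abs(pH_high - pH_low)
    return SlopeFit(slope=slope, accepted=slope >= C.MIN_SLOPE_MV)


def subtract_channels(rec: RawRecording) -> tuple[np.ndarray, np.ndarray]:
    """The digital subtraction: pH_i channel minus V_m, pH_S channel minus
    the bulk reference."""
    return rec.V_pHi_raw - rec.V_m, rec.V_pHS_raw - rec.V_ref


def _trimmed_mean(x: np.ndarray, trim: float) -> float:
    return float(sps.trim_mean(x, trim)) if x.size > 2 else float(np.mean(x))


def apply_segmentwise_calibration(
    diff_pHS: np.ndarray,
    diff_pHi: np.ndarray,
    timeline: ProtocolTimeline,
    slope_pHS: float,
    slope_pHi: float,
    pHi_cal: list[CalPoint],
    V_m: np.ndarray | None = None,
    anchor_override: dict[str, float] | None = None,
    repeat_pHi_co2_cal: bool = True,
    trim: float = 0.05,
    min_window_s: float = 10.0,
) -> CalibratedTraces:
    """Invert differential voltages to pH with one offset per bulk window.

    Each retraction window yields an offset (5% trimmed mean of the
    differential voltage, assigned the window solution's bulk pH): the first
    window calibrates the initial ND96 dimple segment, the middle window all
    CO2/HCO3- dimple samples, the third the final ND96 segment. The pH_i
    electrode uses its initial ND96 one-point calibration throughout; if
    ``repeat_pHi_co2_cal`` the CO2-solution repeat is applied to CO2-phase
    samples (removing any CO2-sensitivity offset symmetrically with pH_S).

    ``anchor_override`` maps window labels to a forced anchor pH (e.g.
    ``{"co2_cal": 7.50}`` to reproduce a fixed-anchor convention).
    """
    if slope_pHS < C.MIN_SLOPE_MV or slope_pHi < C.MIN_SLOPE_MV:
        raise CalibrationError("electrode slope below the 55 mV/pH acceptance bound")
    t = timeline.times()
    if diff_pHS.size != t.size or diff_pHi.size != t.size:
        raise CalibrationError("voltage series do not match the timeline grid")

    windows = timeline.calibration_windows()
    if len(windows) != 3:
        missing = {"nd96_cal_init", "co2_cal", "nd96_cal_final"} - {
            w.label for w in windows}
        raise CalibrationError(f"missing recalibration window(s): {sorted(missing)}")
    idx = timeline.segment_index(t)
    labels = np.array([s.label for s in timeline.segments])[idx]

    offsets, anchors = [], []
    for w in windows:
        if w.duration < min_window_s:
            raise CalibrationError(
                f"calibration window '{w.label}' shorter than {min_window_s} s")
        sel = labels == w.label
        offsets.append(_trimmed_mean(diff_pHS[sel], trim))
        anc = (anchor_override or {}).get(w.label, w.solution.pH_bulk)
        anchors.append(anc)

    # map: window -> dimple segments it calibrates (plus the window itself)
    assign = {
        "nd96_cal_init": ("nd96_cal_init", "nd96_dimple"),
        "co2_cal": ("co2_dimple_a", "co2_cal", "co2_dimple_b"),
        "nd96_cal_final": ("nd96_dimple_final", "nd96_cal_final"),
    }
    pH_S = np.full(t.size, np.nan)
    for w, off, anc in zip(windows, offsets, anchors):
        for lab in assign[w.label]:
            sel = labels == lab
            pH_S[sel] = anc - (diff_pHS[sel] - off) / slope_pHS

    # pH_i: initial one-point ND96 calibration, optionally the CO2 repeat
    cal_by_sol = {c.solution: c for c in pHi_cal}
    if "ND96" not in cal_by_sol:
        raise CalibrationError("missing initial ND96 one-point pH_i calibration")
    c0 = cal_by_sol["ND96"]
    pH_i = c0.anchor_pH - (diff_pHi - c0.diff_mV) / slope_pHi
    if repeat_pHi_co2_cal and "CO2/HCO3-" in cal_by_sol:
        c1 = cal_by_sol["CO2/HCO3-"]
        in_co2 = np.array([timeline.segments[i].solution.co2_conc > 0
                           for i in idx])
        pH_i[in_co2] = c1.anchor_pH - (diff_pHi[in_co2] - c1.diff_mV) / slope_pHi

    cal = CalibrationResult(slope=slope_pHS, accepted=True,
                            offsets=tuple(offsets), anchors=tuple(anchors))
    vm = V_m if V_m is not None else np.zeros(t.size)
    return CalibratedTraces(time=t, pH_S=pH_S, pH_i=pH_i, V_m=vm,
                            segment_label=labels, mask=timeline.move_mask(t),
                            timeline=timeline, calibration=cal)


def apply_single_offset_calibration(
    diff_pHS: np.ndarray, diff_pHi: np.ndarray, timeline: ProtocolTimeline,
    slope_pHS: float, slope_pHi: float, pHi_cal: list[CalPoint],
    trim: float = 0.05,
) -> CalibratedTraces:
    """Naive variant: the initial ND96 window's offset applied to the whole
    record (no mid/final recalibration). Kept as the comparison arm that
    shows why segment-wise recalibration matters whenever the electrode
    drifts or responds to CO2."""
    t = timeline.times()
    idx = timeline.segment_index(t)
    labels = np.array([s.label for s in timeline.segments])[idx]
    w = timeline.calibration_windows()[0]
    off = _trimmed_mean(diff_pHS[labels == w.label], trim)
    anc = w.solution.pH_bulk
    pH_S = anc - (diff_pHS - off) / slope_pHS
    c0 = next(c for c in pHi_cal if c.solution == "ND96")
    pH_i = c0.anchor_pH - (diff_pHi - c0.diff_mV) / slope_pHi
    cal = CalibrationResult(slope=slope_pHS, accepted=True,
                            offsets=(off, off, off), anchors=(anc, anc, anc))
    return CalibratedTraces(time=t, pH_S=pH_S, pH_i=pH_i,
                            V_m=np.zeros(t.size), segment_label=labels,
                            mask=timeline.move_mask(t), timeline=timeline,
                            calibration=cal)


def calibrate_recording(rec: RawRecording, slope_pHS: float = 58.0,
                        slope_pHi: float = 58.0,
                        **kwargs) -> CalibratedTraces:
    """Convenience: subtraction followed by segment-wise calibration."""
    d_i, d_s = subtract_channels(rec)
    return apply_segmentwise_calibration(
        d_s, d_i, rec.timeline, slope_pHS, slope_pHi, rec.pHi_cal,
        V_m=rec.V_m, **kwargs)


def vm_health_gate(rec: RawRecording, threshold_mV: float = -40.0,
                   span_s: float = 30.0) -> bool:
    """Advisory oocyte-health filter: True if the early membrane potential
    is more negative than the threshold."""
    sel = rec.time <= rec.time[0] + span_s
    return float(np.mean(rec.V_m[sel])) < threshold_mV
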