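"""Per-oocyte metric extraction from calibrated pH traces.

The assay quantifies transmembrane CO2 flux through:

* ``dpHS_up`` / ``dpHS_down`` — the surface-pH excursions on CO2/HCO3-
  addition (peak minus ND96 baseline, positive) and removal (nadir minus
  CO2-phase tail, negative);
* ``(dpH_S/dt)_Max`` — the steepest post-peak relaxation rate, read as the
  derivative at the local time origin of a double-exponential (DExp) fit;
* ``(dpH_i/dt)_Max`` — the steepest intracellular pH change after a
  solution switch, from a ~10 s linear fit anchored at the extreme of the
  running slope;
* ``beta_I`` — intrinsic intracellular buffering power from the CO2-induced
  acid load, -Delta[HCO3-]_i / DeltapH_i.

Stable-state values are 30 s (>= 90 samples at 3 Hz) tail averages taken
where the trace is flat.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import least_squares

from . import constants as C
from .instrument import CalibratedTraces
from .protocol import ProtocolTimeline

#: default sliding window (s) for running linear fits
RUNNING_SLOPE_WINDOW_S = 5.0
#: default smoothing window (s) applied before peak/nadir searches
PEAK_SMOOTH_S = 5.0


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------
def running_slope(t: np.ndarray, y: np.ndarray, window_s: float):
    """Least-squares slope of y vs t in a sliding window.

    Returns (centre_times, slopes); the window length in samples is rounded
    from ``window_s`` at the series' own sampling rate.
    """
    if t.size < 2:
        raise MetricError("need at least two samples")
    dt = float(np.median(np.diff(t)))
    w = max(3, int(round(window_s / dt)))
    if t.size < w:
        raise MetricError("segment shorter than the running-fit window")
    tw = sliding_window_view(t, w)
    yw = sliding_window_view(y, w)
    tc = tw.mean(axis=1)
    slopes = ((tw - tc[:, None]) * (yw - yw.mean(axis=1)[:, None])).sum(axis=1)
    sxx = ((tw - tc[:, None]) ** 2).sum(axis=1)
    return tc, slopes / sxx


def smooth(y: np.ndarray, rate_hz: float, window_s: float = PEAK_SMOOTH_S):
    """Centered running mean (reflective ends)."""
    w = max(1, int(round(window_s * rate_hz)))
    if w <= 1 or y.size < w:
        return y
    ypad = np.pad(y, w, mode="reflect")
    return np.convolve(ypad, np.ones(w) / w, mode="same")[w:-w]


# ---------------------------------------------------------------------------
# stable window / excursions
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class StableWindowSpec:
    min_duration: float = 30.0       # s
    min_points: int = 90
    flatness_threshold: float = 2e-4  # pH s^-1

    def __post_init__(self) -> None:
        if self.min_points > self.min_duration * C.SAMPLE_RATE_HZ + 1:
            raise ValueError("min_points inconsistent with min_duration at 3 Hz")


def stable_tail_mean(t: np.ndarray, y: np.ndarray,
                     spec: StableWindowSpec = StableWindowSpec()):
    """Mean over the latest window of ``min_duration`` whose running slope
    is flat; falls back to the final window (flagged unstable) if none is.

    Returns (mean, stable_flag).
    """
    dt = float(np.median(np.diff(t)))
    w = max(spec.min_points, int(round(spec.min_duration / dt)))
    if t.size < w:
        raise MetricError(
            f"segment ({t.size} samples) shorter than the stable window ({w})")
    tw = sliding_window_view(t, w)
    yw = sliding_window_view(y, w)
    tc = tw.mean(axis=1)
    slopes = (((tw - tc[:, None]) * (yw - yw.mean(axis=1)[:, None])).sum(axis=1)
              / ((tw - tc[:, None]) ** 2).sum(axis=1))
    flat = np.abs(slopes) < spec.flatness_threshold
    if flat.any():
        i = int(np.max(np.nonzero(flat)[0]))
        return float(yw[i].mean()), True
    return float(y[-w:].mean()), False


def delta_pHS(traces: CalibratedTraces,
              spec: StableWindowSpec = StableWindowSpec(),
              smooth_s: float = PEAK_SMOOTH_S):
    """Upward and downward surface-pH excursions.

    dpHS_up = peak pH_S during the CO2 dimple segments minus the stable tail
    of the initial ND96 dimple; dpHS_down = nadir during the final ND96
    dimple minus the stable tail of the CO2 phase (a negative number). The
    peak/nadir search runs on a lightly smoothed trace restricted to
    unmasked dimple samples; a peak abutting a masked interval is flagged.

    Returns (dpHS_up, dpHS_down, flags).
    """
    tl = traces.timeline
    t, pS = traces.time, traces.pH_S
    rate = tl.sample_rate
    lab = traces.segment_label
    ok = ~traces.mask
    flags: dict[str, bool] = {}

    pS_s = smooth(pS, rate, smooth_s)

    def segsel(*labels):
        m = np.isin(lab, labels) & ok
        if not m.any():
            raise MetricError(f"missing segment(s) {labels}")
        return m

    m_base = segsel("nd96_dimple")
    base, st1 = stable_tail_mean(t[m_base], pS[m_base], spec)
    flags["baseline_unstable"] = not st1

    m_co2 = segsel("co2_dimple_a", "co2_dimple_b")
    i_pk = np.nonzero(m_co2)[0][np.argmax(pS_s[m_co2])]
    peak = float(pS_s[i_pk])
    flags["peak_near_mask"] = bool(
        traces.mask[max(0, i_pk - 1): i_pk + 2].any())

    m_tail = traces.segment_label == "co2_dimple_b"
    tail, st2 = stable_tail_mean(t[m_tail], pS[m_tail], spec)
    flags["co2_tail_unstable"] = not st2

    m_fin = segsel("nd96_dimple_final")
    i_nd = np.nonzero(m_fin)[0][np.argmin(pS_s[m_fin])]
    nadir = float(pS_s[i_nd])
    flags["nadir_near_mask"] = bool(
        traces.mask[max(0, i_nd - 1): i_nd + 2].any())

    return peak - base, nadir - tail, flags


# ---------------------------------------------------------------------------
# relaxation-rate machinery
# ---------------------------------------------------------------------------
def locate_tlocal_zero(t: np.ndarray, y: np.ndarray,
                       window_s: float = RUNNING_SLOPE_WINDOW_S,
                       mode: str = "falling") -> tuple[float, float]:
    """Local time origin of the relaxation: centre time of the sliding
    window with the most negative (``falling``) or most positive
    (``rising``) running slope. Ties break to the earliest window.

    Returns (t_local_zero, extreme_slope).
    """
    tc, s = running_slope(t, y, window_s)
    i = int(np.argmin(s)) if mode == "falling" else int(np.argmax(s))
    return float(tc[i]), float(s[i])


@dataclass
class DExpFit:
    y_inf: float
    A1: float
    A2: float
    tau1: float
    tau2: float
    rss: float
    derivative_at_zero: float
    single_exp_fallback: bool = False
    n_points: int = 0

    def __post_init__(self) -> None:
        assert self.tau1 > 0 and self.tau2 > 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        return (self.y_inf + self.A1 * np.exp(-t / self.tau1)
                + self.A2 * np.exp(-t / self.tau2))


def _fit_exp_sum(t, y, taus0: list[tuple[float, float]]):
    """Multi-start least squares of y = y_inf + A1 e^-t/tau1 + A2 e^-t/tau2
    with deterministic starts; amplitudes are seeded by linear projection.
    Returns (params, rss, jac) of the best start."""
    best = None
    for tau1, tau2 in taus0:
        X = np.column_stack([np.ones_like(t), np.exp(-t / tau1),
                             np.exp(-t / tau2)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        p0 = np.array([coef[0], coef[1], coef[2],
                       math.log(tau1), math.log(tau2)])

        def resid(p):
            return (p[0] + p[1] * np.exp(-t / np.exp(p[3]))
                    + p[2] * np.exp(-t / np.exp(p[4]))) - y

        try:
            res = least_squares(resid, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(res.cost * 2)
        if best is None or rss < best[1] - 1e-18:
            best = (res, rss)
    if best is None:
        raise MetricError("double-exponential fit failed to converge from any start")
    return best


def fit_dexp_and_derivative(t: np.ndarray, y: np.ndarray,
                            min_points: int = 20,
                            tau_ratio_min: float = 1.5) -> DExpFit:
    """DExp fit of the relaxation, time measured from t_Local = 0.

    The fit starts from several deterministic (tau1, tau2) pairs spanning
    the record length; the reported maximal rate is the analytic derivative
    of the fitted curve at zero, -A1/tau1 - A2/tau2. If the two time
    constants collapse (tau2/tau1 < ``tau_ratio_min``) or the slow amplitude
    is indistinguishable from zero (|A2| < 2 SE), the fit falls back to a
    single exponential and says so.
    """
    if t.size < min_points:
        raise MetricError(f"need at least {min_points} samples for the DExp fit")
    t = t - t[0]
    span = max(t[-1], 1.0)
    starts = [(span / 30, span / 3), (span / 10, span),
              (span / 50, span / 5), (span / 5, span * 2),
              (span / 100, span / 2)]
    res, rss = _fit_exp_sum(t, y, starts)
    y_inf, A1, A2, l1, l2 = res.x
    tau1, tau2 = math.exp(l1), math.exp(l2)
    if tau1 > tau2:
        tau1, tau2, A1, A2 = tau2, tau1, A2, A1

    # profile-style identifiability check on the slow component
    dof = max(t.size - 5, 1)
    try:
        J = res.jac
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        order = res.x[3] <= res.x[4]
        se_A2 = math.sqrt(abs(cov[2, 2] if order else cov[1, 1]))
    except np.linalg.LinAlgError:
        se_A2 = np.inf
    fallback = (tau2 / tau1 < tau_ratio_min) or (abs(A2) < 2 * se_A2)

    if fallback:
        def resid1(p):
            return p[0] + p[1] * np.exp(-t / np.exp(p[2])) - y
        p0 = np.array([y_inf, A1 + A2, math.log(max(tau1, 1e-3))])
        r1 = least_squares(resid1, p0, method="lm", max_nfev=2000)
        y_inf, A1 = r1.x[0], r1.x[1]
        tau1 = math.exp(r1.x[2])
        A2, tau2 = 0.0, tau1 * tau_ratio_min
        rss = float(r1.cost * 2)
        deriv = -A1 / tau1
    else:
        deriv = -A1 / tau1 - A2 / tau2
    return DExpFit(y_inf=float(y_inf), A1=float(A1), A2=float(A2),
                   tau1=float(tau1), tau2=float(tau2), rss=rss,
                   derivative_at_zero=float(deriv),
                   single_exp_fallback=bool(fallback), n_points=t.size)


def dphs_dt_max(traces: CalibratedTraces, phase: str = "addition",
                window_s: float = RUNNING_SLOPE_WINDOW_S):
    """(dpH_S/dt)_Max for one phase: locate t_Local = 0 on the post-extreme
    relaxation inside the dimple segment, DExp-fit from there to the
    electrode retraction, and evaluate the fitted derivative at zero.

    Returns (rate, DExpFit, flags).
    """
    tl = traces.timeline
    lab = traces.segment_label
    ok = ~traces.mask
    if phase == "addition":
        seg, mode = "co2_dimple_a", "falling"
    elif phase == "removal":
        seg, mode = "nd96_dimple_final", "rising"
    else:
        raise ValueError("phase must be 'addition' or 'removal'")
    m = (lab == seg) & ok
    if not m.any():
        raise MetricError(f"missing segment {seg}")
    t, y = traces.time[m], traces.pH_S[m]
    ys = smooth(y, tl.sample_rate, PEAK_SMOOTH_S)
    i_ext = int(np.argmax(ys)) if phase == "addition" else int(np.argmin(ys))
    t2, y2 = t[i_ext:], y[i_ext:]
    if t2.size < 25:
        raise MetricError(
            f"no post-extreme relaxation before retraction in {seg}")
    t0, _ = locate_tlocal_zero(t2, y2, window_s, mode)
    # relaxation interrupted by the retraction: fit what is available
    truncated = (t2 >= t0).sum() < 20
    if truncated:
        t0 = float(t2[-20])
    sel = t2 >= t0
    fit = fit_dexp_and_derivative(t2[sel], y2[sel])
    flags = {"dexp_single_fallback": fit.single_exp_fallback,
             "relaxation_truncated": truncated}
    return fit.derivative_at_zero, fit, flags


def dphi_dt_max(traces: CalibratedTraces, phase: str = "addition",
                fit_span_s: float = 10.0,
                window_s: float = RUNNING_SLOPE_WINDOW_S):
    """(dpH_i/dt)_Max: extreme of the running pH_i slope after the solution
    switch, then a plain linear fit over the following ~10 s.

    Returns (rate, flags).
    """
    tl = traces.timeline
    if phase == "addition":
        t_sw = tl.segment("co2_dimple_a").t0
        t_end = tl.segment("nd96_dimple_final").t0
        mode = "falling"
    elif phase == "removal":
        t_sw = tl.segment("nd96_dimple_final").t0
        t_end = tl.total_duration
        mode = "rising"
    else:
        raise ValueError("phase must be 'addition' or 'removal'")
    m = (traces.time >= t_sw) & (traces.time < t_end)
    t, y = traces.time[m], traces.pH_i[m]
    t0, _ = locate_tlocal_zero(t, y, window_s, mode)
    sel = (t >= t0) & (t <= t0 + fit_span_s)
    flags = {"dphidt_span_short": bool(
        t[sel].size and (t[sel][-1] - t[sel][0]) < fit_span_s * 0.9)}
    if t[sel].size < 3:
        raise MetricError("trace too short after the switch for the linear fit")
    slope = np.polyfit(t[sel], y[sel], 1)[0]
    return float(slope), flags


# ---------------------------------------------------------------------------
# buffering power
# ---------------------------------------------------------------------------
@dataclass
class BufferingResult:
    dpHi: float              # pH (negative on addition)
    dHCO3_mM: float          # mM, the acid load
    beta_I: float            # mM per pH


def buffering_power(pHi_init: float, pHi_tail: float,
                    hco3_bulk_mM: float = 10.0,
                    pH_anchor: float = C.PH_ANCHOR) -> BufferingResult:
    """Intrinsic intracellular buffering power from the CO2-induced acid
    load.

    Assumes pre-exposure [HCO3-]_i = 0, [CO2]_i = [CO2]_o at the stable
    tail, and equal intra/extracellular carbonate pK, so the final
    [HCO3-]_i is ``hco3_bulk * 10^(pHi_tail - pH_anchor)`` and
    beta_I = -Delta[HCO3-]_i / DeltapH_i.
    """
    if hco3_bulk_mM <= 0:
        raise ValueError("hco3_bulk_mM must be positive")
    dpHi = pHi_tail - pHi_init
    if dpHi >= 0:
        raise MetricError("no acid load: pH_i did not fall during the exposure")
    dHCO3 = hco3_bulk_mM * 10.0 ** (pHi_tail - pH_anchor)
    return BufferingResult(dpHi=dpHi, dHCO3_mM=dHCO3, beta_I=-dHCO3 / dpHi)


# ---------------------------------------------------------------------------
# condition + full extraction
# ---------------------------------------------------------------------------
ALLOWED_DOSES = (0.0, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class OocyteCondition:
    hAQP5: bool = False
    hCAII_ng: float = 0.0
    bCA: bool = False

    def __post_init__(self) -> None:
        if float(self.hCAII_ng) not in ALLOWED_DOSES:
            raise ValueError(f"hCA II dose must be one of {ALLOWED_DOSES} ng")

    def label(self) -> str:
        return (("+" if self.hAQP5 else "-") + "hAQP5/"
                + (f"+hCAII{self.hCAII_ng:g}" if self.hCAII_ng else "-hCAII")
                + "/" + ("+" if self.bCA else "-") + "bCA")


@dataclass
class OocyteMetrics:
    dpHS_up: float
    dpHS_down: float
    dpHSdt_max_add: float
    dpHSdt_max_rem: float
    dpHidt_max_add: float
    dpHidt_max_rem: float
    pHi_init: float
    dpHi: float
    beta_I: float
    condition: OocyteCondition = field(default_factory=OocyteCondition)
    flags: dict = field(default_factory=dict)

    METRIC_FIELDS = ("dpHS_up", "dpHS_down", "dpHSdt_max_add",
                     "dpHSdt_max_rem", "dpHidt_max_add", "dpHidt_max_rem",
                     "pHi_init", "dpHi", "beta_I")

    def to_row(self, oocyte_id: str = "") -> pd.Series:
        d = {"oocyte_id": oocyte_id, "hAQP5": self.condition.hAQP5,
             "hCAII_ng": self.condition.hCAII_ng, "bCA": self.condition.bCA}
        d.update({k: getattr(self, k) for k in self.METRIC_FIELDS})
        d["quality_flags"] = ";".join(k for k, v in self.flags.items() if v)
        return pd.Series(d)


def extract_metrics(traces: CalibratedTraces,
                    condition: OocyteCondition = OocyteCondition(),
                    spec: StableWindowSpec = StableWindowSpec(),
                    hco3_bulk_mM: float = 10.0) -> OocyteMetrics:
    """Run the full per-oocyte analysis on calibrated traces.

    Individual metric failures that reflect trace content (e.g. no acid
    load on a flat record) are recorded as flags with NaN values rather than
    aborting the whole extraction.
    """
    flags: dict[str, bool] = {}
    up, down, f = delta_pHS(traces, spec)
    flags.update(f)

    def attempt(fn, *a, **k):
        try:
            out = fn(*a, **k)
            return out
        except MetricError as err:
            flags[f"{fn.__name__}_failed"] = True
            flags[f"{fn.__name__}_msg"] = str(err)  # type: ignore[assignment]
            return None

    r_add = attempt(dphs_dt_max, traces, "addition")
    r_rem = attempt(dphs_dt_max, traces, "removal")
    if r_add:
        flags.update({f"add_{k}": v for k, v in r_add[2].items()})
    if r_rem:
        flags.update({f"rem_{k}": v for k, v in r_rem[2].items()})
    i_add = attempt(dphi_dt_max, traces, "addition")
    i_rem = attempt(dphi_dt_max, traces, "removal")

    tl = traces.timeline
    lab = traces.segment_label
    t = traces.time
    m0 = lab == "nd96_dimple"
    pHi_init, st = stable_tail_mean(t[m0], traces.pH_i[m0], spec)
    flags["pHi_init_unstable"] = not st
    m1 = lab == "co2_dimple_b"
    pHi_tail, st = stable_tail_mean(t[m1], traces.pH_i[m1], spec)
    flags["pHi_tail_unstable"] = not st

    try:
        buf = buffering_power(pHi_init, pHi_tail, hco3_bulk_mM)
        beta, dpHi = buf.beta_I, buf.dpHi
    except MetricError as err:
        flags["no_acid_load"] = True
        flags["beta_msg"] = str(err)  # type: ignore[assignment]
        beta, dpHi = float("nan"), pHi_tail - pHi_init

    return OocyteMetrics(
        dpHS_up=up, dpHS_down=down,
        dpHSdt_max_add=r_add[0] if r_add else float("nan"),
        dpHSdt_max_rem=r_rem[0] if r_rem else float("nan"),
        dpHidt_max_add=i_add[0] if i_add else float("nan"),
        dpHidt_max_rem=i_rem[0] if i_rem else float("nan"),
        pHi_init=pHi_init, dpHi=dpHi, beta_I=beta,
        condition=condition, flags=flags)
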