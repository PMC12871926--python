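"""Protocol timeline: the ordered sequence of perfusion and electrode events.

The standard experiment is, in order:

1. bulk ND96 with the surface-pH electrode retracted (initial one-point
   calibration window),
2. ND96 with the electrode dimpling the membrane,
3. CO2/HCO3- exposure, dimpling (first half),
4. mid-exposure retraction into the bulk CO2/HCO3- solution (second
   calibration window),
5. CO2/HCO3- exposure, dimpling (second half),
6. return to ND96, dimpling (acid-unloading phase),
7. final retraction into bulk ND96 (third calibration window).

Three bulk windows and four dimple segments: the first and third windows
anchor the ND96-phase calibration, the middle window anchors the
CO2/HCO3- -phase calibration. Electrode retraction/advance steps are 340 um
and create short masked intervals around each move.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .solutions import SolutionSpec, co2_hco3, nd96

#: half-width (s) of the mask applied around each electrode move
MOVE_MASK_HALF_WIDTH_S = 2.0


@dataclass(frozen=True)
class Segment:
    label: str
    t0: float
    t1: float
    solution: SolutionSpec
    position: str  # "surface" (dimpling) or "bulk" (retracted)
    is_calibration: bool = False

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass(frozen=True)
class ProtocolTimeline:
    segments: tuple[Segment, ...]
    sample_rate: float = C.SAMPLE_RATE_HZ
    #: electrode retraction distance recorded as protocol metadata (cm)
    retraction_cm: float = C.RETRACTION_CM

    def __post_init__(self) -> None:
        t = 0.0
        for seg in self.segments:
            if not np.isclose(seg.t0, t):
                raise ValueError("segments must tile time without gaps")
            if seg.t1 <= seg.t0:
                raise ValueError(f"segment '{seg.label}' has non-positive duration")
            t = seg.t1
        if len(self.calibration_windows()) < 3:
            raise ValueError("protocol requires three bulk recalibration windows")

    # -- basic queries -------------------------------------------------------
    @property
    def total_duration(self) -> float:
        return self.segments[-1].t1

    def times(self) -> np.ndarray:
        """The uniform acquisition grid (s)."""
        n = int(np.floor(self.total_duration * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"no segment labelled '{label}'")

    def calibration_windows(self) -> list[Segment]:
        return [s for s in self.segments if s.is_calibration]

    def segment_index(self, times: np.ndarray) -> np.ndarray:
        """Index of the segment containing each time (last segment closed)."""
        edges = np.array([s.t1 for s in self.segments])
        return np.minimum(np.searchsorted(edges, times, side="right"),
                          len(self.segments) - 1)

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        labels = np.array([s.label for s in self.segments])
        return labels[self.segment_index(times)]

    # -- events --------------------------------------------------------------
    def solution_switch_times(self) -> list[tuple[float, SolutionSpec]]:
        """(time, new solution) at every bulk-composition change."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.solution.name != b.solution.name:
                out.append((b.t0, b.solution))
        return out

    def electrode_move_times(self) -> list[float]:
        return [b.t0 for a, b in zip(self.segments, self.segments[1:])
                if a.position != b.position]

    def move_mask(self, times: np.ndarray,
                  half_width: float = MOVE_MASK_HALF_WIDTH_S) -> np.ndarray:
        """Boolean mask, True where a sample falls within ``half_width``
        seconds of an electrode position step (excluded from metrics)."""
        mask = np.zeros_like(times, dtype=bool)
        for tm in self.electrode_move_times():
            mask |= np.abs(times - tm) <= half_width
        return mask

    def solution_at(self, times: np.ndarray) -> list[SolutionSpec]:
        idx = self.segment_index(times)
        return [self.segments[i].solution for i in idx]

    def events_table(self):
        """Events as (time_s, event_type, label) rows (for the events file)."""
        rows = [(0.0, "segment_start", self.segments[0].label)]
        for t, sol in self.solution_switch_times():
            rows.append((t, "solution_switch", sol.name))
        for t in self.electrode_move_times():
            rows.append((t, "electrode_move", f"{self.retraction_cm * 1e4:.0f}um"))
        for seg in self.segments[1:]:
            rows.append((seg.t0, "segment_start", seg.label))
        return sorted(rows)


def build_protocol(
    init_cal_s: float = 60.0,
    nd96_dimple_s: float = 60.0,
    co2_total_s: float = 600.0,
    mid_cal_s: float = 60.0,
    nd96_final_s: float = 600.0,
    final_cal_s: float = 60.0,
    sol_nd96: SolutionSpec | None = None,
    sol_co2: SolutionSpec | None = None,
    sample_rate: float = C.SAMPLE_RATE_HZ,
    mid_cal_frac: float = 0.7,
) -> ProtocolTimeline:
    """Assemble the standard addition/removal timeline.

    The CO2/HCO3- exposure of total length ``co2_total_s`` is split around a
    bulk recalibration window of ``mid_cal_s`` placed after a fraction
    ``mid_cal_frac`` of the dimpling time (the retraction happens once the
    surface-pH relaxation is largely over); the final ND96 phase of
    ``nd96_final_s`` ends with the third calibration window of
    ``final_cal_s``.
    """
    durs = dict(init_cal_s=init_cal_s, nd96_dimple_s=nd96_dimple_s,
                co2_total_s=co2_total_s, nd96_final_s=nd96_final_s)
    for name, d in durs.items():
        if d <= 0:
            raise ValueError(f"{name} must be positive (got {d})")
    if mid_cal_s <= 0 or final_cal_s <= 0:
        raise ValueError("missing recalibration window: "
                         "mid_cal_s and final_cal_s must be positive")
    if co2_total_s <= mid_cal_s:
        raise ValueError("CO2 phase shorter than its recalibration window")
    if nd96_final_s <= final_cal_s:
        raise ValueError("final ND96 phase shorter than its calibration window")

    if not 0.1 <= mid_cal_frac <= 0.9:
        raise ValueError("mid_cal_frac must lie in [0.1, 0.9]")
    sol_nd96 = sol_nd96 if sol_nd96 is not None else nd96()
    sol_co2 = sol_co2 if sol_co2 is not None else co2_hco3()
    dimple_co2 = co2_total_s - mid_cal_s
    co2_a = mid_cal_frac * dimple_co2
    co2_b = dimple_co2 - co2_a

    spans = [
        ("nd96_cal_init", init_cal_s, sol_nd96, "bulk", True),
        ("nd96_dimple", nd96_dimple_s, sol_nd96, "surface", False),
        ("co2_dimple_a", co2_a, sol_co2, "surface", False),
        ("co2_cal", mid_cal_s, sol_co2, "bulk", True),
        ("co2_dimple_b", co2_b, sol_co2, "surface", False),
        ("nd96_dimple_final", nd96_final_s - final_cal_s, sol_nd96, "surface", False),
        ("nd96_cal_final", final_cal_s, sol_nd96, "bulk", True),
    ]
    segments, t = [], 0.0
    for label, dur, sol, pos, is_cal in spans:
        segments.append(Segment(label, t, t + dur, sol, pos, is_cal))
        t += dur
    return ProtocolTimeline(tuple(segments), sample_rate=sample_rate)


def with_bca(timeline: ProtocolTimeline) -> ProtocolTimeline:
    """Return a copy of the timeline with bCA dissolved in every solution."""
    segs = tuple(
        replace(s, solution=replace(s.solution, bca_factor=C.BCA_FACTOR))
        for s in timeline.segments
    )
    return ProtocolTimeline(segs, timeline.sample_rate, timeline.retraction_cm)
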