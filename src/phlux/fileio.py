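"""File formats: delimited-text traces/recordings/events/metrics, YAML run
configuration and JSON parameter sidecars. Everything the package writes it
can read back losslessly (full float precision)."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .instrument import CalPoint, RawRecording
from .metrics import OocyteCondition
from .pf import VolumeSeries
from .protocol import ProtocolTimeline, build_protocol
from .sim import TrueTraces

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# traces / recordings
# ---------------------------------------------------------------------------
def write_true_traces(tr: TrueTraces, path: str | Path) -> None:
    tr.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_true_traces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"time_s", "pH_S", "pH_i", "J_co2"}
    if not need <= set(df.columns):
        raise ValueError(f"trace file missing columns {need - set(df.columns)}")
    return df


def write_recording(rec: RawRecording, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": rec.time, "V_m_mV": rec.V_m, "V_pHi_mV": rec.V_pHi_raw,
        "V_pHS_mV": rec.V_pHS_raw, "V_ref_mV": rec.V_ref,
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_events(timeline: ProtocolTimeline, path: str | Path) -> None:
    rows = timeline.events_table()
    pd.DataFrame(rows, columns=["time_s", "event_type", "label"]).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def write_pHi_cal(cal: list[CalPoint], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in cal]).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_pHi_cal(path: str | Path) -> list[CalPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [CalPoint(r.time, r.solution, r.diff_mV, r.anchor_pH)
            for r in df.itertuples()]


def read_recording(path: str | Path, timeline: ProtocolTimeline,
                   cal_path: str | Path | None = None) -> RawRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    cal = read_pHi_cal(cal_path) if cal_path else []
    return RawRecording(
        time=df["time_s"].to_numpy(), V_m=df["V_m_mV"].to_numpy(),
        V_pHi_raw=df["V_pHi_mV"].to_numpy(),
        V_pHS_raw=df["V_pHS_mV"].to_numpy(),
        V_ref=df["V_ref_mV"].to_numpy(), timeline=timeline, pHi_cal=cal)


def read_area_series(path: str | Path, scale: float = 1.0) -> VolumeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "area_cm2" in df.columns:
        area = df["area_cm2"].to_numpy()
    elif "area_px" in df.columns:
        area = df["area_px"].to_numpy() * scale
    else:
        raise ValueError("area file needs an 'area_cm2' or 'area_px' column")
    return VolumeSeries(time=df["time_s"].to_numpy(), area=area, scale=scale)


# ---------------------------------------------------------------------------
# bundles (one synthetic experiment on disk)
# ---------------------------------------------------------------------------
def write_bundle(outdir: str | Path, tr: TrueTraces, rec: RawRecording,
                 condition: OocyteCondition, seed: int,
                 extra_params: dict | None = None) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_true_traces(tr, out / "true_traces.csv")
    write_recording(rec, out / "recording.csv")
    write_events(rec.timeline, out / "events.csv")
    write_pHi_cal(rec.pHi_cal, out / "pHi_cal.csv")
    params = {
        "seed": seed,
        "condition": dataclasses.asdict(condition),
        "timeline": {
            "segments": [
                {"label": s.label, "t0": s.t0, "t1": s.t1,
                 "solution": s.solution.name, "position": s.position,
                 "is_calibration": s.is_calibration}
                for s in rec.timeline.segments],
            "sample_rate": rec.timeline.sample_rate,
            "retraction_cm": rec.timeline.retraction_cm,
        },
        "sim": {
            "pm_co2": tr.config.membrane.pm_co2,
            "A_i": tr.config.chem.A_i,
            "A_o_surface": tr.config.chem.A_o_surface,
            "euf_thickness": tr.config.geometry.euf_thickness,
            "radius": tr.config.geometry.radius,
        },
    }
    if extra_params:
        params.update(extra_params)
    (out / "params.json").write_text(json.dumps(params, indent=2) + "\n")
    return out


def read_bundle(bundle_dir: str | Path):
    """Load a bundle back: (recording, condition, true-trace frame)."""
    b = Path(bundle_dir)
    params = json.loads((b / "params.json").read_text())
    cond = OocyteCondition(**params["condition"])
    # reconstruct the timeline from recorded segment durations
    segs = params["timeline"]["segments"]

    def dur(label):
        s = next(s for s in segs if s["label"] == label)
        return s["t1"] - s["t0"]

    tl = build_protocol(
        init_cal_s=dur("nd96_cal_init"), nd96_dimple_s=dur("nd96_dimple"),
        co2_total_s=dur("co2_dimple_a") + dur("co2_cal") + dur("co2_dimple_b"),
        mid_cal_s=dur("co2_cal"),
        nd96_final_s=dur("nd96_dimple_final") + dur("nd96_cal_final"),
        final_cal_s=dur("nd96_cal_final"),
        sample_rate=params["timeline"]["sample_rate"])
    if cond.bCA:
        from .protocol import with_bca
        tl = with_bca(tl)
    rec = read_recording(b / "recording.csv", tl, b / "pHi_cal.csv")
    true_df = (read_true_traces(b / "true_traces.csv")
               if (b / "true_traces.csv").exists() else None)
    return rec, cond, true_df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------
DEFAULT_CONFIG = {
    "seed": 1,
    "noisy": True,
    "protocol": {"init_cal_s": 60.0, "nd96_dimple_s": 60.0,
                 "co2_total_s": 600.0, "mid_cal_s": 60.0,
                 "nd96_final_s": 600.0, "final_cal_s": 60.0},
    "condition": {"hAQP5": False, "hCAII_ng": 0.0, "bCA": False},
    "electrodes": {"slope": 58.0, "noise_sd": 0.1, "drift_rate": 0.0,
                   "co2_sensitivity_shift": 0.0},
    "stable_window": {"min_duration": 30.0, "min_points": 90,
                      "flatness_threshold": 2e-4},
}


def load_config(path: str | Path | None) -> dict:
    """Read a YAML run configuration, rejecting unknown keys."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key '{key}'")
        if isinstance(cfg[key], dict):
            unknown = set(val) - set(cfg[key])
            if unknown:
                raise ValueError(f"unknown config key(s) {key}.{sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg
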