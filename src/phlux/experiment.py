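"""Model/Results objects tying the pipeline together.

``CO2FluxExperiment`` is built from one oocyte's raw recording (real or
synthetic); ``fit()`` runs subtraction, segment-wise calibration and metric
extraction and returns a ``CO2FluxResults`` carrying the per-oocyte
estimates, quality flags and a ``summary()`` table. ``simulate_experiment``
produces a complete synthetic experiment (ground truth + instrument) for a
given condition and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C
from .instrument import (CalibratedTraces, ElectrodeSet, RawRecording,
                         calibrate_recording, synthesize_voltages,
                         vm_health_gate)
from .metrics import (OocyteCondition, OocyteMetrics, StableWindowSpec,
                      extract_metrics)
from .sim import SimConfig, TrueTraces, config_for_condition, simulate


def simulate_experiment(condition: OocyteCondition = OocyteCondition(),
                        seed: int = 0,
                        electrodes: ElectrodeSet | None = None,
                        noisy: bool = True,
                        base: SimConfig | None = None,
                        timeline=None,
                        true_traces: TrueTraces | None = None
                        ) -> tuple[TrueTraces, RawRecording]:
    """One full synthetic experiment: forward-simulate the condition (or
    reuse supplied ground truth) and synthesize the electrode channels.

    The forward model itself is deterministic; all randomness is the
    instrument noise controlled by ``seed``.
    """
    if true_traces is None:
        cfg = config_for_condition(condition.hAQP5, condition.hCAII_ng,
                                   condition.bCA, base=base,
                                   timeline=timeline)
        cfg = replace(cfg, seed=seed)
        true_traces = simulate(cfg)
    if electrodes is None:
        electrodes = ElectrodeSet() if noisy else ElectrodeSet.noiseless()
    rec = synthesize_voltages(true_traces, electrodes, seed=seed)
    return true_traces, rec


def calibrated_from_truth(tr: TrueTraces) -> CalibratedTraces:
    """Wrap ground-truth traces as CalibratedTraces so every metric can be
    computed directly on the simulator output (the oracle side of
    pipeline-vs-truth comparisons)."""
    tl = tr.config.timeline
    t = tr.time
    labels = np.array([s.label for s in tl.segments])[tl.segment_index(t)]
    return CalibratedTraces(time=t, pH_S=tr.pH_S.copy(), pH_i=tr.pH_i.copy(),
                            V_m=np.zeros(t.size), segment_label=labels,
                            mask=tl.move_mask(t), timeline=tl,
                            calibration=None)


@dataclass
class CO2FluxResults:
    """Per-oocyte results of the flux assay."""
    metrics: OocyteMetrics
    traces: CalibratedTraces
    condition: OocyteCondition
    vm_healthy: bool | None = None

    def summary(self) -> str:
        m = self.metrics
        rows = [
            ("dpHS_up (pH)", m.dpHS_up),
            ("dpHS_down (pH)", m.dpHS_down),
            ("(dpHS/dt)_Max add (pH/s)", m.dpHSdt_max_add),
            ("(dpHS/dt)_Max rem (pH/s)", m.dpHSdt_max_rem),
            ("(dpHi/dt)_Max add (pH/s)", m.dpHidt_max_add),
            ("(dpHi/dt)_Max rem (pH/s)", m.dpHidt_max_rem),
            ("pHi initial (pH)", m.pHi_init),
            ("dpHi (pH)", m.dpHi),
            ("beta_I (mM/pH)", m.beta_I),
        ]
        w = max(len(r[0]) for r in rows)
        head = (f"CO2 flux assay results - condition {self.condition.label()}"
                + ("" if self.vm_healthy is None else
                   f"  [Vm gate: {'ok' if self.vm_healthy else 'FAIL'}]"))
        lines = [head, "-" * len(head)]
        lines += [f"{name:<{w}}  {val:+.5g}" for name, val in rows]
        bad = [k for k, v in m.flags.items() if v is True]
        if bad:
            lines.append("flags: " + ", ".join(bad))
        return "\n".join(lines)

    def to_row(self, oocyte_id: str = "") -> pd.Series:
        return self.metrics.to_row(oocyte_id)

    def plot(self, ax=None):
        """Plot the calibrated pH_S / pH_i traces with segment shading."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        tr = self.traces
        ax.plot(tr.time, tr.pH_S, lw=0.8, color="crimson", label="pH$_S$")
        ax.plot(tr.time, tr.pH_i, lw=0.8, color="seagreen", label="pH$_i$")
        for seg in tr.timeline.segments:
            if seg.is_calibration:
                ax.axvspan(seg.t0, seg.t1, color="0.85", zorder=0)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pH")
        ax.legend(loc="best", frameon=False)
        ax.set_title(self.condition.label())
        return ax


class CO2FluxExperiment:
    """One oocyte's CO2/HCO3- addition-removal experiment.

    Built from a raw recording plus its protocol timeline and condition
    descriptor; ``fit()`` runs the calibration chain and metric extraction.
    """

    def __init__(self, recording: RawRecording,
                 condition: OocyteCondition = OocyteCondition(),
                 slope_pHS: float = 58.0, slope_pHi: float = 58.0,
                 stable_window: StableWindowSpec | None = None,
                 vm_gate: bool = True):
        self.recording = recording
        self.condition = condition
        self.slope_pHS = slope_pHS
        self.slope_pHi = slope_pHi
        self.stable_window = stable_window or StableWindowSpec()
        self.vm_gate = vm_gate

    @classmethod
    def from_synthetic(cls, condition: OocyteCondition = OocyteCondition(),
                       seed: int = 0, noisy: bool = True,
                       **kwargs) -> "CO2FluxExperiment":
        _, rec = simulate_experiment(condition, seed=seed, noisy=noisy)
        return cls(rec, condition, **kwargs)

    def fit(self) -> CO2FluxResults:
        traces = calibrate_recording(self.recording, self.slope_pHS,
                                     self.slope_pHi)
        metrics = extract_metrics(traces, self.condition,
                                  spec=self.stable_window)
        healthy = vm_health_gate(self.recording) if self.vm_gate else None
        return CO2FluxResults(metrics=metrics, traces=traces,
                              condition=self.condition, vm_healthy=healthy)


class SynergyStudy:
    """Cohort-level model: a metrics table over conditions.

    ``fit()`` returns the ANOVA/Tukey report for a metric and the
    delta-delta-delta synergy diagnostic for a chosen CA axis/modifier.
    """

    def __init__(self, table: pd.DataFrame, metric: str = "dpHS_up",
                 ca_axis: str = "hCAII", mod_axis: str = "hAQP5"):
        self.table = table
        self.metric = metric
        self.ca_axis = ca_axis
        self.mod_axis = mod_axis

    def fit(self):
        from .stats import anova_tukey, delta_delta
        rep = anova_tukey(self.table, self.metric)
        dd = delta_delta(self.table, self.metric, self.ca_axis, self.mod_axis)
        return SynergyResults(anova=rep, ddd=dd, metric=self.metric)


@dataclass
class SynergyResults:
    anova: "object"
    ddd: "object"
    metric: str

    def summary(self) -> str:
        return (f"metric {self.metric}: omnibus F = {self.anova.F:.3f} "
                f"(p = {self.anova.p_omnibus:.3g});\n" + self.ddd.summary())
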