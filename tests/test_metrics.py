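"""Trace metrics: stable windows, excursions, DExp derivative, buffering."""
import numpy as np
import pytest

from phlux.experiment import calibrated_from_truth, simulate_experiment
from phlux.instrument import CalibratedTraces, calibrate_recording
from phlux.metrics import (MetricError, OocyteCondition, StableWindowSpec,
                           buffering_power, delta_pHS, dphi_dt_max,
                           dphs_dt_max, extract_metrics,
                           fit_dexp_and_derivative, locate_tlocal_zero,
                           stable_tail_mean)
from phlux.protocol import build_protocol
from tests.conftest import condition_for


def synthetic_traces(tl, pH_S, pH_i=None):
    t = tl.times()
    labels = np.array([s.label for s in tl.segments])[tl.segment_index(t)]
    phi = np.asarray(pH_i, float) if pH_i is not None else np.full(t.size, 7.3)
    return CalibratedTraces(
        time=t, pH_S=np.asarray(pH_S, float), pH_i=phi,
        V_m=np.zeros(t.size), segment_label=labels,
        mask=tl.move_mask(t), timeline=tl)


class TestStableTail:
    def test_constant_segment(self):
        t = np.arange(0, 60, 1 / 3)
        mean, stable = stable_tail_mean(t, np.full(t.size, 7.5))
        assert mean == pytest.approx(7.50)
        assert stable

    def test_ramp_flagged_unstable_with_fallback(self):
        t = np.arange(0, 60, 1 / 3)
        y = 7.5 + 1e-3 * t                     # 1 mpH/s, above threshold
        mean, stable = stable_tail_mean(t, y)
        assert not stable
        assert mean == pytest.approx(y[-90:].mean())

    def test_short_segment_errors(self):
        t = np.arange(0, 10, 1 / 3)
        with pytest.raises(MetricError, match="shorter"):
            stable_tail_mean(t, np.full(t.size, 7.5))


class TestDeltaPHS:
    def test_constructed_excursions(self):
        """Baseline 7.500, CO2 peak 7.620, CO2 tail 7.500, ND96 nadir 7.370
        -> (+0.120, -0.130)."""
        tl = build_protocol()
        t = tl.times()
        y = np.full(t.size, 7.5)
        on = tl.segment("co2_dimple_a").t0
        off = tl.segment("nd96_dimple_final").t0
        # 40 s plateaus well inside the segments (flat vs the smoother)
        y[(t >= on + 30) & (t < on + 70)] = 7.620
        y[(t >= off + 30) & (t < off + 70)] = 7.370
        up, down, flags = delta_pHS(synthetic_traces(tl, y))
        assert up == pytest.approx(0.120, abs=1e-9)
        assert down == pytest.approx(-0.130, abs=1e-9)
        assert not flags["baseline_unstable"]

    def test_flat_trace_zero_excursions(self):
        tl = build_protocol()
        up, down, _ = delta_pHS(synthetic_traces(tl, np.full(tl.times().size, 7.5)))
        assert up == pytest.approx(0.0, abs=1e-12)
        assert down == pytest.approx(0.0, abs=1e-12)

    def test_permeability_factor_raises_up_excursion(self, truth_grid):
        base = delta_pHS(calibrated_from_truth(truth_grid[(False, False, False)]))[0]
        aqp = delta_pHS(calibrated_from_truth(truth_grid[(True, False, False)]))[0]
        assert aqp > base


class TestTLocalZero:
    def test_pure_decay_earliest_window(self):
        t = np.arange(0, 120, 1 / 3)
        y = 7.5 + 0.1 * np.exp(-t / 30)
        t0, s = locate_tlocal_zero(t, y, 5.0, "falling")
        assert t0 == pytest.approx(t[:15].mean())  # first admissible window
        assert s == pytest.approx(-0.1 / 30, rel=0.10)

    def test_sigmoid_inflection_located(self):
        t = np.arange(0, 120, 1 / 3)
        y = 7.5 - 0.1 / (1 + np.exp(-(t - 50) / 10))
        t0, _ = locate_tlocal_zero(t, y, 5.0, "falling")
        assert t0 == pytest.approx(50.0, abs=1.0)

    def test_flat_segment_tie_breaks_earliest(self):
        t = np.arange(0, 60, 1 / 3)
        t0, s = locate_tlocal_zero(t, np.full(t.size, 7.5), 5.0, "falling")
        assert s == 0.0
        assert t0 == pytest.approx(t[:15].mean())

    def test_too_short_errors(self):
        with pytest.raises(MetricError):
            locate_tlocal_zero(np.arange(3.0), np.zeros(3), 5.0)


class TestDExp:
    TRUE = -(0.05 / 20 + 0.02 / 200)  # -A1/tau1 - A2/tau2 = -0.0026

    def test_noiseless_self_generated_recovery(self):
        t = np.arange(0, 300, 1 / 3)
        y = 7.5 + 0.05 * np.exp(-t / 20) + 0.02 * np.exp(-t / 200)
        fit = fit_dexp_and_derivative(t, y)
        assert not fit.single_exp_fallback
        assert fit.derivative_at_zero == pytest.approx(self.TRUE, rel=1e-4)
        assert fit.tau1 <= fit.tau2
        # derivative equals the (central) finite difference of the fitted
        # curve at the local time origin
        h = 1e-3
        fd = float((fit.predict(np.array([h]))[0]
                    - fit.predict(np.array([-h]))[0]) / (2 * h))
        assert fit.derivative_at_zero == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_recovery_within_ten_percent(self, seed):
        t = np.arange(0, 300, 1 / 3)
        y = 7.5 + 0.05 * np.exp(-t / 20) + 0.02 * np.exp(-t / 200)
        rng = np.random.default_rng(4000 + seed)
        fit = fit_dexp_and_derivative(t, y + rng.normal(0, 0.002, t.size))
        assert fit.derivative_at_zero == pytest.approx(self.TRUE, rel=0.10)

    def test_single_exponential_truth_triggers_fallback(self):
        t = np.arange(0, 300, 1 / 3)
        y = 7.5 + 0.05 * np.exp(-t / 30)
        fit = fit_dexp_and_derivative(t, y)
        assert fit.single_exp_fallback
        assert fit.derivative_at_zero == pytest.approx(-0.05 / 30, rel=0.01)

    def test_too_few_samples_errors(self):
        with pytest.raises(MetricError):
            fit_dexp_and_derivative(np.arange(10.0), np.zeros(10))


class TestDpHiDt:
    def test_linear_ramp_recovered_exactly(self):
        tl = build_protocol()
        t = tl.times()
        phi = 7.3 - 2e-3 * np.clip(t - tl.segment("co2_dimple_a").t0, 0, None)
        rate, _ = dphi_dt_max(synthetic_traces(tl, np.full(t.size, 7.5), phi),
                              "addition")
        assert rate == pytest.approx(-2e-3, rel=1e-6)

    def test_flat_trace_zero(self):
        tl = build_protocol()
        t = tl.times()
        rate, _ = dphi_dt_max(synthetic_traces(tl, np.full(t.size, 7.5)),
                              "addition")
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_extracellular_ca_magnifies_acidification(self, truth_grid):
        plain = dphi_dt_max(calibrated_from_truth(
            truth_grid[(False, False, False)]), "addition")[0]
        bca = dphi_dt_max(calibrated_from_truth(
            truth_grid[(False, False, True)]), "addition")[0]
        assert abs(bca) > abs(plain)


class TestBufferingPower:
    def test_hand_evaluated_example(self):
        res = buffering_power(7.30, 7.10)
        assert res.dHCO3_mM == pytest.approx(10 * 10 ** (-0.40), rel=1e-12)
        assert res.beta_I == pytest.approx(res.dHCO3_mM / 0.20, rel=1e-12)
        assert res.beta_I == pytest.approx(19.905, abs=0.01)

    def test_tail_at_anchor_gives_bulk_hco3_exactly(self):
        res = buffering_power(7.70, 7.50)
        assert res.dHCO3_mM == pytest.approx(10.0, rel=1e-12)
        assert res.beta_I == pytest.approx(50.0, rel=1e-12)

    def test_no_acid_load_errors(self):
        with pytest.raises(MetricError, match="no acid load"):
            buffering_power(7.30, 7.30)
        with pytest.raises(MetricError):
            buffering_power(7.10, 7.30)
        with pytest.raises(ValueError):
            buffering_power(7.3, 7.1, hco3_bulk_mM=0.0)


class TestExtractMetrics:
    def test_sign_conventions_on_synthetic_run(self, truth_grid):
        for key in [(False, False, False), (True, True, False),
                    (True, False, True)]:
            m = extract_metrics(calibrated_from_truth(truth_grid[key]),
                                condition_for(key))
            assert m.dpHS_up >= 0
            assert m.dpHS_down <= 0
            assert m.dpHSdt_max_add <= 0
            assert m.dpHSdt_max_rem >= 0
            assert m.dpHidt_max_add <= 0
            assert m.dpHidt_max_rem >= 0
            assert m.dpHi <= 0
            assert m.beta_I > 0

    def test_pipeline_equals_truth_on_noise_free_grid(self, truth_grid):
        """Metrics through the full instrument + calibration chain equal
        metrics computed directly on ground truth (2x2x2 grid)."""
        for key, tr in truth_grid.items():
            _, rec = simulate_experiment(true_traces=tr, seed=0, noisy=False)
            via_pipe = extract_metrics(calibrate_recording(rec),
                                       condition_for(key))
            via_truth = extract_metrics(calibrated_from_truth(tr),
                                        condition_for(key))
            for fname in ("dpHS_up", "dpHS_down", "pHi_init", "dpHi"):
                assert getattr(via_pipe, fname) == pytest.approx(
                    getattr(via_truth, fname), abs=0.005), (key, fname)
            for fname in ("dpHSdt_max_add", "dpHSdt_max_rem",
                          "dpHidt_max_add", "dpHidt_max_rem"):
                assert getattr(via_pipe, fname) == pytest.approx(
                    getattr(via_truth, fname), rel=0.05, abs=1e-6), (key, fname)
            assert via_pipe.beta_I == pytest.approx(via_truth.beta_I, rel=0.05)

    def test_flat_traces_flag_no_acid_load(self):
        tl = build_protocol()
        t = tl.times()
        m = extract_metrics(synthetic_traces(tl, np.full(t.size, 7.5)))
        assert m.flags.get("no_acid_load")
        assert np.isnan(m.beta_I)
        assert m.dpHS_up == pytest.approx(0.0, abs=1e-12)
        assert m.dpHidt_max_add == pytest.approx(0.0, abs=1e-12)

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            OocyteCondition(hCAII_ng=5.0)
        assert OocyteCondition(True, 100.0, True).label() == \
            "+hAQP5/+hCAII100/+bCA"


def test_stable_window_spec_consistency():
    with pytest.raises(ValueError):
        StableWindowSpec(min_duration=10.0, min_points=90)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------
from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=50, derandomize=True, deadline=None)
@given(pHi_init=st.floats(6.9, 7.7), drop=st.floats(0.01, 0.6),
       hco3=st.floats(1.0, 30.0))
def test_buffering_power_positive_and_linear_in_bulk_hco3(pHi_init, drop,
                                                          hco3):
    """beta_I is positive for any genuine acid load and scales linearly
    with the bulk HCO3- used in the shorthand."""
    res = buffering_power(pHi_init, pHi_init - drop, hco3_bulk_mM=hco3)
    assert res.beta_I > 0
    res2 = buffering_power(pHi_init, pHi_init - drop, hco3_bulk_mM=2 * hco3)
    assert res2.beta_I == pytest.approx(2 * res.beta_I, rel=1e-9)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(shift=st.floats(-0.3, 0.3), scale=st.floats(0.25, 4.0),
       a1=st.floats(0.01, 0.1), tau=st.floats(10.0, 60.0))
def test_tlocal_zero_invariant_to_offset_and_gain(shift, scale, a1, tau):
    """The located time origin does not move under affine transforms of the
    trace; the extreme slope scales with the gain."""
    t = np.arange(0, 120, 1 / 3)
    y = 7.5 + a1 * np.exp(-t / tau)
    t0, s0 = locate_tlocal_zero(t, y, 5.0, "falling")
    t1, s1 = locate_tlocal_zero(t, shift + scale * y, 5.0, "falling")
    assert t0 == t1
    assert s1 == pytest.approx(scale * s0, rel=1e-9)
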