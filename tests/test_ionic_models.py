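"""Cell models: resting stability, gating bounds, clamp linearity, numerics."""

import numpy as np
import pytest

from chronocard.cell_protocols import ap_metrics, default_stim_amplitude
from chronocard.ionic_models import (IntegrationError, build_human_model,
                                     build_mouse_model, integrate_cell,
                                     pacing_protocol, voltage_clamp)
from chronocard.ionic_models.base import StimulusProtocol

QUIET = StimulusProtocol(np.array([1e12]), np.array([1.0]), np.array([0.0]))


class TestRestingBehaviour:
    def test_mouse_quiescent_one_second(self, mouse_model):
        tr = integrate_cell(mouse_model, QUIET, 1000.0, record_dt=1.0)
        assert abs(tr.final_state[0] - mouse_model.resting_vm) < 0.5
        assert tr.vm.max() < mouse_model.resting_vm + 5.0  # no spontaneous AP

    def test_human_quiescent_ten_seconds(self, human_model):
        tr = integrate_cell(human_model, QUIET, 10_000.0, record_dt=10.0)
        assert abs(tr.vm[-1] - tr.vm[0]) < 0.5

    def test_mouse_resting_potential_documented(self, mouse_model):
        assert -85.0 < mouse_model.resting_vm < -75.0


class TestActionPotentials:
    def test_mouse_ap_is_mouse_like(self, mouse_steady):
        met = mouse_steady["ZT0"]["metrics"]
        assert met.apd90 < 40.0
        assert met.dvdt_max > 100.0
        assert met.overshoot > 0.0

    def test_human_apd90_in_documented_range(self, human_steady):
        assert 250.0 <= human_steady["ZT0"]["metrics"].apd90 <= 320.0

    def test_species_contrast(self, mouse_steady, human_steady):
        assert mouse_steady["ZT0"]["metrics"].apd90 < \
            human_steady["ZT0"]["metrics"].apd90

    def test_mouse_without_fast_sodium_fails_overshoot(self):
        model = build_mouse_model({"g_Na": 0.0})
        amp = default_stim_amplitude(build_mouse_model())
        tr = integrate_cell(model, pacing_protocol(150.0, 1, amp), 150.0,
                            record_dt=0.05)
        assert tr.vm.max() < 0.0

    def test_human_ikr_block_prolongs_apd(self, human_steady):
        from chronocard.cell_protocols import pace_to_steady_state
        blocked = build_human_model({"g_Kr": 0.0})
        _, beat, _ = pace_to_steady_state(blocked, 1000.0, dt=0.02,
                                          min_beats=20, max_beats=40)
        assert ap_metrics(beat).apd90 > human_steady["ZT0"]["metrics"].apd90

    def test_human_dome_morphology(self, human_steady):
        beat = human_steady["ZT0"]["beat"]
        plateau_ms = np.sum(beat.vm > 0.0) * np.median(np.diff(beat.times))
        assert plateau_ms > 100.0


class TestIntegration:
    def test_zero_stimulus_stays_at_rest(self, mouse_model):
        stim = StimulusProtocol(np.array([10.0]), np.array([1.0]),
                                np.array([0.0]))
        tr = integrate_cell(mouse_model, stim, 100.0, record_dt=0.5)
        assert np.all(np.abs(tr.vm - mouse_model.resting_vm) < 0.5)

    def test_deterministic_repeat(self, mouse_model):
        amp = default_stim_amplitude(mouse_model)
        stim = pacing_protocol(150.0, 2, amp)
        a = integrate_cell(mouse_model, stim, 300.0, record_dt=0.1)
        b = integrate_cell(mouse_model, stim, 300.0, record_dt=0.1)
        assert np.array_equal(a.vm, b.vm)
        assert np.array_equal(a.final_state, b.final_state)

    def test_gating_variables_bounded(self, mouse_model, human_model):
        for model in (mouse_model, human_model):
            amp = default_stim_amplitude(model)
            bcl = 150.0 if "mouse" in model.name else 1000.0
            stim = pacing_protocol(bcl, 3, amp)
            tr = integrate_cell(model, stim, 3 * bcl)
            gates = tr.final_state[model.gating_indices]
            assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_apd90_converges_when_dt_halved(self, mouse_model):
        # 10 paced beats at dt = 0.005 vs 0.0025 ms
        amp = default_stim_amplitude(mouse_model)
        apds = {}
        for dt in (0.005, 0.0025):
            state = mouse_model.initial_state.copy()
            for _ in range(10):
                tr = integrate_cell(mouse_model,
                                    pacing_protocol(150.0, 1, amp), 150.0,
                                    dt=dt, state=state, record_dt=0.025)
                state = tr.final_state
            apds[dt] = ap_metrics(tr).apd90
        assert abs(apds[0.005] - apds[0.0025]) / apds[0.0025] < 0.01

    def test_divergence_aborts_with_diagnostic(self, mouse_model):
        huge = StimulusProtocol(np.array([1.0]), np.array([50.0]),
                                np.array([5000.0]))
        with pytest.raises(IntegrationError):
            integrate_cell(mouse_model, huge, 100.0)


class TestParameterHandling:
    def test_negative_override_rejected(self):
        with pytest.raises(ValueError):
            build_mouse_model({"g_Na": -1.0})
        with pytest.raises(ValueError):
            build_human_model({"g_Kr": -0.1})

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            build_mouse_model({"g_funny": 1.0})

    def test_current_breakdown_sums_to_total(self, mouse_model, human_model):
        for model in (mouse_model, human_model):
            d = model.currents(model.initial_state)
            parts = sum(v for k, v in d.items() if k != "I_total")
            assert d["I_total"] == pytest.approx(parts, abs=1e-12)


class TestVoltageClamp:
    def test_ina_iv_peak_between_minus40_and_minus20(self, mouse_model):
        iv = voltage_clamp(mouse_model, holding_mv=-80.0,
                           step_mvs=np.arange(-60.0, 21.0, 5.0),
                           step_duration_ms=30.0, current_label="I_Na",
                           measure="peak")
        k = int(np.argmin(iv.currents))  # most negative = inward peak
        assert iv.currents[k] < 0
        assert -40.0 <= iv.voltages[k] <= -20.0

    def test_holding_only_gives_background_current(self, mouse_model):
        iv = voltage_clamp(mouse_model, holding_mv=-80.0, step_mvs=[-80.0],
                           step_duration_ms=50.0, current_label="I_Na",
                           measure="end")
        assert abs(iv.currents[0]) < 0.1

    def test_peak_current_linear_in_conductance(self, mouse_model):
        # doubling g_Kr doubles end-pulse I_Kr at every step
        doubled = mouse_model.with_params(
            g_Kr=2 * mouse_model.get_param("g_Kr"))
        steps = np.arange(-20.0, 41.0, 20.0)
        base = voltage_clamp(mouse_model, -80.0, steps, 300.0, "I_Kr",
                             measure="end")
        dbl = voltage_clamp(doubled, -80.0, steps, 300.0, "I_Kr",
                            measure="end")
        assert np.allclose(dbl.currents, 2 * base.currents, rtol=1e-9)

    def test_unknown_current_label_rejected(self, mouse_model):
        with pytest.raises(KeyError):
            voltage_clamp(mouse_model, -80.0, [0.0], 10.0, "I_nonexistent")

    def test_blocker_subtraction_isolates_channel(self, mouse_model):
        with_b = voltage_clamp(mouse_model, -80.0, [20.0], 300.0, "I_Kr",
                               measure="end", blocker_mode=True)
        plain = voltage_clamp(mouse_model, -80.0, [20.0], 300.0, "I_Kr",
                              measure="end", blocker_mode=False)
        assert with_b.currents[0] == pytest.approx(plain.currents[0], rel=1e-9)
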