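"""Cable propagation: causality, CV scaling, S2 outcome classification, PES."""

import numpy as np
import pytest

from chronocard.cable_sim import (CableConfig, activation_time,
                                  build_pes_train, cable_stim_amplitude,
                                  conduction_velocity, s1_stimulus,
                                  simulate_cable, wavelength)
from chronocard.ionic_models.base import StimulusProtocol


@pytest.fixture(scope="module")
def single_wave(mouse_model, cable_config):
    amp = cable_stim_amplitude(mouse_model, cable_config)
    tr = simulate_cable(mouse_model, cable_config,
                        s1_stimulus(cable_config, 1000.0, 1, amp), 80.0)
    return tr


class TestPropagation:
    def test_no_stimulus_uniform_resting_sheet(self, mouse_model,
                                               cable_config):
        quiet = StimulusProtocol(np.array([1e12]), np.array([1.0]),
                                 np.array([0.0]))
        tr = simulate_cable(mouse_model, cable_config, quiet, 50.0)
        assert np.all(np.abs(tr.vm - mouse_model.resting_vm) < 0.5)

    def test_activation_time_increases_with_distance(self, single_wave):
        acts = [activation_time(single_wave.times, single_wave.vm[:, k])
                for k in range(10, single_wave.positions.size - 5, 10)]
        assert np.all(np.isfinite(acts))
        assert np.all(np.diff(acts) > 0)

    def test_cv_in_physiological_range(self, single_wave):
        cv = conduction_velocity(single_wave)
        assert 0.3 <= cv <= 0.6

    def test_cv_converges_when_dx_halved(self, mouse_model, cable_config):
        cvs = {}
        for dx in (0.05, 0.025):
            cfg = CableConfig(dx=dx)
            amp = cable_stim_amplitude(mouse_model, cfg, dt=0.005)
            tr = simulate_cable(mouse_model, cfg,
                                s1_stimulus(cfg, 1000.0, 1, amp), 80.0,
                                dt=0.005)
            cvs[dx] = conduction_velocity(tr)
        assert abs(cvs[0.05] - cvs[0.025]) / cvs[0.025] < 0.02

    def test_cv_scales_with_sqrt_diffusion(self, mouse_model):
        # continuous-cable theory: CV ∝ √D; R² > 0.99 over a 4x range
        ds = np.array([0.025, 0.05, 0.075, 0.1])
        cvs = []
        for d in ds:
            cfg = CableConfig(diffusion=float(d))
            amp = cable_stim_amplitude(mouse_model, cfg, dt=0.01)
            tr = simulate_cable(mouse_model, cfg,
                                s1_stimulus(cfg, 1000.0, 1, amp), 100.0,
                                dt=0.01)
            cvs.append(conduction_velocity(tr))
        cvs = np.array(cvs)
        x = np.sqrt(ds)
        slope = (x * cvs).sum() / (x * x).sum()  # through-origin fit
        r2 = 1 - np.sum((cvs - slope * x) ** 2) / np.sum((cvs - cvs.mean()) ** 2)
        assert r2 > 0.99
        # doubling D multiplies CV by ~sqrt(2)
        assert cvs[3] / cvs[1] == pytest.approx(np.sqrt(2.0), rel=0.03)

    def test_symmetric_midpoint_stimulus_equal_cv(self, mouse_model,
                                                  cable_config):
        amp = cable_stim_amplitude(mouse_model, cable_config)
        n = cable_config.n_nodes
        # ~1-mm interior site; doubled amplitude against two-sided loading
        mid = StimulusProtocol(np.array([1.0]), np.array([1.0]),
                               np.array([2 * amp]),
                               np.array([n // 2 - 10], dtype=np.int64),
                               np.array([n // 2 + 11], dtype=np.int64))
        tr = simulate_cable(mouse_model, cable_config, mid, 60.0)
        t = tr.times
        c = n // 2
        off = 60
        t_c = activation_time(t, tr.vm[:, c])
        t_l = activation_time(t, tr.vm[:, c - off])
        t_r = activation_time(t, tr.vm[:, c + off])
        assert t_l - t_c == pytest.approx(t_r - t_c, rel=0.02)

    def test_unstable_diffusion_settings_rejected(self, mouse_model):
        cfg = CableConfig(diffusion=0.4)
        stim = s1_stimulus(cfg, 1000.0, 1, 60.0)
        with pytest.raises(ValueError, match="unstable"):
            simulate_cable(mouse_model, cfg, stim, 10.0, dt=0.05)

    def test_deterministic_bit_reproducible(self, mouse_model, cable_config):
        amp = 60.0
        stim = s1_stimulus(cable_config, 1000.0, 1, amp)
        a = simulate_cable(mouse_model, cable_config, stim, 40.0)
        b = simulate_cable(mouse_model, cable_config, stim, 40.0)
        assert np.array_equal(a.vm, b.vm)


class TestVulnerableWindow:
    def test_outcomes_ordered_in_interval(self, mouse_vw):
        order = {"no_capture": 0, "unidirectional": 1, "bidirectional": 2}
        for vw in mouse_vw.values():
            labs = [lab for _, lab in sorted(vw.outcomes.items())
                    if lab in order]
            codes = [order[lab] for lab in labs]
            assert codes == sorted(codes), "outcome ordering not monotone"

    def test_width_consistent_with_bounds(self, mouse_vw):
        for vw in mouse_vw.values():
            if np.isfinite(vw.vw_lower):
                assert vw.width == pytest.approx(vw.vw_upper - vw.vw_lower)
                assert vw.width >= 0

    def test_zt12_window_wider_than_zt0(self, mouse_vw):
        assert mouse_vw["ZT12"].width > mouse_vw["ZT0"].width

    def test_grko_window_equals_zt0(self, mouse_vw):
        assert mouse_vw["ZT12_GRKO"].width == pytest.approx(
            mouse_vw["ZT0"].width, abs=0.25)

    def test_no_capture_below_unidirectional_above_bidirectional(self,
                                                                 mouse_vw):
        vw = mouse_vw["ZT12"]
        for interval, lab in vw.outcomes.items():
            if interval < vw.vw_lower - 0.3:
                assert lab == "no_capture"
            elif interval > vw.vw_upper + 0.3:
                assert lab == "bidirectional"


class TestWavelength:
    def test_arithmetic(self):
        assert wavelength(50.0, 0.4) == pytest.approx(20.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            wavelength(0.0, 0.4)
        with pytest.raises(ValueError):
            wavelength(50.0, -0.1)

    def test_zt12_wavelength_shorter(self, mouse_steady, mouse_cv):
        wl = {s: wavelength(mouse_steady[s]["metrics"].apd90,
                            mouse_cv[(s, 150.0)])
              for s in ("ZT0", "ZT12", "ZT12_GRKO")}
        assert wl["ZT12"] < wl["ZT0"]
        assert wl["ZT12_GRKO"] == pytest.approx(wl["ZT0"], rel=1e-6)


class TestDiurnalCV:
    def test_zt12_cv_lower_at_every_bcl(self, mouse_cv):
        for bcl in (150.0, 200.0, 300.0):
            assert mouse_cv[("ZT12", bcl)] < mouse_cv[("ZT0", bcl)]

    def test_grko_cv_equals_zt0(self, mouse_cv):
        for bcl in (150.0, 200.0, 300.0):
            assert mouse_cv[("ZT12_GRKO", bcl)] == pytest.approx(
                mouse_cv[("ZT0", bcl)], rel=1e-9)


class TestPESTrain:
    def test_default_protocol_structure(self):
        pes = build_pes_train()
        starts = pes.start_ms
        # 20 S1 at 98 ms
        assert np.allclose(np.diff(starts[:20]), 98.0)
        # first extra-stimulus train at 58-ms cycle length
        assert np.allclose(np.diff(starts[19:29]), 58.0)
        # last train at 8-ms cycle length
        assert np.allclose(np.diff(starts[-9:]), 8.0)
        # 6 trains of the 58 -> 8 sweep
        assert starts.size == 20 + 6 * 9

    def test_single_conditioning_beat(self):
        pes = build_pes_train(s1_count=1)
        assert pes.start_ms.size == 1 + 6 * 9
        assert pes.start_ms[0] == 0.0

    def test_invalid_sweep_rejected(self):
        with pytest.raises(ValueError):
            build_pes_train(s2_start=8.0, s2_end=58.0)
        with pytest.raises(ValueError):
            build_pes_train(s2_decrement=0.0)
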