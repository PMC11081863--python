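"""Shared fixtures: models, scenarios, and cached expensive simulations.

Session-scoped fixtures hold paced steady states, conduction velocities and
vulnerable-window maps so that directional comparisons across test modules
reuse one simulation per scenario.
"""

from __future__ import annotations

import numpy as np
import pytest

from chronocard.cable_sim import (CableConfig, cable_stim_amplitude,
                                  conduction_velocity, s1_stimulus,
                                  simulate_cable, vulnerability_window)
from chronocard.cell_protocols import (ap_metrics, pace_to_steady_state,
                                       restitution)
from chronocard.diurnal_scaling import apply_scenario, builtin_scenarios
from chronocard.ionic_models import build_human_model, build_mouse_model

SCENARIO_IDS = ("ZT0", "ZT12", "ZT12_GRKO")


@pytest.fixture(scope="session")
def mouse_model():
    return build_mouse_model()


@pytest.fixture(scope="session")
def human_model():
    return build_human_model()


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def cable_config():
    return CableConfig()


@pytest.fixture(scope="session")
def mouse_steady(mouse_model, scenarios):
    """Per-scenario steady-state pacing of the mouse cell at BCL 150 ms."""
    out = {}
    for sid in SCENARIO_IDS:
        mod = apply_scenario(mouse_model, scenarios[sid])
        state, beat, info = pace_to_steady_state(mod, 150.0, dt=0.005)
        out[sid] = {"state": state, "beat": beat, "info": info,
                    "metrics": ap_metrics(beat)}
    return out


@pytest.fixture(scope="session")
def human_steady(human_model, scenarios):
    """Per-scenario steady-state pacing of the human cell at BCL 1000 ms."""
    out = {}
    for sid in SCENARIO_IDS:
        mod = apply_scenario(human_model, scenarios[sid])
        state, beat, info = pace_to_steady_state(mod, 1000.0, dt=0.02)
        out[sid] = {"state": state, "beat": beat, "info": info,
                    "metrics": ap_metrics(beat)}
    return out


@pytest.fixture(scope="session")
def mouse_cv(mouse_model, scenarios, cable_config):
    """Conduction velocity per scenario and BCL on the default cable."""
    out = {}
    for sid in SCENARIO_IDS:
        sc = scenarios[sid]
        mod = apply_scenario(mouse_model, sc)
        amp = cable_stim_amplitude(mod, cable_config, sc.coupling_scale)
        for bcl in (150.0, 200.0, 300.0):
            state, _, _ = pace_to_steady_state(mod, bcl, dt=0.005,
                                               amplitude=amp)
            Y0 = np.tile(state, (cable_config.n_nodes, 1))
            tr = simulate_cable(mod, cable_config,
                                s1_stimulus(cable_config, bcl, 3, amp),
                                3 * bcl, coupling_scale=sc.coupling_scale,
                                state=Y0)
            out[(sid, bcl)] = conduction_velocity(tr, t_min=2 * bcl)
    return out


@pytest.fixture(scope="session")
def mouse_vw(mouse_model, scenarios):
    """Vulnerable window per scenario at S1 BCL 200 ms (0.25-ms edges)."""
    out = {}
    for sid in SCENARIO_IDS:
        out[sid] = vulnerability_window(mouse_model, scenarios[sid],
                                        s1_bcl=200.0, coarse_step=1.0,
                                        refine_step=0.25)
    return out


@pytest.fixture(scope="session")
def mouse_restitution(mouse_model, scenarios):
    """Restitution at S1 BCL 300 ms for ZT0 and ZT12."""
    out = {}
    for sid in ("ZT0", "ZT12"):
        mod = apply_scenario(mouse_model, scenarios[sid])
        out[sid] = restitution(mod, s1_bcl=300.0, dt=0.005)
    return out
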