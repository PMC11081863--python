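"""Voltage-clamp harnesses producing current-voltage relationships.

Mirrors the experimental protocols used for diurnal current measurements:
depolarizing steps from a holding potential, with the peak current reported
for fast inward (I_Na-type) currents and the end-of-pulse or tail current
for slowly activating (I_Kr-type) currents.  ``blocker_mode`` computes a
difference current — the run with the channel intact minus the run with
its conductance zeroed — mirroring pharmacological subtraction (E-4031 for
I_Kr).
"""

from __future__ import annotations

import numpy as np

from ..rhythm_stats import IVCurve
from .base import MembraneModel, _drive_clamp

__all__ = ["voltage_clamp", "clamp_current_trace"]


def clamp_current_trace(model: MembraneModel, v_command: np.ndarray,
                        current_label: str, dt: float = 0.01,
                        state: np.ndarray | None = None) -> np.ndarray:
    """Current of one species under an arbitrary voltage-command waveform.

    v_command holds the clamped potential at every integration step; the
    returned array has the same length.
    """
    if current_label not in model.current_names:
        raise KeyError(f"{model.name} exposes no current {current_label!r}")
    idx = model.current_names.index(current_label)
    y = (model.initial_state if state is None else state).copy()
    i_rec = np.empty(v_command.size)
    _drive_clamp(model.step_all, model.currents_fn, y, model.params, dt,
                 np.asarray(v_command, dtype=float),
                 len(model.current_names), idx, i_rec)
    return i_rec


def _step_command(holding_mv: float, step_mv: float, hold_ms: float,
                  step_ms: float, tail_ms: float, dt: float) -> np.ndarray:
    n_hold = int(round(hold_ms / dt))
    n_step = int(round(step_ms / dt))
    n_tail = int(round(tail_ms / dt))
    return np.concatenate([
        np.full(n_hold, holding_mv),
        np.full(n_step, step_mv),
        np.full(n_tail, holding_mv),
    ])


def voltage_clamp(model: MembraneModel, holding_mv: float, step_mvs,
                  step_duration_ms: float, current_label: str,
                  measure: str = "peak", blocker_mode: bool = False,
                  hold_ms: float = 200.0, tail_ms: float = 0.0,
                  dt: float = 0.01) -> IVCurve:
    """Step-protocol IV curve for one membrane current.

    measure:
      "peak"  — extremum-magnitude current during the step (I_Na protocols)
      "end"   — current at the end of the depolarizing pulse (I_Kr protocols)
      "tail"  — extremum-magnitude current during the post-step tail
                (requires tail_ms > 0)

    With blocker_mode the measured trace is the difference between the
    intact model and the model with that conductance zeroed, as with a
    specific channel blocker.
    """
    if measure not in ("peak", "end", "tail"):
        raise ValueError("measure must be 'peak', 'end' or 'tail'")
    if measure == "tail" and tail_ms <= 0:
        raise ValueError("tail measurement requires tail_ms > 0")
    steps = np.asarray(step_mvs, dtype=float)
    values = np.empty(steps.size)
    blocked = None
    if blocker_mode:
        gname = model.conductance_params.get(current_label)
        if gname is None:
            raise KeyError(f"no conductance mapped for {current_label!r}")
        blocked = model.with_params(**{gname: 0.0})
    n_step = int(round(step_duration_ms / dt))
    n_tail = int(round(tail_ms / dt))
    for si, v_step in enumerate(steps):
        cmd = _step_command(holding_mv, v_step, hold_ms, step_duration_ms,
                            tail_ms, dt)
        trace = clamp_current_trace(model, cmd, current_label, dt=dt)
        if blocked is not None:
            trace = trace - clamp_current_trace(blocked, cmd, current_label, dt=dt)
        n_hold = cmd.size - n_step - n_tail
        if measure == "peak":
            seg = trace[n_hold:n_hold + n_step]
        elif measure == "end":
            seg = trace[n_hold + n_step - 1:n_hold + n_step]
        else:
            seg = trace[n_hold + n_step:]
        values[si] = seg[np.argmax(np.abs(seg))]
    order = np.argsort(steps)
    return IVCurve(voltages=steps[order], currents=values[order],
                   label=current_label)
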