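"""Single-cell pacing experiments: AP metrics and S1-S2 restitution.

Protocols mirror the single-myocyte simulation experiments of the diurnal
comparison: steady-state pacing at a fixed basic cycle length (BCL),
action-potential metrics (upstroke velocity, amplitude, APD90), and the
standard S1-S2 restitution protocol in which a single premature stimulus
follows a steady drive train.

APD90 is measured from the instant of maximum upstroke velocity to the
crossing of 90% repolarization (overshoot − 0.9·amplitude), with linear
interpolation between samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ionic_models.base import (CellTrace, MembraneModel, StimulusProtocol,
                                integrate_cell, pacing_protocol)

__all__ = [
    "APMetrics",
    "RestitutionCurve",
    "CaptureError",
    "ap_metrics",
    "diastolic_threshold",
    "default_stim_amplitude",
    "pace_to_steady_state",
    "restitution",
]

log = logging.getLogger(__name__)

#: capture criterion: overshoot above this voltage within the capture window
CAPTURE_VM = -10.0
CAPTURE_WINDOW_MS = 10.0


class CaptureError(RuntimeError):
    """Loss of 1:1 capture during a pacing protocol."""


@dataclass(frozen=True)
class APMetrics:
    """Metrics of a single captured action potential."""

    dvdt_max: float      # V/s
    apa: float           # mV, overshoot - resting
    apd90: float         # ms
    resting_vm: float    # mV
    overshoot: float     # mV

    def __post_init__(self):
        if self.apd90 <= 0:
            raise ValueError("apd90 must be positive for a captured beat")


@dataclass(frozen=True)
class RestitutionCurve:
    """APD90 of the premature (S2) beat against the S2 coupling interval."""

    s2_intervals: np.ndarray
    apd90_values: np.ndarray
    s1_bcl: float

    def __post_init__(self):
        s2 = np.asarray(self.s2_intervals, dtype=float)
        ap = np.asarray(self.apd90_values, dtype=float)
        if s2.shape != ap.shape:
            raise ValueError("s2_intervals and apd90_values must match")
        object.__setattr__(self, "s2_intervals", s2)
        object.__setattr__(self, "apd90_values", ap)


def ap_metrics(trace: CellTrace | tuple[np.ndarray, np.ndarray]) -> APMetrics:
    """Measure one stimulated action potential.

    The trace must contain exactly one AP with full repolarization:
    resting potential is the pre-stimulus voltage, overshoot the maximum,
    dV/dt_max the maximum upstroke slope, and APD90 runs from the
    dV/dt_max instant to the 90%-repolarization crossing (linear
    interpolation).  A trace with no crossing (incomplete repolarization)
    or no upstroke raises.
    """
    if isinstance(trace, CellTrace):
        t, v = trace.times, trace.vm
    else:
        t, v = (np.asarray(a, dtype=float) for a in trace)
    if t.size < 4:
        raise ValueError("trace too short for AP metrics")
    resting = float(v[0])
    overshoot = float(v.max())
    apa = overshoot - resting
    if apa < 10.0:
        raise ValueError("no action potential in trace (amplitude < 10 mV)")
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[i_up])     # mV/ms == V/s
    i_peak = int(np.argmax(v))
    thr = overshoot - 0.9 * apa
    after = np.nonzero((np.arange(v.size) > i_peak) & (v < thr))[0]
    if after.size == 0:
        raise ValueError("no 90% repolarization crossing: incomplete repolarization")
    k = int(after[0])
    # linear interpolation between samples k-1 (above) and k (below)
    t_cross = t[k - 1] + (t[k] - t[k - 1]) * (v[k - 1] - thr) / (v[k - 1] - v[k])
    apd90 = float(t_cross - t[i_up])
    return APMetrics(dvdt_max=dvdt_max, apa=apa, apd90=apd90,
                     resting_vm=resting, overshoot=overshoot)


def _captured(trace: CellTrace, stim_time: float) -> bool:
    sel = (trace.times >= stim_time) & (trace.times <= stim_time + CAPTURE_WINDOW_MS)
    return bool(sel.any() and trace.vm[sel].max() > CAPTURE_VM)


def diastolic_threshold(model: MembraneModel, dt: float | None = None,
                        pulse_ms: float = 1.0, hi: float = 200.0,
                        rel_tol: float = 0.05) -> float:
    """Diastolic stimulus threshold (µA/µF) by bisection from rest.

    A 1-ms rectangular pulse is applied to the resting cell; capture means
    the membrane exceeds −10 mV within 10 ms of the pulse.
    """
    dt = model.default_dt if dt is None else dt

    def captures(amp: float) -> bool:
        stim = StimulusProtocol(np.array([1.0]), np.array([pulse_ms]),
                                np.array([amp]))
        tr = integrate_cell(model, stim, 1.0 + CAPTURE_WINDOW_MS + 2.0, dt=dt,
                            record_dt=max(dt, 0.05))
        return _captured(tr, 1.0)

    lo = 0.0
    if not captures(hi):
        raise CaptureError(f"{model.name}: no capture even at {hi} µA/µF")
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    log.info("%s: diastolic threshold %.2f µA/µF (pulse %.1f ms)",
             model.name, hi, pulse_ms)
    return hi


_AMPLITUDE_CACHE: dict[bytes, float] = {}


def default_stim_amplitude(model: MembraneModel, dt: float | None = None) -> float:
    """1.5× the diastolic threshold, cached per parameter vector."""
    key = model.name.encode() + model.params.tobytes()
    if key not in _AMPLITUDE_CACHE:
        _AMPLITUDE_CACHE[key] = 1.5 * diastolic_threshold(model, dt=dt)
        log.info("%s: stimulus amplitude %.2f µA/µF (1.5x threshold)",
                 model.name, _AMPLITUDE_CACHE[key])
    return _AMPLITUDE_CACHE[key]


def pace_to_steady_state(model: MembraneModel, bcl: float,
                         max_beats: int = 200, tol: float = 0.1,
                         dt: float | None = None,
                         amplitude: float | None = None,
                         min_beats: int = 50,
                         record_dt: float = 0.05
                         ) -> tuple[np.ndarray, CellTrace, dict]:
    """Pace from rest until APD90 is beat-to-beat stable.

    Integrates beat by beat at the given BCL; convergence means the
    absolute APD90 change between consecutive beats is below tol (ms)
    after at least min_beats beats.  Returns (state after the last beat,
    trace of the last beat, info dict with beats/apd90 history).  Loss of
    1:1 capture raises CaptureError naming the first skipped beat.
    """
    dt = model.default_dt if dt is None else dt
    if amplitude is None:
        amplitude = default_stim_amplitude(model, dt=dt)
    state = model.initial_state.copy()
    one_beat = pacing_protocol(bcl, 1, amplitude)
    apds: list[float] = []
    trace = None
    for beat in range(max_beats):
        trace = integrate_cell(model, one_beat, bcl, dt=dt, state=state,
                               record_dt=record_dt)
        state = trace.final_state
        if not _captured(trace, 0.0):
            raise CaptureError(
                f"{model.name}: loss of capture at beat {beat + 1} "
                f"(bcl={bcl} ms, amplitude={amplitude:.2f})")
        try:
            apds.append(ap_metrics(trace).apd90)
        except ValueError:
            raise CaptureError(
                f"{model.name}: unmeasurable AP at beat {beat + 1} (bcl={bcl})")
        if beat + 1 >= min_beats and len(apds) >= 2 and \
                abs(apds[-1] - apds[-2]) < tol:
            break
    else:
        log.warning("%s: steady state not reached in %d beats (ΔAPD=%.3f ms)",
                    model.name, max_beats, abs(apds[-1] - apds[-2]))
    info = {"beats": len(apds), "apd90_history": np.array(apds),
            "amplitude": amplitude, "bcl": bcl, "dt": dt}
    return state, trace, info


def restitution(model: MembraneModel, s1_bcl: float = 300.0,
                s2_grid=None, n_s1: int = 10, dt: float | None = None,
                amplitude: float | None = None,
                s2_window_ms: float | None = None) -> RestitutionCurve:
    """S1-S2 restitution: APD90 of a single premature beat vs its interval.

    The cell is first paced to steady state at s1_bcl, then for every S2
    coupling interval a fresh run delivers n_s1 further S1 beats and one
    S2; the S2 beat's APD90 enters the curve only when the S2 captures.
    Uncaptured intervals are recorded as NaN and excluded.
    """
    dt = model.default_dt if dt is None else dt
    if amplitude is None:
        amplitude = default_stim_amplitude(model, dt=dt)
    if s2_grid is None:
        # default mapped range: 50 ms up to 80% of the drive cycle length;
        # shorter couplings produce graded (partially regenerative) responses
        upper = min(250.0, 0.8 * s1_bcl)
        s2_grid = np.arange(upper, 45.0, -10.0)
    s2_grid = np.asarray(s2_grid, dtype=float)

    state, last_beat, _ = pace_to_steady_state(model, s1_bcl, dt=dt,
                                               amplitude=amplitude)
    # S1 tail shared by every S2 trial: n_s1 - 1 full beats, snapshot at the
    # instant the final S1 is due; each trial then delivers that S1 itself
    if n_s1 > 1:
        s1_train = pacing_protocol(s1_bcl, n_s1 - 1, amplitude)
        tail = integrate_cell(model, s1_train, (n_s1 - 1) * s1_bcl, dt=dt,
                              state=state, record_dt=1.0)
        snap = tail.final_state
    else:
        snap = state
    steady_apd = ap_metrics(last_beat).apd90
    if s2_window_ms is None:
        s2_window_ms = max(3.0 * steady_apd, 60.0)

    apds = np.full(s2_grid.size, np.nan)
    for k, s2 in enumerate(s2_grid):
        # final S1 at t=0, S2 at the coupling interval t=s2
        stim = StimulusProtocol(np.array([0.0, s2]), np.array([1.0, 1.0]),
                                np.array([amplitude, amplitude]))
        tr = integrate_cell(model, stim, s2 + s2_window_ms, dt=dt,
                            state=snap.copy(), record_dt=0.05)
        sel = tr.times >= s2
        sub = CellTrace(times=tr.times[sel] - s2, vm=tr.vm[sel],
                        final_state=tr.final_state, dt=dt)
        if not _captured(sub, 0.0):
            continue
        try:
            apds[k] = ap_metrics(sub).apd90
        except ValueError:
            continue
    ok = np.isfinite(apds)
    order = np.argsort(s2_grid[ok])
    return RestitutionCurve(s2_intervals=s2_grid[ok][order],
                            apd90_values=apds[ok][order], s1_bcl=s1_bcl)
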