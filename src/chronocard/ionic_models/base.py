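"""Membrane-model contract and numerical integration engine.

A :class:`MembraneModel` bundles a state vector layout, a parameter vector,
and two compiled kernels: ``step_all`` advances every node of a state array
by one time step (Rush-Larsen exponential updates for gating variables,
explicit stepping for voltage and concentrations), and ``currents_fn``
evaluates the instantaneous per-current breakdown for one node.  The same
kernels drive single cells (one node), voltage-clamp harnesses, and the
1-D monodomain cable.

Units follow the cardiac-modelling convention: mV, ms, µA/µF (current
density), mM; time zero at the first stimulus of a protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "MembraneModel",
    "CellTrace",
    "StimulusProtocol",
    "pacing_protocol",
    "s1s2_protocol",
    "IntegrationError",
    "integrate_cell",
    "run_engine",
]


class IntegrationError(RuntimeError):
    """Numerical failure during integration (non-finite state or blow-up)."""


@dataclass(frozen=True)
class StimulusProtocol:
    """A train of rectangular current pulses.

    start_ms/duration_ms/amplitude are parallel arrays; node_lo/node_hi give
    the stimulated node range (half-open) and default to node 0 only, the
    single-cell case.  Amplitude is depolarizing-positive in µA/µF.
    """

    start_ms: np.ndarray
    duration_ms: np.ndarray
    amplitude: np.ndarray
    node_lo: np.ndarray | None = None
    node_hi: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.start_ms, dtype=float)
        d = np.asarray(self.duration_ms, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if not (s.shape == d.shape == a.shape):
            raise ValueError("stimulus arrays must have equal shapes")
        lo = self.node_lo if self.node_lo is not None else np.zeros(s.size, dtype=np.int64)
        hi = self.node_hi if self.node_hi is not None else np.ones(s.size, dtype=np.int64)
        object.__setattr__(self, "start_ms", s)
        object.__setattr__(self, "duration_ms", d)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "node_lo", np.asarray(lo, dtype=np.int64))
        object.__setattr__(self, "node_hi", np.asarray(hi, dtype=np.int64))

    @property
    def n_events(self) -> int:
        return self.start_ms.size

    def shifted(self, offset_ms: float) -> "StimulusProtocol":
        return StimulusProtocol(self.start_ms + offset_ms, self.duration_ms,
                                self.amplitude, self.node_lo, self.node_hi)

    @staticmethod
    def concat(*protocols: "StimulusProtocol") -> "StimulusProtocol":
        return StimulusProtocol(
            np.concatenate([p.start_ms for p in protocols]),
            np.concatenate([p.duration_ms for p in protocols]),
            np.concatenate([p.amplitude for p in protocols]),
            np.concatenate([p.node_lo for p in protocols]),
            np.concatenate([p.node_hi for p in protocols]),
        )


def pacing_protocol(bcl_ms: float, n_beats: int, amplitude: float,
                    pulse_ms: float = 1.0, start_ms: float = 0.0,
                    node_lo: int = 0, node_hi: int = 1) -> StimulusProtocol:
    """Regular pacing: n_beats pulses at a fixed basic cycle length."""
    starts = start_ms + bcl_ms * np.arange(n_beats, dtype=float)
    n = starts.size
    return StimulusProtocol(starts, np.full(n, pulse_ms), np.full(n, amplitude),
                            np.full(n, node_lo, dtype=np.int64),
                            np.full(n, node_hi, dtype=np.int64))


def s1s2_protocol(s1_bcl: float, n_s1: int, s2_interval: float,
                  amplitude: float, pulse_ms: float = 1.0,
                  s2_amplitude: float | None = None) -> StimulusProtocol:
    """n_s1 S1 pulses followed by a single premature S2.

    The S2 is delivered s2_interval after the last S1 pulse onset.
    """
    s1 = pacing_protocol(s1_bcl, n_s1, amplitude, pulse_ms)
    t2 = (n_s1 - 1) * s1_bcl + s2_interval
    amp2 = amplitude if s2_amplitude is None else s2_amplitude
    s2 = StimulusProtocol(np.array([t2]), np.array([pulse_ms]), np.array([amp2]))
    return StimulusProtocol.concat(s1, s2)


@dataclass(frozen=True)
class CellTrace:
    """Membrane-potential trace with the final full state."""

    times: np.ndarray
    vm: np.ndarray
    final_state: np.ndarray
    dt: float

    def dvdt(self) -> np.ndarray:
        # V/s: gradient of mV over ms equals V/s numerically
        return np.gradient(self.vm, self.times)


@dataclass(frozen=True)
class MembraneModel:
    """A ventricular myocyte model behind a uniform contract.

    state_names orders the state vector (V_m first, mV); param_names orders
    the parameter vector; conductance_params maps current labels (I_Na,
    I_Kr, ...) to the parameter holding that current's maximal conductance
    or flux scale.  step_all and currents_fn are numba-compiled kernels
    shared by all integration harnesses.
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    params: np.ndarray
    initial_state: np.ndarray
    current_names: tuple[str, ...]
    conductance_params: dict[str, str]
    step_all: object = field(repr=False)
    currents_fn: object = field(repr=False)
    resting_vm: float = -80.0
    default_dt: float = 0.005

    def __post_init__(self):
        if len(self.state_names) != self.initial_state.size:
            raise ValueError("state_names/initial_state length mismatch")
        if len(self.param_names) != self.params.size:
            raise ValueError("param_names/params length mismatch")
        if self.state_names[0] != "V_m":
            raise ValueError("first state must be V_m")

    # -- parameter access ---------------------------------------------------
    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"{self.name} has no parameter {name!r}") from None

    def get_param(self, name: str) -> float:
        return float(self.params[self.param_index(name)])

    def with_params(self, **overrides: float) -> "MembraneModel":
        """A copy with named parameters replaced (must be >= 0)."""
        p = self.params.copy()
        for k, v in overrides.items():
            if v < 0:
                raise ValueError(f"parameter {k} must be non-negative, got {v}")
            p[self.param_index(k)] = v
        return replace(self, params=p)

    def scaled(self, channel_factors: dict[str, float]) -> "MembraneModel":
        """A copy with per-current maximal conductances multiplied by factors.

        Keys are current labels (e.g. "I_Na"); unknown labels raise.
        """
        p = self.params.copy()
        for label, factor in channel_factors.items():
            if label not in self.conductance_params:
                raise KeyError(f"{self.name} exposes no scalable current {label!r}")
            if factor <= 0:
                raise ValueError(f"scale factor for {label} must be > 0")
            p[self.param_index(self.conductance_params[label])] *= factor
        return replace(self, params=p)

    # -- evaluation ---------------------------------------------------------
    def currents(self, state: np.ndarray) -> dict[str, float]:
        """Instantaneous per-current densities plus their total (µA/µF)."""
        out = np.empty(len(self.current_names))
        self.currents_fn(np.asarray(state, dtype=float), self.params, out)
        d = {name: float(v) for name, v in zip(self.current_names, out)}
        d["I_total"] = float(out.sum())
        return d

    @property
    def gating_indices(self) -> np.ndarray:
        """Indices of states constrained to [0, 1] (gates)."""
        skip = {"V_m"}
        return np.array([k for k, n in enumerate(self.state_names)
                         if n not in skip and not n.startswith(("Ca", "Na", "K"))],
                        dtype=np.int64)


# ---------------------------------------------------------------------------
# compiled drivers
# ---------------------------------------------------------------------------

@njit(cache=False)
def _drive(step_all, Y, params, dt, t0, n_steps,
           stim_start, stim_dur, stim_amp, stim_lo, stim_hi,
           d_over_dx2, record_stride, v_rec):
    """Advance Y by n_steps; returns -1 on success else the failing step.

    Operator splitting per step: explicit diffusion on V (no-flux
    boundaries) followed by the reaction update of every node.  v_rec is
    filled with V at each node every record_stride steps.
    """
    n_nodes = Y.shape[0]
    istim = np.zeros(n_nodes)
    lap = np.zeros(n_nodes)
    rec = 0
    for s in range(n_steps):
        t = t0 + s * dt
        for k in range(n_nodes):
            istim[k] = 0.0
        for e in range(stim_start.size):
            if stim_start[e] <= t < stim_start[e] + stim_dur[e]:
                hi = min(stim_hi[e], n_nodes)
                for k in range(stim_lo[e], hi):
                    istim[k] += stim_amp[e]
        if d_over_dx2 > 0.0 and n_nodes > 1:
            lap[0] = Y[1, 0] - Y[0, 0]
            lap[n_nodes - 1] = Y[n_nodes - 2, 0] - Y[n_nodes - 1, 0]
            for k in range(1, n_nodes - 1):
                lap[k] = Y[k - 1, 0] - 2.0 * Y[k, 0] + Y[k + 1, 0]
            for k in range(n_nodes):
                Y[k, 0] += dt * d_over_dx2 * lap[k]
        step_all(Y, params, dt, istim)
        if (s + 1) % record_stride == 0:
            for k in range(n_nodes):
                v_rec[rec, k] = Y[k, 0]
            rec += 1
        if s % 50 == 0:
            for k in range(n_nodes):
                vk = Y[k, 0]
                if not np.isfinite(vk) or vk > 200.0 or vk < -200.0:
                    return s
    return -1


@njit(cache=False)
def _drive_clamp(step_all, currents_fn, y, params, dt, v_cmd, n_currents,
                 i_index, i_rec):
    """Voltage-clamp: V is forced to v_cmd[s] each step; one current recorded."""
    n_steps = v_cmd.size
    Y = y.reshape((1, y.size))
    istim = np.zeros(1)
    out = np.zeros(n_currents)
    for s in range(n_steps):
        Y[0, 0] = v_cmd[s]
        step_all(Y, params, dt, istim)
        Y[0, 0] = v_cmd[s]
        currents_fn(Y[0], params, out)
        i_rec[s] = out[i_index]
    return 0


def run_engine(model: MembraneModel, Y: np.ndarray, stim: StimulusProtocol,
               duration_ms: float, dt: float, t0: float = 0.0,
               d_over_dx2: float = 0.0,
               record_dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Low-level driver: advances the node-state array Y in place.

    Returns (times, v_rec) with v_rec of shape (n_records, n_nodes).
    Raises IntegrationError naming the first non-finite state on failure.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration_ms / dt))
    stride = 1 if record_dt is None else max(1, int(round(record_dt / dt)))
    n_rec = n_steps // stride
    v_rec = np.empty((n_rec, Y.shape[0]))
    bad = _drive(model.step_all, Y, model.params, dt, t0, n_steps,
                 stim.start_ms, stim.duration_ms, stim.amplitude,
                 stim.node_lo, stim.node_hi, d_over_dx2, stride, v_rec)
    if bad >= 0:
        names = model.state_names
        for node in range(Y.shape[0]):
            for si, val in enumerate(Y[node]):
                if not np.isfinite(val):
                    raise IntegrationError(
                        f"{model.name}: non-finite state {names[si]!r} at node "
                        f"{node}, t={t0 + bad * dt:.3f} ms (dt={dt})")
        raise IntegrationError(
            f"{model.name}: |V| exceeded 200 mV at t={t0 + bad * dt:.3f} ms "
            f"(dt={dt}); reduce dt or check diffusion stability")
    times = t0 + dt * stride * (1.0 + np.arange(n_rec))
    return times, v_rec


def integrate_cell(model: MembraneModel, stimulus: StimulusProtocol,
                   duration_ms: float, dt: float | None = None,
                   state: np.ndarray | None = None,
                   record_dt: float | None = None) -> CellTrace:
    """Integrate a single cell and return its voltage trace.

    Gating variables use Rush-Larsen exponential updates; voltage and
    concentrations use explicit stepping.  Deterministic: identical inputs
    give identical traces.
    """
    dt = model.default_dt if dt is None else dt
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    y0 = (model.initial_state if state is None else state).copy()
    Y = y0.reshape(1, -1)
    times, v_rec = run_engine(model, Y, stimulus, duration_ms, dt,
                              record_dt=record_dt)
    return CellTrace(times=times, vm=v_rec[:, 0], final_state=Y[0].copy(), dt=dt)
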