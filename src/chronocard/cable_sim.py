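"""1-D monodomain cable: conduction velocity, S1-S2 vulnerable window.

The tissue model is a string of ventricular cells coupled by a single
effective diffusion coefficient D (the gap-junction/Cx43 proxy):

    ∂V/∂t = D ∂²V/∂x² − I_ion + I_stim,   no-flux boundaries,

integrated by operator splitting — explicit finite-difference diffusion on
V followed by the cell reaction step (Rush-Larsen gates).  S1 waves are
launched from one end; the premature S2 is delivered at an interior site
in the wake of the S1 wave, so a unidirectional block conducts
retrogradely (toward the S1 origin, where tissue recovered earliest) but
not anterogradely.  The vulnerable window is the range of S2 coupling
intervals producing unidirectional block; its width is the 1-D surrogate
for reentry inducibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cell_protocols import ap_metrics, default_stim_amplitude, pace_to_steady_state
from .diurnal_scaling import ScenarioScaling, apply_scenario
from .ionic_models.base import (MembraneModel, StimulusProtocol,
                                pacing_protocol, run_engine)

__all__ = [
    "CableConfig",
    "SpaceTimeTrace",
    "VWResult",
    "simulate_cable",
    "cable_stim_amplitude",
    "activation_time",
    "conduction_velocity",
    "classify_s2_outcome",
    "vulnerability_window",
    "wavelength",
    "build_pes_train",
]

log = logging.getLogger(__name__)

#: upward crossing of this potential marks local activation
ACTIVATION_VM = -30.0


@dataclass(frozen=True)
class CableConfig:
    """Geometry and coupling of the 1-D cable.

    Defaults: 15-mm mouse cable at 0.1-mm resolution (150 nodes), S1 site
    at the left end, S2 site centred at 50% of the length, activation
    sensors at 25% and 75%.  diffusion is the pre-scenario coupling
    (mm²/ms), chosen so the baseline conduction velocity falls in the
    physiological 0.3-0.6 mm/ms range.
    """

    length: float = 15.0          # mm
    dx: float = 0.05              # mm
    diffusion: float = 0.05       # mm²/ms, before coupling_scale
    s1_mm: float = 0.3            # stimulated length at the left end
    s2_center_frac: float = 0.5   # fractional position of the S2 site
    s2_half_mm: float = 0.5       # S2 site half-width (~1-mm electrode)
    sensor_fracs: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.n_nodes < 50:
            raise ValueError("cable must resolve >= 50 nodes (length/dx)")
        lo, hi = self.s2_node_range
        if lo <= self.s1_nodes or hi >= self.n_nodes - 1:
            raise ValueError("S2 site must be strictly interior")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dx))

    @property
    def s1_nodes(self) -> int:
        return max(1, int(round(self.s1_mm / self.dx)))

    @property
    def positions(self) -> np.ndarray:
        return self.dx * np.arange(self.n_nodes)

    @property
    def s2_node_range(self) -> tuple[int, int]:
        c = int(round(self.s2_center_frac * self.n_nodes))
        half = max(1, int(round(self.s2_half_mm / self.dx)))
        return c - half, c + half + 1

    def sensor_nodes(self) -> tuple[int, ...]:
        return tuple(int(round(f * (self.n_nodes - 1))) for f in self.sensor_fracs)


@dataclass(frozen=True)
class SpaceTimeTrace:
    """Membrane potential over (time, position) from a cable run."""

    positions: np.ndarray
    times: np.ndarray
    vm: np.ndarray               # shape (n_times, n_nodes)
    final_state: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.vm.shape != (self.times.size, self.positions.size):
            raise ValueError("vm shape must be (n_times, n_nodes)")
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("space-time trace contains non-finite values")

    def node_trace(self, node: int) -> np.ndarray:
        return self.vm[:, node]

    def to_dataframe(self):
        import pandas as pd
        t, x = np.meshgrid(self.times, self.positions, indexing="ij")
        return pd.DataFrame({"time_ms": t.ravel(), "position_mm": x.ravel(),
                             "vm_mv": self.vm.ravel()})


@dataclass(frozen=True)
class VWResult:
    """Vulnerable-window bounds (ms of S2 coupling interval) and width."""

    s1_bcl: float
    vw_lower: float
    vw_upper: float
    width: float
    outcomes: dict[float, str]

    def __post_init__(self):
        if self.width < -1e-9:
            raise ValueError("window width cannot be negative")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_cable(model: MembraneModel, config: CableConfig,
                   stimuli: StimulusProtocol, duration_ms: float,
                   dt: float = 0.02, coupling_scale: float = 1.0,
                   record_dt: float = 0.25,
                   state: np.ndarray | None = None) -> SpaceTimeTrace:
    """Integrate the monodomain cable and record V(x, t).

    state optionally provides the initial node-state matrix
    (n_nodes, n_states); by default every node starts at the model's
    resting state.  Deterministic for fixed inputs.  An explicit-diffusion
    stability violation aborts with a diagnostic naming dt/dx.
    """
    d_eff = config.diffusion * coupling_scale
    if d_eff * dt / config.dx ** 2 > 0.5:
        raise ValueError(
            f"explicit diffusion unstable: D·dt/dx² = "
            f"{d_eff * dt / config.dx**2:.2f} > 0.5 (dt={dt}, dx={config.dx})")
    n = config.n_nodes
    if state is None:
        Y = np.tile(model.initial_state, (n, 1))
    else:
        Y = state.copy()
        if Y.shape != (n, model.initial_state.size):
            raise ValueError("state shape mismatch with cable config")
    times, v_rec = run_engine(model, Y, stimuli, duration_ms, dt,
                              d_over_dx2=d_eff / config.dx ** 2,
                              record_dt=record_dt)
    return SpaceTimeTrace(positions=config.positions, times=times, vm=v_rec,
                          final_state=Y)


def s1_stimulus(config: CableConfig, bcl: float, n_beats: int,
                amplitude: float, pulse_ms: float = 1.0,
                start_ms: float = 0.0) -> StimulusProtocol:
    """S1 pacing applied to the proximal end of the cable."""
    return pacing_protocol(bcl, n_beats, amplitude, pulse_ms=pulse_ms,
                           start_ms=start_ms, node_lo=0,
                           node_hi=config.s1_nodes)


_CABLE_AMP_CACHE: dict[tuple, float] = {}


def cable_stim_amplitude(model: MembraneModel, config: CableConfig,
                         coupling_scale: float = 1.0, dt: float = 0.02,
                         hi: float = 150.0) -> float:
    """1.5× the cable diastolic threshold (µA/µF), found by bisection.

    Tissue needs a stronger stimulus than the isolated cell because the
    stimulated nodes lose charge to their unexcited neighbours
    (source-sink mismatch); the threshold is defined as the smallest
    1-ms pulse at the S1 site that launches a propagating wave (node at
    10% of the cable activates within 25 ms of wave onset).
    """
    key = (model.name, model.params.tobytes(), config.length, config.dx,
           config.diffusion, config.s1_nodes, round(coupling_scale, 9))
    if key in _CABLE_AMP_CACHE:
        return _CABLE_AMP_CACHE[key]
    probe = int(round(0.10 * config.n_nodes))

    def propagates(amp: float) -> bool:
        stim = s1_stimulus(config, 1000.0, 1, amp)
        tr = simulate_cable(model, config, stim, 30.0, dt=dt,
                            coupling_scale=coupling_scale, record_dt=0.25)
        return not math.isnan(activation_time(tr.times, tr.vm[:, probe]))

    lo = 0.0
    if not propagates(hi):
        raise RuntimeError(f"{model.name}: no propagated wave even at {hi} µA/µF")
    while hi - lo > 0.05 * hi:
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    amp = 1.5 * hi
    log.info("%s: cable stimulus amplitude %.1f µA/µF (1.5x threshold)",
             model.name, amp)
    _CABLE_AMP_CACHE[key] = amp
    return amp


def s2_stimulus(config: CableConfig, t_ms: float, amplitude: float,
                pulse_ms: float = 1.0) -> StimulusProtocol:
    lo, hi = config.s2_node_range
    return StimulusProtocol(np.array([t_ms]), np.array([pulse_ms]),
                            np.array([amplitude]),
                            np.array([lo], dtype=np.int64),
                            np.array([hi], dtype=np.int64))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def activation_time(times: np.ndarray, v: np.ndarray, t_min: float = -np.inf,
                    threshold: float = ACTIVATION_VM) -> float:
    """First upward threshold crossing after t_min (linear interpolation).

    Returns NaN when the trace never activates after t_min.
    """
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above & (times[1:] > t_min))[0]
    if idx.size == 0:
        return float("nan")
    k = int(idx[0])
    frac = (threshold - v[k]) / (v[k + 1] - v[k])
    return float(times[k] + frac * (times[k + 1] - times[k]))


def conduction_velocity(trace: SpaceTimeTrace,
                        sensor_fracs: tuple[float, float] = (0.25, 0.75),
                        t_min: float = -np.inf) -> float:
    """CV (mm/ms) between two fractional sensor positions on one wave."""
    n = trace.positions.size
    k1, k2 = (int(round(f * (n - 1))) for f in sensor_fracs)
    t1 = activation_time(trace.times, trace.vm[:, k1], t_min=t_min)
    t2 = activation_time(trace.times, trace.vm[:, k2], t_min=t_min)
    if math.isnan(t1) or math.isnan(t2):
        raise RuntimeError("sensor not activated: conduction block")
    if t2 == t1:
        raise RuntimeError("zero transit time between sensors")
    return float(abs(trace.positions[k2] - trace.positions[k1]) / (t2 - t1))


def classify_s2_outcome(trace: SpaceTimeTrace, config: CableConfig,
                        s2_time: float, s1_window_end: float | None = None,
                        margin_ms: float = 0.5) -> str:
    """Label one S2 trial: no_capture | unidirectional | bidirectional.

    Capture means the S2 site re-activates after the S2 stimulus;
    anterograde/retrograde propagation means the distal/proximal sensor
    activates after the S2 (the S1 wave is excluded by requiring the S1
    wave to have passed the sensors before s2_time — otherwise the trial
    is flagged "indeterminate").
    """
    prox_node, dist_node = config.sensor_nodes()
    lo, hi = config.s2_node_range
    site = (lo + hi) // 2
    t = trace.times
    if s1_window_end is None:
        # the S1 wave must have cleared both sensors before the S2
        s1_prox = activation_time(t, trace.vm[:, prox_node])
        s1_dist = activation_time(t, trace.vm[:, dist_node])
        s1_window_end = max(s1_prox, s1_dist)
        if math.isnan(s1_window_end):
            s1_window_end = -np.inf  # S1 wave never reached the sensors
    if s2_time <= s1_window_end:
        return "indeterminate"
    t_site = activation_time(t, trace.vm[:, site], t_min=s2_time + margin_ms)
    if math.isnan(t_site):
        return "no_capture"
    retro = activation_time(t, trace.vm[:, prox_node], t_min=s2_time + margin_ms)
    antero = activation_time(t, trace.vm[:, dist_node], t_min=s2_time + margin_ms)
    if math.isnan(antero) and not math.isnan(retro):
        return "unidirectional"
    if not math.isnan(antero):
        return "bidirectional"
    return "no_capture"  # local capture that failed to propagate either way


# ---------------------------------------------------------------------------
# vulnerable window
# ---------------------------------------------------------------------------

def _vw_outcome_fn(model, config, s1_bcl, dt, amplitude, coupling_scale,
                   n_s1_cable: int, post_window: float):
    """Build a classifier interval -> outcome sharing the S1 history.

    The cable is initialised from the single-cell steady state at s1_bcl,
    conditioned with n_s1_cable in-cable S1 beats, and snapshotted at the
    instant the final S1 is due.  Each trial then delivers that S1 at t=0
    plus the S2 at its coupling interval.
    """
    cell_state, _, _ = pace_to_steady_state(model, s1_bcl, dt=min(dt, 0.01),
                                            amplitude=amplitude)
    n = config.n_nodes
    Y0 = np.tile(cell_state, (n, 1))
    if n_s1_cable > 1:
        cond = s1_stimulus(config, s1_bcl, n_s1_cable - 1, amplitude)
        tr = simulate_cable(model, config, cond, (n_s1_cable - 1) * s1_bcl,
                            dt=dt, coupling_scale=coupling_scale,
                            record_dt=1.0, state=Y0)
        Y0 = tr.final_state
    snap = Y0

    # S1-only reference run: when does the final S1 wave clear the sensors?
    s1_only = s1_stimulus(config, s1_bcl, 1, amplitude)
    ref = simulate_cable(model, config, s1_only, post_window, dt=dt,
                         coupling_scale=coupling_scale, record_dt=0.25,
                         state=snap)
    prox_node, dist_node = config.sensor_nodes()
    passes = [activation_time(ref.times, ref.vm[:, node])
              for node in (prox_node, dist_node)]
    if any(math.isnan(p) for p in passes):
        raise RuntimeError("S1 wave failed to traverse the cable "
                           "(conduction block under this scenario)")
    s1_clear = max(passes)

    def run(interval: float) -> tuple[str, SpaceTimeTrace]:
        s1 = s1_stimulus(config, s1_bcl, 1, amplitude)
        s2 = s2_stimulus(config, interval, amplitude)
        stim = StimulusProtocol.concat(s1, s2)
        trace = simulate_cable(model, config, stim, interval + post_window,
                               dt=dt, coupling_scale=coupling_scale,
                               record_dt=0.25, state=snap)
        label = classify_s2_outcome(trace, config, s2_time=interval,
                                    s1_window_end=s1_clear)
        return label, trace

    return run, s1_clear


def _bisect_edge(run, lo: float, hi: float, lo_label: str, refine_step: float,
                 outcomes: dict[float, str]) -> float:
    """Refine the boundary between lo (labelled lo_label) and hi."""
    while hi - lo > refine_step:
        mid = 0.5 * (lo + hi)
        label, _ = run(mid)
        outcomes[round(mid, 6)] = label
        if label == lo_label:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def vulnerability_window(model: MembraneModel,
                         scenario: ScenarioScaling | None = None,
                         s1_bcl: float = 200.0, coarse_step: float = 1.0,
                         refine_step: float = 0.1,
                         config: CableConfig | None = None,
                         dt: float = 0.02, s2_min: float = 5.0,
                         s2_max: float = 150.0, n_s1_cable: int = 4,
                         post_window: float = 80.0,
                         amplitude: float | None = None) -> VWResult:
    """Map the S2 vulnerable window on the cable for one diurnal scenario.

    Scans S2 coupling intervals (measured from the final S1 onset) in
    coarse_step increments until the outcome sequence has passed from
    no_capture through any unidirectional band to bidirectional, then
    refines both band edges by bisection to refine_step.  Returns width 0
    with the full outcome map when no unidirectional interval exists.
    """
    config = config or CableConfig()
    coupling = 1.0
    if scenario is not None:
        model = apply_scenario(model, scenario)
        coupling = scenario.coupling_scale
    if amplitude is None:
        amplitude = cable_stim_amplitude(model, config, coupling)
    run, s1_clear = _vw_outcome_fn(model, config, s1_bcl, dt, amplitude,
                                   coupling, n_s1_cable, post_window)
    outcomes: dict[float, str] = {}
    last_nc = None
    first_uni = last_uni = None
    first_bi = None
    # S2s delivered before the S1 wave clears the sensors are indeterminate
    interval = max(s2_min, coarse_step * math.ceil((s1_clear + 1.0) / coarse_step))
    while interval <= s2_max:
        label, _ = run(interval)
        outcomes[round(interval, 6)] = label
        if label == "no_capture":
            last_nc = interval
        elif label == "unidirectional":
            if first_uni is None:
                first_uni = interval
            last_uni = interval
        elif label == "bidirectional":
            first_bi = interval
            break
        interval += coarse_step
    if first_uni is None and last_nc is not None and first_bi is not None:
        # the unidirectional band may be narrower than the coarse step:
        # bisect the no_capture -> bidirectional jump looking for it
        lo, hi = last_nc, first_bi
        while hi - lo > refine_step:
            mid = 0.5 * (lo + hi)
            label, _ = run(mid)
            outcomes[round(mid, 6)] = label
            if label == "no_capture":
                lo = mid
            elif label == "bidirectional":
                hi = mid
            else:
                first_uni = last_uni = mid
                last_nc, first_bi = lo, hi
                break
    if first_uni is None:
        log.info("VW: no unidirectional interval found (bcl=%s)", s1_bcl)
        return VWResult(s1_bcl=s1_bcl, vw_lower=float("nan"),
                        vw_upper=float("nan"), width=0.0, outcomes=outcomes)
    lower = first_uni
    if last_nc is not None and last_nc < first_uni:
        lower = _bisect_edge(run, last_nc, first_uni, "no_capture",
                             refine_step, outcomes)
    upper = last_uni
    if first_bi is not None:
        upper = _bisect_edge(run, last_uni, first_bi, "unidirectional",
                             refine_step, outcomes)
    return VWResult(s1_bcl=s1_bcl, vw_lower=float(lower),
                    vw_upper=float(upper), width=float(upper - lower),
                    outcomes=outcomes)


def wavelength(apd90: float, cv: float) -> float:
    """Excitation wavelength: APD90 (ms) × CV (mm/ms) → mm."""
    if apd90 <= 0 or cv <= 0:
        raise ValueError("apd90 and cv must be positive")
    return apd90 * cv


def build_pes_train(s1_count: int = 20, s1_cl: float = 98.0,
                    s2_start: float = 58.0, s2_end: float = 8.0,
                    s2_decrement: float = 10.0, extra_count: int = 9,
                    gap: float = 3000.0, amplitude: float = 80.0,
                    pulse_ms: float = 1.0, node_lo: int = 0,
                    node_hi: int = 3) -> StimulusProtocol:
    """Programmed-electrical-stimulation timing for demonstration runs.

    A drive train of s1_count S1 pulses at s1_cl is followed by trains of
    extra_count extra stimuli (S2...S10) at cycle lengths stepping from
    s2_start down to s2_end in s2_decrement intervals, with a gap between
    successive extra-stimulus trains.  Defaults reproduce the ex vivo
    protocol: 20 S1 at 98 ms, then S2-S10 trains at 58, 48, ..., 8 ms with
    3-s gaps.
    """
    if s2_decrement <= 0:
        raise ValueError("s2_decrement must be positive")
    if s2_end > s2_start:
        raise ValueError("s2_end must not exceed s2_start")
    onsets = list(s1_cl * np.arange(s1_count, dtype=float))
    t_last = onsets[-1]
    cls = np.arange(s2_start, s2_end - 1e-9, -s2_decrement)
    t_ref = t_last
    for k, cl in enumerate(cls):
        if k > 0:
            t_ref = onsets[-1] + gap
        for e in range(1, extra_count + 1):
            onsets.append(t_ref + e * cl)
    onsets = np.asarray(onsets)
    n = onsets.size
    return StimulusProtocol(onsets, np.full(n, pulse_ms),
                            np.full(n, amplitude),
                            np.full(n, node_lo, dtype=np.int64),
                            np.full(n, node_hi, dtype=np.int64))
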