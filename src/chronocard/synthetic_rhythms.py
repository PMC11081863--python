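"""Seeded synthetic diurnal panels and IV curves with known ground truth.

The generators emulate the 6-timepoint zeitgeber sampling design used for
diurnal expression/physiology panels (ZT0, ZT4, ..., ZT20; 4-h spacing over
a 24-h cycle): a cosine of known MESOR, amplitude, acrophase and period
plus i.i.d. noise, with a configurable number of replicates per timepoint,
plus pure-noise null panels for type-I-error studies.  Every generator is a
pure function of (parameters, time grid, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rhythm_stats import IVCurve

__all__ = [
    "DEFAULT_TIMEPOINTS_H",
    "RhythmTruth",
    "TimeSeriesPanel",
    "generate_panel",
    "generate_null_panel",
    "generate_iv_curve",
    "generate_screen_table",
]

#: the study sampling grid: every 4 h across the 24-h cycle
DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)


@dataclass(frozen=True)
class RhythmTruth:
    """Ground-truth cosine parameters for a synthetic diurnal signal.

    The deterministic signal is
    mesor + amplitude·cos(2π(t − acrophase_h)/period_h); each replicate adds
    independent noise of standard deviation sigma.
    """

    mesor: float
    amplitude: float
    acrophase_h: float
    sigma: float
    n_reps: int = 4
    period_h: float = 24.0
    seed: int = 0
    noise: str = "gaussian"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.acrophase_h < self.period_h):
            raise ValueError("acrophase_h must lie in [0, period_h)")
        if self.n_reps < 1:
            raise ValueError("need at least one replicate per timepoint")
        if self.noise not in ("gaussian", "lognormal"):
            raise ValueError("noise must be 'gaussian' or 'lognormal'")

    def signal(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 2.0 * math.pi / self.period_h
        return self.mesor + self.amplitude * np.cos(w * (t - self.acrophase_h))


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Long-format diurnal panel: one value per (timepoint, replicate).

    data columns: feature_id, time_h, replicate, value.
    """

    data: pd.DataFrame
    period_h: float = 24.0
    feature_id: str = field(default="feature")

    def __post_init__(self) -> None:
        df = self.data
        for col in ("feature_id", "time_h", "replicate", "value"):
            if col not in df.columns:
                raise ValueError(f"panel missing column {col!r}")
        vals = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("panel values must all be finite")
        tp = np.unique(df["time_h"].to_numpy(dtype=float))
        if tp.size == 0:
            raise ValueError("panel has no timepoints")
        if tp.min() < 0 or tp.max() >= self.period_h:
            raise ValueError("timepoints must lie in [0, period_h)")
        counts = df.groupby("time_h").size()
        if (counts < 1).any():
            raise ValueError("every timepoint needs >= 1 replicate")

    @property
    def timepoints_h(self) -> np.ndarray:
        return np.unique(self.data["time_h"].to_numpy(dtype=float))

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, period_h: float = 24.0) -> "TimeSeriesPanel":
        df = pd.read_csv(path)
        fid = str(df["feature_id"].iloc[0]) if len(df) else "feature"
        return cls(data=df, period_h=period_h, feature_id=fid)


def generate_panel(truth: RhythmTruth,
                   timepoints_h=DEFAULT_TIMEPOINTS_H,
                   feature_id: str = "feature") -> TimeSeriesPanel:
    """Simulate a diurnal panel from known cosine ground truth.

    Replicate r at timepoint t is signal(t) + ε with ε i.i.d.
    Normal(0, sigma²) (or multiplicative log-normal when truth.noise is
    "lognormal").  Identical (truth, grid) pairs give bitwise-identical
    panels.
    """
    tp = np.asarray(timepoints_h, dtype=float)
    if tp.size == 0:
        raise ValueError("time grid is empty")
    if not np.all(np.diff(tp) > 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(truth.seed)
    times = np.repeat(tp, truth.n_reps)
    reps = np.tile(np.arange(truth.n_reps), tp.size)
    signal = truth.signal(times)
    if truth.noise == "gaussian":
        values = signal + rng.normal(0.0, truth.sigma, size=times.size)
    else:
        # multiplicative noise with unit median
        values = signal * rng.lognormal(0.0, truth.sigma, size=times.size)
    df = pd.DataFrame({
        "feature_id": feature_id,
        "time_h": times,
        "replicate": reps,
        "value": values,
    })
    return TimeSeriesPanel(data=df, period_h=truth.period_h, feature_id=feature_id)


def generate_null_panel(mesor: float, sigma: float, n_reps: int, seed: int,
                        timepoints_h=DEFAULT_TIMEPOINTS_H,
                        feature_id: str = "null") -> TimeSeriesPanel:
    """A pure-noise panel (amplitude identically zero) for null studies."""
    if sigma <= 0:
        raise ValueError("null panel requires sigma > 0")
    truth = RhythmTruth(mesor=mesor, amplitude=0.0, acrophase_h=0.0,
                        sigma=sigma, n_reps=n_reps, seed=seed)
    return generate_panel(truth, timepoints_h, feature_id=feature_id)


def generate_iv_curve(g_max: float, v_half: float, slope: float, v_rev: float,
                      voltages, noise_sd: float = 0.0,
                      seed: int | None = None, label: str = "") -> IVCurve:
    """Synthetic Boltzmann IV curve: I = g_max(V−v_rev)/(1+exp((v_half−V)/slope)).

    Additive Gaussian noise of SD noise_sd per point when requested.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        raise ValueError("voltages must be non-empty")
    i = g_max * (v - v_rev) / (1.0 + np.exp((v_half - v) / slope))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=v.size)
    return IVCurve(voltages=v, currents=i, label=label)


def generate_screen_table(n_features: int, frac_rhythmic: float,
                          amplitude: float, sigma: float, n_reps: int,
                          seed: int, mesor: float = 10.0,
                          timepoints_h=DEFAULT_TIMEPOINTS_H) -> tuple[pd.DataFrame, np.ndarray]:
    """A multi-feature long table mixing rhythmic and null features.

    Returns (table, truth_mask) where truth_mask[i] is True for features
    generated with the given nonzero amplitude (random acrophase) and False
    for pure-noise features.  Used for power / FDR simulation studies.
    """
    rng = np.random.default_rng(seed)
    n_rhythmic = int(round(frac_rhythmic * n_features))
    mask = np.zeros(n_features, dtype=bool)
    mask[:n_rhythmic] = True
    rng.shuffle(mask)
    frames = []
    for k in range(n_features):
        amp = amplitude if mask[k] else 0.0
        acro = float(rng.uniform(0, 24)) if mask[k] else 0.0
        truth = RhythmTruth(mesor=mesor, amplitude=amp, acrophase_h=acro,
                            sigma=sigma, n_reps=n_reps,
                            seed=int(rng.integers(0, 2**31 - 1)))
        frames.append(generate_panel(truth, timepoints_h,
                                     feature_id=f"f{k:04d}").data)
    return pd.concat(frames, ignore_index=True), mask
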