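"""Rhythm-detection statistics for diurnal time-series panels.

Implements single-component cosinor regression with the zero-amplitude F
test, a JTK_CYCLE-style nonparametric rhythm test based on Kendall's tau
against lagged reference cosines, Benjamini-Hochberg FDR adjustment, and
Boltzmann current-voltage (IV) curve fitting for voltage-clamp data.

All rhythm fits assume a fixed, known period (24 h by default); period
estimation is deliberately out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IVCurve",
    "RhythmFit",
    "JTKResult",
    "BoltzmannFit",
    "fit_cosinor",
    "jtk_test",
    "bh_adjust",
    "fit_boltzmann_iv",
    "kendall_tau",
    "rhythm_screen",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IVCurve:
    """A current-voltage relationship from a voltage-clamp protocol.

    voltages are test potentials in mV (strictly increasing); currents are
    the measured current densities at each potential (model units or pA/pF).
    """

    voltages: np.ndarray
    currents: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if v.shape != i.shape or v.ndim != 1:
            raise ValueError("voltages and currents must be 1-D and equal length")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("voltages must be strictly increasing")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)


@dataclass(frozen=True)
class RhythmFit:
    """Cosinor fit: y = MESOR + A·cos(2π(t − acrophase)/period)."""

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    f_statistic: float
    p_value: float
    residual_df: int
    se_amplitude: float = float("nan")
    se_acrophase_h: float = float("nan")


@dataclass(frozen=True)
class JTKResult:
    """JTK-style rhythm test result.

    best_lag_h is the reference-cosine peak time (acrophase convention)
    maximising Kendall concordance; p_value is the minimum one-sided tau
    p across lags, Bonferroni-corrected for the number of lags tested.
    """

    best_lag_h: float
    tau: float
    p_value: float
    amplitude_est: float
    n_lags: int
    exact: bool
    adj_p: float = float("nan")


@dataclass(frozen=True)
class BoltzmannFit:
    """Fit of I(V) = g_max·(V − v_rev) / (1 + exp((v_half − V)/slope))."""

    g_max: float
    v_rev: float
    v_half: float
    slope: float
    rss: float
    ok: bool
    message: str = ""

    def predict(self, voltages: np.ndarray) -> np.ndarray:
        v = np.asarray(voltages, dtype=float)
        return _boltzmann(v, self.g_max, self.v_rev, self.v_half, self.slope)


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

def _panel_arrays(panel) -> tuple[np.ndarray, np.ndarray]:
    """Accept a TimeSeriesPanel or a long DataFrame with time_h / value."""
    if hasattr(panel, "data"):
        df = panel.data
    elif isinstance(panel, pd.DataFrame):
        df = panel
    else:
        raise TypeError(f"cannot interpret panel of type {type(panel)!r}")
    t = df["time_h"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("panel contains non-finite values")
    return t, y


def fit_cosinor(panel, period_h: float = 24.0) -> RhythmFit:
    """Single-component cosinor regression with the zero-amplitude F test.

    Fits y = M + β₁cos(ωt) + β₂sin(ωt) by ordinary least squares with
    ω = 2π/period.  The amplitude is √(β₁²+β₂²) and the acrophase (peak
    time, hours into the cycle) comes from atan2(β₂, β₁)/ω.  The
    zero-amplitude test compares the full model against the intercept-only
    model with an F(2, N−3) statistic; under H₀ (no rhythm) the p-value is
    uniform.

    Standard errors of amplitude and acrophase are delta-method
    approximations from the OLS covariance of (β₁, β₂).
    """
    t, y = _panel_arrays(panel)
    n = y.size
    if np.unique(t).size < 3:
        raise ValueError("cosinor needs >= 3 distinct timepoints (design is singular)")
    if n <= 3:
        raise ValueError("cosinor needs more than 3 observations")
    w = 2.0 * math.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - 3
    mesor, b1, b2 = (float(b) for b in beta)
    amplitude = math.hypot(b1, b2)
    acrophase = (math.atan2(b2, b1) / w) % period_h
    if rss <= 0.0:
        # perfect fit: F is infinite unless the signal itself is flat
        f_stat = math.inf if tss > rss else 0.0
        p = 0.0 if tss > 0 else 1.0
        f_stat = 0.0 if tss == 0.0 else f_stat
        return RhythmFit(mesor, amplitude, acrophase, period_h, f_stat, p,
                         df_resid, 0.0, 0.0)
    f_stat = ((tss - rss) / 2.0) / (rss / df_resid)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, 2, df_resid))
    # delta method: var(A) and var(phi) from cov(beta1, beta2)
    sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv[1:, 1:]
    if amplitude > 0:
        gA = np.array([b1, b2]) / amplitude
        se_amp = math.sqrt(float(gA @ cov @ gA))
        gphi = np.array([-b2, b1]) / (amplitude ** 2 * w)
        se_phi = math.sqrt(float(gphi @ cov @ gphi))
    else:
        se_amp = math.sqrt(float(cov[0, 0]))
        se_phi = math.inf
    return RhythmFit(mesor, amplitude, acrophase, period_h, float(f_stat), p,
                     df_resid, se_amp, se_phi)


# ---------------------------------------------------------------------------
# Kendall tau and the JTK-style test
# ---------------------------------------------------------------------------

def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-b between two vectors (ties corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    tau = stats.kendalltau(x, y).statistic
    return float(tau) if np.isfinite(tau) else 0.0


def _tau_b_from_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Return (S, tau_b) where S = concordant − discordant pairs."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    s = int(np.sum(dx[iu] * dy[iu]))
    n_pairs = iu[0].size
    tx = int(np.sum(dx[iu] == 0))
    ty = int(np.sum(dy[iu] == 0))
    denom = math.sqrt((n_pairs - tx) * (n_pairs - ty))
    tau = s / denom if denom > 0 else 0.0
    return s, tau


def _distinct_permutation_count(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    total = math.factorial(y.size)
    for c in counts:
        total //= math.factorial(int(c))
    return total


_EXACT_N_MAX = 10
_EXACT_PERM_CAP = 200_000


def _exact_tau_pvalue(ref: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    """One-sided P(S >= s_obs) under exchangeability of y against fixed ref.

    Enumerates the distinct permutations of the observation multiset, so
    ties in either vector are respected exactly.
    """
    n = y.size
    # pair-sign matrix of the reference is fixed
    dref = np.sign(ref[:, None] - ref[None, :])
    iu = np.triu_indices(n, k=1)
    dref_u = dref[iu]
    count = 0
    total = 0
    seen_rank = np.array(y, dtype=float)
    for perm in _multiset_permutations(sorted(seen_rank.tolist())):
        p = np.array(perm)
        dy = np.sign(p[:, None] - p[None, :])[iu]
        s = int(np.sum(dref_u * dy))
        total += 1
        if s >= s_obs:
            count += 1
    return count / total


def _multiset_permutations(items):
    """Yield the distinct permutations of a sorted list (multiset)."""
    if not items:
        yield []
        return
    prev = object()
    for i, v in enumerate(items):
        if v == prev:
            continue
        prev = v
        rest = items[:i] + items[i + 1:]
        for tail in _multiset_permutations(rest):
            yield [v] + tail


def _tau_normal_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided asymptotic p for positive association (tie-corrected)."""
    res = stats.kendalltau(x, y, method="asymptotic")
    tau, p2 = float(res.statistic), float(res.pvalue)
    if not np.isfinite(tau):
        return 1.0
    return p2 / 2.0 if tau > 0 else 1.0 - p2 / 2.0


def jtk_test(panel, period_h: float = 24.0, lag_step_h: float | None = None) -> JTKResult:
    """Nonparametric rhythm test in the style of JTK_CYCLE.

    For each candidate lag on a grid dividing the period, the observations
    are correlated (Kendall tau-b) with a reference cosine peaking at that
    lag, evaluated at the observation times.  The reported statistic is the
    tau at the best lag; the p-value is the minimum one-sided tau tail
    probability across lags multiplied by the number of lags (Bonferroni),
    truncated at 1.  The tail probability is exact (tie-respecting
    permutation enumeration) for small samples and a tie-corrected normal
    approximation otherwise.  amplitude_est is the least-squares cosine
    amplitude at the selected lag.
    """
    t, y = _panel_arrays(panel)
    n = y.size
    if np.unique(t).size < 2:
        raise ValueError("JTK needs >= 2 distinct timepoints")
    if lag_step_h is None:
        steps = np.diff(np.unique(t))
        lag_step_h = float(steps.min()) if steps.size else period_h / 6.0
    n_lags_f = period_h / lag_step_h
    if abs(n_lags_f - round(n_lags_f)) > 1e-9:
        raise ValueError("lag_step_h must divide period_h")
    lags = np.arange(0.0, period_h, lag_step_h)
    w = 2.0 * math.pi / period_h

    if np.all(y == y[0]):
        # fully tied data carry no ordering information
        return JTKResult(best_lag_h=float(lags[0]), tau=0.0, p_value=1.0,
                         amplitude_est=0.0, n_lags=lags.size, exact=False)

    use_exact = (n <= _EXACT_N_MAX and
                 _distinct_permutation_count(y) <= _EXACT_PERM_CAP)

    best = None  # (p, -tau, lag, tau, exact)
    for lag in lags:
        ref = np.cos(w * (t - lag))
        s_obs, tau = _tau_b_from_counts(y, ref)
        if use_exact:
            p1 = _exact_tau_pvalue(ref, y, s_obs)
        else:
            p1 = _tau_normal_pvalue(ref, y)
        key = (p1, -tau)
        if best is None or key < best[0]:
            best = (key, float(lag), float(tau), float(p1))
    _, best_lag, best_tau, best_p = best
    p_adj = min(1.0, best_p * lags.size)
    p_adj = max(p_adj, np.nextafter(0.0, 1.0))  # p-values live in (0, 1]

    # amplitude: least-squares fit of M + A·cos(w(t - best_lag)), A free
    c = np.cos(w * (t - best_lag))
    X = np.column_stack([np.ones(n), c])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    amplitude_est = abs(float(coef[1]))
    return JTKResult(best_lag_h=best_lag, tau=best_tau, p_value=p_adj,
                     amplitude_est=amplitude_est, n_lags=lags.size,
                     exact=use_exact)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Boltzmann IV fitting
# ---------------------------------------------------------------------------

def _boltzmann(v, g_max, v_rev, v_half, slope):
    return g_max * (v - v_rev) / (1.0 + np.exp((v_half - v) / slope))


def fit_boltzmann_iv(iv: IVCurve, init: tuple[float, float, float, float] | None = None,
                     max_restarts: int = 5) -> BoltzmannFit:
    """Nonlinear least-squares fit of the Boltzmann IV relation.

    I(V) = g_max·(V − v_rev)/{1 + exp[(v_half − V)/slope]} with slope > 0
    (activation convention).  Starting values are derived from the data
    (linear extrapolation of the fully activated limb for g_max and v_rev)
    unless given; on failure the fit restarts from perturbed initials.

    A curve that is identically ~0 is flagged degenerate: g_max ≈ 0 with
    the remaining parameters unidentifiable (ok=False).
    """
    v = iv.voltages
    i = iv.currents
    if v.size < 5:
        raise ValueError("need >= 5 IV points spanning the activation range")
    scale = float(np.max(np.abs(i)))
    if scale == 0.0 or scale < 1e-12:
        return BoltzmannFit(0.0, float("nan"), float("nan"), float("nan"),
                            0.0, ok=False,
                            message="all-zero currents: parameters unidentifiable")

    if init is None:
        # fully activated limb: last third is ~linear, I ≈ g(V − v_rev)
        k = max(3, v.size // 3)
        A = np.column_stack([v[-k:], np.ones(k)])
        m, b = np.linalg.lstsq(A, i[-k:], rcond=None)[0]
        g0 = m if abs(m) > 1e-9 else (1.0 if i[-1] >= 0 else -1.0)
        vr0 = float(np.clip(-b / g0, v.min() - 200, v.max() + 200))
        # half-activation: where |I| reaches half its linear-limb prediction
        frac = i / np.where(np.abs(g0 * (v - vr0)) < 1e-12, np.nan,
                            g0 * (v - vr0))
        ok_frac = np.isfinite(frac)
        vh0 = float(v[ok_frac][np.argmin(np.abs(frac[ok_frac] - 0.5))]) if ok_frac.any() else float(np.median(v))
        init = (float(g0), vr0, vh0, 6.0)

    rng = np.random.default_rng(0)
    best = None
    x0 = np.asarray(init, dtype=float)
    for trial in range(max_restarts + 1):
        start = x0 if trial == 0 else x0 * (1 + 0.2 * rng.standard_normal(4)) + \
            np.array([0, 5, 5, 1]) * rng.standard_normal(4)
        start[3] = max(abs(start[3]), 0.5)
        try:
            popt, _ = optimize.curve_fit(
                _boltzmann, v, i, p0=start, maxfev=20000,
                bounds=([-np.inf, -np.inf, -np.inf, 1e-6],
                        [np.inf, np.inf, np.inf, np.inf]))
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((i - _boltzmann(v, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss < (1e-12 * scale ** 2) * v.size:
            break
    if best is None:
        return BoltzmannFit(float("nan"), float("nan"), float("nan"),
                            float("nan"), float("inf"), ok=False,
                            message="nonlinear fit failed to converge after restarts")
    popt, rss = best
    return BoltzmannFit(g_max=float(popt[0]), v_rev=float(popt[1]),
                        v_half=float(popt[2]), slope=float(popt[3]),
                        rss=rss, ok=True)


# ---------------------------------------------------------------------------
# per-feature screen
# ---------------------------------------------------------------------------

def rhythm_screen(df: pd.DataFrame, period_h: float = 24.0,
                  lag_step_h: float | None = None) -> pd.DataFrame:
    """Cosinor + JTK statistics for every feature of a long-format table.

    df columns: feature_id, time_h, replicate, value.  Returns one row per
    feature with mesor, amplitude, acrophase_h, F, cosinor_p, jtk_tau,
    jtk_lag_h, jtk_p, jtk_amplitude and BH-adjusted p columns.
    """
    required = {"feature_id", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    bad = df[~np.isfinite(df["value"].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"non-finite values in rows: {bad.index.tolist()[:10]}")
    rows = []
    for fid, sub in df.groupby("feature_id", sort=True):
        cos = fit_cosinor(sub, period_h=period_h)
        jtk = jtk_test(sub, period_h=period_h, lag_step_h=lag_step_h)
        rows.append({
            "feature_id": fid,
            "mesor": cos.mesor,
            "amplitude": cos.amplitude,
            "acrophase_h": cos.acrophase_h,
            "f_statistic": cos.f_statistic,
            "cosinor_p": cos.p_value,
            "jtk_tau": jtk.tau,
            "jtk_lag_h": jtk.best_lag_h,
            "jtk_p": jtk.p_value,
            "jtk_amplitude": jtk.amplitude_est,
        })
    out = pd.DataFrame(rows)
    out["cosinor_adj_p"] = bh_adjust(out["cosinor_p"].to_numpy())
    out["jtk_adj_p"] = bh_adjust(out["jtk_p"].to_numpy())
    return out
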