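"""Cosinor, JTK-style test, BH adjustment, Boltzmann fits — against oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chronocard.rhythm_stats import (bh_adjust, fit_boltzmann_iv, fit_cosinor,
                                     jtk_test, kendall_tau)
from chronocard.synthetic_rhythms import (RhythmTruth, generate_iv_curve,
                                          generate_null_panel, generate_panel)


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

def _grid_search_cosinor(t, y, period=24.0, n_phi=2400):
    """Independent oracle: direct least squares over (M, A, phi) by phi grid."""
    best = None
    for phi in np.linspace(0, period, n_phi, endpoint=False):
        c = np.cos(2 * np.pi * (t - phi) / period)
        X = np.column_stack([np.ones_like(t), c])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if best is None or rss < best[0]:
            best = (rss, coef[0], coef[1], phi)
    _, m, a, phi = best
    if a < 0:
        a, phi = -a, (phi + period / 2) % period
    return m, a, phi


class TestCosinor:
    def test_noise_free_recovery_exact(self):
        truth = RhythmTruth(mesor=3.0, amplitude=2.0, acrophase_h=12.0,
                            sigma=0.0, n_reps=2, seed=0)
        fit = fit_cosinor(generate_panel(truth))
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(12.0, abs=1e-9)
        assert fit.mesor == pytest.approx(3.0, abs=1e-9)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)

    def test_constant_panel_flat_fit(self):
        truth = RhythmTruth(mesor=7.0, amplitude=0.0, acrophase_h=0.0,
                            sigma=0.0, n_reps=2, seed=0)
        fit = fit_cosinor(generate_panel(truth))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.f_statistic == 0.0
        assert fit.p_value == 1.0

    def test_noisy_recovery_within_3se_and_matches_grid_oracle(self):
        truth = RhythmTruth(mesor=5.0, amplitude=1.0, acrophase_h=8.0,
                            sigma=0.3, n_reps=5, seed=11)
        panel = generate_panel(truth)
        fit = fit_cosinor(panel)
        assert abs(fit.amplitude - 1.0) < 3 * fit.se_amplitude
        assert abs(fit.acrophase_h - 8.0) < 3 * fit.se_acrophase_h
        t = panel.data.time_h.to_numpy()
        y = panel.values
        m, a, phi = _grid_search_cosinor(t, y)
        assert fit.mesor == pytest.approx(m, abs=1e-3)
        assert fit.amplitude == pytest.approx(a, rel=1e-3)
        assert fit.acrophase_h == pytest.approx(phi, abs=24 / 2400 + 1e-6)

    def test_too_few_timepoints_rejected(self):
        truth = RhythmTruth(mesor=0, amplitude=1, acrophase_h=0, sigma=0.1,
                            n_reps=4, seed=0)
        panel = generate_panel(truth, timepoints_h=(0.0, 12.0))
        with pytest.raises(ValueError, match="distinct timepoints"):
            fit_cosinor(panel)

    def test_estimates_unbiased_over_simulations(self):
        # A/sigma = 2, n_reps 4: mean estimate within 2% of truth
        amps, acros = [], []
        for seed in range(500):
            truth = RhythmTruth(mesor=10.0, amplitude=2.0, acrophase_h=10.0,
                                sigma=1.0, n_reps=4, seed=seed)
            fit = fit_cosinor(generate_panel(truth))
            amps.append(fit.amplitude)
            acros.append(fit.acrophase_h)
        assert np.mean(amps) == pytest.approx(2.0, rel=0.02)
        assert np.mean(acros) == pytest.approx(10.0, rel=0.02)


# ---------------------------------------------------------------------------
# Kendall tau and JTK
# ---------------------------------------------------------------------------

def _tau_b_oracle(x, y):
    """O(n²) pair-counting tau-b with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a = np.sign(x[j] - x[i])
        b = np.sign(y[j] - y[i])
        if a == 0 and b == 0:
            tx += 1
            ty += 1
        elif a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom else 0.0


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(-3, 3), min_size=3, max_size=12),
       st.integers(0, 2**30))
def test_kendall_tau_matches_pair_counting_oracle(ys, seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(-3, 4, size=len(ys)).astype(float)
    y = np.array(ys, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        assert kendall_tau(x, y) == 0.0
    else:
        assert kendall_tau(x, y) == pytest.approx(_tau_b_oracle(x, y), abs=1e-12)


def _brute_force_jtk_p(t, y, lag, period=24.0):
    """Exact one-sided tau tail by full enumeration of all N! orderings."""
    ref = np.cos(2 * np.pi / period * (t - lag))

    def s_stat(vec):
        s = 0
        for i, j in itertools.combinations(range(len(vec)), 2):
            s += np.sign(vec[j] - vec[i]) * np.sign(ref[j] - ref[i])
        return s

    s_obs = s_stat(y)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if s_stat(perm) >= s_obs:
            count += 1
    return count / total


class TestJTK:
    def test_noise_free_cosine_best_lag_matches_acrophase(self):
        truth = RhythmTruth(mesor=0.0, amplitude=1.0, acrophase_h=12.0,
                            sigma=0.0, n_reps=2, seed=0)
        res = jtk_test(generate_panel(truth))
        assert res.best_lag_h == 12.0
        assert res.p_value < 0.05
        assert res.amplitude_est == pytest.approx(1.0, rel=1e-6)

    def test_antiphase_series_shifts_lag_by_half_period(self):
        truth = RhythmTruth(mesor=0.0, amplitude=1.0, acrophase_h=4.0,
                            sigma=0.0, n_reps=2, seed=0)
        panel = generate_panel(truth)
        flipped = panel.data.copy()
        flipped["value"] = -flipped["value"]
        res = jtk_test(flipped)
        assert res.best_lag_h == (4.0 + 12.0) % 24.0

    def test_all_tied_observations_degenerate(self):
        truth = RhythmTruth(mesor=2.0, amplitude=0.0, acrophase_h=0.0,
                            sigma=0.0, n_reps=3, seed=0)
        res = jtk_test(generate_panel(truth))
        assert res.tau == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [3, 17])
    def test_exact_p_equals_brute_force_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        t = np.repeat([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 2)[:8]
        y = np.round(rng.normal(size=8), 1)  # rounding induces ties
        import pandas as pd
        panel = pd.DataFrame({"feature_id": "f", "time_h": t,
                              "replicate": 0, "value": y})
        res = jtk_test(panel, lag_step_h=4.0)
        assert res.exact
        # recover the uncorrected minimum-p and its lag via brute force
        best = min((_brute_force_jtk_p(t, y, lag) for lag in
                    np.arange(0.0, 24.0, 4.0)))
        assert res.p_value == pytest.approx(min(1.0, best * 6), rel=1e-12)

    def test_p_values_valid_under_null(self):
        # conservative: empirical rejection <= alpha (with MC slack)
        rejections = 0
        n_sim = 400
        for seed in range(n_sim):
            panel = generate_null_panel(mesor=0.0, sigma=1.0, n_reps=4,
                                        seed=10_000 + seed)
            if jtk_test(panel).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_power_at_moderate_effect_size(self):
        # A/sigma = 2, 6 timepoints x 4 replicates, alpha 0.05
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            truth = RhythmTruth(mesor=0.0, amplitude=2.0, acrophase_h=6.0,
                                sigma=1.0, n_reps=4, seed=20_000 + seed)
            if jtk_test(generate_panel(truth)).p_value < 0.05:
                hits += 1
        assert hits / n_sim >= 0.9

    def test_lag_step_must_divide_period(self):
        truth = RhythmTruth(mesor=0, amplitude=1, acrophase_h=0, sigma=0.1,
                            n_reps=2, seed=0)
        with pytest.raises(ValueError, match="divide"):
            jtk_test(generate_panel(truth), lag_step_h=7.0)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_computed_step_up(self):
        # p(3)=0.03 -> 0.03; p(2)=0.02*3/2=0.03; p(1)=0.01*3=0.03
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        adj = bh_adjust([0.04] * 5)
        assert np.allclose(adj, 0.04)

    def test_monotone_and_dominates_input(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Boltzmann IV fit
# ---------------------------------------------------------------------------

class TestBoltzmann:
    def test_noise_free_roundtrip_within_0p1_percent(self):
        v = np.arange(-80.0, 41.0, 5.0)
        iv = generate_iv_curve(g_max=1.0, v_half=-40.0, slope=5.0, v_rev=40.0,
                               voltages=v)
        fit = fit_boltzmann_iv(iv)
        assert fit.ok
        assert fit.g_max == pytest.approx(1.0, rel=1e-3)
        assert fit.v_half == pytest.approx(-40.0, rel=1e-3)
        assert fit.slope == pytest.approx(5.0, rel=1e-3)
        assert fit.v_rev == pytest.approx(40.0, rel=1e-3)

    def test_all_zero_currents_flagged_degenerate(self):
        v = np.arange(-80.0, 41.0, 10.0)
        fit = fit_boltzmann_iv(generate_iv_curve(0.0, -40.0, 5.0, 40.0, v))
        assert not fit.ok
        assert fit.g_max == 0.0

    def test_noisy_roundtrip_within_5_percent(self):
        v = np.arange(-80.0, 41.0, 2.5)
        clean = generate_iv_curve(1.0, -40.0, 5.0, 40.0, v)
        noise_sd = 0.02 * np.max(np.abs(clean.currents))
        iv = generate_iv_curve(1.0, -40.0, 5.0, 40.0, v, noise_sd=noise_sd,
                               seed=4)
        fit = fit_boltzmann_iv(iv)
        assert fit.ok and fit.rss > 0
        assert fit.g_max == pytest.approx(1.0, rel=0.05)
        assert fit.v_half == pytest.approx(-40.0, rel=0.05)
        assert fit.slope == pytest.approx(5.0, rel=0.05)

    def test_too_few_points_rejected(self):
        iv = generate_iv_curve(1.0, -40.0, 5.0, 40.0, [-60, -40, -20, 0])
        with pytest.raises(ValueError, match=">= 5"):
            fit_boltzmann_iv(iv)
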