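# Methods

## Scope and model of the problem

The package quantifies how day–night (zeitgeber-time, ZT) rhythms in
cardiac ion-channel expression alter the ventricular electrophysiological
substrate.  The causal chain it implements is: measured diurnal changes in
ionic current densities → multiplicative scaling of maximal conductances in
a ventricular myocyte model → changes in the action potential (upstroke
velocity, amplitude, APD90) → changes in tissue-level markers of
arrhythmia vulnerability on a 1-D cable (conduction velocity, S1–S2
vulnerable window, wavelength).  A parallel statistical track implements
the rhythm-detection methods used to identify such diurnal changes in
time-series panels (cosinor, JTK-style nonparametric testing, FDR
adjustment) and Boltzmann IV fitting for voltage-clamp data.

## Diurnal scenarios

Scenarios are maps current-label → multiplicative factor on the model's
maximal conductance, plus a coupling factor on cable diffusion
(`diurnal_scaling`).  Two factors are anchored to printed patch-clamp
measurements: at ZT12 peak I_Na at a −30 mV test potential is ≈42% lower
(factor 0.58) and end-of-pulse I_Kr ≈150% higher (factor 2.50) than at
ZT0.  Under voltage clamp a current is exactly proportional to its maximal
conductance (gating trajectories do not depend on conductance), so these
factors reproduce the measured percentage changes exactly; the package
verifies this by simulated clamp rather than asserting it.

The coupling factor 0.75 at ZT12 encodes only the *direction* of the lower
Cx43/Gja1 expression in the dark phase; it is a configurable default, not a
measurement, and is flagged as a placeholder in the scenario provenance.
Factors for currents whose diurnal magnitudes are not printed (I_CaL, I_to,
I_NCX, …) default to 1; the YAML scenario schema accepts them so a full
scaling table can be supplied verbatim.  `ZT12_GRKO` (cardiomyocyte
glucocorticoid-receptor knockout) equals ZT12 with the I_Na, I_Kr and
coupling factors restored to 1; with all placeholders at their defaults it
is numerically identical to ZT0, which the test suite uses as a
harness-level identity check.

## Myocyte models

**Human.** The ten Tusscher–Panfilov 2006 human ventricular formulation
with the epicardial parameter set, implemented in full (19 states: fast
Na⁺ current; L-type Ca²⁺ current with subspace Ca²⁺-dependent
inactivation; I_to; I_Kr; I_Ks; I_K1; NCX; Na⁺/K⁺ pump; plateau and
background currents; cytosol/subspace/SR Ca²⁺ dynamics with a four-state
release gate; dynamic Na⁺ᵢ and K⁺ᵢ).  Paced at a 1000-ms cycle length from
the published initial conditions with ≥50 pre-pacing beats it yields
APD90 ≈ 307 ms, inside the 250–320 ms range documented for that model.

**Mouse.** No complete published equation set was available for the mouse
model the tissue analysis is normally paired with, so the package provides
its own compact mouse ventricular model assembled from documented
formulations: Luo–Rudy-type I_Na kinetics (m³hj); an L-type Ca²⁺ current
with voltage- and Ca²⁺-dependent inactivation; the murine repolarization
currents I_to,f and I_Kur/I_K,slow with Bondarenko-style activation
kinetics; small I_Kr (retained and scalable because it is measured and
diurnally regulated in mouse) and I_Ks; inward-rectifier I_K1; NCX and
Na⁺/K⁺ pump with ten Tusscher-type driving terms; background/pump Ca²⁺
currents; and a single-compartment SR (SERCA uptake, leak, d-gate-triggered
release).  Intracellular Na⁺ (12 mM) and K⁺ (140 mM) are fixed so the
quiescent cell is a genuine steady state anchored by I_K1; the frozen
resting state (V ≈ −79.9 mV) is the 60-s unstimulated fixed point.

Default conductances (µA/µF per mV unless noted): g_Na 13, g_CaL 0.10,
g_to 0.16, g_Kur 0.12, g_Kr 0.20, g_Ks 0.02, g_K1 0.50, k_NCX 1000 (scale),
p_NaK 1.2, g_bNa 0.009, g_bCa 5×10⁻⁴, g_pCa 0.05.  They were chosen once so
that the paced cell reproduces the defining murine phenotype: resting
potential ≈ −80 mV, dV/dt_max ≈ 280 V/s, triangular AP with APD90 ≈ 12 ms
at a 150-ms cycle length, and a restitution curve that rises with the S2
coupling interval.  Three kinetic choices serve that last property and are
worth recording: I_CaL recovers slowly from inactivation at rest
(τ_f ≈ 135 ms) while murine I_to,f recovers fast (τ_i ≈ 8 ms); I_Kr
deactivates slowly at rest (τ_xr ≈ 300 ms) so premature beats carry extra
residual repolarizing current; and the I_K1 rectification is shallow
(exponent 0.06/mV) so the terminal repolarization tail is brisk.  Because
all mouse-side claims in the acceptance suite are directional (ZT12 vs
ZT0), none of these choices is tuned to a printed simulation value.

**Contract.** Both models sit behind one `MembraneModel` interface: an
ordered state vector (V_m first), a named parameter vector, a compiled
per-node step kernel and a per-current breakdown whose components sum to
the total ionic current.  Scenario application multiplies named
conductances and never mutates the source model.

## Numerics

Gating variables advance by Rush–Larsen exponential updates
(g ← g∞ + (g−g∞)e^(−Δt/τ)), which keeps them in [0, 1] unconditionally;
voltage and concentrations use explicit Euler steps.  Default Δt: 0.005 ms
(mouse single cell), 0.02 ms (human and cable).  Halving Δt changes the
mouse APD90 by <1% (tested).  The cable is monodomain with no-flux
boundaries, operator-split per step: explicit finite-difference diffusion
on V, then the reaction update; the stability bound D·Δt/Δx² ≤ 0.5 is
enforced with a diagnostic.  Space step Δx = 0.05 mm on a 15-mm cable
(300 nodes): at 0.1 mm the ~0.4-mm upstroke is only four nodes wide and
halving Δx moved CV by ~4%, whereas at 0.05 mm the halving error is ~0.9%,
within the package's 2% convergence requirement.  The diffusion default
D = 0.05 mm²/ms puts the baseline CV at 0.43 mm/ms (physiological
0.3–0.6 band), and CV ∝ √D holds with R² > 0.99 over a 4× range, matching
continuous-cable theory.  Divergence (non-finite state or |V| > 200 mV)
aborts with the first offending state named.  All simulations are
deterministic and bit-reproducible for fixed inputs.

## Protocols and measurements

Stimuli are 1-ms rectangular current pulses at 1.5× the diastolic
threshold, found by bisection — per model for single cells, and per
(model, cable, coupling) for tissue, where source–sink loading raises the
threshold severalfold; both are logged.  Capture means the membrane
exceeds −10 mV within 10 ms of the pulse.  Steady-state pacing runs ≥50
pre-pacing beats until consecutive-beat |ΔAPD90| < 0.1 ms (≤200 beats,
warned otherwise).  APD90 is measured from the instant of dV/dt_max to the
crossing of overshoot − 0.9·(overshoot − resting V), linearly interpolated;
on an analytic triangular AP this reproduces the closed form to <0.1 ms.

**Restitution.** After steady S1 pacing, ten further S1 beats precede a
single premature S2 per trial (no cumulative S2 memory); the S2 beat's
APD90 is plotted against the coupling interval.  The default grid maps
S2 ∈ [50, 0.8·BCL] ms.  Below ~45 ms the model produces graded,
low-amplitude responses whose fixed-percentage repolarization level dives
toward rest, inflating the measured duration — a known artifact of
amplitude-referenced APD on decremental beats — so the mapped range
excludes them; within the mapped range APD90 is monotone in the coupling
interval.

**Conduction velocity.** Activation = first upward crossing of −30 mV;
CV = distance/Δ(activation time) between sensors at 25% and 75% of the
cable, measured on the last of three in-cable S1 beats started from the
single-cell paced steady state.

**Vulnerable window.** S1 waves are launched from one cable end; the S2 is
delivered to a 1-mm electrode at 50% of the length, in the wake of the S1
wave, so retrograde tissue (activated earliest) recovers first.  Outcomes
per S2 coupling interval: *no_capture* (site does not re-activate),
*unidirectional* (retrograde propagation only — the arrhythmogenic case),
*bidirectional*.  Attribution excludes the S1 wave by requiring it to have
cleared both sensors before the S2; earlier S2s are flagged indeterminate.
The scan walks 1-ms coarse steps, additionally bisecting any direct
no_capture→bidirectional jump (the band can be narrower than the coarse
step), then refines both band edges by bisection to 0.1 ms (0.25 ms in the
test fixtures).  With a 0.5-mm electrode the baseline band collapses below
0.25 ms; the 1-mm default yields ZT0 ≈ 2.9 ms and ZT12 ≈ 4.5 ms at a
200-ms S1 cycle.  Wavelength multiplies the single-cell steady-state APD90
at the same cycle length by the cable CV.

**Programmed electrical stimulation.** `build_pes_train` reproduces the ex
vivo timing: a drive train of 20 S1 at 98 ms followed by S2–S10
extra-stimulus trains at cycle lengths 58, 48, …, 8 ms with 3-s gaps —
exposed for demonstration runs on the cable, not used in acceptance.

## Rhythm statistics

**Cosinor.** OLS on y = M + β₁cos ωt + β₂sin ωt with fixed ω = 2π/24 h
(no period scan); amplitude √(β₁²+β₂²), acrophase atan2(β₂,β₁)/ω mapped to
[0, 24) h in peak-time convention; zero-amplitude F(2, N−3) test; delta-
method standard errors.  Calibration: empirical type-I error 0.052 at
α = 0.05 over 1000 null panels (6 timepoints × 4 replicates), inside the
95% binomial band; amplitude/acrophase estimates unbiased to <2% at
A/σ ≥ 2.

**JTK-style test.** For each lag on the sampling grid (6 lags at 4-h
spacing), Kendall τ-b between observations and the reference cosine peaking
at that lag; the reported p is the minimum one-sided tail probability ×
number of lags (Bonferroni), truncated at 1.  The tail is exact for N ≤ 10
via enumeration of tie-respecting permutations (capped at 2×10⁵ distinct
arrangements) and a tie-corrected normal approximation otherwise; the exact
path is verified against full N! enumeration in the tests.  Amplitude is
the least-squares cosine amplitude at the selected lag.  The test is
conservative under the null and has power 1.0 at A/σ = 2 with the 6×4
design (200 simulations).

**FDR.** Benjamini–Hochberg step-up (statsmodels), applied across features
in the screening table.

**Boltzmann IV.** Nonlinear least squares of
I = G_max(V−V_rev)/{1+exp[(V_0.5−V)/s]} with s > 0, data-derived starting
values (linear extrapolation of the fully activated limb) and bounded
random restarts; all-zero curves are flagged degenerate rather than fitted.
Noise-free round-trips recover generator parameters to ≪0.1%.

## Synthetic data

`synthetic_rhythms` emulates the study design of 6-timepoint diurnal
panels — ZT0…ZT20 at 4-h spacing over a 24-h cycle — as a cosine of known
MESOR, amplitude, acrophase and period plus i.i.d. Gaussian noise per
replicate (log-normal multiplicative noise available but off by default),
with configurable replicate count and pure-noise nulls.  Replicates within
a timepoint are exchangeable; there is no animal-level random effect,
matching the pooled-replicate design of the panels it stands in for.  No
per-replicate variance is reported for the real panels, so the default σ
values in tests are fixture choices, not estimates.  Generators are pure
functions of (parameters, grid, seed).  Consequently, passing statistical
tests demonstrate calibration and power under Gaussian, balanced,
fixed-period conditions — not robustness to the heteroscedastic, missing-
data, multi-animal structure of real telemetry or qPCR panels.

## Problem sizes

Default analysis sizes, chosen to keep a full comparison on one CPU in
minutes: 15-mm cable at 300 nodes; VW edges to 0.1 ms; 1000 null panels
for type-I calibration; 200 simulations for power; 500 for bias.  The
`ComparisonConfig` dataclass exposes all of them.

## Known limitations

* The mouse model is a compact construction from documented current
  formulations, not a re-implementation of any specific published mouse
  model; only directional diurnal conclusions should be drawn from it.
* Scaling factors for non-anchored currents default to 1; results reflect
  the two measured anchors plus the coupling placeholder, and will change
  if a full scaling table is supplied.
* 1-D monodomain tissue only: the vulnerable window is a surrogate for
  reentry initiation; no 2-D/3-D reentry, fiber heterogeneity or bidomain
  effects.
* Fixed 24-h period in all rhythm statistics; no period estimation,
  detrending, or mixed-effects cosinor.
* β-adrenergic/CaMKII signalling, stochastic gating and temperature
  effects are out of scope.
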