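# Methods

## 3Q relaxation model

The observables are the forbidden/allowed peak-intensity ratio and the
allowed-intensity decay of a ¹³CH₃ probe:

    R(T) = (3·N_all / 4·N_forb) · η·tanh(λT) / (λ − δ·tanh(λT)),   λ = √(η² + δ²)
    I_all(T) = (A/2)·(3·e^(−R_slow·T) + e^(−R_fast·T))
    η = (R_fast − R_slow)/2 ∝ S²axis · τ_c

η > 0 is the intra-methyl ¹H–¹H dipolar cross-correlated relaxation rate,
δ < 0 the coupling between fast- and slow-decaying single-quantum
coherences, and the 3:1 amplitude ratio of the biexponential is fixed by
the spin physics of the methyl group. All delays are seconds and rates s⁻¹
internally; files carry delays in ms.

δ = 0 is accepted in model evaluation (the ratio collapses to
(3N_all/4N_forb)·tanh(ηT), a useful limiting check) but excluded by the
fitting constraints.

### η ↔ S²axis conversion

η = C·τ_c·S²axis with

    C = (9/10)·P₂(cos θ)²·γ_H⁴·ħ²·(μ₀/4π)²/r_HH⁶

Defaults: r_HH = 1.813 Å and θ (methyl axis to H–H vector) = 90°, giving
C ≈ 3.61·10⁹ s⁻² — e.g. τ_c = 20 ns and S²axis = 0.6 give η ≈ 43 s⁻¹.
Both geometry constants and τ_c are user-settable; converted values
outside [0, 1] are returned with a warning, since they usually indicate a
wrong τ_c. Rate measurements themselves never depend on this constant.

## Fitting

**Full scheme.** Forbidden/allowed ratios at all matched delays are fit by
weighted least squares (weights 1/σ², σ from standard first-order
propagation of the two intensity noises) for (η, δ) under box constraints
η > 0, δ < 0. The single-quantum rates are not separately identifiable
from ratios alone and are left unset.

**Reduced scheme.** For short-lived samples with five allowed spectra and
one (or two) forbidden spectra, the allowed decay and the available
ratio(s) enter one objective, each residual in its own noise units, with
free parameters (A, R_slow, η, δ) and R_fast = R_slow + 2η by
construction — the rate ordering therefore cannot be violated and η is
tied to the decay-rate spread. No extra weighting factor balances the two
residual blocks; the noise units already do.

**Initialization** is deterministic and data-driven: η₀ from the small-T
ratio slope (ratio at the shortest delay divided by the prefactor times
that delay), R_slow,₀ from a log-linear fit to the allowed decay, A₀ from
the same fit extrapolated to T = 0 (halved, since I_all(0) = 2A), and
δ₀ = −1 s⁻¹. The optimizer is a trust-region reflective least-squares
solver with tolerances 10⁻¹⁴ and at most 10⁴ function evaluations;
non-convergence is flagged on the result, never silently dropped.

**Low-intensity filter.** Peaks whose forbidden intensity at the reference
delay (default: the longest acquired forbidden delay, 16 ms in the full
delay set) is below 10× that spectrum's noise are excluded before fitting;
the threshold and reference are configurable and exclusions carry reason
codes.

**Forbidden-delay selection.** To decide which forbidden delay a reduced
acquisition should keep, every peak of a fully sampled dataset is refit
with each candidate subset of one or two forbidden delays; the
across-peak sum of squared η differences against the full-scheme fits is
reported per subset and the minimizer selected (ties: fewer delays, then
shorter maximum delay — cheaper acquisitions first).

## Bootstrap uncertainties

Each replicate redraws every measured intensity from
Normal(measured, noise σ), refits, and the reported parameters are the
mean over converged replicates with the SD as the error (default 1000
replicates; tests and the acceptance script use 200, which changes SD
estimates by only ~5%). Negative resampled intensities are allowed into
the fit — the parameter constraints protect the result. Replicates are a
pure function of (data, master seed); per-peak child seeds derive
deterministically from the master seed and peak index. Results with more
than half the replicates non-converged are flagged unreliable.

Calibration: the median bootstrap SD over ten independent 2%-noise
datasets matches the empirical SD of 200 independently simulated fits to
within ~10% for the full scheme. The median (not the mean) summarizes the
bootstrap SD because a single dataset's bootstrap SD is itself a random
quantity with occasional large excursions where the fit lands in a locally
flat region.

## PRE analysis

Per-peak ratio = I_para/I_dia with first-order error propagation
(σ_ratio finite at I_para = 0). Exposure flag: ratio < mean − k·SD across
peaks, sample (n − 1) SD, default k = 1 — the mean ± 1 SD band is the
customary visual reference for these plots, and k is configurable because
no universal numeric cut exists. Ratios and flags are invariant to a
common intensity rescaling of both spectra.

## MD order parameters

S²axis per window is the second-rank tensor (Lipari–Szabo plateau)
estimate

    S² = (3/2)·Σ_ab ⟨e_a e_b⟩² − 1/2

over molecular-frame unit bond vectors; it is rotation-invariant, exactly
1 for a rigid vector, and 0 in the isotropic limit. Input vectors must
already be in a molecule-fixed frame — removing overall tumbling from raw
Cartesian trajectories is a preprocessing contract, not done here.

Windowing defaults: discard 25 ns of equilibration, then 32-ns windows
overlapping by 28 ns (an ~80-ns trajectory yields six windows starting at
25, 29, …, 45 ns). The across-window SD exposes motions slower than a
window: a designed two-state trajectory (cone center jumping mid-run)
shows a larger window SD than a stationary one of equal length. A window
subset can be selected by index when a protocol uses only some windows.

Ligand differences: Δ = value(condition a) − value(condition b) per shared
peak, errors in quadrature; negative Δη means faster ps–ns motions in
condition a. The same operation serves η (NMR) and S²axis (MD).

## Synthetic data

The relaxation generator draws per-peak truths uniformly — η ∈ [10, 100]
s⁻¹ and δ ∈ [−10, −0.5] s⁻¹ (bracketing values typical of large
protein–micelle particles), R_slow ∈ [20, 60] s⁻¹ — sets
R_fast = R_slow + 2η, evaluates the closed forms, and adds one Gaussian σ
per experiment type with σ = noise_fraction × I_all(0) (spectral noise
floors are homoscedastic per spectrum). η is drawn directly rather than
derived from (S², τ_c) so that simulated rates never depend on the
geometry constant; an S²/τ_c-driven mode exists via the exact inverse
conversion. Delay sets default to 0.8/2/4/8/16 ms (full) and
0.8/2/4/8/14 ms allowed + 8 ms forbidden (reduced). When
noise_fraction = 0 a tiny positive σ (10⁻⁹ of I(0)) is recorded so the
σ > 0 validator holds while round-trips stay exact to ≤ 10⁻⁶ relative
error (measured: ~10⁻¹⁴).

The cone generator diffuses a unit vector by isotropic tangent-plane
Gaussian kicks of angular scale √(2·dt/τ), reflecting the polar angle at
the cone edge; its stationary distribution is uniform within the cone,
which is the only property the S² estimator depends on. An i.i.d.
uniform-in-cone sampler provides the sharper oracle for estimator tests.

The PRE generator draws diamagnetic intensities around a common scale,
multiplies by prescribed true ratios for the paramagnetic table, and adds
Gaussian noise to both.

What the generators do **not** emulate: peak overlap and lineshapes,
baseline artifacts, sample-degradation drift across summed acquisitions,
heteroscedastic noise within a spectrum, and correlated MD noise beyond a
single diffusive timescale. Green tests therefore demonstrate estimator
correctness and statistical calibration under the stated noise model, not
robustness to spectral pathologies.

## Problem sizes and known limitations

- Scheme-comparison runs use 50 synthetic methyls with 200 bootstrap
  replicates; calibration uses 200 independent realizations; cone oracles
  use 4·10⁵–10⁶ samples. These sizes put Monte-Carlo error well below the
  tolerances tested while keeping a full run around a minute.
- With a single forbidden point, (η, δ) sit on a likelihood ridge: a large
  η with proportionally large |δ| fits the lone ratio, and only the
  allowed decay penalizes it. At 2% spectral noise roughly the noisiest
  sixth of reduced-scheme fits drift up this ridge; their bootstrap SDs
  grow commensurately, so estimates remain statistically consistent with
  full-scheme values (the reduced scheme's agreement check passes by wide,
  honest error bars, not by tight recovery). Fitting two forbidden delays,
  or better intrinsic S/N (e.g. summed forbidden scans), tightens η
  substantially.
- The exclusion filter keys on one reference delay; peaks missing that
  measurement are excluded with a reason code rather than guessed.
- Bootstrap resampling is over intensities (the measured quantity), not
  over delays — with ≤ 6 points per curve, case resampling would be
  meaningless.
- S² estimates from finite windows can fall slightly outside [0, 1]
  (sampling noise); they are reported unclamped.
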