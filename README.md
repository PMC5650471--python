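# methyldyn

Quantify ligand-modulated, fast (ps–ns) methyl sidechain dynamics of large
membrane proteins — GPCRs in detergent micelles being the motivating case —
from three complementary measurements:

1. **Triple-quantum (3Q) NMR relaxation.** In paired "forbidden"/"allowed"
   methyl-TROSY experiments, single-quantum ¹H coherence of a ¹³CH₃ group
   converts into triple-quantum coherence at the intra-methyl ¹H–¹H dipolar
   cross-correlated relaxation rate η. The forbidden/allowed intensity
   ratio as a function of relaxation delay *T* follows

       I_forb/I_all = (3·N_all / 4·N_forb) · η·tanh(√(η²+δ²)·T) / (√(η²+δ²) − δ·tanh(√(η²+δ²)·T))

   with δ < 0 a coupling between fast- and slow-relaxing coherences and
   N the scans per experiment, while the allowed intensity decays as

       I_all(T) = (A/2)·(3·e^(−R₂ₕˢ·T) + e^(−R₂ₕᶠ·T)),   η = (R₂ₕᶠ − R₂ₕˢ)/2 ∝ S²axis·τ_c.

   η is therefore a per-methyl rigidity meter: higher η, more rigid methyl
   axis. `methyldyn` fits η per peak in the **full scheme** (ratios at all
   delays) or a **reduced scheme** (five allowed spectra plus a single
   forbidden spectrum, for samples too short-lived for the full series),
   with Monte-Carlo bootstrap uncertainties, a ten-fold noise exclusion
   filter, and a tool for choosing which forbidden delay to keep.

2. **Solvent PRE.** Paramagnetic/diamagnetic intensity ratios report
   solvent accessibility; peaks attenuated below mean − k·SD are flagged
   exposed.

3. **MD order parameters.** Windowed S²axis estimates from molecular-frame
   methyl-axis bond vectors (tensor/Lipari–Szabo plateau estimator,
   default six 32-ns windows overlapping by 28 ns after a 25-ns discard),
   and per-peak condition differences (Δη or ΔS²) between two ligand
   states with propagated errors.

A synthetic-data module generates every input with known ground truth:
noisy forbidden/allowed series from the closed-form model, PRE pairs, and
cone-restricted bond-vector diffusion whose analytic
S² = [cosθ₀(1+cosθ₀)/2]² anchors the order-parameter estimator.

## Worked example

```python
from methyldyn import (SyntheticRelaxationSpec, simulate_relaxation_dataset,
                       mask_forbidden, fit_full_scheme, bootstrap_fit,
                       BootstrapConfig)

spec = SyntheticRelaxationSpec(n_peaks=3, noise_fraction=0.02, seed=42)
dataset, truths = simulate_relaxation_dataset(spec)
for i, s in enumerate(dataset):
    full = fit_full_scheme(s)
    boot = bootstrap_fit(mask_forbidden(s, (0.008,)), scheme="reduced",
                         config=BootstrapConfig(n_replicates=200, seed=i))
    t = truths[s.peak.peak_id]
    print(f"{s.peak.peak_id}  true {t['eta']:5.1f}  full {full.params.eta:5.1f}  "
          f"reduced {boot.fit.params.eta:6.1f} +/- {boot.fit.eta_err:5.1f}")
```

prints

```
syn000  true  79.7  full  84.2  reduced  370.1 +/- 228.8
syn001  true  84.0  full  85.8  reduced  116.5 +/- 118.3
syn002  true  52.0  full  55.4  reduced   68.0 +/-  24.4
```

The full scheme, with five ratio points, pins η to within a few s⁻¹ at 2%
spectral noise. The reduced scheme keeps only the 8-ms forbidden point, so
η is carried largely by the biexponential allowed decay; at this noise
level that leaves η weakly determined for some peaks, and the bootstrap
standard deviations say so honestly (syn000's estimate is consistent with
its full-scheme value *because* its error bar is wide). This is exactly
why the reduced scheme is paired with bootstrap errors rather than point
estimates.

The same pipeline is available from the shell:

```sh
methyldyn simulate --out fixtures --n-peaks 25 --seed 7
methyldyn fit fixtures/relaxation.tsv --scheme reduced --bootstrap 200 --seed 7 --out results
methyldyn pre fixtures/pre.tsv --k 1 --out results
methyldyn mdorder fixtures/bond_vectors.tsv --out results
methyldyn report results_a/fits.tsv results_b/fits.tsv --out results  # Δη table
```

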