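# gradmech

Mechanistic–statistical modelling of chemokine gradient images.

## The problem

Secreted guidance cues such as the chemokine CCL21 form spatial gradients in
tissue: CCL21 is released at dermal lymphatic vessels, diffuses through the
interstitium, binds to heparan sulfate, and the immobilized fraction guides
dendritic cells towards the lymphatics. Confocal immunostainings visualize
the immobilized fraction pixel by pixel — but they also contain structured
noise: bright intracellular-CCL21 spots that have nothing to do with the
extracellular gradient. Fitting a mechanistic model to such images therefore
has to solve two problems at once: use the *whole* image (summary statistics
discard most of the information) and not be fooled by the artefacts.

`gradmech` implements this programme for researchers doing image-based
parameter estimation of reaction–diffusion models:

- a steady-state reaction–diffusion model of gradient formation
  (soluble `u1`, free heparan sulfate `u2`, immobilized complex `u3`):

  ```
  ∂t u1 = D Δu1 + α Σ_l q_l(x) − k1 u1 u2 + k−1 u3 − γ u1
  ∂t u2 = −k1 u1 u2 + k−1 u3
  ∂t u3 =  k1 u1 u2 − k−1 u3,          ∂u1/∂ν = 0 on ∂Ω
  ```

  observed per pixel as `y_j = s (u3(x_j) + b)` with multiplicative
  log-normal noise, and reparametrized to the identifiable combination
  `(D/γ, ρ = α k1/(γ k−1), s·S0, bg)`;
- three statistical approaches to artefacts: **direct** (ignore them),
  **filtered** (exclude MSER-detected bright spots), and **integrated** —
  an ε-contamination mixture in which each pixel is an outlier with
  probability `w_o` drawn from a shifted log-normal (`μ_o`, `σ_o`), fitted
  jointly with the mechanics;
- multi-start maximum likelihood (latin hypercube starts, bounded
  quasi-Newton), profile-likelihood confidence intervals with
  non-identifiability flags, and BIC comparison of heparan sulfate field
  hypotheses (uniform / vessel-vs-tissue / per-vessel);
- a synthetic-data generator with full ground truth (seeded vessel
  geometries, ellipsoidal bright-spot artefacts with sampled shape and size
  parameters, log-normal pixel noise) for benchmarking the approaches.

See `docs/methods.md` for the model, the estimation machinery and all
packaged defaults.

## Worked example

```python
import gradmech as gm

# a seeded 64x64 um scene: one wide collecting vessel + two capillaries
grid, vessels = gm.default_scene(seed=0, shape=(64, 64), n_vessels=3)

# spot-free dataset first: check the noise regime
ds0 = gm.generate_artificial_dataset(grid, vessels, n_spots=0, seed=0)
print(ds0.params)           # ground truth (reduced parametrization)
print(round(gm.empirical_snr(ds0.clean, ds0.noisy), 2))

# artificial image: steady-state gradient + 40 bright spots + pixel noise
ds = gm.generate_artificial_dataset(grid, vessels, n_spots=40, seed=0)

# fit the outlier-mixture (integrated) model, 20 multistarts
af = gm.fit_approach(ds.noisy, grid, vessels, approach="integrated",
                     n_starts=20, seed=1)
print({k: round(v, 3) for k, v in af.estimate.items()})
```

prints (exact numbers for these seeds):

```
ReducedParameters(d_over_gamma=64.0, rho=2.0, s_s0=100.0, bg=40.0)
5.62
{'d_over_gamma': 69.442, 'rho': 1.996, 's_s0': 101.206, 'bg': 39.473,
 'sigma': 0.164, 'w_o': 0.199, 'mu_o': 0.945, 'sigma_o': 0.585}
```

The signal-to-noise ratio of the artificial data is ≈ 5.6 (the packaged
noise level targets the regime ≈ 6). Although 17% of the pixels in the
spotted image are covered by artefacts, the integrated fit recovers the
decay length √(D/γ) = 8 µm as 8.3 µm, the gain ρ = 2 as 2.0 and the
intensity scale s·S0 = 100 as 101, because the mixture has absorbed the
spots: ŵ_o ≈ 0.20 of pixels are classified as outliers, brighter than the
model by a factor e^{μ̂_o} ≈ 2.6 on average.
Profile confidence intervals for any parameter come from
`gm.profile_likelihood(af.objective, af.space, af.fit, "rho")`.

The same machinery is scriptable from the shell:

```sh
gradmech generate --spots 40 --seed 0 --out run/
gradmech fit --dataset run/ --approach integrated --out run/fit
gradmech experiment --kind robustness --seed 1 --out run/rob
```

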