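# Methods

## The biological model

`gradmech` models the formation of immobilized CCL21 gradients around dermal
lymphatic vessels. Three concentration fields live on a 2D tissue domain Ω
with pixel grid discretization:

- `u1` — soluble CCL21, secreted at rate α inside the vessel masks
  Σ_l q_l(x), diffusing with coefficient D and degraded at rate γ;
- `u2` — free heparan sulfate;
- `u3` — the immobilized CCL21–heparan-sulfate complex, the quantity an
  anti-CCL21 immunostaining visualizes.

Binding `u1 + u2 ⇌ u3` has rates k1 / k−1. Heparan sulfate is not
transported, so `u2 + u3 = s0(x)` is conserved pointwise; `s0(x)` is the
total heparan sulfate field. Boundaries are no-flux for `u1`.

At equilibrium the binding terms cancel, leaving the linear screened-Poisson
problem

    D Δu1 − γ u1 + α Σ_l q_l = 0,     u3 = s0(x) · w/(1+w),  w = k1 u1 / k−1,

which the solver exploits: the steady state is computed exactly by one
linear solve plus an algebraic map, while a full nonlinear IMEX
time-marching solver is retained purely as an independent validation oracle
(the two agree to a relative L∞ of 1e−4 in the tests).

### Discretization and the fast solve

The Laplacian is the 5-point finite-difference stencil on the pixel grid
with reflective ghost nodes (no-flux). That discrete operator is exactly
diagonalized by the type-II DCT, so the default solve is
`idctn(dctn(q)/(1 + λ² μ))` with `λ² = D/γ` and `μ` the analytic stencil
eigenvalues — exact for the same operator the sparse-matrix path assembles
(the two paths agree to better than 1e−12 in tests; the sparse path is kept as a
reference). This makes an objective evaluation O(n log n) and is what lets
the multi-start/profile experiments run at full spec scale. Because the PDE
solve depends only on `D/γ`, objective evaluations cache the solution keyed
by that value; finite-difference gradients then re-solve the PDE only when
perturbing `D/γ`.

Pixel observation is centre-point (midpoint) quadrature: solver nodes
coincide with pixel centres, so `y_j = s (u3(x_j) + b)`.

### Identifiable reparametrization

A single equilibrium image determines only

    (D/γ,  ρ = α k1/(γ k−1),  s·S0,  bg = s·b).

The background is kept on the observed-intensity scale (`bg = s·b`) because
the image depends on `s` and `b` only through that product; the raw
8-parameter vector is structurally non-identifiable (tested bit-exactly with
two raw vectors of equal reduction). In the heparan-field hypotheses the
levels generalize to intensity-scale values `s·S_T`, `s·S_{L,l}`.

The 1D approximation used for summary-statistic fitting solves
`D u1'' − γ u1 = 0` on an interval with the physical influx condition
`−D u1'(0) = α` and no flux at the far end; its cosh closed form is the test
oracle (relative error < 1e−6 on a fine grid). The printed convention
`u1'(0) = α` differs only by a sign/scale absorbed into α (and hence ρ).

## Statistical model

Pixel intensities carry multiplicative log-normal noise,
`y^m = y·ε`, `log ε ~ N(0, σ²)`, with one shared σ per dataset estimated
jointly with the mechanistic parameters (per-channel σ is supported,
per-pixel σ is not). Bright-spot artefacts are handled three ways:

- **direct** — ignore them;
- **filtered** — exclude MSER-detected bright regions from the sum;
- **integrated** — an ε-contamination mixture: with probability `w_o` a
  pixel is an outlier whose density is log-normal with log-location
  `log y + μ_o` and scale `σ_o`.

All likelihoods are computed in log space; the mixture uses log-sum-exp.
`w_o ∈ {0,1}` reduce exactly to the pure components, and the optimized
integrated objective can never exceed the direct one (nesting).

## Estimation and uncertainty

Multi-start maximum likelihood: latin-hypercube start points in the
transformed bounds box, bounded quasi-Newton (L-BFGS-B) refinement with
central finite differences (step 1e−5 on the transformed scale), results
sorted into a convergence ladder. Positive parameters are estimated on
log10 scale, `w_o` on logit scale, and `μ_o` on a linear scale because its
sign is deliberately unconstrained (bounds [−2, 5]).

Default bounds boxes: mechanistic parameters span ≥ 4 decades
(`D/γ ∈ [1, 1e4] µm²`, `ρ ∈ [1e−2, 1e2]`); the intensity-scale levels span
6 decades (`[1e−1, 1e5]`). The wider intensity boxes are deliberate: along
the structural `ρ·sS0` ridge a box corner would otherwise truncate the
ridge and manufacture spurious identifiability of its members.

Profile likelihoods walk outward from the MLE with growing steps,
re-optimize all other parameters with warm starts, and locate the
chi-square (1 d.o.f.) threshold crossings by bisection. Confidence
intervals are pointwise. A parameter is flagged practically
non-identifiable ("n.i.") when its profile reaches a bound before crossing
the 99% threshold **or** when its 99% interval spans more than 2 decades.
The second clause is needed on principle: when two parameters are tied by a
near-exact product ridge and the product itself has a finite interval, each
member's profile must cross somewhere inside the box (where the partner's
box ends), so a pure bound-hit rule can never flag both — yet a 3-decade
interval carries no usable information. Profiles of the product are
computed by a linear reparametrization of the log-scale coordinates.

Model comparison uses `BIC = 2·nll + n_θ·log(n_D)`; differences ≥ 10 are
substantial. Comparisons are refused across different datasets or
statistical approaches (the filtering approach changes the data set, making
BICs incommensurable).

The paired comparison of approaches uses the standard paired one-sided
t-test on per-replicate error differences (a "Welch" correction is
undefined for paired designs); zero-variance differences degenerate to
p ∈ {0, ½, 1} by the sign of the mean.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the structure of the experimental images: a
steady-state gradient around seeded vessel masks, ellipsoidal bright spots
(intracellular CCL21 in scattered cells) and multiplicative log-normal
noise. Spots are rendered before noise; their effect is multiplicative
elevation by default (an additive mode is available), which preserves
positivity under the log-normal model. Overlapping spots multiply.

Packaged study conditions (chosen once, to sit in the regime the
identifiability and robustness analyses require, and frozen):

| quantity | default | rationale |
| --- | --- | --- |
| field of view | 64 × 64 µm | gradients decay within the image |
| pixel size | 64/min(n_rows, n_cols) µm | coarser grids sample the same scene |
| D/γ | 64 µm² (λ = 8 µm) | decay length ≪ field of view |
| ρ | 2 | mild saturation: w ≲ 1.2 inside the large vessel — pixels near the vessel are informative about ρ and s·S0 separately, distance-bin averages are not |
| s·S0 | 100, bg = 40 (intensity units) | vessel-to-background contrast ≈ 2 with a substantial unspecific background |
| σ | sqrt(ln(1 + 1/36)) ≈ 0.166 | closed-form SNR 1/sqrt(e^{σ²}−1) = 6 |
| vessels | one 10–13 µm "collecting" section + small 2.5–4.5 µm capillaries | heterogeneous calibres as in dermal tissue; the calibre contrast is what the distance-binned summary statistic averages away |
| spots | area log-normal, median 16 µm²; axis ratio Beta(5,2); orientation uniform; elevation 1 + log-normal (median ≈ 2.5) | cell-sized bright artefacts, always brighter than their surroundings |

The empirical SNR of a generated gradient image sits a few percent below
the constant-image closed form because the clean image is not constant;
tests assert the closed form exactly only on constant images.

Not emulated: point-spread function, shot noise, bleaching, spatially
correlated noise, vessel segmentation errors. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated noise
model, not robustness to all real-microscopy artefacts.

## Bright-spot detection (MSER)

Bright-on-dark maximally stable extremal regions on the component tree of
upper level sets: a region at threshold t is kept when its relative area
change across ±δ thresholds is at most `max_variation` and its area lies in
`[min_area, max_area]`; nested detections keep the most stable. Float
images are quantized to 8 bits with 1st/99th-percentile clipping so that a
few extreme outlier pixels cannot compress the bulk dynamic range. Defaults
δ = 10 (≈ 4% of the quantized range, above the ≈ 17% multiplicative noise
scale after quantization), `min_area` = 5 px, `max_area` = 1% of the image,
`max_variation` = 0.25; all are config-exposed and recorded in output
metadata. Detection on small integer images is verified pixel-set-exact
against a brute-force per-threshold BFS oracle. Ellipse descriptors come
from normalized second central moments (semi-axis = 2√eigenvalue, plus the
1/12 moment of the unit pixel).

## Experiment drivers and problem sizes

All drivers are deterministic functions of (config, master seed); one
master seed spawns per-component seeds through `SeedSequence` spawn keys.

- *Set-up comparison* (whole image vs summary statistic): one clean 32 × 32
  dataset; direct fits with 20 starts; profiles at 75/90/99%. The expected
  pattern — all reduced parameters identifiable with covering 99% intervals
  from the whole image; ρ and s·S0 individually n.i. but their product
  finite from the distance-binned profile under either the 1D or the 2D
  model — is asserted in the acceptance tests.
- *Robustness*: 30 replicates per spot count, paired across approaches,
  32 × 32, 20 starts; errors are |log10(estimate/truth)| per reduced
  parameter (a relative-linear metric is config-switchable); summaries are
  means with 95% percentile bands, plus one-sided paired t-tests of each
  baseline against the integrated approach.
- *Model selection*: one 64 × 64 image generated under per-vessel heparan
  levels (tissue 50; vessels 150/450/1350, ≥ 3-fold apart), hypotheses 1–3
  fitted with the integrated approach and ranked by BIC.

These sizes keep a full acceptance run in minutes on one CPU while
preserving the qualitative structure of the full-scale analyses; they are
the package's chosen study scales.

## Numerical choices and degenerate cases

- Equilibrium tolerance of the transient oracle: max relative state change
  < 1e−8 per unit time (1e−10 in the validation tests).
- Objective evaluations returning non-finite values are treated as +1e300;
  a start that fails entirely is recorded as failed, and estimation only
  aborts if every start fails.
- Empty distance bins carry NaN means and are excluded from summary
  objectives rather than imputed.
- α = 0 (zero secretion) is allowed and yields the exact zero/`s0(x)`
  equilibrium; D ≤ 0 or γ ≤ 0 raise immediately (no bounded steady state).
- Labelled-mask TIFFs (0 = tissue, 1..L) and per-vessel binary TIFFs are
  interchangeable on input.

## Known limitations

- Single implicit time point (equilibrium data only); no time-resolved
  fitting, 3D domains or advection.
- The outlier mixture ignores spatial correlation of structured noise; with
  extreme spot loads the two mixture components can swap roles (label
  switching) without affecting the mechanistic estimates.
- Multi-image joint fitting shares mechanistic parameters and background
  while the per-image scaling varies; it is exposed through the library
  (per-image level scaling) but the experiment drivers operate on single
  images.
- Profile intervals are pointwise (chi-square with 1 d.o.f.), not
  simultaneous.
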