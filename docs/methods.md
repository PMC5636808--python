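# Methods

This note documents the model, the parameter choices, the numerical decisions
and the known limits of `dwifuse`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic benchmark: what it emulates

The generator produces populations of single-shell diffusion profiles whose
fiber orientations vary across subjects, the situation template fusion has to
survive after spatial registration has done its best.

- **Shell**: K = 81 unit directions at b = 3000 s/mm², placed by
  electrostatic-repulsion minimization of antipodal charge pairs from a seeded
  start. The resulting minimum axis separation is ≈ 15.3°, matching typical
  81-direction acquisitions. For K = 6 the optimizer recovers the icosahedral
  half-set (verified against its closed-form repulsion energy).
- **Fiber configurations**: one fiber; two equal fibers 90° or 60° apart; two
  fibers 90° apart with weights 0.65/0.35 (the unequal split is not specified
  anywhere authoritative; 0.65/0.35 is a representative asymmetry and is
  configurable).
- **Dispersion**: each fiber axis of each (subject, voxel) is drawn from a
  Watson distribution about the nominal axis with concentration
  κ = 2/sin²(θ_T), θ_T ∈ {15°, 30°, 45°}. Sampling includes the sin θ
  solid-angle Jacobian — the density is over orientations, not over the scalar
  angle — via an exact rejection sampler (truncated-exponential proposal in
  1 − cos θ, acceptance probability e^{κt(t−1)} ≤ 1) that stays ≈ 50%
  efficient for arbitrarily large κ. Each fiber of a multi-fiber voxel is
  perturbed independently; voxels are independent replicates.
- **Signal**: axially symmetric multi-tensor, S(g) = S0 Σ_f w_f exp(−b gᵀD_f g)
  with λ∥ = 1.7×10⁻³, λ⊥ = 3×10⁻⁴ mm²/s (standard white-matter values; the
  source data's calibration is not published) and S0 = 150 identified with the
  maximum signal v = 150.
- **Noise**: Gaussian noise N(0, σ²), σ = v·(p/100), added to the real and
  imaginary channels, magnitude taken (Rician), p ∈ {3, 5, 7, 9}%.

What the generator does **not** emulate: spatial misregistration fields,
anatomical structure across voxels, multi-shell decay, spatially varying
noise. A green benchmark therefore certifies the q-space behavior of the
fusion on dispersed orientations, not registration robustness on real brains.

## Patch features

A patch is the set of scheme axes within α_p = 30° of a center direction,
antipodally canonicalized to the center's hemisphere, then projected by the
azimuthal equidistant projection (AEP); radii are normalized by α_p so the
patch fills the unit disc. The latitude/longitude convention follows standard
spherical trigonometry; the forward azimuth and the inverse (Snyder) formulas
are mutually consistent, which the round-trip test verifies.

PCET moments are computed two ways, and both are exposed:

- **Polar-grid quadrature** (`patches.resample_to_polar_grid` + `pcet`):
  a real, antipodally symmetric spherical-harmonic fit to the whole shell
  (even orders ≤ 8, Laplace–Beltrami λ = 0.006) is evaluated at grid nodes
  pulled back through the inverse AEP. The grid places its 8 rings at
  midpoints in ρ² (equal-area rings) and 16 uniform angular midpoints. This
  deliberate deviation from equal-radius rings makes the quadrature of
  e^{i2πnρ²}ρ dρ *exact* for |n| < 8 and of e^{ilθ} exact for |l| < 16, so
  basis orthonormality and the constant-patch moments hold to machine
  precision rather than to O(grid⁻²). (Moments with |Δn| = 8 alias on this
  grid; at m = 4 the largest Δn in use is 8 only between the extreme orders,
  which affects no test or default.)
- **Member-sample quadrature** (`fusion`, default): the same integral
  discretized directly on the projected member samples with equal weights,
  i.e. M_{n,l} = mean_p [H_{n,l}(ρ_p, θ_p)]* S_p. No smoothing is applied, so
  the per-sample noise survives into the features.

Rotation invariance: restricted to a circle about the patch center, a
degree-8 SH expansion is a trigonometric polynomial of degree ≤ 8, so on the
16-angle grid the moment magnitudes are invariant under arbitrary in-plane
rotation essentially to machine precision. Under a *global* rotation of scheme
and signal, the projected grid acquires an in-plane rotation (the AEP azimuth
origin is frame-dependent), so `grid_signal` is equal only for rotations
preserving the azimuth origin (e.g. about the polar axis) while the PCET
magnitudes are equal for all rotations; the tests check exactly that split.

## Matching and fusion

Weights follow the non-local-means form with the stated parameters r_s = 2
voxels, α_s = α_p = 30°, β = 0.1, m = 4, feature bandwidth
h_M = √(2βσ²·(2m+1)²) (the feature-vector *count* reading; the Euclidean-norm
reading is available via `bandwidth_mode="norm"`), spatial bandwidth
h_x = √2·σ_x with σ_x = 1 voxel (voxel units; a background-derived spatial
scale is not actionable for synthetic data). σ is the known generator value
for synthetic data and may always be overridden.

Two design choices matter and were settled empirically; both are configurable:

1. **Feature pipeline.** The bandwidth rule above is calibrated, in the
   denoising literature it comes from, to distances whose coordinates each
   carry ~σ² of noise. The SH-grid features are so strongly smoothed that
   their noise covariance has ≈ 4 effective degrees of freedom, which makes
   the stated h_M an order of magnitude too wide: weights become nearly
   uniform over the 30° q-neighborhood, the weighted pooling blurs the angular
   profile, and the fused template scores *below* the simple average. The
   member-sample features keep the sampling noise in the distance statistic
   and restore the intended operating point, so they are the fusion default
   (`feature_pipeline="members"`); the SH-grid route remains available.
2. **Debias placement.** Applying −2σ² inside every iteration clamps
   low-signal template values to zero; a zero-valued patch resembles nothing
   in the Rician-floored data, its matches degenerate, and the zero region
   spreads until the template collapses. The default therefore iterates the
   uncorrected weighted quadratic mean and subtracts the bias once after the
   final iteration (`bias_correction="final"`); for the simple average and for
   any fixed weights the two orders are algebraically identical. The literal
   per-iteration form is selectable.

Iteration: the reference features are refreshed from the current template
(subject candidate features are precomputed once); the loop starts from the
(uncorrected) quadratic-mean average, stops when the mean absolute change
drops below γσ with γ = 0.001 (absolute tolerance 10⁻¹² when σ = 0) and is
capped at T_max = 10. Weights for one target exist only while that target is
updated. If every unnormalized weight underflows, that target falls back to
uniform weights with a logged warning.

## Evaluation

PSNR uses MAX = 150 and the MSE over all voxels and directions. Fiber
orientations are extracted by an analytical Q-ball stand-in: even-order-8 SH
fit, Funk–Radon transform in the SH domain (scaling by 2πP_l(0)), discrete
maxima on a 642-vertex icosphere, continuous refinement of each maximum
(Nelder–Mead on tangent coordinates), then a 0.4 relative threshold, 25°
minimum separation and at most 3 peaks. OD is the symmetric average-Hausdorff
angle under d(g₁,g₂) = arccos|g₁·g₂| (peaks are taken from ODF *maxima*; the
occasional description of orientation sets via ODF minima in the literature
refers to the diffusion signal, whose minima coincide with ODF maxima).

Known estimator limits, measured here: on the noise-free 60° crossing the two
Q-ball maxima are biased ≈ 11.5° toward each other, and after strong
dispersion averaging the crossing merges into a single bisector maximum; for
the 0.65/0.35 crossing at high dispersion the weak fiber's local maximum can
vanish entirely. Absolute OD values for those configurations saturate near
30° (and comparisons between methods there become uninformative), which is
why the benchmark's ordering claim holds cleanly for single-fiber and
equal-90° configurations but not for the hard crossings. A sharper
deconvolution-type estimator would be needed to lift this ceiling; it is out
of scope.

## Degenerate inputs and numerical notes

- σ = 0 makes h_M = 0; the kernel degrades to an exact-match indicator and
  the stopping rule switches to the absolute tolerance.
- Negative brackets under the square root (bias correction) clamp to zero:
  magnitudes are non-negative.
- A patch whose only member is its center is allowed and flagged
  (`is_singleton`).
- SH fits raise a descriptive error when the direction set cannot resolve the
  requested order.
- All randomness flows through seeded `numpy` generators; populations are
  byte-reproducible given a seed, and the benchmark spawns per-condition seeds
  from one root seed.

## Limitations

Single-shell only; no registration or gradient reorientation (inputs are
assumed co-registered with gradients in the image frame); no spatially
adaptive noise estimation; no pre-screening speedups. The mean PSNR advantage
of mean-shift fusion over averaging on this benchmark is driven by the
single-fiber and unequal-crossing conditions; equal-crossing conditions sit
near parity under the stated bandwidth, as discussed above.
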