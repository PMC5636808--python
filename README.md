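# dwifuse

Robust fusion of co-registered diffusion MRI data for template construction.

## The problem

A diffusion MRI template is built by aligning many subjects' diffusion-weighted
volumes to a common space and fusing them. Even after good spatial
registration, the *microstructure* is not aligned: at a given voxel, fiber
orientations, crossing configurations and anisotropy differ across subjects.
Simple voxel-wise averaging of such a population blurs the angular profiles and
creates artifacts — a population of single-fiber voxels contaminated by a few
crossing-fiber profiles averages into a spurious crossing.

`dwifuse` implements a mode-seeking alternative: at every point of the joint
voxel/wavevector domain (x, q) the template value is estimated by a mean-shift
iteration whose kernel weights come from rotation-invariant **q-space patch
matching**. The mode of a distribution of signal profiles is robust to
outliers, so the fused template tracks the *most probable* local profile
instead of the blurred mean.

## The method

For each shell direction q_k, the signals on the spherical patch within an
angle α_p of q_k are mapped to the unit disc with the azimuthal equidistant
projection (after antipodal canonicalization) and summarized by the magnitudes
of polar complex exponential transform (PCET) moments

    M_{n,l} = (1/π) ∫ [H_{n,l}(ρ, θ)]* S(ρ, θ) ρ dρ dθ,
    H_{n,l}(ρ, θ) = exp(i2πnρ²) exp(ilθ),   −m ≤ n, l ≤ m,

whose magnitudes are invariant to in-plane patch rotation. A candidate
(x_j, q_l) of subject d in the local neighborhood (‖x_i − x_j‖ ≤ r_s,
∠(q_k, q_l) ≤ α_s) is weighted by

    w ∝ exp(−‖M_ref − M_cand‖² / h_M²) · exp(−‖x_i − x_j‖² / h_x²),
    h_M = √(2 β σ² (2m+1)²),   h_x = √2 σ_x,

and the template value is the Rician-debiased weighted quadratic mean
√(Σ w S² − 2σ²). Iterating with the current template as the matching
reference is a mean shift that converges to the mode of the local profile
distribution. The baseline is bias-corrected simple averaging,
√(mean_d S² − 2σ²).

The package also ships the synthetic benchmark used to validate the method
(multi-tensor profiles whose fiber axes disperse across subjects per a Watson
distribution with κ = 2/sin²θ_T, complex-domain Rician noise at a percentage
of the maximum signal 150) and the evaluation protocol: PSNR against the
dispersion-free ground truth, and the orientational discrepancy (OD) — the
symmetric average-Hausdorff angle between extracted and true fiber axes, with
peaks extracted by an analytical Q-ball (spherical harmonics + Funk–Radon)
estimator.

## Worked example

```python
import dwifuse as dw

scheme = dw.default_scheme(K=81, seed=0)          # 81 directions, b = 3000
sim = dw.SimulationConfig(theta_T=30.0, noise_percent=5.0,
                          population_size=20, grid_shape=(3, 3, 3), seed=7)
population = dw.make_population(sim, dw.named_fiber_config("single"), scheme)

average = dw.simple_average(population)
template = dw.mean_shift_fuse(population, config=dw.FusionConfig(r_s=2.0))

print(dw.psnr(average.signals, population.ground_truth))   # 24.71 dB
print(dw.psnr(template.signals, population.ground_truth))  # 31.99 dB
```

Running `python examples/02_fuse_template.py` prints exactly this comparison:
the dispersed single-fiber population averages to 24.71 dB while the
mean-shift template reaches 31.99 dB (+7.28 dB), because mode seeking
suppresses the orientationally deviant subjects that the mean smears together.
`examples/03_evaluate_template.py` shows the angular counterpart on a
90°-crossing population at θ_T = 45°, 9% noise: the averaging template's peaks
drift to a mean OD of 28.5° while the mean-shift template stays at 4.1°.

## Layout

- `src/dwifuse/synthetic.py` — Watson-dispersed multi-tensor populations, Rician noise
- `src/dwifuse/gradients.py` — gradient schemes (electrostatic repulsion)
- `src/dwifuse/patches.py` — spherical patches, azimuthal equidistant projection, polar-grid resampling
- `src/dwifuse/pcet.py` — PCET moments and rotation-invariant features
- `src/dwifuse/fusion.py` — matching weights, bias-corrected means, mean-shift fusion
- `src/dwifuse/evaluation.py` — PSNR, Q-ball peak extraction, OD, benchmark grid
- `src/dwifuse/io.py` — NIfTI + FSL bvec/bval I/O, YAML run configs
- `docs/methods.md` — model assumptions, parameter choices, numerical notes, limitations
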