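"""Fuse a population into a template: mean-shift patch matching vs averaging.

Simulates a single-fiber population with strong inter-subject orientation
dispersion, fuses it with both estimators and compares each template with the
noise-free, dispersion-free ground truth.  The mean-shift template seeks the
mode of the local signal-profile distribution and is markedly closer to the
truth than the simple average, which blurs the dispersed profiles together.
"""

import dwifuse as dw

scheme = dw.default_scheme(K=81, seed=0)
sim = dw.SimulationConfig(theta_T=30.0, noise_percent=5.0, population_size=20,
                          grid_shape=(3, 3, 3), seed=7)
population = dw.make_population(sim, dw.named_fiber_config("single"), scheme)

average = dw.simple_average(population)

config = dw.FusionConfig(r_s=2.0)  # r_s = 2 voxels, alpha_p = alpha_s = 30 deg,
                                   # beta = 0.1, m = 4, gamma = 0.001
template = dw.mean_shift_fuse(population, config=config)
print(f"mean shift converged after {template.iterations_used} iterations; "
      f"per-iteration mean absolute change: "
      f"{[round(t, 4) for t in template.trace]}")

psnr_avg = dw.psnr(average.signals, population.ground_truth)
psnr_ms = dw.psnr(template.signals, population.ground_truth)
print(f"PSNR vs ground truth: averaging {psnr_avg:.2f} dB, "
      f"mean shift {psnr_ms:.2f} dB ({psnr_ms - psnr_avg:+.2f} dB)")

report = dw.write_template(template, "scratch/example_template/template",
                           config=config, sigma=population.sigma)
print(f"template written; stop threshold gamma*sigma = {report['stop_threshold']:.4f}")
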