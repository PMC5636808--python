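"""Score templates with PSNR and orientational discrepancy.

Extracts fiber orientations from fused 90-degree-crossing templates with the
analytical Q-ball estimator and measures the orientational discrepancy (OD,
the symmetric average-Hausdorff angle between axis sets) against the true
fiber axes.  Smaller OD means the template's peaks sit closer to the true
crossing geometry.
"""

import dwifuse as dw
from dwifuse.evaluation import template_od

scheme = dw.default_scheme(K=81, seed=0)
fibers = dw.named_fiber_config("cross90eq")
sim = dw.SimulationConfig(theta_T=45.0, noise_percent=9.0, population_size=20,
                          grid_shape=(3, 3, 3), seed=11)
population = dw.make_population(sim, fibers, scheme)

average = dw.simple_average(population)
template = dw.mean_shift_fuse(population, config=dw.FusionConfig(r_s=2.0))

# peaks of one voxel's fused profile
peaks = dw.estimate_peaks(template.signals[0], scheme)
print(f"voxel 0 mean-shift template: {len(peaks)} peak(s); angles to the true axes:")
for ax in peaks.axes:
    print("   ", [round(float(dw.axis_angle(ax, t)), 1) for t in fibers.axes], "deg")

od_avg = template_od(average, fibers.axes)
od_ms = template_od(template, fibers.axes)
print(f"mean OD over voxels: averaging {od_avg:.2f} deg, mean shift {od_ms:.2f} deg")
print("(the averaging template's peaks drift with the dispersion; "
      "mode seeking pulls them back toward the true axes)")

psnr = dw.psnr(template.signals, population.ground_truth, max_value=150.0)
print(f"mean-shift template PSNR vs ground truth: {psnr:.2f} dB")
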