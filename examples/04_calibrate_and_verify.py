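"""Full calibration loop: fit the misalignments, precompensate, verify.

Runs the complete synthetic experiment at the default study conditions
(25 beads, 81 planes spanning ±200 um, 0.1 um localization noise, truth
misalignments X=2.3 mm, Y=1.3 mm, Z=-69 mm) and prints the fitted
parameters and the residual pointing error after precompensation.
"""

from refocal import run_calibration_experiment

exp = run_calibration_experiment(seed=1)
fit = exp.fit

print("truth:   X=+2.300  Y=+1.300  Z=-69.000 mm")
print(f"fitted:  X={fit.x_error:+.3f}  Y={fit.y_error:+.3f} "
      f" Z={fit.z_error:+.3f} mm")
print(f"stderr:  X={fit.stderr['x_error']:.4f}  Y={fit.stderr['y_error']:.4f}"
      f"  Z={fit.stderr['z_error']:.3f} mm")
print(f"fit residual RMS: {fit.residual_rms_um:.3f} um over {fit.n_obs} "
      f"observations")
print(f"before correction: max bead displacement "
      f"{exp.report_uncompensated['max_displacement_um']:.1f} um")
print(f"after precompensation: max bead displacement "
      f"{exp.report['max_displacement_um']:.3f} um "
      f"(mean per-bead max {exp.report['mean_max_displacement_um']:.3f} "
      f"+- {exp.report['std_max_displacement_um']:.3f} um)")
print("the residual is set by the localization noise alone: the distortion "
      "itself is corrected exactly")
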