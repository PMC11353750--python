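"""Separate glare from volume reflectance on the rough phantom and score it.

Per pixel, the solver fits R_tot(lam, i) = R_vol(lam) + eps_i with a
6th-order volume polynomial and per-direction glare intensities, then the
corrected spectra R_tot - eps_i are compared against the smooth phantom
(identical composition, no roughness) exactly as a phantom validation
experiment would.
"""

import deglare as dg
from deglare.phantom import PhantomConfig, generate_phantom_pair

cfg = PhantomConfig(seed=0)
smooth, rough = generate_phantom_pair(cfg)

result = dg.decompose_cube(rough.reflectance, cfg=dg.SolverConfig(poly_order=6))
center = (cfg.shape[0] // 2, cfg.shape[1] // 2)

rep = dg.variability_reduction(rough.reflectance, result, center, 5)
print(f"inter-direction variability on the central 5x5 ROI: "
      f"{rep.before:.5f} -> {rep.after:.5f}  "
      f"(reduction {100 * rep.reduction:.1f}%)")

corrected = dg.corrected_reflectance(rough.reflectance, result)
reference = dg.extract_roi(smooth.reflectance, center, 5).mean.mean(axis=0)
rmse = dg.roi_rmse_report(corrected, result, center, 5, reference)
print(f"RMSE of corrected rough-ROI spectra vs smooth reference: "
      f"{rmse.mean:.4f} +/- {rmse.std:.4f} (over {rmse.n_spectra} spectra)")
print("-> glare removal collapses the three directions onto one volume "
      "spectrum; what remains is the sensor noise floor, and the corrected")
print("   rough phantom matches the glare-free twin it shares its "
      "composition with.")
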