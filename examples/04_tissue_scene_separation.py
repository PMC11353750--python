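"""Glare removal disentangles tissue-like regions that overlap spectrally.

Three regions with distinct volume templates (fat-like, stroma-like,
tumor-like) are imaged under rough-mode glare.  Before correction, the
per-region mean +/- STD spectra overlap; after correction they separate —
the synthetic counterpart of distinguishing tissue types in a resection
specimen only after the surface reflectance is removed.
"""

import deglare as dg
from deglare.phantom import PhantomConfig, generate_tissue_scene

scene = generate_tissue_scene(PhantomConfig(shape=(96, 96), seed=0))
result = dg.decompose_cube(scene.reflectance, cfg=dg.SolverConfig(poly_order=6))

raw = scene.reflectance.stack()
corrected = dg.corrected_reflectance(scene.reflectance, result)

print("fraction of bands where the mean +/- STD bands of two regions overlap:")
pairs = [(0, 1), (1, 2), (0, 2)]
for a, b in pairs:
    before = dg.region_band_overlap(raw, scene.labels, a, b)
    after = dg.region_band_overlap(corrected, scene.labels, a, b)
    print(f"  {scene.region_names[a]:>10} vs {scene.region_names[b]:<10}  "
          f"raw: {100 * before:5.1f}%   corrected: {100 * after:5.1f}%")
print("-> glare masks the compositional differences between regions; the "
      "separation restores them without rescaling the spectra.")
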