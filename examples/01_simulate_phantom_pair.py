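"""Generate the seeded smooth/rough phantom pair and look at its glare.

The two synthetic phantoms share one true volume-reflectance spectrum
(an Intralipid-like scattering baseline with weak water dips); they differ
only in the per-pixel, per-direction glare intensity eps.  The numbers
below show that roughness drives the inter-direction variability.
"""

import numpy as np

from deglare.phantom import PhantomConfig, generate_phantom_pair

cfg = PhantomConfig(seed=0)  # 128x128 px, 500-900 nm step 3, 3 directions
smooth, rough = generate_phantom_pair(cfg)

for name, ph in (("smooth", smooth), ("rough", rough)):
    eps = ph.truth.epsilon
    spread = np.std(eps, axis=-1, ddof=1).mean()
    print(f"{name:>6} phantom: mean eps = {eps.mean():.4f}, "
          f"mean across-direction eps spread = {spread:.4f}")

frac_zero = (rough.truth.epsilon.min(axis=-1) == 0).mean()
print(f"rough phantom pixels with at least one glare-free direction: "
      f"{100 * frac_zero:.1f}%")
print("-> the rough surface adds direction-dependent glare an order of "
      "magnitude above the smooth phantom's residual gloss;")
print("   pixels with one glare-free direction make the min-eps-zero "
      "solver convention exactly attainable there.")
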