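# deglare

Separate **surface (specular/glare) reflectance** from **volume (diffuse)
reflectance** in hyperspectral images acquired under several illumination
directions.

## The problem

In medical hyperspectral imaging — e.g. margin assessment of excised tissue
during cancer surgery — the measured reflectance of a pixel mixes two very
different signals:

* **volume reflectance** `R_vol(λ)`: light that entered the sample,
  scattered, and escaped; it carries the absorption signatures that
  distinguish tissue types;
* **surface reflectance** `R_surf(λ)`: light reflected at the sample–air
  interface.  On a rough surface this becomes diffuse-looking *glare*
  whose intensity varies strongly from pixel to pixel and with the
  position of the light source.

Glare produces large baseline offsets that make spectra of identical
tissue overlap with spectra of different tissue.  The usual fixes
(standard normal variate, multiplicative scatter correction) remove the
offsets but also destroy amplitude and scattering information.

`deglare` instead *models* the mixture.  If a scene is imaged from `m_i`
axial illumination directions sharing one zenith angle (30° in the
reference geometry), the volume reflectance at a pixel is the same in
every image while the glare intensity differs:

```
R_tot(λ, i) = R_vol(λ) + ε_i · R_spec(λ),        i = 1 … m_i
```

`R_spec(λ)` is the specular spectral shape — flat to a good approximation
for fat/water mixtures (`R_spec ≡ 1` by default; a Fresnel-derived shape
from refractive-index spectra is supported).  `R_vol` is modelled as an
order-`m_p` polynomial (default 6) in an orthonormal basis, so each pixel
is an `m_λ·m_i`-equation, `(m_p+1)+m_i`-unknown least-squares problem,
solved in closed form for the whole frame at once.  The per-direction
glare intensities `ε_i` come out as images in their own right — glare is
*separated and kept*, not discarded.

The package includes flat-field calibration (dark current + white
reference), saturation masking for 12-bit counts, a fully seeded
synthetic phantom generator with ground truth, evaluation metrics and a
thin CLI.

## Worked example

`examples/03_decompose_and_evaluate.py` generates the seeded synthetic
phantom pair — two phantoms with identical volume reflectance, one with a
smooth and one with a rough (glare-producing) surface — decomposes the
rough series and scores the correction:

```
inter-direction variability on the central 5x5 ROI: 0.03259 -> 0.00446  (reduction 86.3%)
RMSE of corrected rough-ROI spectra vs smooth reference: 0.0087 +/- 0.0117 (over 25 spectra)
```

The first line is the mean across-direction standard deviation of the ROI
spectra before and after subtracting the fitted glare: the separation
removes ~86% of the inter-illumination variability, leaving roughly the
sensor noise floor.  The second line says the corrected rough-phantom
spectra agree with the independently measured glare-free twin to about
0.009 reflectance units.

The other scripts in `examples/` walk through simulation, calibration,
tissue-scene separation and glare-map rendering.  The same pipeline is
scriptable from the shell:

```sh
deglare simulate  --out sim --mode pair --seed 0
deglare calibrate --out cal --reference sim/rough_reference.txt \
    --sample sim/rough_counts_dir1.img --sample sim/rough_counts_dir2.img \
    --sample sim/rough_counts_dir3.img \
    --dark sim/rough_dark.img --white sim/rough_white.img
deglare decompose --out dec --roi 64,64,5 \
    --cube cal/reflectance_dir1.img --cube cal/reflectance_dir2.img \
    --cube cal/reflectance_dir3.img
deglare render    --out png --result dec
```

## Layout

```
src/deglare/        hypercube.py   containers, ROI spectra, pseudo-RGB
                    io.py          ENVI / TIFF-stack / HDF5 cubes, masks
                    calibration.py flat-field calibration, saturation
                    decomposition.py  the per-pixel solver
                    phantom.py     seeded synthetic phantoms + truth
                    metrics.py     RMSE, variability reduction, glare maps
                    cli.py         deglare simulate|calibrate|decompose|evaluate|render
examples/           one narrative script per capability
docs/methods.md     model, conventions, numerical choices, limitations
```
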