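# Methods

## Measurement model

A pixel viewed under illumination direction `i` (all sources at one zenith
angle, different axial positions) measures

    R_tot(λ, i) = R_vol(λ) + ε_i · R_spec(λ)

* `R_vol(λ)` — volume (diffuse) reflectance: light that scattered inside
  the sample.  Because the diffuse light distribution varies on the scale
  of the scattering mean free path, `R_vol` is assumed identical across
  directions at a pixel and spectrally smooth (tissue absorbers are broad
  relative to modern spectral sampling).
* `R_spec(λ)` — the spectral shape of interface (specular) reflectance.
  For fat/water-like media the normal-incidence Fresnel reflectance is
  nearly wavelength-independent over 500–900 nm, so the default shape is
  flat, `R_spec ≡ 1`.  A `fresnel-derived` mode builds the shape from two
  refractive-index spectra via `((n_s − n_m)/(n_s + n_m))²` and
  peak-normalizes it.
* `ε_i ≥ 0` — the fraction of specular reflectance reaching the detector
  for this pixel and direction; it encodes surface slope/roughness and is
  the quantity rendered in the glare maps.

Joint estimation of an *unknown, non-flat* `R_spec(λ)` together with
`R_vol` and `ε` is deliberately out of scope: without extra conventions
the general problem has scale and shift degeneracies that make it
underdetermined.

## Per-pixel solver

`R_vol` is expanded in an orthonormal polynomial basis of order `m_p`
(default 6) built by QR-orthonormalizing a Vandermonde matrix on the
wavelength axis affinely mapped to [−1, 1].  Raw powers of nm-scale
wavelengths are catastrophically ill-conditioned; the orthonormal basis
keeps the design matrix condition number near 1.  Column 0 is the
constant; column signs are fixed for determinism.  `m_p = 6` tracks the
broad absorber dips of the 500–900 nm range while staying far below the
band count (`m_p + 1 + m_i = 10` unknowns against `m_λ·m_i ≈ 400`
equations for the default grid); it is exposed as a config/CLI flag.

Two solver paths exist and must agree (tested to ≤ 1e−8):

* **closed-form-linear** (default): with a fixed `R_spec` shape the
  problem is linear; a single SVD of the shared design matrix solves every
  pixel with the same saturation pattern in one matrix product.  The SVD
  also reveals rank: a design singular beyond the expected flat-model
  degeneracy marks the pixel failed.
* **iterative-nonlinear**: a trust-region nonlinear least-squares
  minimizer (`scipy.optimize.least_squares`, TRF, analytic Jacobian,
  objective-change tolerance 1e−12, ≤ 200 iterations), mirroring the
  generic `lsqnonlin`-style approach; kept for non-flat specular shapes
  and as an independent cross-check of the linear path.

### Identifiability

With a flat `R_spec`, adding a constant `t` to the volume polynomial and
subtracting `t` from every `ε_i` leaves the model unchanged — a rank-1
degeneracy.  The default convention returns the representative with
`min_i ε_i = 0` per pixel: glare common to *all* directions is
indistinguishable from volume signal in this geometry, and attributing it
to volume is the conservative choice.  This also makes `ε_i ≥ 0` hold by
construction.  A `minimum-norm` representative (the plain SVD
least-squares solution) is selectable; it changes `ε` by a per-pixel
constant but never the residual.

### Saturation granularity

Saturated samples (counts ≥ 4000 on a 4096 full-scale sensor; the `≥`
comparison is the safe direction for a ceiling) are excluded from the
objective at the (pixel, band, direction) level, preserving maximal data.
A (pixel, direction) is dropped wholesale only when more than 50% of its
bands saturate (its `ε` becomes NaN).  A pixel remains solvable with 2 of
3 directions and is flagged *degraded*; fewer unmasked samples than
unknowns, or fewer than 2 live directions, marks it *failed*.

### Other numerical choices

* Volume non-negativity is **not** enforced; pixels whose evaluated
  `R_vol` dips below zero are counted and reported in a warning so they
  can be inspected (they typically coincide with model violations).
* No special treatment of sample edges, where the constant-zenith
  assumption breaks; the per-pixel `residual_rms` lets users threshold
  edge pixels themselves.
* Frames are processed in row blocks with one shared solve operator per
  saturation pattern, so a full push-broom frame (795×1312 px, 254 bands,
  3 directions) decomposes in about 1–2 minutes on one CPU core without
  a second frame-sized allocation (measured 19.6 s for a 400×656 quarter
  frame; the cost is linear in pixel count).

## Calibration

Counts convert to total reflectance per illumination direction via a
dark-current cube and a white-reference (Spectralon-type tile) cube:

    R_total = (I_sample − I_dark) / (I_white − I_dark) · R_reference(λ)

Dark/white may be full cubes or single-row line references broadcast
across rows (the natural shape for a push-broom scanner, whose
illumination profile varies along the imaged line).  A non-positive
denominator anywhere in use is a hard error that lists offending
coordinates.  ROI statistics throughout the package use the sample
standard deviation (ddof = 1): ROIs are small samples.

## Synthetic phantom generator

The generator emulates the *statistical* structure of a phantom
validation experiment — not surface micro-optics (no BRDF or Monte Carlo
photon transport):

* **Volume template** `a·(λ/500 nm)^(−b)` minus Gaussian dips, clamped to
  (0, 1); defaults `a = 0.55`, `b = 0.6` echo the decreasing reduced
  scattering of an Intralipid dilution (≈ 0.8–1.65 mm⁻¹ over 500–900 nm),
  with weak water-band dips at 740/840 nm.  An explicit-coefficient mode
  generates volumes exactly inside the solver basis for recovery tests.
* **Glare fields.**  Smooth surface: `ε ~ |N(0, σ_smooth)|` with
  `σ_smooth = 0.002` — residual gloss of a nominally smooth surface.
  Rough surface: `ε = max(0, σ_rough · G)` with `G` a unit-variance
  Gaussian random field of correlation length 1 px (the ~0.1 mm grit
  scale of the roughening tool at 0.16 mm/px) and `σ_rough = 0.05`,
  drawn independently per direction.  The zero-truncation yields both
  glare-free and bright-glint pixels; ~88% of pixels have at least one
  glare-free direction, so the min-ε-zero convention is exactly
  attainable there (a `min_eps_zero_fraction` option can force it).
* **Noise**: additive Gaussian on reflectance, `σ_noise = 0.005`.
* **Counts model**: dark level 100, white level 3600 with a smooth
  spectral gain profile, reference reflectance 0.99, clipping at 4095 on
  a 4096 full scale, with the clipped-sample mask kept as ground truth.
  Inverting this model and re-calibrating reproduces the reflectance
  cubes to machine precision wherever unclipped.
* **Seeding**: one global seed expands into fixed per-field subseeds
  (`phantom.FIELD_SEEDS`), so individual fields can be regenerated and
  all output is bitwise reproducible.

The default three-region tissue scene uses fat-like / stroma-like /
tumor-like templates whose amplitudes (0.46 / 0.42 / 0.38) were chosen
once so that rough-mode glare makes adjacent regions' mean ± STD spectra
overlap while the underlying templates never cross — the regime in which
glare, not composition, limits discrimination.

**What passing tests show — and what they do not.**  The generator
realizes the additive model exactly: glare is spectrally flat, volume is
direction-independent, noise is white.  Tests therefore verify the
solver, calibration and metrics under the model's own assumptions, plus
graceful degradation under saturation and noise.  They cannot certify
behavior under real-data violations — curved edges (non-constant zenith),
chromatic glare, inter-direction registration error, sensor
non-linearity — which is exactly why the per-pixel residual and validity
diagnostics are first-class outputs.

## Evaluation metrics

* **RMSE** between a corrected spectrum and a reference:
  `sqrt(Σ_k (R̂_k − R_k)² / n)`.  The ROI report compares each ROI
  pixel's direction-averaged corrected spectrum against the
  direction-averaged mean spectrum of a glare-free reference ROI and
  reports mean ± sample STD over the ROI pixels (25 for a 5×5 ROI).
* **Variability reduction**: `1 − after/before`, where *before* is the
  mean over (ROI pixel, band) of the across-direction sample STD of the
  raw spectra and *after* is the same statistic on corrected spectra.
  "Average deviation across directions" admits several poolings; this
  per-pixel pooled convention is fixed here and used everywhere.  When
  *before* is exactly zero the reduction is reported as not-applicable.

On the default phantom the *after* statistic sits at the noise floor
(≈ 0.0044) regardless of seed, while *before* depends on how much glare
the specific 25-pixel ROI received; with the truncated-Gaussian glare
field the 5×5-ROI reduction estimate consequently spreads over roughly
60–87% across seeds (image-wide it is stable at ≈ 81%).  A larger ROI or
the whole frame gives a much tighter estimate; the 25-pixel ROI is kept
because it mirrors the phantom-experiment protocol.

* **Glare maps**: per-direction `ε` images on one shared linear scale
  from a pooled 1st–99th percentile stretch (robust to glints); for three
  directions an RGB composite assigns direction 1→R, 2→G, 3→B.  Invalid
  pixels are excluded from the stretch and rendered in a sentinel color.
  A stretch span at numerical-noise level renders black rather than
  amplifying float rounding.  Pseudo-RGB renders of reflectance cubes use
  the bands nearest 900/752/602 nm (ties break toward the lower
  wavelength; a band farther than 10 nm from its target is an error) with
  a per-channel 1–99% percentile stretch — the display mapping is a
  package convention.

* **SNV baseline** (`snv_normalize`): per-spectrum mean 0 / std 1
  (ddof = 1).  Provided only as the comparison baseline whose affine
  invariance demonstrates the amplitude information it destroys and the
  decomposition preserves.

## Coordinate and format conventions

Arrays are `(row Y, column X, band)`, 0-based.  ENVI files use BSQ or BIL
interleave (BIP is rejected — line-scan systems do not produce it); the
wavelength list in the header is mandatory.  Binary masks travel as
single-band 0/1 ENVI images.  TIFF stacks carry the grid as JSON in the
image description; HDF5 cubes as dataset attributes.

## Known limitations

* Glare common to all directions is fundamentally unidentifiable in this
  geometry; the min-ε-zero convention under-reports such glare and
  correspondingly over-reports volume.
* The flat-`R_spec` assumption degrades for strongly dispersive surfaces
  (chromatic glare leaks into the volume polynomial).
* Cubes must be spatially registered; the package performs no alignment.
* Edge pixels with non-constant effective zenith angle violate the shared
  `R_vol` assumption and should be screened by residual.
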