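"""Seeded synthetic phantoms and tissue-like scenes with full ground truth.

The generator emulates the statistical structure of a multi-direction
acquisition of an Intralipid/agarose optical phantom pair:

* a smooth, physically plausible volume-reflectance spectrum shared by all
  directions (decreasing scattering baseline minus Gaussian absorption
  dips), identical between the smooth and rough phantom;
* per-pixel, per-direction glare intensities ``eps``: near zero for the
  smooth-surface phantom (half-normal, sigma ~ 0.002), large and spatially
  noisy for the rough-surface phantom (zero-truncated Gaussian random
  field, correlation length ~ 1 px — the grit scale of the scouring pad
  that roughened the real phantom at 0.16 mm/px);
* additive Gaussian sensor noise on reflectance;
* a 12-bit counts model (dark level, white reference, gain, saturation
  clipping) so the calibration path can be exercised end to end.

Everything is driven by one seed expanded into per-field subseeds, so any
single field can be regenerated and the whole output is bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import CalibrationSet
from .hypercube import Hypercube, IlluminationSeries, WavelengthGrid, RAW_COUNTS, REFLECTANCE

__all__ = [
    "PhantomConfig",
    "RegionSpec",
    "SyntheticTruth",
    "PhantomRealization",
    "TissueScene",
    "volume_template",
    "generate_phantom",
    "generate_phantom_pair",
    "generate_tissue_scene",
    "expected_clipped_fraction",
]

# stable per-field subseed ids (documented so single fields can be regenerated)
FIELD_SEEDS = {
    "smooth_eps": 1,
    "rough_eps": 2,
    "smooth_noise": 3,
    "rough_noise": 4,
    "scene_eps": 5,
    "scene_noise": 6,
    "modulation": 7,
}


def _rng(seed: int, field_name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), FIELD_SEEDS[field_name]])


def default_grid() -> WavelengthGrid:
    """500-900 nm in 3 nm steps (134 bands)."""
    return WavelengthGrid.from_range(500.0, 900.0, 3.0)


def volume_template(
    grid: WavelengthGrid,
    amplitude: float = 0.55,
    scattering_power: float = 0.6,
    dips: tuple[tuple[float, float, float], ...] = ((740.0, 20.0, 0.010), (840.0, 30.0, 0.020)),
) -> np.ndarray:
    """Smooth volume-reflectance spectrum on ``grid``.

    ``amplitude * (lam/500)**(-scattering_power)`` echoes the decreasing
    reduced-scattering of an Intralipid dilution (0.8-1.65 mm^-1 over
    500-900 nm), minus Gaussian dips ``(center_nm, width_nm, depth)`` for
    the weak water absorption bands.  Clamped to (0, 1).
    """
    lam = grid.values
    r = amplitude * (lam / 500.0) ** (-scattering_power)
    for center, width, depth in dips:
        r = r - depth * np.exp(-0.5 * ((lam - center) / width) ** 2)
    return np.clip(r, 1e-6, 1.0)


@dataclass(frozen=True)
class RegionSpec:
    """Volume-spectrum template of one tissue-like region."""

    name: str
    amplitude: float
    scattering_power: float
    dips: tuple[tuple[float, float, float], ...] = ()


#: default 3-region scene: fat-like, stroma-like and tumor-like templates,
#: offset in amplitude so glare makes their raw spectra overlap while the
#: underlying volume spectra stay distinct
DEFAULT_REGIONS = (
    RegionSpec("adipose", 0.46, 0.45, ((760.0, 14.0, 0.025),)),
    RegionSpec("connective", 0.42, 0.55, ((840.0, 25.0, 0.020),)),
    RegionSpec("carcinoma", 0.38, 0.65, ((542.0, 12.0, 0.035), (577.0, 10.0, 0.030))),
)


@dataclass
class PhantomConfig:
    """Parameters of the synthetic phantom generator (see module docstring)."""

    shape: tuple[int, int] = (128, 128)
    grid: WavelengthGrid = field(default_factory=default_grid)
    n_directions: int = 3
    # volume model: template parameters, or explicit basis coefficients
    amplitude: float = 0.55
    scattering_power: float = 0.6
    dips: tuple[tuple[float, float, float], ...] = (
        (740.0, 20.0, 0.010),
        (840.0, 30.0, 0.020),
    )
    volume_coeffs: np.ndarray | None = None  # coefficients in build_basis(grid, mp)
    # roughness / glare
    sigma_smooth: float = 0.002
    sigma_rough: float = 0.05
    corr_length_px: float = 1.0
    min_eps_zero_fraction: float | None = None
    # sensor
    sigma_noise: float = 0.005
    dark_level: float = 100.0
    white_level: float = 3600.0
    full_scale: float = 4096.0
    reference_reflectance: float = 0.99
    spatial_resolution_mm_per_pixel: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_smooth", "sigma_rough", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.white_level <= self.dark_level:
            raise ValueError("white_level must exceed dark_level")
        if self.n_directions < 2:
            raise ValueError("need at least 2 illumination directions")

    @property
    def clip_ceiling(self) -> float:
        return self.full_scale - 1.0

    def true_volume_spectrum(self) -> np.ndarray:
        if self.volume_coeffs is not None:
            from .decomposition import build_basis

            coeffs = np.asarray(self.volume_coeffs, dtype=float)
            basis = build_basis(self.grid, coeffs.size - 1)
            return basis @ coeffs
        return volume_template(self.grid, self.amplitude, self.scattering_power, self.dips)

    def white_minus_dark(self) -> np.ndarray:
        """Smooth spectral gain profile of the white reference (counts)."""
        lam = self.grid.values
        profile = 1.0 - 0.1 * ((lam - 700.0) / 200.0) ** 2
        return (self.white_level - self.dark_level) * profile

    def echo(self) -> dict:
        d = asdict(self)
        d["grid"] = [float(v) for v in self.grid.values]
        if self.volume_coeffs is not None:
            d["volume_coeffs"] = [float(v) for v in self.volume_coeffs]
        return d


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside generator output."""

    volume: np.ndarray    # (Y, X, m_lambda) true volume reflectance
    epsilon: np.ndarray   # (Y, X, n_directions) true glare intensities
    clipped: np.ndarray   # (Y, X, m_lambda, n_directions) saturated samples
    config: dict


@dataclass
class PhantomRealization:
    """One synthetic phantom: reflectance + counts series and calibration."""

    reflectance: IlluminationSeries
    counts: IlluminationSeries
    calibrations: list[CalibrationSet]
    truth: SyntheticTruth


@dataclass
class TissueScene(PhantomRealization):
    labels: np.ndarray = None          # (Y, X) region index
    region_names: tuple[str, ...] = ()
    region_volumes: np.ndarray = None  # (n_regions, m_lambda) true templates


def _gaussian_random_field(
    rng: np.random.Generator, shape: tuple[int, int], corr_length_px: float
) -> np.ndarray:
    """Stationary GRF with unit marginal variance (periodic smoothing)."""
    white = rng.standard_normal(shape)
    if corr_length_px <= 0:
        return white
    smoothed = gaussian_filter(white, corr_length_px, mode="wrap")
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    kernel = gaussian_filter(impulse, corr_length_px, mode="wrap")
    norm = np.sqrt((kernel**2).sum())
    return smoothed / norm


def _epsilon_field(cfg: PhantomConfig, mode: str, field_name: str) -> np.ndarray:
    """Per-direction glare intensity fields, shape (Y, X, n_directions)."""
    rng = _rng(cfg.seed, field_name)
    ny, nx = cfg.shape
    if mode == "smooth":
        # half-normal: tiny residual gloss of a nominally smooth surface
        eps = np.abs(rng.normal(0.0, cfg.sigma_smooth, (ny, nx, cfg.n_directions)))
    elif mode == "rough":
        fields = [
            _gaussian_random_field(rng, (ny, nx), cfg.corr_length_px)
            for _ in range(cfg.n_directions)
        ]
        eps = np.maximum(0.0, cfg.sigma_rough * np.stack(fields, axis=-1))
    else:
        raise ValueError(f"unknown roughness mode {mode!r}")
    if cfg.min_eps_zero_fraction is not None:
        frac = cfg.min_eps_zero_fraction
        if not 0.0 <= frac <= 1.0:
            raise ValueError("min_eps_zero_fraction must lie in [0, 1]")
        flat = eps.reshape(-1, cfg.n_directions)
        n_force = int(round(frac * flat.shape[0]))
        idx = rng.permutation(flat.shape[0])[:n_force]
        flat[idx] -= flat[idx].min(axis=1, keepdims=True)
    return eps


def _counts_from_reflectance(
    refl: np.ndarray, cfg: PhantomConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the flat-field relation and clip at the sensor ceiling."""
    gain = cfg.white_minus_dark()  # (m_lambda,)
    if refl.ndim == 4:  # (Y, X, m_lambda, directions)
        gain = gain[:, None]
    counts = cfg.dark_level + refl / cfg.reference_reflectance * gain
    clipped = counts > cfg.clip_ceiling
    counts = np.minimum(counts, cfg.clip_ceiling)
    return np.maximum(counts, 0.0), clipped


def _calibration_sets(cfg: PhantomConfig) -> list[CalibrationSet]:
    """One calibration set per direction (line references, broadcast over rows)."""
    _, nx = cfg.shape
    m_lambda = len(cfg.grid)
    dark_line = np.full((1, nx, m_lambda), cfg.dark_level)
    white_line = dark_line + cfg.white_minus_dark()[None, None, :]
    ref = np.full(m_lambda, cfg.reference_reflectance)
    cal = CalibrationSet(
        dark=Hypercube(dark_line, cfg.grid, kind=RAW_COUNTS),
        white=Hypercube(white_line, cfg.grid, kind=RAW_COUNTS),
        reference_spectrum=ref,
    )
    return [cal for _ in range(cfg.n_directions)]


def _realize(
    cfg: PhantomConfig, volume: np.ndarray, eps: np.ndarray, noise_field: str
) -> PhantomRealization:
    ny, nx = cfg.shape
    m_lambda = len(cfg.grid)
    rng = _rng(cfg.seed, noise_field)
    noise = rng.normal(0.0, cfg.sigma_noise, (ny, nx, m_lambda, cfg.n_directions))
    total = volume[:, :, :, None] + eps[:, :, None, :] + noise
    counts, clipped = _counts_from_reflectance(total, cfg)

    refl_cubes, count_cubes = [], []
    for i in range(cfg.n_directions):
        refl_cubes.append(
            Hypercube(total[:, :, :, i], cfg.grid, kind=REFLECTANCE,
                      spatial_resolution_mm_per_pixel=cfg.spatial_resolution_mm_per_pixel)
        )
        count_cubes.append(
            Hypercube(counts[:, :, :, i], cfg.grid, kind=RAW_COUNTS,
                      spatial_resolution_mm_per_pixel=cfg.spatial_resolution_mm_per_pixel)
        )
    truth = SyntheticTruth(
        volume=volume, epsilon=eps, clipped=clipped, config=cfg.echo()
    )
    return PhantomRealization(
        reflectance=IlluminationSeries(refl_cubes),
        counts=IlluminationSeries(count_cubes),
        calibrations=_calibration_sets(cfg),
        truth=truth,
    )


def generate_phantom(cfg: PhantomConfig, mode: str) -> PhantomRealization:
    """Generate a single phantom with ``mode`` in {'smooth', 'rough'}."""
    ny, nx = cfg.shape
    volume = np.broadcast_to(
        cfg.true_volume_spectrum(), (ny, nx, len(cfg.grid))
    ).copy()
    eps = _epsilon_field(cfg, mode, f"{mode}_eps")
    return _realize(cfg, volume, eps, f"{mode}_noise")


def generate_phantom_pair(cfg: PhantomConfig) -> tuple[PhantomRealization, PhantomRealization]:
    """Smooth/rough phantom pair sharing the same true volume reflectance.

    Emulates two phantoms of identical chemical composition whose only
    difference is surface roughness.  A self-check verifies that the rough
    phantom's inter-direction glare spread exceeds the smooth one's
    (skipped when the configuration itself makes that false).
    """
    smooth = generate_phantom(cfg, "smooth")
    rough = generate_phantom(cfg, "rough")
    if cfg.sigma_rough > cfg.sigma_smooth:
        spread = lambda e: np.std(e, axis=-1, ddof=1).mean()
        if not spread(rough.truth.epsilon) > spread(smooth.truth.epsilon):
            raise RuntimeError(
                "generator self-check failed: rough phantom does not show "
                "larger inter-direction glare spread than the smooth one"
            )
    return smooth, rough


def _stripe_labels(shape: tuple[int, int], n_regions: int) -> np.ndarray:
    ny, nx = shape
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    labels = np.empty((ny, nx), dtype=int)
    for r in range(n_regions):
        labels[:, edges[r]:edges[r + 1]] = r
    return labels


def generate_tissue_scene(
    cfg: PhantomConfig,
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS,
    labels: np.ndarray | None = None,
    region_masks: list[np.ndarray] | None = None,
    mode: str = "rough",
    modulation_amplitude: float = 0.0,
) -> TissueScene:
    """Multi-region scene with distinct volume templates per region.

    Regions default to vertical stripes; pass ``labels`` (a (Y, X) integer
    image) or ``region_masks`` (boolean masks, which must not overlap and
    must tile the image) for custom geometry.  ``modulation_amplitude``
    optionally applies a smooth multiplicative field to the volume.
    """
    if len(regions) < 2:
        raise ValueError("a tissue scene needs at least 2 regions")
    ny, nx = cfg.shape
    if region_masks is not None:
        counts = np.zeros((ny, nx), dtype=int)
        for m in region_masks:
            counts += np.asarray(m, dtype=bool).astype(int)
        if np.any(counts > 1):
            raise ValueError("region masks overlap")
        if np.any(counts == 0):
            raise ValueError("region masks must tile the image")
        labels = np.zeros((ny, nx), dtype=int)
        for r, m in enumerate(region_masks):
            labels[np.asarray(m, dtype=bool)] = r
    elif labels is None:
        labels = _stripe_labels(cfg.shape, len(regions))
    labels = np.asarray(labels)
    if labels.shape != (ny, nx):
        raise ValueError("label image shape does not match the configured shape")
    if labels.max() >= len(regions) or labels.min() < 0:
        raise ValueError("label image refers to undefined regions")

    templates = np.stack(
        [volume_template(cfg.grid, r.amplitude, r.scattering_power, r.dips)
         for r in regions]
    )
    volume = templates[labels]  # (Y, X, m_lambda)
    if modulation_amplitude:
        mod = _gaussian_random_field(
            _rng(cfg.seed, "modulation"), cfg.shape, max(cfg.corr_length_px, 4.0)
        )
        volume = volume * (1.0 + modulation_amplitude * mod)[:, :, None]
        volume = np.clip(volume, 1e-6, 1.0)

    eps = _epsilon_field(cfg, mode, "scene_eps")
    base = _realize(cfg, volume, eps, "scene_noise")
    return TissueScene(
        reflectance=base.reflectance,
        counts=base.counts,
        calibrations=base.calibrations,
        truth=base.truth,
        labels=labels,
        region_names=tuple(r.name for r in regions),
        region_volumes=templates,
    )


def expected_clipped_fraction(cfg: PhantomConfig, mode: str = "rough") -> float:
    """Analytic probability that a (pixel, band, direction) sample clips.

    For the homogeneous phantom, a sample clips when
    ``eps + noise > c_b`` with
    ``c_b = R_ref * (ceiling - dark) / gain_b - Rvol_b`` per band.  With
    ``eps = max(0, Z)``, ``Z ~ N(0, sigma_r^2)`` and independent noise the
    tail is a one-dimensional integral, evaluated numerically.  Averaged
    over bands; marginals do not depend on the spatial correlation length.
    """
    from scipy.stats import norm

    rvol = cfg.true_volume_spectrum()
    gain = cfg.white_minus_dark()
    c = cfg.reference_reflectance * (cfg.clip_ceiling - cfg.dark_level) / gain - rvol
    sig_r = cfg.sigma_rough if mode == "rough" else cfg.sigma_smooth
    sig_n = cfg.sigma_noise

    if sig_r == 0:
        return float(np.mean(norm.sf(c / max(sig_n, 1e-300))))
    z = np.linspace(0.0, 8.0 * sig_r, 4001)
    pdf = norm.pdf(z, scale=sig_r)
    probs = np.empty(c.size)
    for b, cb in enumerate(c):
        if mode == "smooth":
            # half-normal: eps = |Z|, fold the density
            tail = np.trapezoid(2.0 * pdf * norm.sf((cb - z) / max(sig_n, 1e-300)), z)
        else:
            tail = (
                np.trapezoid(pdf * norm.sf((cb - z) / max(sig_n, 1e-300)), z)
                + 0.5 * norm.sf(cb / max(sig_n, 1e-300))
            )
        probs[b] = tail
    return float(probs.mean())
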