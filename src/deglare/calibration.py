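"""Flat-field calibration and saturation handling.

Raw sensor counts are converted to total reflectance with a dark-current
measurement and a diffuse white reference (a Spectralon tile with known
reflectance spectrum):

    R_total = (I_sample - I_dark) / (I_white - I_dark) * R_reference

Calibration is per illumination direction: each direction has its own
dark/white pair because the illumination field differs between source
positions.

A 12-bit sensor tops out at 4096 counts; samples at or above a 4000-count
threshold are treated as saturated and excluded from the decomposition.
The ``>=`` comparison is the safe direction for a ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import Hypercube, IlluminationSeries, WavelengthGrid, RAW_COUNTS, REFLECTANCE

__all__ = [
    "CalibrationSet",
    "SaturationMask",
    "calibrate",
    "calibrate_series",
    "saturation_mask",
    "series_saturation_mask",
    "DEFAULT_SATURATION_THRESHOLD",
    "FULL_SCALE_COUNTS",
]

DEFAULT_SATURATION_THRESHOLD = 4000.0
FULL_SCALE_COUNTS = 4096.0


@dataclass
class CalibrationSet:
    """Dark cube, white-reference cube and reference-tile spectrum.

    ``dark`` and ``white`` may be full cubes or single-row line references
    (shape ``(1, X, bands)``), in which case they are broadcast across
    image rows — the natural shape for a push-broom system where the
    illumination profile varies along the scan line only.
    """

    dark: Hypercube
    white: Hypercube
    reference_spectrum: np.ndarray  # per-band reflectance of the reference tile

    def __post_init__(self) -> None:
        self.reference_spectrum = np.asarray(self.reference_spectrum, dtype=float)
        for name, cube in (("dark", self.dark), ("white", self.white)):
            if cube.kind != RAW_COUNTS:
                raise ValueError(f"{name} cube must be raw-counts, got {cube.kind!r}")
        if self.dark.grid != self.white.grid:
            raise ValueError("dark and white cubes have different wavelength grids")
        if self.reference_spectrum.shape != (len(self.dark.grid),):
            raise ValueError(
                "reference spectrum length does not match the wavelength grid"
            )
        if np.any(self.reference_spectrum <= 0) or np.any(self.reference_spectrum > 1.2):
            raise ValueError(
                "reference-tile reflectance must lie in (0, 1.2] "
                "(a Spectralon tile is ~0.99)"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return self.dark.grid

    @classmethod
    def from_files(cls, dark_path, white_path, reference_path, dialect="envi"):
        """Load dark/white cubes and a two-column text reference spectrum."""
        from .io import read_cube, read_spectrum

        dark = read_cube(dark_path, dialect)
        white = read_cube(white_path, dialect)
        wl, refl = read_spectrum(reference_path)
        if wl.shape != dark.grid.values.shape or not np.allclose(wl, dark.grid.values):
            raise ValueError(
                "reference-spectrum wavelengths do not match the calibration cubes"
            )
        return cls(dark=dark, white=white, reference_spectrum=refl)


def _broadcast(cal_cube: Hypercube, shape: tuple[int, int, int]) -> np.ndarray:
    data = cal_cube.data
    if data.shape == shape:
        return data
    if data.shape[0] == 1 and data.shape[1:] == shape[1:]:
        return np.broadcast_to(data, shape)
    raise ValueError(
        f"calibration cube shape {data.shape} matches neither the sample shape "
        f"{shape} nor a single-row line reference"
    )


def calibrate(sample: Hypercube, cal: CalibrationSet) -> Hypercube:
    """Convert a raw-counts cube to total reflectance.

    Raises if the white-minus-dark denominator is not strictly positive at
    any sample location (the flat-field would be undefined there).
    """
    if sample.kind != RAW_COUNTS:
        raise ValueError(f"sample cube must be raw-counts, got {sample.kind!r}")
    if sample.grid != cal.grid:
        raise ValueError("sample and calibration wavelength grids differ")
    dark = _broadcast(cal.dark, sample.shape)
    white = _broadcast(cal.white, sample.shape)
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        coords = np.argwhere(bad)[:5]
        raise ValueError(
            "white - dark is not strictly positive at "
            f"{int(bad.sum())} samples, e.g. (Y, X, band) = "
            f"{[tuple(int(v) for v in c) for c in coords]}"
        )
    refl = (sample.data - dark) / denom * cal.reference_spectrum
    return Hypercube(
        data=refl,
        grid=sample.grid,
        kind=REFLECTANCE,
        spatial_resolution_mm_per_pixel=sample.spatial_resolution_mm_per_pixel,
    )


def calibrate_series(
    series: IlluminationSeries, cals: list[CalibrationSet]
) -> IlluminationSeries:
    """Calibrate each direction with its own calibration set."""
    if len(cals) != series.n_directions:
        raise ValueError(
            f"{series.n_directions} directions but {len(cals)} calibration sets"
        )
    return IlluminationSeries(
        cubes=[calibrate(cube, cal) for cube, cal in zip(series.cubes, cals)],
        zenith_deg=series.zenith_deg,
    )


@dataclass
class SaturationMask:
    """Saturated-sample flags; ``True`` means saturated/invalid.

    ``band_mask`` has shape (Y, X, bands, directions); ``pixel_mask``
    (Y, X, directions) is the any-band summary.
    """

    band_mask: np.ndarray
    pixel_mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.band_mask = np.asarray(self.band_mask, dtype=bool)
        self.pixel_mask = np.asarray(self.pixel_mask, dtype=bool)
        if self.band_mask.ndim != 4 or self.pixel_mask.ndim != 3:
            raise ValueError("band_mask must be 4-D and pixel_mask 3-D")

    @property
    def n_saturated_samples(self) -> int:
        return int(self.band_mask.sum())

    @classmethod
    def none(cls, spatial_shape, n_bands, n_directions) -> "SaturationMask":
        ny, nx = spatial_shape
        return cls(
            band_mask=np.zeros((ny, nx, n_bands, n_directions), dtype=bool),
            pixel_mask=np.zeros((ny, nx, n_directions), dtype=bool),
            threshold=np.inf,
        )


def saturation_mask(
    sample: Hypercube, threshold: float = DEFAULT_SATURATION_THRESHOLD
) -> np.ndarray:
    """Boolean (Y, X, bands) mask of samples with counts >= threshold."""
    if sample.kind != RAW_COUNTS:
        raise ValueError("saturation_mask expects a raw-counts cube")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return sample.data >= threshold


def series_saturation_mask(
    series: IlluminationSeries, threshold: float = DEFAULT_SATURATION_THRESHOLD
) -> SaturationMask:
    """Per-direction saturation mask for a raw-counts series.

    Lowering the threshold can only add flagged samples (monotonicity),
    since the comparison is ``counts >= threshold``.
    """
    band = np.stack([saturation_mask(c, threshold) for c in series.cubes], axis=-1)
    return SaturationMask(
        band_mask=band, pixel_mask=band.any(axis=2), threshold=threshold
    )
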