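"""Core containers for hyperspectral cubes and multi-direction series.

Conventions used throughout the package:

* arrays are indexed ``(row Y, column X, band)``, 0-based;
* wavelengths are in nanometres on a strictly increasing grid;
* a cube is either ``raw-counts`` (sensor counts, >= 0) or ``reflectance``
  (dimensionless, typically in [0, ~1.2] but not clamped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "IlluminationSeries",
    "RoiSpectra",
    "extract_roi",
    "pseudo_rgb",
    "nearest_band",
]

#: cube kinds
RAW_COUNTS = "raw-counts"
REFLECTANCE = "reflectance"
_KINDS = (RAW_COUNTS, REFLECTANCE)

#: default pseudo-RGB wavelength assignment (nm): red, green, blue
DEFAULT_RGB_BANDS_NM = (900.0, 752.0, 602.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres.

    The per-pixel solver needs at least 3 bands, so a grid shorter than
    that is rejected at construction time.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("wavelength grid must be 1-D")
        if values.size < 3:
            raise ValueError(
                f"wavelength grid needs at least 3 bands, got {values.size}"
            )
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("wavelengths must be finite and positive (nm)")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @classmethod
    def from_range(cls, start_nm: float, stop_nm: float, step_nm: float) -> "WavelengthGrid":
        """Inclusive-start grid ``start, start+step, ... <= stop``."""
        n = int(np.floor((stop_nm - start_nm) / step_nm)) + 1
        return cls(start_nm + step_nm * np.arange(n))


def nearest_band(grid: WavelengthGrid, target_nm: float, tol_nm: float = 10.0) -> int:
    """Index of the grid wavelength closest to ``target_nm``.

    Ties (a target exactly between two bands) break toward the lower
    wavelength so band selection is deterministic.  Raises ``ValueError``
    if the nearest band is farther than ``tol_nm``.
    """
    dist = np.abs(grid.values - target_nm)
    idx = int(np.argmin(dist))  # argmin returns the first (lower-λ) minimum
    if dist[idx] > tol_nm:
        raise ValueError(
            f"no band within {tol_nm} nm of {target_nm} nm "
            f"(nearest is {grid.values[idx]:.1f} nm)"
        )
    return idx


@dataclass
class Hypercube:
    """A single hyperspectral image: ``data[Y, X, band]`` plus its grid."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = REFLECTANCE
    spatial_resolution_mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (Y, X, band)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match wavelength "
                f"grid length ({len(self.grid)})"
            )
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == REFLECTANCE:
            if not np.all(np.isfinite(self.data)):
                raise ValueError("reflectance cube contains non-finite values")
        else:
            if np.any(self.data < 0):
                raise ValueError("raw-counts cube contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class IlluminationSeries:
    """Registered cubes of the same scene, one per illumination direction.

    All sources share a common zenith angle (30 degrees in the reference
    acquisition geometry) and differ only in axial position, so the volume
    reflectance at a pixel is the same in every cube while the surface
    (glare) contribution varies.
    """

    cubes: list[Hypercube]
    zenith_deg: float = 30.0

    def __post_init__(self) -> None:
        if len(self.cubes) < 2:
            raise ValueError("an illumination series needs at least 2 directions")
        ref = self.cubes[0]
        for i, cube in enumerate(self.cubes[1:], start=2):
            if cube.shape != ref.shape:
                raise ValueError(
                    f"direction {i} shape {cube.shape} differs from "
                    f"direction 1 shape {ref.shape}"
                )
            if cube.grid != ref.grid:
                raise ValueError(f"direction {i} wavelength grid differs from direction 1")

    @property
    def n_directions(self) -> int:
        return len(self.cubes)

    @property
    def grid(self) -> WavelengthGrid:
        return self.cubes[0].grid

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.cubes[0].shape[:2]

    def stack(self) -> np.ndarray:
        """Return data as one array of shape (Y, X, band, direction)."""
        return np.stack([c.data for c in self.cubes], axis=-1)


@dataclass
class RoiSpectra:
    """Per-direction mean and sample-STD spectra over a square ROI."""

    center: tuple[int, int]
    size: int
    grid: WavelengthGrid
    mean: np.ndarray  # (n_directions, n_bands)
    std: np.ndarray   # (n_directions, n_bands), ddof=1

    @property
    def n_pixels(self) -> int:
        return self.size * self.size


def _roi_slices(center: tuple[int, int], size: int, shape: tuple[int, int]):
    if size % 2 != 1 or size < 1:
        raise ValueError(f"ROI size must be odd and positive, got {size}")
    cy, cx = center
    half = size // 2
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
        raise ValueError(
            f"ROI center={center} size={size} clips the image edge "
            f"(image shape {shape}); edge pixels are unreliable"
        )
    return slice(y0, y1), slice(x0, x1)


def extract_roi(
    series: IlluminationSeries, center: tuple[int, int], size: int
) -> RoiSpectra:
    """Mean and sample STD (ddof=1) spectra over a ``size`` x ``size`` ROI.

    The ROI must lie fully inside the image; size must be odd.  The STD is
    the sample standard deviation over the ``size**2`` ROI pixels, computed
    independently for each band and illumination direction.
    """
    sy, sx = _roi_slices(center, size, series.spatial_shape)
    means, stds = [], []
    for cube in series.cubes:
        patch = cube.data[sy, sx, :].reshape(-1, cube.n_bands)
        means.append(patch.mean(axis=0))
        stds.append(patch.std(axis=0, ddof=1) if patch.shape[0] > 1 else np.zeros(cube.n_bands))
    return RoiSpectra(
        center=tuple(center),
        size=size,
        grid=series.grid,
        mean=np.array(means),
        std=np.array(stds),
    )


def pseudo_rgb(
    cube: Hypercube,
    bands_nm: tuple[float, float, float] = DEFAULT_RGB_BANDS_NM,
    tol_nm: float = 10.0,
    stretch: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Render a reflectance cube as a 3-channel image in [0, 1].

    Each channel is the band nearest the requested wavelength (default
    900 / 752 / 602 nm for R / G / B), linearly rescaled by a per-channel
    percentile stretch (default 1st-99th), which is robust to saturated
    outliers.  A degenerate channel (zero dynamic range) renders mid-gray.
    """
    if cube.kind != REFLECTANCE:
        raise ValueError("pseudo_rgb expects a reflectance cube; calibrate first")
    lo_p, hi_p = stretch
    out = np.empty(cube.shape[:2] + (3,), dtype=float)
    for ch, target in enumerate(bands_nm):
        band = cube.data[:, :, nearest_band(cube.grid, target, tol_nm)]
        lo, hi = np.percentile(band, [lo_p, hi_p])
        if hi > lo:
            out[:, :, ch] = np.clip((band - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[:, :, ch] = 0.5
    return out
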