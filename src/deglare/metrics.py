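"""Performance metrics and glare-map rendering.

Two quantities summarize how well the separation works:

* the RMSE between a corrected (glare-removed) spectrum and a reference
  volume spectrum, ``sqrt(sum_k (Rhat_k - R_k)^2 / n)``;
* the fractional reduction in inter-illumination variability, defined as
  the mean (over ROI pixels and bands) of the across-direction sample STD
  of the spectra, compared before and after correction.  "Average
  deviation across directions" is fixed here as that pooled mean STD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .decomposition import DecompositionResult, STATUS_FAILED, corrected_reflectance
from .hypercube import IlluminationSeries, _roi_slices

__all__ = [
    "rmse",
    "roi_rmse_report",
    "variability_reduction",
    "epsilon_maps",
    "region_band_overlap",
    "RmseReport",
    "VariabilityReport",
    "EvaluationReport",
]


def rmse(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Root-mean-square error between two equal-length spectra."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {measured.shape}"
        )
    if predicted.size < 1:
        raise ValueError("spectra must have at least one sample")
    return float(np.sqrt(np.mean((predicted - measured) ** 2)))


@dataclass
class RmseReport:
    mean: float
    std: float
    n_spectra: int
    n_excluded: int


@dataclass
class VariabilityReport:
    before: float
    after: float
    reduction: float | None  # None when before == 0 (not applicable)


@dataclass
class EvaluationReport:
    """Aggregate report of a decomposition run."""

    rmse: RmseReport | None
    variability: VariabilityReport | None
    n_failed_pixels: int
    n_degraded_pixels: int
    config: dict

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        if self.variability is not None and self.variability.reduction is None:
            d["variability"]["reduction"] = "not-applicable"
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = []
        if self.rmse is not None:
            lines.append(
                f"RMSE vs reference: {self.rmse.mean:.4f} +/- {self.rmse.std:.4f} "
                f"(mean +/- STD over {self.rmse.n_spectra} ROI spectra, "
                f"{self.rmse.n_excluded} excluded)"
            )
        if self.variability is not None:
            v = self.variability
            red = "n/a" if v.reduction is None else f"{100 * v.reduction:.1f}%"
            lines.append(
                f"inter-direction variability: {v.before:.5f} -> {v.after:.5f} "
                f"(reduction {red})"
            )
        lines.append(
            f"pixels: {self.n_degraded_pixels} degraded, {self.n_failed_pixels} failed"
        )
        return "\n".join(lines)


def roi_rmse_report(
    corrected: np.ndarray,
    result: DecompositionResult,
    center: tuple[int, int],
    size: int,
    reference_spectrum: np.ndarray,
) -> RmseReport:
    """Per-pixel RMSE of corrected ROI spectra against a reference.

    For each valid ROI pixel, the corrected spectrum averaged over
    directions is compared with ``reference_spectrum`` (typically the
    direction-averaged mean spectrum of a glare-free reference ROI).
    Failed/saturation-excluded pixels are dropped and counted.
    """
    sy, sx = _roi_slices(center, size, result.status.shape)
    patch = corrected[sy, sx]            # (s, s, m_lambda, mi)
    status = result.status[sy, sx]
    reference_spectrum = np.asarray(reference_spectrum, dtype=float)
    if reference_spectrum.shape != (patch.shape[2],):
        raise ValueError("reference spectrum length does not match the cube")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN failed pixels
        spectra = np.nanmean(patch, axis=-1).reshape(-1, patch.shape[2])
    valid = (status != STATUS_FAILED).reshape(-1) & np.isfinite(spectra).all(axis=1)
    spectra = spectra[valid]
    if spectra.shape[0] == 0:
        raise ValueError("no valid ROI spectra left after masking")
    errors = np.sqrt(np.mean((spectra - reference_spectrum) ** 2, axis=1))
    return RmseReport(
        mean=float(errors.mean()),
        std=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        n_spectra=int(errors.size),
        n_excluded=int((~valid).sum()),
    )


def variability_reduction(
    series: IlluminationSeries,
    result: DecompositionResult,
    center: tuple[int, int],
    size: int,
) -> VariabilityReport:
    """Inter-illumination variability before vs after glare removal.

    ``before`` is the mean over (ROI pixel, band) of the across-direction
    sample STD of the raw spectra; ``after`` is the same statistic on the
    corrected spectra; ``reduction = 1 - after / before``.  Pixels where
    the decomposition failed are excluded from both statistics.
    """
    sy, sx = _roi_slices(center, size, result.status.shape)
    raw = series.stack()[sy, sx]                    # (s, s, m_lambda, mi)
    corr = corrected_reflectance(series, result)[sy, sx]
    ok = result.status[sy, sx] != STATUS_FAILED
    if not ok.any():
        raise ValueError("every ROI pixel failed to decompose")
    raw, corr = raw[ok], corr[ok]
    before = float(np.std(raw, axis=-1, ddof=1).mean())
    after = float(np.nanmean(np.nanstd(corr, axis=-1, ddof=1)))
    if before == 0.0:
        return VariabilityReport(before=before, after=after, reduction=None)
    return VariabilityReport(
        before=before, after=after, reduction=1.0 - after / before
    )


def region_band_overlap(
    cube_stack: np.ndarray,
    labels: np.ndarray,
    region_a: int,
    region_b: int,
) -> float:
    """Fraction of bands where two regions' mean +/- STD bands intersect.

    ``cube_stack`` is (Y, X, m_lambda, mi); mean and STD pool region
    pixels and directions per band (as a shaded-STD spectrum plot would).
    NaN samples (failed pixels) are ignored.
    """
    out = []
    for region in (region_a, region_b):
        vals = cube_stack[labels == region]          # (npix, m_lambda, mi)
        vals = np.moveaxis(vals, 1, -1).reshape(-1, cube_stack.shape[2])
        mean = np.nanmean(vals, axis=0)
        std = np.nanstd(vals, axis=0, ddof=1)
        out.append((mean - std, mean + std))
    (lo_a, hi_a), (lo_b, hi_b) = out
    intersect = (lo_a <= hi_b) & (lo_b <= hi_a)
    return float(intersect.mean())


def epsilon_maps(
    result: DecompositionResult,
    stretch: tuple[float, float] = (1.0, 99.0),
    sentinel_rgb: tuple[float, float, float] = (1.0, 0.0, 1.0),
    composite: bool = True,
) -> tuple[list[np.ndarray], np.ndarray | None]:
    """Per-direction glare maps and (for 3 directions) an RGB composite.

    All grayscale maps share one linear scale from the pooled percentile
    stretch of valid epsilon values, so intensities are comparable between
    directions.  Invalid pixels (failed, or a dropped direction) are NaN
    in the grayscale maps and rendered in a sentinel color (default
    magenta) in the composite; they are excluded from the stretch.
    """
    eps = result.epsilon
    valid = np.isfinite(eps)
    if not valid.any():
        raise ValueError("no valid epsilon values to render")
    lo, hi = np.percentile(eps[valid], list(stretch))
    # a span at numerical-noise level means "no glare anywhere": render black
    # instead of amplifying float rounding into full-scale speckle
    span = hi - lo
    if span <= 1e-12:
        lo, span = np.inf, 1.0

    grays = []
    for i in range(result.n_directions):
        g = np.clip((eps[:, :, i] - lo) / span, 0.0, 1.0)
        g[~valid[:, :, i]] = np.nan
        grays.append(g)

    if not composite:
        return grays, None
    if result.n_directions != 3:
        raise ValueError(
            f"the RGB composite needs exactly 3 directions, got "
            f"{result.n_directions}; pass composite=False for grayscale maps only"
        )
    rgb = np.stack([np.nan_to_num(g, nan=0.0) for g in grays], axis=-1)
    bad = ~valid.all(axis=-1)
    rgb[bad] = sentinel_rgb
    return grays, rgb


def save_png(image: np.ndarray, path: str | Path) -> Path:
    """Write a float image in [0, 1] (2-D gray or 3-channel) as 8-bit PNG."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.nan_to_num(np.asarray(image, dtype=float), nan=0.0)
    iio.imwrite(path, (np.clip(arr, 0.0, 1.0) * 255).round().astype(np.uint8))
    return path
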