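"""Per-pixel separation of volume and surface reflectance.

Model
-----
A pixel imaged under ``mi`` illumination directions with a shared zenith
angle sees the same volume (diffuse) reflectance in every direction but a
direction-dependent amount of surface (specular/glare) reflectance:

    R_tot(lam, i) = R_vol(lam) + eps_i * R_spec(lam)

R_spec is spectrally flat to a good approximation for fat/water mixtures,
so the default specular shape is a constant.  R_vol is smooth (broad tissue
absorbers), so it is modelled as a polynomial of order ``mp`` in an
orthonormal basis on the affinely normalized wavelength axis.  That leaves
``mp + 1 + mi`` unknowns against ``m_lambda * mi`` equations, solved per
pixel by linear least squares (closed form) or iterative nonlinear least
squares (retained for non-flat specular shapes and as a cross-check).

Identifiability
---------------
With a flat specular shape the model is shift-degenerate: moving a constant
``t`` from every ``eps_i`` into the volume polynomial leaves the fit
unchanged.  The default convention returns the representative with
``min_i eps_i = 0`` at each pixel — any signal common to all directions is
attributed to the volume, which is the conservative reading of this
acquisition geometry.  A minimum-norm representative is selectable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .calibration import SaturationMask
from .hypercube import Hypercube, IlluminationSeries, WavelengthGrid, REFLECTANCE

__all__ = [
    "SpecularModel",
    "SolverConfig",
    "DecompositionResult",
    "build_basis",
    "fresnel_normal",
    "decompose_pixel",
    "decompose_cube",
    "corrected_reflectance",
    "snv_normalize",
    "STATUS_OK",
    "STATUS_DEGRADED",
    "STATUS_FAILED",
]

STATUS_OK = 0          # solved from a full set of samples
STATUS_DEGRADED = 1    # solved, but saturated samples were excluded
STATUS_FAILED = 2      # not solvable (too few samples / singular design)


def build_basis(grid: WavelengthGrid, mp: int) -> np.ndarray:
    """Orthonormal polynomial basis, shape ``(m_lambda, mp + 1)``.

    Wavelengths are affinely mapped to [-1, 1] and a Vandermonde matrix is
    orthonormalized (QR) under the discrete inner product; raw powers of
    nm-scale wavelengths would be hopelessly ill-conditioned.  Column 0 is
    the constant, and column signs are fixed so the expansion is
    deterministic.
    """
    m_lambda = len(grid)
    if mp < 0:
        raise ValueError(f"polynomial order must be >= 0, got {mp}")
    if mp + 1 > m_lambda:
        raise ValueError(
            f"polynomial order {mp} needs {mp + 1} basis functions but the "
            f"grid has only {m_lambda} bands"
        )
    lam = grid.values
    x = 2.0 * (lam - lam[0]) / (lam[-1] - lam[0]) - 1.0
    vander = np.vander(x, mp + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def fresnel_normal(n_sample: np.ndarray, n_medium: np.ndarray) -> np.ndarray:
    """Normal-incidence Fresnel reflectance from two refractive-index spectra."""
    n_sample = np.asarray(n_sample, dtype=float)
    n_medium = np.asarray(n_medium, dtype=float)
    if n_sample.shape != n_medium.shape:
        raise ValueError("refractive-index spectra must share the same grid")
    if np.any(n_sample <= 0) or np.any(n_medium <= 0):
        raise ValueError("refractive indices must be positive")
    return ((n_sample - n_medium) / (n_sample + n_medium)) ** 2


@dataclass
class SpecularModel:
    """Spectral shape of the specular reflectance, peak-normalized to 1."""

    mode: str = "flat"  # 'flat' | 'fresnel-derived'
    shape: np.ndarray | None = None

    @classmethod
    def flat(cls, grid: WavelengthGrid) -> "SpecularModel":
        return cls(mode="flat", shape=np.ones(len(grid)))

    @classmethod
    def from_refractive_index(
        cls, grid: WavelengthGrid, n_sample: np.ndarray, n_medium: np.ndarray
    ) -> "SpecularModel":
        r = fresnel_normal(n_sample, n_medium)
        if r.shape != (len(grid),):
            raise ValueError("refractive-index spectra do not match the grid")
        peak = r.max()
        if peak <= 0:
            raise ValueError(
                "Fresnel reflectance is zero everywhere (index-matched); "
                "no specular shape can be derived"
            )
        return cls(mode="fresnel-derived", shape=r / peak)

    def on_grid(self, grid: WavelengthGrid) -> np.ndarray:
        if self.shape is None:
            return np.ones(len(grid))
        shape = np.asarray(self.shape, dtype=float)
        if shape.shape != (len(grid),):
            raise ValueError("specular shape length does not match the grid")
        if self.mode == "flat" and np.ptp(shape) != 0:
            raise ValueError("flat specular model must have a constant shape")
        if np.any(shape <= 0):
            raise ValueError("specular shape must be positive")
        return shape


@dataclass
class SolverConfig:
    """Knobs of the per-pixel solver.

    ``poly_order`` is the volume-polynomial order ``mp`` (default 6: seven
    coefficients track the broad absorber dips of the 500-900 nm range
    while staying far below the band count).  ``drop_direction_band_fraction``
    is the saturation granularity policy: a (pixel, direction) is dropped
    wholesale only when more than this fraction of its bands is saturated;
    otherwise only the saturated bands are excluded.
    """

    poly_order: int = 6
    epsilon_nonneg: bool = True
    identifiability: str = "min-epsilon-zero"  # or 'minimum-norm'
    solver: str = "closed-form-linear"          # or 'iterative-nonlinear'
    max_iter: int = 200
    tol: float = 1e-12
    drop_direction_band_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.identifiability not in ("min-epsilon-zero", "minimum-norm"):
            raise ValueError(f"unknown identifiability rule {self.identifiability!r}")
        if self.solver not in ("closed-form-linear", "iterative-nonlinear"):
            raise ValueError(f"unknown solver {self.solver!r}")

    def echo(self) -> dict:
        return asdict(self)


def _design_matrix(
    basis: np.ndarray, spec_shape: np.ndarray, unmasked: np.ndarray,
    active_dirs: np.ndarray,
) -> np.ndarray:
    """Design matrix over unmasked (band, direction) samples.

    Sample ordering is C-order of the (band, direction) pair.  Columns are
    the ``mp + 1`` basis functions followed by one specular-intensity
    column per active direction.
    """
    m_lambda, n_dirs = unmasked.shape
    k = basis.shape[1]
    lam_idx, dir_idx = np.nonzero(unmasked)
    n_rows = lam_idx.size
    a = np.zeros((n_rows, k + active_dirs.size))
    a[:, :k] = basis[lam_idx]
    dir_col = np.searchsorted(active_dirs, dir_idx)
    a[np.arange(n_rows), k + dir_col] = spec_shape[lam_idx]
    return a


def _apply_identifiability(
    coeffs: np.ndarray, eps: np.ndarray, ones_coef: np.ndarray, cfg: SolverConfig,
    flat: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the representative along the flat-model degenerate direction.

    ``coeffs`` (..., k) and ``eps`` (..., n_active) are modified in the
    min-epsilon-zero convention: subtract ``t = min_i eps_i`` from every
    eps and add a constant ``t`` to the volume.  Minimum-norm keeps the
    SVD least-squares representative unchanged.
    """
    if not flat or cfg.identifiability != "min-epsilon-zero":
        return coeffs, eps
    t = eps.min(axis=-1, keepdims=True)
    eps = eps - t
    coeffs = coeffs + t * ones_coef
    return coeffs, eps


def _solve_group(
    y: np.ndarray, a: np.ndarray, n_coef: int, cfg: SolverConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Least-squares solve for many pixels sharing one design matrix.

    ``y``: (n_pixels, n_samples).  Returns (coeffs, eps, residual_rms,
    rank); callers compare the rank against the expected rank to detect a
    design that is singular beyond the flat-model degeneracy.
    """
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    tol = s[0] * max(a.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    s_inv = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0), 0.0)
    theta = (y @ u) * s_inv @ vt  # minimum-norm solution, vectorized
    # residuals in chunks: a frame-sized `y - theta @ a.T` temporary would
    # double the memory footprint
    rms = np.empty(y.shape[0])
    chunk = max(1, int(2e8 // (8 * max(1, y.shape[1]))))
    for lo in range(0, y.shape[0], chunk):
        blk = y[lo:lo + chunk] - theta[lo:lo + chunk] @ a.T
        rms[lo:lo + chunk] = np.sqrt(np.mean(blk**2, axis=-1))
    return theta[:, :n_coef], theta[:, n_coef:], rms, rank


def _solve_iterative(
    y: np.ndarray, a: np.ndarray, n_coef: int, cfg: SolverConfig
) -> np.ndarray:
    """Nonlinear-least-squares path (one pixel), mirroring a generic
    ``lsqnonlin``-style minimizer.  Used for non-flat specular shapes and
    as an independent route to the closed-form solution."""
    from scipy.optimize import least_squares

    n_unknowns = a.shape[1]
    if cfg.epsilon_nonneg:
        lb = np.full(n_unknowns, -np.inf)
        lb[n_coef:] = 0.0
        bounds = (lb, np.inf)
    else:
        bounds = (-np.inf, np.inf)
    # the flat-model design is deliberately rank-deficient; TRF handles it
    # but emits divide-by-zero warnings from its trust-region internals
    with np.errstate(divide="ignore", invalid="ignore"):
        res = least_squares(
            lambda th: a @ th - y,
            x0=np.zeros(n_unknowns),
            jac=lambda th: a,
            bounds=bounds,
            method="trf",
            ftol=cfg.tol,
            xtol=None,
            gtol=None,
            max_nfev=cfg.max_iter,
        )
    return res.x


def decompose_pixel(
    spectra: np.ndarray,
    mask: np.ndarray | None,
    basis: np.ndarray,
    spec_model: SpecularModel,
    cfg: SolverConfig,
    grid: WavelengthGrid | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Decompose one pixel.

    Parameters
    ----------
    spectra : (m_lambda, mi) total reflectance, one column per direction.
    mask : (m_lambda, mi) boolean, True = excluded sample, or None.
    basis : (m_lambda, mp + 1) from :func:`build_basis`.

    Returns
    -------
    (coefficients, eps, residual_rms, status); ``eps`` is NaN for dropped
    directions, everything is NaN when status is failed.
    """
    spectra = np.asarray(spectra, dtype=float)
    m_lambda, n_dirs = spectra.shape
    n_coef = basis.shape[1]
    if mask is None:
        mask = np.zeros_like(spectra, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spectra.shape:
        raise ValueError("mask shape does not match spectra shape")
    spec_shape = (
        spec_model.shape if spec_model.shape is not None else np.ones(m_lambda)
    )
    spec_shape = np.asarray(spec_shape, dtype=float)

    coeffs = np.full(n_coef, np.nan)
    eps = np.full(n_dirs, np.nan)

    # saturation granularity policy: drop a direction wholesale only when
    # most of its bands are gone
    frac_masked = mask.mean(axis=0)
    keep_dir = frac_masked <= cfg.drop_direction_band_fraction
    active_dirs = np.nonzero(keep_dir)[0]
    unmasked = ~mask
    unmasked[:, ~keep_dir] = False

    flat = spec_model.mode == "flat"
    n_unknowns = n_coef + active_dirs.size
    n_samples = int(unmasked.sum())
    if active_dirs.size < 2 or n_samples < n_unknowns:
        return coeffs, eps, float("nan"), STATUS_FAILED

    a = _design_matrix(basis, spec_shape, unmasked, active_dirs)
    y = spectra[unmasked]

    if cfg.solver == "iterative-nonlinear":
        theta = _solve_iterative(y, a, n_coef, cfg)
        c, e = theta[:n_coef], theta[n_coef:]
        resid = y - a @ theta
        rms = float(np.sqrt(np.mean(resid**2)))
    else:
        c2, e2, rms_arr, rank = _solve_group(y[None, :], a, n_coef, cfg)
        expected_rank = n_unknowns - (1 if flat else 0)
        if rank < expected_rank:
            return coeffs, eps, float("nan"), STATUS_FAILED
        c, e, rms = c2[0], e2[0], float(rms_arr[0])

    ones_coef = basis.T @ np.ones(m_lambda) * (spec_shape[0] if flat else 1.0)
    c, e = _apply_identifiability(c, e, ones_coef, cfg, flat)

    coeffs[:] = c
    eps[active_dirs] = e
    degraded = bool(mask.any() or not keep_dir.all())
    return coeffs, eps, rms, STATUS_DEGRADED if degraded else STATUS_OK


@dataclass
class DecompositionResult:
    """Per-pixel output of :func:`decompose_cube`."""

    grid: WavelengthGrid
    coefficients: np.ndarray     # (Y, X, mp + 1)
    epsilon: np.ndarray          # (Y, X, mi); NaN where dropped/failed
    residual_rms: np.ndarray     # (Y, X)
    status: np.ndarray           # (Y, X) uint8
    spec_shape: np.ndarray       # (m_lambda,)
    spec_mode: str
    config: dict

    @property
    def basis(self) -> np.ndarray:
        return build_basis(self.grid, self.coefficients.shape[-1] - 1)

    @property
    def volume(self) -> np.ndarray:
        """Evaluated volume-reflectance cube (Y, X, m_lambda)."""
        return self.coefficients @ self.basis.T

    @property
    def n_directions(self) -> int:
        return self.epsilon.shape[-1]

    @property
    def negative_volume_mask(self) -> np.ndarray:
        """Pixels whose evaluated volume reflectance dips below zero."""
        with np.errstate(invalid="ignore"):
            return (self.volume < 0).any(axis=-1)

    def save(self, directory: str | Path) -> Path:
        """Persist volume cube, epsilon/residual images, status and config."""
        from .io import write_cube, write_mask

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        vol = np.nan_to_num(self.volume, nan=0.0)
        write_cube(
            Hypercube(vol, self.grid, kind=REFLECTANCE),
            directory / "volume.img",
        )
        np.savetxt(directory / "residual_rms.txt", self.residual_rms, fmt="%.10g")
        np.savetxt(directory / "status.txt", self.status, fmt="%d")
        np.save(directory / "coefficients.npy", self.coefficients)
        np.save(directory / "epsilon.npy", self.epsilon)
        for i in range(self.n_directions):
            np.savetxt(
                directory / f"epsilon_dir{i + 1}.txt", self.epsilon[:, :, i],
                fmt="%.10g",
            )
        write_mask(self.status == STATUS_FAILED, directory / "failed_mask.img")
        echo = dict(self.config)
        echo["spec_mode"] = self.spec_mode
        echo["spec_shape"] = [float(v) for v in self.spec_shape]
        echo["wavelengths_nm"] = [float(v) for v in self.grid.values]
        (directory / "config.json").write_text(json.dumps(echo, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "DecompositionResult":
        directory = Path(directory)
        echo = json.loads((directory / "config.json").read_text())
        grid = WavelengthGrid(np.array(echo.pop("wavelengths_nm")))
        spec_shape = np.array(echo.pop("spec_shape"))
        spec_mode = echo.pop("spec_mode")
        status = np.loadtxt(directory / "status.txt", dtype=int)
        status = np.atleast_2d(status).astype(np.uint8)
        return cls(
            grid=grid,
            coefficients=np.load(directory / "coefficients.npy"),
            epsilon=np.load(directory / "epsilon.npy"),
            residual_rms=np.atleast_2d(np.loadtxt(directory / "residual_rms.txt")),
            status=status,
            spec_shape=spec_shape,
            spec_mode=spec_mode,
            config=echo,
        )


def decompose_cube(
    series: IlluminationSeries,
    mask: SaturationMask | None = None,
    spec_model: SpecularModel | None = None,
    cfg: SolverConfig | None = None,
) -> DecompositionResult:
    """Decompose every pixel of a calibrated series.

    Pixels sharing an identical saturation pattern reuse one precomputed
    solve operator, so an unmasked frame reduces to a single matrix
    product; a full push-broom frame decomposes in seconds to minutes on
    one CPU.
    """
    cfg = cfg or SolverConfig()
    spec_model = spec_model or SpecularModel.flat(series.grid)
    for i, cube in enumerate(series.cubes, start=1):
        if cube.kind != REFLECTANCE:
            raise ValueError(
                f"direction {i} cube is {cube.kind!r}; decompose_cube needs "
                "calibrated reflectance cubes"
            )
    grid = series.grid
    basis = build_basis(grid, cfg.poly_order)
    spec_shape = spec_model.on_grid(grid)
    flat = spec_model.mode == "flat"
    ny, nx = series.spatial_shape
    m_lambda, n_dirs = len(grid), series.n_directions
    n_coef = cfg.poly_order + 1
    n_pix = ny * nx
    if mask is not None and mask.band_mask.shape != (ny, nx, m_lambda, n_dirs):
        raise ValueError("saturation mask shape does not match the series")

    coefficients = np.full((n_pix, n_coef), np.nan)
    epsilon = np.full((n_pix, n_dirs), np.nan)
    residual_rms = np.full(n_pix, np.nan)
    status = np.full(n_pix, STATUS_FAILED, dtype=np.uint8)
    ones_coef = basis.T @ np.ones(m_lambda) * (spec_shape[0] if flat else 1.0)

    # process in row blocks so a full push-broom frame never needs a second
    # frame-sized array in memory
    rows_per_block = max(1, int(2.5e7 // max(1, nx * m_lambda * n_dirs)))
    for r0 in range(0, ny, rows_per_block):
        r1 = min(ny, r0 + rows_per_block)
        p0 = r0 * nx
        blk_pix = (r1 - r0) * nx
        data = np.stack(
            [c.data[r0:r1] for c in series.cubes], axis=-1
        ).reshape(blk_pix, m_lambda, n_dirs)
        if mask is None:
            band_mask = np.zeros((blk_pix, m_lambda, n_dirs), dtype=bool)
        else:
            band_mask = mask.band_mask[r0:r1].reshape(blk_pix, m_lambda, n_dirs)

        # group pixels by identical mask pattern; each group shares one
        # precomputed solve operator
        packed = np.packbits(band_mask.reshape(blk_pix, -1), axis=1)
        patterns, inverse = np.unique(packed, axis=0, return_inverse=True)

        for g in range(patterns.shape[0]):
            pix = np.nonzero(inverse == g)[0]
            pmask = band_mask[pix[0]]  # (m_lambda, n_dirs), shared by the group

            frac_masked = pmask.mean(axis=0)
            keep_dir = frac_masked <= cfg.drop_direction_band_fraction
            active_dirs = np.nonzero(keep_dir)[0]
            unmasked = ~pmask
            unmasked[:, ~keep_dir] = False
            n_samples = int(unmasked.sum())
            n_unknowns = n_coef + active_dirs.size
            if active_dirs.size < 2 or n_samples < n_unknowns:
                continue  # stays failed

            if pix.size == blk_pix and not pmask.any():
                y = data.reshape(blk_pix, -1)  # view: avoids copying the block
            else:
                y = data[pix][:, unmasked]  # (n_group, n_samples)
            a = _design_matrix(basis, spec_shape, unmasked, active_dirs)

            if cfg.solver == "iterative-nonlinear":
                c = np.empty((pix.size, n_coef))
                e = np.empty((pix.size, active_dirs.size))
                rms = np.empty(pix.size)
                for j in range(pix.size):
                    theta = _solve_iterative(y[j], a, n_coef, cfg)
                    c[j], e[j] = theta[:n_coef], theta[n_coef:]
                    rms[j] = np.sqrt(np.mean((y[j] - a @ theta) ** 2))
            else:
                c, e, rms, rank = _solve_group(y, a, n_coef, cfg)
                if rank < n_unknowns - (1 if flat else 0):
                    continue  # singular beyond the expected degeneracy

            c, e = _apply_identifiability(c, e, ones_coef, cfg, flat)
            coefficients[p0 + pix] = c
            epsilon[np.ix_(p0 + pix, active_dirs)] = e
            residual_rms[p0 + pix] = rms
            degraded = bool(pmask.any() or not keep_dir.all())
            status[p0 + pix] = STATUS_DEGRADED if degraded else STATUS_OK

    result = DecompositionResult(
        grid=grid,
        coefficients=coefficients.reshape(ny, nx, n_coef),
        epsilon=epsilon.reshape(ny, nx, n_dirs),
        residual_rms=residual_rms.reshape(ny, nx),
        status=status.reshape(ny, nx),
        spec_shape=spec_shape,
        spec_mode=spec_model.mode,
        config=cfg.echo(),
    )
    n_neg = int(result.negative_volume_mask.sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} pixels have negative evaluated volume reflectance "
            "(not constrained by default); inspect residual_rms there",
            stacklevel=2,
        )
    return result


def corrected_reflectance(
    series: IlluminationSeries, result: DecompositionResult
) -> np.ndarray:
    """Glare-corrected spectra ``R_tot - eps_i * R_spec``.

    Returns an array of shape (Y, X, m_lambda, directions); NaN at failed
    pixels and dropped directions.  At noiseless pixels all directions
    collapse onto the volume spectrum.
    """
    data = series.stack()
    if data.shape[:2] != result.status.shape or data.shape[3] != result.n_directions:
        raise ValueError("series does not match the decomposition result")
    corr = data - result.epsilon[:, :, None, :] * result.spec_shape[None, None, :, None]
    corr[result.status == STATUS_FAILED] = np.nan
    return corr


def snv_normalize(spectra: np.ndarray, axis: int = -1) -> np.ndarray:
    """Standard-normal-variate transform: per-spectrum mean 0, std 1.

    Uses the sample-std convention (ddof=1).  SNV removes baseline offsets
    and amplitude, which is exactly why it is only a comparison baseline
    here: the decomposition keeps amplitude/scattering information, SNV
    destroys it.
    """
    spectra = np.asarray(spectra, dtype=float)
    mean = spectra.mean(axis=axis, keepdims=True)
    std = spectra.std(axis=axis, ddof=1, keepdims=True)
    if np.any(std == 0):
        raise ValueError("SNV is undefined for constant spectra (zero std)")
    return (spectra - mean) / std
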