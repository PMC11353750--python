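"""Per-pixel solver: basis, Fresnel, recovery, degeneracy and SNV."""

import numpy as np
import pytest

import deglare as dg
from deglare.decomposition import STATUS_DEGRADED, STATUS_FAILED, STATUS_OK

from conftest import make_series


def flat_model(grid):
    return dg.SpecularModel.flat(grid)


def objective(y, basis, coeffs, eps, spec_shape=None):
    spec = np.ones(y.shape[0]) if spec_shape is None else spec_shape
    model = (basis @ coeffs)[:, None] + eps[None, :] * spec[:, None]
    return float(((y - model) ** 2).sum())


class TestBasis:
    def test_order_zero_is_constant(self, grid134):
        b = dg.build_basis(grid134, 0)
        assert b.shape == (134, 1)
        assert np.ptp(b[:, 0]) == 0

    def test_columns_orthonormal(self, grid134):
        b = dg.build_basis(grid134, 6)
        gram = b.T @ b
        assert np.abs(gram - np.eye(7)).max() <= 1e-10

    def test_complete_basis_is_square_full_rank(self, small_grid):
        b = dg.build_basis(small_grid, len(small_grid) - 1)
        assert b.shape == (4, 4)
        assert np.linalg.matrix_rank(b) == 4

    def test_too_high_order_rejected(self, small_grid):
        with pytest.raises(ValueError):
            dg.build_basis(small_grid, len(small_grid))


class TestFresnel:
    def test_index_matched_gives_zero(self):
        n = np.full(5, 1.4)
        np.testing.assert_array_equal(dg.fresnel_normal(n, n), 0.0)

    def test_glass_air_value(self):
        r = dg.fresnel_normal(np.array([1.5]), np.array([1.0]))
        assert r[0] == pytest.approx(0.04)

    def test_water_air_value(self):
        r = dg.fresnel_normal(np.array([1.33]), np.array([1.0]))
        assert r[0] == pytest.approx((0.33 / 2.33) ** 2)
        assert r[0] == pytest.approx(0.02006, abs=5e-6)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dg.fresnel_normal(np.ones(3), np.ones(4))

    def test_specular_model_peak_normalized(self, small_grid):
        n_s = np.array([1.33, 1.4, 1.45, 1.5])
        model = dg.SpecularModel.from_refractive_index(small_grid, n_s, np.ones(4))
        assert model.shape.max() == pytest.approx(1.0)
        assert model.mode == "fresnel-derived"


class TestDecomposePixel:
    def test_identical_spectra_give_zero_glare(self, grid134):
        basis = dg.build_basis(grid134, 6)
        spectrum = 0.4 + 0.1 * basis[:, 1]
        spectra = np.tile(spectrum[:, None], (1, 3))
        c, e, rms, st = dg.decompose_pixel(
            spectra, None, basis, flat_model(grid134), dg.SolverConfig()
        )
        assert st == STATUS_OK
        np.testing.assert_allclose(e, 0.0, atol=1e-12)
        np.testing.assert_allclose(basis @ c, spectrum, atol=1e-12)

    def test_exact_recovery_of_polynomial_and_glare(self, grid134):
        """Noiseless model data with min-eps = 0 is recovered exactly."""
        basis = dg.build_basis(grid134, 6)
        rng = np.random.default_rng(4)
        coeffs = rng.normal(0, 0.3, 7)
        true_eps = np.array([0.0, 0.1, 0.3])
        spectra = (basis @ coeffs)[:, None] + true_eps[None, :]
        c, e, rms, st = dg.decompose_pixel(
            spectra, None, basis, flat_model(grid134), dg.SolverConfig()
        )
        np.testing.assert_allclose(c, coeffs, atol=1e-10)
        np.testing.assert_allclose(e, true_eps, atol=1e-10)
        assert rms <= 1e-12

    def test_three_bands_three_directions_exact_solution(self):
        """With 3 bands, 3 directions and a quadratic volume, the system is
        exactly determined after resolving the shift degeneracy."""
        grid = dg.WavelengthGrid(np.array([500.0, 700.0, 900.0]))
        basis = dg.build_basis(grid, 2)
        coeffs = np.array([1.0, 0.3, -0.2])
        true_eps = np.array([0.0, 0.2, 0.5])
        spectra = (basis @ coeffs)[:, None] + true_eps[None, :]
        cfg = dg.SolverConfig(poly_order=2)
        c, e, rms, st = dg.decompose_pixel(spectra, None, basis, flat_model(grid), cfg)
        assert rms == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(e, true_eps, atol=1e-10)

    def test_insufficient_samples_fail(self, small_grid):
        basis = dg.build_basis(small_grid, 3)
        spectra = np.ones((4, 2))
        mask = np.ones((4, 2), dtype=bool)
        mask[:2, 0] = False  # only 2 unmasked samples for 6 unknowns
        c, e, rms, st = dg.decompose_pixel(
            spectra, mask, basis, flat_model(small_grid), dg.SolverConfig(poly_order=3)
        )
        assert st == STATUS_FAILED
        assert np.all(np.isnan(c)) and np.all(np.isnan(e))

    def test_mostly_saturated_direction_dropped(self, grid134):
        basis = dg.build_basis(grid134, 4)
        rng = np.random.default_rng(9)
        coeffs = rng.normal(0, 0.2, 5)
        true_eps = np.array([0.0, 0.05, 0.2])
        spectra = (basis @ coeffs)[:, None] + true_eps[None, :]
        mask = np.zeros((134, 3), dtype=bool)
        mask[:, 1] = True  # direction 2 wholly saturated
        cfg = dg.SolverConfig(poly_order=4)
        c, e, rms, st = dg.decompose_pixel(spectra, mask, basis, flat_model(grid134), cfg)
        assert st == STATUS_DEGRADED
        assert np.isnan(e[1])
        np.testing.assert_allclose(e[[0, 2]], true_eps[[0, 2]], atol=1e-10)

    def test_residual_optimality_under_perturbation(self, grid134):
        """No +/- delta perturbation of the solution decreases the objective."""
        basis = dg.build_basis(grid134, 5)
        rng = np.random.default_rng(12)
        y = 0.4 + rng.normal(0, 0.01, (134, 3))
        c, e, rms, st = dg.decompose_pixel(
            y, None, basis, flat_model(grid134), dg.SolverConfig(poly_order=5)
        )
        base = objective(y, basis, c, e)
        delta = 1e-4
        for k in range(c.size):
            for sign in (+1, -1):
                cp = c.copy(); cp[k] += sign * delta
                assert objective(y, basis, cp, e) >= base - 1e-12
        for i in range(e.size):
            for sign in (+1, -1):
                ep = e.copy(); ep[i] += sign * delta
                assert objective(y, basis, c, ep) >= base - 1e-12

    def test_degeneracy_shift_leaves_objective_unchanged(self, grid134):
        basis = dg.build_basis(grid134, 6)
        rng = np.random.default_rng(13)
        y = 0.4 + rng.normal(0, 0.01, (134, 3))
        c, e, rms, st = dg.decompose_pixel(
            y, None, basis, flat_model(grid134), dg.SolverConfig()
        )
        ones_coef = basis.T @ np.ones(134)
        for t in (0.05, -0.3, 1.0):
            shifted = objective(y, basis, c + t * ones_coef, e - t)
            assert shifted == pytest.approx(objective(y, basis, c, e), abs=1e-12)
        assert e.min() == pytest.approx(0.0, abs=1e-10)

    def test_minimum_norm_changes_eps_but_not_residual(self, grid134):
        basis = dg.build_basis(grid134, 6)
        rng = np.random.default_rng(14)
        y = 0.4 + np.array([0.0, 0.1, 0.2])[None, :] + rng.normal(0, 0.005, (134, 3))
        c1, e1, rms1, _ = dg.decompose_pixel(
            y, None, basis, flat_model(grid134), dg.SolverConfig()
        )
        c2, e2, rms2, _ = dg.decompose_pixel(
            y, None, basis, flat_model(grid134),
            dg.SolverConfig(identifiability="minimum-norm", epsilon_nonneg=False),
        )
        assert rms1 == pytest.approx(rms2, abs=1e-12)
        assert np.abs(e1 - e2).max() > 1e-6  # different representative
        # same representative after re-shifting
        np.testing.assert_allclose(e2 - e2.min(), e1, atol=1e-9)

    def test_iterative_path_matches_closed_form(self, grid134):
        basis = dg.build_basis(grid134, 6)
        rng = np.random.default_rng(15)
        worst = 0.0
        for _ in range(25):
            coeffs = rng.normal(0, 0.2, 7); coeffs[0] += 3.0
            eps = np.maximum(0.0, rng.normal(0, 0.05, 3))
            y = (basis @ coeffs)[:, None] + eps[None, :] + rng.normal(0, 0.005, (134, 3))
            c1, e1, _, _ = dg.decompose_pixel(
                y, None, basis, flat_model(grid134), dg.SolverConfig()
            )
            c2, e2, _, _ = dg.decompose_pixel(
                y, None, basis, flat_model(grid134),
                dg.SolverConfig(solver="iterative-nonlinear"),
            )
            worst = max(worst, np.abs(np.r_[c1 - c2, e1 - e2]).max())
        assert worst <= 1e-8

    def test_nonflat_specular_shape_recovered(self, small_grid):
        """A non-flat (Fresnel-derived) shape removes the degeneracy."""
        shape = np.array([1.0, 0.9, 0.8, 0.7])
        model = dg.SpecularModel(mode="fresnel-derived", shape=shape)
        basis = dg.build_basis(small_grid, 1)
        coeffs = np.array([0.8, -0.1])
        true_eps = np.array([0.02, 0.0, 0.1])
        y = (basis @ coeffs)[:, None] + true_eps[None, :] * shape[:, None]
        cfg = dg.SolverConfig(poly_order=1, solver="iterative-nonlinear")
        c, e, rms, st = dg.decompose_pixel(y, None, basis, model, cfg)
        np.testing.assert_allclose(e, true_eps, atol=1e-8)
        np.testing.assert_allclose(c, coeffs, atol=1e-8)


class TestDecomposeCube:
    def test_monotone_masking_robustness(self, small_grid):
        """Extra masking elsewhere never changes unaffected pixels."""
        rng = np.random.default_rng(21)
        vol = rng.uniform(0.3, 0.6, 4)
        eps = np.maximum(0, rng.normal(0, 0.05, (5, 5, 3)))
        eps -= eps.min(axis=-1, keepdims=True)
        data = vol[None, None, :, None] + eps[:, :, None, :]
        series = make_series([data[:, :, :, i] for i in range(3)], small_grid)
        cfg = dg.SolverConfig(poly_order=1)
        res1 = dg.decompose_cube(series, cfg=cfg)
        bm = np.zeros((5, 5, 4, 3), dtype=bool)
        bm[4, 4, 0, 0] = True
        mask = dg.SaturationMask(bm, bm.any(axis=2), 4000.0)
        res2 = dg.decompose_cube(series, mask=mask, cfg=cfg)
        np.testing.assert_array_equal(res1.epsilon[:4], res2.epsilon[:4])
        np.testing.assert_array_equal(res1.coefficients[:4], res2.coefficients[:4])
        assert res2.status[4, 4] == STATUS_DEGRADED

    def test_requires_reflectance_kind(self, small_grid):
        series = make_series([np.ones((2, 2, 4))] * 3, small_grid, "raw-counts")
        with pytest.raises(ValueError, match="reflectance"):
            dg.decompose_cube(series)

    def test_corrected_collapses_across_directions_noiseless(self, small_grid):
        rng = np.random.default_rng(22)
        vol = rng.uniform(0.3, 0.6, 4)
        eps = np.maximum(0, rng.normal(0, 0.08, (6, 6, 3)))
        eps -= eps.min(axis=-1, keepdims=True)
        data = vol[None, None, :, None] + eps[:, :, None, :]
        series = make_series([data[:, :, :, i] for i in range(3)], small_grid)
        res = dg.decompose_cube(series, cfg=dg.SolverConfig(poly_order=1))
        corr = dg.corrected_reflectance(series, res)
        spread = np.ptp(corr, axis=-1)
        assert spread.max() <= 1e-10

    def test_zero_glare_leaves_input_unchanged(self, small_grid):
        vol = np.array([0.3, 0.4, 0.45, 0.5])
        data = np.tile(vol, (4, 4, 1))
        series = make_series([data] * 3, small_grid)
        res = dg.decompose_cube(series, cfg=dg.SolverConfig(poly_order=2))
        corr = dg.corrected_reflectance(series, res)
        np.testing.assert_allclose(corr, series.stack(), atol=1e-10)

    def test_save_load_roundtrip(self, tmp_path, small_grid):
        rng = np.random.default_rng(23)
        data = 0.4 + rng.normal(0, 0.01, (3, 3, 4, 3))
        series = make_series([data[:, :, :, i] for i in range(3)], small_grid)
        res = dg.decompose_cube(series, cfg=dg.SolverConfig(poly_order=1))
        res.save(tmp_path / "out")
        back = dg.DecompositionResult.load(tmp_path / "out")
        np.testing.assert_array_equal(back.coefficients, res.coefficients)
        np.testing.assert_array_equal(back.epsilon, res.epsilon)
        np.testing.assert_array_equal(back.status, res.status)
        assert back.grid == res.grid
        np.testing.assert_allclose(back.volume, res.volume)


class TestSnv:
    def test_output_mean_zero_std_one(self):
        rng = np.random.default_rng(31)
        x = rng.random((10, 50))
        out = dg.snv_normalize(x)
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=-1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(32)
        x = rng.random(40)
        np.testing.assert_allclose(
            dg.snv_normalize(3.2 * x + 0.7), dg.snv_normalize(x), atol=1e-10
        )

    def test_three_point_example(self):
        np.testing.assert_allclose(
            dg.snv_normalize(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0]
        )

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError):
            dg.snv_normalize(np.full(10, 0.5))
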