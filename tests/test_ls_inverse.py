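"""Least-squares inverse solver: design matrix, solve, experiments."""

import numpy as np
import pytest

from turinverse.ls_inverse import (IdentifiabilityError, build_design,
                                   crop_experiment, min_pixels, mix_models,
                                   noise_sweep, power_law_slope,
                                   random_pixel_sweep, solve_ls,
                                   solve_normal_equations)
from turinverse.models import NotNondimensionalError, get_model
from turinverse.simulate import Pattern

from conftest import MODEL_CASES


class TestDesignMatrix:
    def test_schnakenberg_row_layout(self):
        """Hand-checked rows for u=1, v=2, Lap(u)=0.5, Lap(v)=-0.25."""
        m = get_model("schnakenberg_nd")
        A_u, b_u, A_v, b_v = m.linear_terms(
            np.array([1.0]), np.array([2.0]), np.array([0.5]),
            np.array([-0.25]))
        np.testing.assert_allclose(A_u[:, 0], [1.0, 2.0, 0.0, 0.0])
        assert -b_u[0] == pytest.approx(0.5)          # y = u - Lap(u)
        np.testing.assert_allclose(A_v[:, 0], [0.0, -2.0, 1.0, -0.25])
        assert b_v[0] == 0.0

    def test_two_pixel_matrix_structure(self, schnak_pattern):
        prob = build_design("schnakenberg_nd", schnak_pattern,
                            [(10, 10), (30, 17)])
        X = prob.X
        assert X.shape == (4, 4)
        # u-rows: [1, a, 0, 0]; v-rows: [0, -a, 1, lap_v]
        np.testing.assert_allclose(X[:2, 0], 1.0)
        np.testing.assert_allclose(X[:2, 2:], 0.0)
        np.testing.assert_allclose(X[2:, 0], 0.0)
        np.testing.assert_allclose(X[2:, 1], -X[:2, 1])
        np.testing.assert_allclose(X[2:, 2], 1.0)

    def test_full_grid_row_count(self, schnak_pattern):
        prob = build_design("schnakenberg_nd", schnak_pattern)
        assert prob.X.shape == (5000, 4)
        assert len(prob.y) == 5000

    def test_dimensional_model_rejected(self, schnak_pattern):
        with pytest.raises(NotNondimensionalError):
            build_design("schnakenberg", schnak_pattern)

    def test_out_of_range_pixel(self, schnak_pattern):
        with pytest.raises(IndexError):
            build_design("schnakenberg_nd", schnak_pattern, [(60, 0)])


class TestSolve:
    @pytest.mark.parametrize("name", list(MODEL_CASES))
    def test_noise_free_exact_recovery(self, name, pattern_bank):
        """Full-pixel LS on a converged pattern returns the generating
        parameters to numerical precision for every built-in model."""
        pattern = pattern_bank[name]
        res = solve_ls(build_design(name, pattern))
        assert res.mean_rel_err(pattern.meta["beta"]) <= 1e-12
        assert res.rank == get_model(name).n_params

    def test_consistent_system_recovers_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        beta0 = rng.normal(size=5)
        prob_like = type("P", (), {"X": X, "y": X @ beta0})
        res = solve_ls(prob_like)
        np.testing.assert_allclose(res.beta_hat, beta0, rtol=1e-12)

    def test_rank_deficiency_warns_and_returns_min_norm(self):
        # constant grids: every pixel identical -> duplicate rows (a = b)
        p = Pattern(u=np.full((8, 8), 1.3), v=np.full((8, 8), 0.7), dx=1.0)
        prob = build_design("schnakenberg_nd", p, [(2, 2), (5, 5)])
        with pytest.warns(RuntimeWarning, match="rank"):
            res = solve_ls(prob)
        assert res.rank < 4
        assert np.all(np.isfinite(res.beta_hat))

    def test_normal_equations_cross_check(self, schnak_pattern):
        prob = build_design("schnakenberg_nd", schnak_pattern)
        svd = solve_ls(prob).beta_hat
        ne = solve_normal_equations(prob)
        np.testing.assert_allclose(ne, svd, rtol=1e-8)

    def test_pixel_permutation_invariance(self, schnak_pattern):
        rng = np.random.default_rng(1)
        n = schnak_pattern.n
        pix = [(int(i), int(j)) for i, j in rng.integers(0, n, (200, 2))]
        a = solve_ls(build_design("schnakenberg_nd", schnak_pattern, pix))
        perm = rng.permutation(len(pix))
        b = solve_ls(build_design("schnakenberg_nd", schnak_pattern,
                                  [pix[k] for k in perm]))
        np.testing.assert_allclose(a.beta_hat, b.beta_hat, rtol=1e-9)

    def test_empty_problem_rejected(self, schnak_pattern):
        prob = build_design("schnakenberg_nd", schnak_pattern, [])
        with pytest.raises(ValueError):
            solve_ls(prob)


class TestMinPixels:
    @pytest.mark.parametrize("name,expected", [
        ("schnakenberg_nd", 2),
        ("brusselator_nd", 2),
        ("fitzhugh_nagumo_nd", 3),
    ])
    def test_model_dependent_minimum(self, name, expected, pattern_bank):
        assert min_pixels(name, pattern_bank[name], seed=0) == expected

    def test_rank_law_below_minimum(self, fhn_pattern):
        """With 2 pixels the FHN design has rank 3 < 4: the two u-equation
        rows are collinear (both only carry the c1 column)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            pix = [tuple(x) for x in rng.integers(0, 50, (2, 2))]
            prob = build_design("fitzhugh_nagumo_nd", fhn_pattern, pix)
            assert np.linalg.matrix_rank(prob.X) == 3


class TestCrop:
    def test_small_window_matches_full_estimate(self, fhn_pattern):
        full = solve_ls(build_design("fitzhugh_nagumo_nd", fhn_pattern))
        crop = crop_experiment("fitzhugh_nagumo_nd", fhn_pattern, (20, 20, 4))
        rel = np.abs(crop.beta_hat - full.beta_hat) / np.abs(full.beta_hat)
        assert np.max(rel) <= 1e-6

    def test_full_grid_window_equals_all_pixels(self, schnak_pattern):
        full = solve_ls(build_design("schnakenberg_nd", schnak_pattern))
        win = crop_experiment("schnakenberg_nd", schnak_pattern, (0, 0, 50))
        np.testing.assert_allclose(win.beta_hat, full.beta_hat, rtol=1e-12)

    def test_single_pixel_window_not_identifiable(self, schnak_pattern):
        with pytest.raises(IdentifiabilityError):
            crop_experiment("schnakenberg_nd", schnak_pattern, (10, 10, 1))

    def test_window_laplacian_variant_close_on_interior(self, schnak_pattern):
        res = crop_experiment("schnakenberg_nd", schnak_pattern, (15, 15, 8),
                              laplacian_source="window")
        truth = np.asarray(schnak_pattern.meta["beta"])
        # interior pixels of the window carry true neighbor information
        assert res.mean_rel_err(truth) <= 1e-9


class TestSweeps:
    def test_power_law_slope_on_synthetic_table(self):
        import pandas as pd
        ns = np.array([10, 100, 1000])
        rows = [{"n_pixels": n, "rep": r, "mean_rel_err": 2.0 * n ** -0.5}
                for n in ns for r in range(3)]
        assert power_law_slope(pd.DataFrame(rows)) == pytest.approx(-0.5)

    def test_noise_free_subsets_stay_at_numerical_precision(self,
                                                            schnak_pattern):
        tab = random_pixel_sweep("schnakenberg_nd", schnak_pattern,
                                 ns=[10, 100], reps=3, seed=0)
        assert tab.mean_rel_err.max() < 1e-9

    def test_zero_noise_sweep_matches_exact_solve(self, schnak_pattern):
        tab = noise_sweep("schnakenberg_nd", schnak_pattern, [0.0], reps=2,
                          seed=0)
        assert tab.mean_rel_err.max() <= 1e-12

    def test_noise_increases_error(self, schnak_pattern):
        tab = noise_sweep("schnakenberg_nd", schnak_pattern, [0.0, 0.5],
                          reps=3, seed=1)
        g = tab.groupby("s").mean_rel_err.mean()
        assert g[0.5] > 100 * g[0.0]


class TestMixing:
    def test_degenerate_mixing_recovers_parameters(self, schnak_pattern):
        res, label, _ = mix_models(schnak_pattern, "schnakenberg_nd",
                                   with_resimulation=False)
        assert res.mean_rel_err(schnak_pattern.meta["beta"]) <= 1e-12
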