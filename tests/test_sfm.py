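"""Sparse fascicle model: design matrix, Elastic Net solver, peaks and
summary statistics."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet

from dwieval import (
    CanonicalKernel,
    FascicleBasis,
    GradientTable,
    SfmFit,
    angular_difference,
    build_design_matrix,
    dispersion_index,
    extract_peaks,
    fascicle_anisotropy,
    fit_sfm,
    grid_search_hyperparameters,
    predict_relative_signal,
    predict_sfm,
    rotate_kernel,
    solve_elastic_net,
)
from dwieval.core import pairwise_axial_angles
from dwieval.sfm import DesignMatrix


def en_objective(x, s, b, lam, alpha):
    """Elastic Net objective in the ridge-at-alpha=1 convention."""
    return float(
        ((s - x @ b) ** 2).sum() + lam * (alpha * b**2 + (1 - alpha) * np.abs(b)).sum()
    )


class TestDesignMatrix:
    def test_isotropic_kernel_gives_zero_matrix(self, gtab150):
        basis = FascicleBasis(
            np.eye(3), CanonicalKernel(1e-3, 1e-3), 2000.0
        )
        d = build_design_matrix(basis, gtab150)
        assert np.abs(d.x).max() < 1e-15

    def test_columns_exactly_zero_mean(self, basis100, gtab150):
        d = build_design_matrix(basis100, gtab150)
        assert np.abs(d.x.mean(axis=0)).max() < 1e-12

    def test_single_fascicle_column_extremum_at_direction(self, kernel, gtab150):
        # the fascicle response is smallest along the fascicle (axial
        # diffusivity is largest), so the fOM column minimum sits at the
        # rows nearest the fascicle direction
        d0 = np.array([0.0, 0.0, 1.0])
        basis = FascicleBasis(d0[None, :], kernel, 2000.0)
        d = build_design_matrix(basis, gtab150)
        ang = pairwise_axial_angles(gtab150.bvecs, d0[None, :]).ravel()
        assert ang[np.argmin(d.x[:, 0])] == pytest.approx(ang.min(), abs=1e-9)
        assert ang[np.argmax(d.x[:, 0])] == pytest.approx(ang.max(), abs=1e-9)

    def test_mixed_bvalues_rejected(self, basis100):
        g = GradientTable([[1, 0, 0], [0, 1, 0]], [1000.0, 2000.0])
        with pytest.raises(ValueError, match="single"):
            build_design_matrix(basis100, g)

    def test_antipodal_duplicates_removed(self, kernel):
        basis = FascicleBasis(
            np.array([[0, 0, 1.0], [0, 0, -1.0], [1.0, 0, 0]]), kernel, 2000.0
        )
        assert len(basis) == 2


class TestSolver:
    def test_unpenalized_limit_matches_pseudo_inverse(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((12, 4))
        s = rng.standard_normal(12)
        b = solve_elastic_net(x, s, 0.0, 0.0, nonneg=False, tol=1e-11)
        assert np.abs(b - np.linalg.pinv(x) @ s).max() < 1e-8

    def test_huge_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 3))
        s = rng.standard_normal(10)
        assert np.all(solve_elastic_net(x, s, 1e9, 0.3, nonneg=False) == 0.0)

    def test_single_column_soft_threshold_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 1))
        s = rng.standard_normal(12)
        lam = 0.5
        b = solve_elastic_net(x, s, lam, 0.0, nonneg=False)
        rho = float(x[:, 0] @ s)
        closed = np.sign(rho) * max(abs(rho) - lam / 2, 0.0) / float(x[:, 0] @ x[:, 0])
        assert b[0] == pytest.approx(closed, abs=1e-10)
        # dense grid over beta confirms the closed form is the optimum
        grid = np.linspace(closed - 1, closed + 1, 20001)
        objs = ((s[:, None] - x * grid[None, :]) ** 2).sum(0) + lam * np.abs(grid)
        assert abs(grid[np.argmin(objs)] - closed) < 2e-4

    def test_ridge_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((15, 5))
        s = rng.standard_normal(15)
        lam = 0.7
        b = solve_elastic_net(x, s, lam, 1.0, nonneg=False)
        closed = np.linalg.solve(x.T @ x + lam * np.eye(5), x.T @ s)
        assert np.abs(b - closed).max() < 1e-8

    def test_alpha_convention_maps_to_sklearn(self):
        """alpha = 1 is ridge here (the reverse of sklearn's l1_ratio):
        solutions match sklearn under the documented parameter mapping."""
        rng = np.random.default_rng(4)
        n, f = 40, 6
        x = rng.standard_normal((n, f))
        s = rng.standard_normal(n)
        for lam, alpha in [(0.8, 0.2), (0.5, 0.7), (1.2, 0.0)]:
            ours = solve_elastic_net(x, s, lam, alpha, nonneg=True)
            a_l1 = lam * (1 - alpha) / (2 * n)
            a_l2 = lam * alpha / n
            sk = ElasticNet(
                alpha=a_l1 + a_l2,
                l1_ratio=a_l1 / (a_l1 + a_l2) if a_l1 + a_l2 > 0 else 0.0,
                fit_intercept=False,
                positive=True,
                tol=1e-12,
                max_iter=100000,
            ).fit(x, s)
            assert np.abs(ours - sk.coef_).max() < 1e-6

    def test_invalid_parameters_rejected(self):
        x = np.ones((4, 2))
        s = np.ones(4)
        with pytest.raises(ValueError):
            solve_elastic_net(x, s, -1.0, 0.5)
        with pytest.raises(ValueError):
            solve_elastic_net(x, s, 1.0, 1.5)

    def test_objective_beats_random_candidates(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t, f = rng.integers(6, 13), rng.integers(1, 5)
            x = rng.standard_normal((t, f))
            s = rng.standard_normal(t)
            lam = float(rng.uniform(0, 2))
            alpha = float(rng.uniform(0, 1))
            b = solve_elastic_net(x, s, lam, alpha, nonneg=True)
            ours = en_objective(x, s, b, lam, alpha)
            cands = np.abs(rng.standard_normal((20000, f)))
            objs = ((s[None, :] - cands @ x.T) ** 2).sum(1) + lam * (
                alpha * cands**2 + (1 - alpha) * np.abs(cands)
            ).sum(1)
            assert ours <= objs.min() + 1e-8


class TestFitPredict:
    def test_isotropic_signal_gives_zero_weights(self, basis100, gtab150):
        fit = fit_sfm(np.full(150, 0.31), gtab150, basis100)
        assert np.all(fit.weights == 0.0)
        assert fit.mean_signal == pytest.approx(0.31)
        assert np.allclose(predict_sfm(fit, gtab150), 0.31)

    def test_exact_basis_single_fascicle_recovery(self, basis100, kernel, gtab150):
        d0 = basis100.directions[37]
        s = predict_relative_signal(rotate_kernel(kernel, d0), gtab150)
        fit = fit_sfm(s, gtab150, basis100, lam=1e-6, alpha=0.2)
        peaks = extract_peaks(fit)
        assert angular_difference(peaks[0][0], d0) == pytest.approx(0.0, abs=1e-9)
        ang = pairwise_axial_angles(basis100.directions, d0[None, :]).ravel()
        assert fit.weights[ang < 5].sum() / fit.weights.sum() > 0.99
        # round-trip within solver tolerance
        assert np.abs(predict_sfm(fit, gtab150) - s).max() < 1e-4

    def test_orthogonal_crossing_recovery(self, basis100, kernel, gtab150):
        t1 = np.array([1.0, 0.0, 0.0])
        t2 = np.array([0.0, 0.0, 1.0])
        s = 0.5 * predict_relative_signal(rotate_kernel(kernel, t1), gtab150)
        s += 0.5 * predict_relative_signal(rotate_kernel(kernel, t2), gtab150)
        fit = fit_sfm(s, gtab150, basis100, lam=1e-6, alpha=0.2)
        peaks = extract_peaks(fit)
        assert len(peaks) >= 2
        errs = sorted(
            min(angular_difference(p, t) for p in (peaks[0][0], peaks[1][0]))
            for t in (t1, t2)
        )
        # recovered within the ~15 degree resolution of the 100-point basis
        assert errs[1] < 15.0

    def test_prediction_mean_equals_mean_signal(self, basis100, gtab150, kernel):
        d0 = basis100.directions[5]
        s = predict_relative_signal(rotate_kernel(kernel, d0), gtab150)
        fit = fit_sfm(s, gtab150, basis100)
        pred = predict_sfm(fit, gtab150)
        assert pred.mean() == pytest.approx(fit.mean_signal, abs=1e-10)

    def test_bvalue_mismatch_rejected(self, basis100):
        g = GradientTable(np.eye(3), np.full(3, 1000.0))
        fit = SfmFit(np.zeros(len(basis100)), 0.3, basis100, 1e-4, 0.2)
        with pytest.raises(ValueError):
            predict_sfm(fit, g)


def _manual_fit(directions, weights, kernel, mean_signal=0.4):
    basis = FascicleBasis(np.asarray(directions, float), kernel, 2000.0)
    return SfmFit(np.asarray(weights, float), mean_signal, basis, 1e-4, 0.2)


class TestPeaks:
    def test_single_weight_single_peak(self, kernel):
        fit = _manual_fit(np.eye(3), [0.0, 0.7, 0.0], kernel)
        peaks = extract_peaks(fit)
        assert len(peaks) == 1
        assert peaks[0][1] == 0.7

    def test_two_equal_weights_90_apart(self, kernel):
        fit = _manual_fit([[1, 0, 0], [0, 0, 1]], [0.5, 0.5], kernel)
        assert len(extract_peaks(fit)) == 2

    def test_relative_threshold(self, kernel):
        dirs = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        fit = _manual_fit(dirs, [1.0, 0.9, 0.05], kernel)
        assert len(extract_peaks(fit, relative_threshold=0.1)) == 2

    def test_all_zero_weights_empty(self, kernel):
        fit = _manual_fit(np.eye(3), [0.0, 0.0, 0.0], kernel)
        assert extract_peaks(fit) == []


class TestSummaryStatistics:
    def test_fascicle_anisotropy_values(self, kernel):
        assert fascicle_anisotropy(_manual_fit(np.eye(3), [0, 0, 0], kernel)) == 0.0
        fit = _manual_fit(np.eye(3), [0.1, 0.06, 0.04], kernel, mean_signal=0.4)
        assert fascicle_anisotropy(fit) == pytest.approx(0.5)
        doubled = _manual_fit(np.eye(3), [0.2, 0.12, 0.08], kernel, mean_signal=0.4)
        assert fascicle_anisotropy(doubled) == pytest.approx(1.0)

    def test_fascicle_anisotropy_needs_positive_mean(self, kernel):
        with pytest.raises(ValueError):
            fascicle_anisotropy(_manual_fit(np.eye(3), [0.1, 0, 0], kernel, 0.0))

    def test_dispersion_index_single_fascicle(self, kernel):
        assert dispersion_index(_manual_fit(np.eye(3), [0, 0.5, 0], kernel)) == 0.0

    def test_dispersion_index_two_equal_90(self, kernel):
        fit = _manual_fit([[1, 0, 0], [0, 0, 1]], [0.5, 0.5], kernel)
        assert dispersion_index(fit) == pytest.approx(0.5, abs=1e-12)

    def test_dispersion_index_two_equal_30(self, kernel):
        a = np.radians(30.0)
        fit = _manual_fit(
            [[0, 0, 1], [np.sin(a), 0, np.cos(a)]], [0.5, 0.5], kernel
        )
        assert dispersion_index(fit, min_separation_deg=20) == pytest.approx(
            0.25, abs=1e-9
        )

    def test_dispersion_index_requires_nonzero_weight(self, kernel):
        with pytest.raises(ValueError):
            dispersion_index(_manual_fit(np.eye(3), [0, 0, 0], kernel))


class TestGridSearch:
    def test_single_cell_grid(self, basis100, gtab150, kernel):
        rng = np.random.default_rng(0)
        clean = predict_relative_signal(
            rotate_kernel(kernel, basis100.directions[0]), gtab150
        )
        d1 = clean + rng.normal(0, 0.02, (3, 150))
        d2 = clean + rng.normal(0, 0.02, (3, 150))
        lam, alpha, surface = grid_search_hyperparameters(
            d1, d2, gtab150, basis100, [5e-4], [0.2]
        )
        assert (lam, alpha) == (5e-4, 0.2)
        assert surface.shape == (1, 1)

    def test_heavier_noise_prefers_more_regularization(self, basis100, gtab150, kernel):
        rng = np.random.default_rng(1)
        clean = predict_relative_signal(
            rotate_kernel(kernel, basis100.directions[10]), gtab150
        )
        grid_l = [1e-5, 3e-2]
        chosen = {}
        for label, sigma in [("low", 0.002), ("high", 0.08)]:
            d1 = np.maximum(clean + rng.normal(0, sigma, (4, 150)), 0)
            d2 = np.maximum(clean + rng.normal(0, sigma, (4, 150)), 0)
            lam, _, surface = grid_search_hyperparameters(
                d1, d2, gtab150, basis100, grid_l, [0.2]
            )
            chosen[label] = lam
            assert surface.shape == (2, 1)
        assert chosen["high"] >= chosen["low"]

    def test_empty_grid_rejected(self, basis100, gtab150):
        with pytest.raises(ValueError):
            grid_search_hyperparameters(
                np.ones((1, 150)), np.ones((1, 150)), gtab150, basis100, [], [0.2]
            )
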