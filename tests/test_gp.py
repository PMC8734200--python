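import numpy as np
import pytest
from scipy.stats import multivariate_normal

from handgp import (
    DoseResponseData,
    Hyperparameters,
    PredictionGrid,
    log_marginal_likelihood,
    mse,
    posterior_predict,
    slice_surface,
)
from handgp.kernels import gram_matrix

from conftest import random_dose_data

THETA = Hyperparameters(sigma2=0.5, sigma_f2=2.0, l1=5.0, l2=1.0)


def _one_point(y):
    # theta chosen so k(x,x) + sigma2 = 1 (up to jitter)
    theta = Hyperparameters(sigma2=0.5, sigma_f2=0.5, l1=5.0, l2=1.0)
    data = DoseResponseData([0.0], [0.0], [y])
    return data, theta


class TestLogMarginalLikelihood:
    def test_single_standard_normal_point(self):
        data, theta = _one_point(0.0)
        assert log_marginal_likelihood(data, theta) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-6
        )

    def test_single_point_closed_form(self):
        data, theta = _one_point(2.0)
        v = theta.sigma_f2 * (1 + 1e-8) + theta.sigma2
        expected = -0.5 * (4.0 / v) - 0.5 * np.log(2 * np.pi * v)
        assert log_marginal_likelihood(data, theta) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_mvn_density(self, seed):
        rng = np.random.default_rng(seed)
        data = random_dose_data(rng, n=5)
        cov = gram_matrix(data.X, THETA) + THETA.sigma2 * np.eye(5)
        expected = multivariate_normal(np.zeros(5), cov).logpdf(data.y)
        assert log_marginal_likelihood(data, THETA) == pytest.approx(expected, rel=1e-10)


class TestPosteriorPredict:
    def test_noise_free_interpolation(self):
        theta = Hyperparameters(sigma2=0.0, sigma_f2=2.0, l1=5.0, l2=1.0)
        data = DoseResponseData([0.0, 10.0, 0.0], [0.0, 0.0, 3.0], [1.0, 4.0, -2.0])
        grid = PredictionGrid(np.array([0.0, 10.0]), np.array([0.0, 3.0]))
        surf = posterior_predict(data, theta, grid)
        assert surf.mean[0, 0] == pytest.approx(1.0, abs=1e-3)
        assert surf.mean[1, 0] == pytest.approx(4.0, abs=1e-3)
        assert surf.variance[0, 0] == pytest.approx(0.0, abs=1e-4)

    def test_prior_reversion_far_from_data(self):
        data = DoseResponseData([0.0, 0.1, 0.0], [0.0, 0.0, 0.1], [5.0, 5.0, 5.0])
        theta = Hyperparameters(sigma2=0.1, sigma_f2=2.0, l1=0.001, l2=0.001)
        grid = PredictionGrid(np.array([0.0, 1000.0]), np.array([0.0, 1000.0]))
        surf = posterior_predict(data, theta, grid)
        assert abs(surf.mean[1, 1]) < 1e-3
        assert surf.variance[1, 1] == pytest.approx(theta.sigma_f2, rel=1e-3)

    def test_matches_explicit_matrix_algebra(self):
        # brute-force posterior equations on a 3-point toy
        data = DoseResponseData([0.0, 2.0, 5.0], [0.0, 1.0, 0.0], [1.0, -0.5, 2.0])
        grid = PredictionGrid(np.array([0.0, 1.0, 5.0]), np.array([0.0, 2.0]))
        surf = posterior_predict(data, THETA, grid)
        K = gram_matrix(data.X, THETA)
        A = K + THETA.sigma2 * np.eye(3)
        from handgp.kernels import cross_matrix

        for idx, node in enumerate(grid.nodes()):
            k = cross_matrix([node], data.X, THETA)[0]
            mu = k @ np.linalg.solve(A, data.y)
            var = THETA.sigma_f2 - k @ np.linalg.solve(A, k)
            i, j = divmod(idx, 2)
            assert surf.mean[i, j] == pytest.approx(mu, abs=1e-10)
            assert surf.variance[i, j] == pytest.approx(var, abs=1e-10)

    def test_posterior_variance_bounded_by_prior(self, rng):
        data = random_dose_data(rng, n=12)
        grid = PredictionGrid(np.linspace(0, 50, 11), np.linspace(0, 50, 11))
        surf = posterior_predict(data, THETA, grid)
        assert (surf.variance <= THETA.sigma_f2 + 1e-9).all()

    def test_extra_point_never_increases_variance(self, rng):
        data = random_dose_data(rng, n=8)
        grid = PredictionGrid(np.linspace(0, 50, 9), np.linspace(0, 50, 9))
        v8 = posterior_predict(data, THETA, grid).variance
        bigger = DoseResponseData(
            np.append(data.dose1, 25.0), np.append(data.dose2, 25.0),
            np.append(data.response, 50.0),
        )
        v9 = posterior_predict(bigger, THETA, grid).variance
        assert (v9 <= v8 + 1e-8).all()

    def test_ci_ordering(self, rng):
        data = random_dose_data(rng, n=8)
        grid = PredictionGrid(np.linspace(0, 50, 9), np.linspace(0, 50, 9))
        surf = posterior_predict(data, THETA, grid)
        lo, hi = surf.ci95
        assert (lo <= surf.mean).all() and (surf.mean <= hi).all()


class TestSlices:
    def _surface(self):
        g1, g2 = np.meshgrid([0.0, 1.0, 2.0, 5.0], [0.0, 1.0, 2.0, 5.0], indexing="ij")
        y = 10.0 - g1.ravel() - g2.ravel()
        data = DoseResponseData(g1.ravel(), g2.ravel(), y)
        grid = PredictionGrid(np.array([0.0, 1.0, 2.0, 5.0]), np.array([0.0, 1.0, 2.0, 5.0]))
        theta = Hyperparameters(sigma2=1e-6, sigma_f2=100.0, l1=5.0, l2=5.0)
        return posterior_predict(data, theta, grid)

    def test_mono_slices_fix_other_dose_at_zero(self):
        surf = self._surface()
        s1 = slice_surface(surf, "drug1-mono")
        np.testing.assert_allclose(s1.mean, surf.mean[:, 0])
        s2 = slice_surface(surf, "drug2-mono")
        np.testing.assert_allclose(s2.mean, surf.mean[0, :])

    def test_diagonal_has_design_length_and_symmetry(self):
        surf = self._surface()
        d = slice_surface(surf, "diagonal")
        assert d.mean.size == 4
        # symmetric data with l1 = l2: diagonal invariant under drug swap
        np.testing.assert_allclose(surf.mean, surf.mean.T, atol=1e-8)

    def test_unknown_slice_kind(self):
        with pytest.raises(ValueError):
            slice_surface(self._surface(), "nope")


class TestMse:
    def test_zero_for_perfect_fit_and_offset(self):
        surf = TestSlices()._surface()
        data = surf_data = DoseResponseData(
            np.repeat([0.0, 1.0, 2.0, 5.0], 4), np.tile([0.0, 1.0, 2.0, 5.0], 4),
            (10.0 - np.repeat([0.0, 1.0, 2.0, 5.0], 4) - np.tile([0.0, 1.0, 2.0, 5.0], 4)),
        )
        assert mse(data, surf) == pytest.approx(0.0, abs=1e-6)
        shifted = DoseResponseData(data.dose1, data.dose2, data.response + 3.0)
        assert mse(shifted, surf) == pytest.approx(9.0, abs=1e-5)

    def test_matches_brute_force_loop(self, rng):
        surf = TestSlices()._surface()
        d1 = np.repeat([0.0, 1.0, 2.0, 5.0], 4)
        d2 = np.tile([0.0, 1.0, 2.0, 5.0], 4)
        y = rng.normal(5, 2, size=16)
        data = DoseResponseData(d1, d2, y)
        total = 0.0
        for a, b, yy in zip(d1, d2, y):
            i = list([0.0, 1.0, 2.0, 5.0]).index(a)
            j = list([0.0, 1.0, 2.0, 5.0]).index(b)
            total += (yy - surf.mean[i, j]) ** 2
        assert mse(data, surf) == pytest.approx(total / 16, rel=1e-12)

    def test_monotherapy_selection(self):
        surf = TestSlices()._surface()
        data = DoseResponseData([0.0, 1.0, 0.0], [0.0, 0.0, 2.0], [10.0, 9.0, 8.0])
        assert mse(data, surf, which="drug1-mono") == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            mse(data, surf, which="bogus")
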