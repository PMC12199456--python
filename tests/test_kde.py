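"""Kernels, KDE evaluation, leave-one-out likelihood, covariance fitting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from donkey.exceptions import InsufficientDataError, InvalidBandwidthError
from donkey.kde import (
    KDEModel,
    PointSet,
    abramson_rescale,
    gaussian_kernel,
    loo_log_likelihood,
    optimize_covariance,
)

from conftest import make_kde


class TestGaussianKernel:
    @pytest.mark.parametrize(
        "disp, cov, alpha, expected",
        [
            ([0.0], [[1.0]], 1.0, 1.0 / np.sqrt(2 * np.pi)),
            ([1.0], [[1.0]], 1.0, norm.pdf(1.0)),
            ([0.5], [[0.25]], 1.0, norm.pdf(0.5, scale=0.5)),
        ],
    )
    def test_matches_normal_pdf(self, disp, cov, alpha, expected):
        assert gaussian_kernel(disp, cov, alpha) == pytest.approx(expected, rel=1e-10)

    def test_isotropic_matrix_equals_scalar_bandwidth(self):
        # a diagonal h^2 I covariance reproduces the textbook isotropic kernel
        h = 0.37
        for x in (0.0, 0.5, -1.2):
            assert gaussian_kernel([x], [[h**2]]) == pytest.approx(
                norm.pdf(x, scale=h), rel=1e-12
            )

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_broadened_kernel_integrates_to_one(self, alpha):
        total, _ = quad(lambda x: gaussian_kernel([x], [[0.3]], alpha), -20, 20)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_alpha_one_recovers_plain_kernel(self):
        v1 = gaussian_kernel([0.4, -0.2], [[0.5, 0.1], [0.1, 0.3]], 1.0)
        c = np.array([[0.5, 0.1], [0.1, 0.3]])
        d = np.array([0.4, -0.2])
        ref = np.exp(-0.5 * d @ np.linalg.inv(c) @ d) / np.sqrt(
            np.linalg.det(2 * np.pi * c)
        )
        assert v1 == pytest.approx(ref, rel=1e-12)

    def test_rejects_non_spd_covariance(self):
        with pytest.raises(InvalidBandwidthError):
            gaussian_kernel([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gaussian_kernel([0.0, 0.0], [[1.0]])


class TestKDEEvaluate:
    def test_closed_form_midpoint(self, model_01):
        # both kernels contribute phi(0.5) at the midpoint
        d, g, h = model_01.evaluate([0.5])
        assert d == pytest.approx(norm.pdf(0.5), rel=1e-12)
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_normalization(self, model_01):
        total, _ = quad(lambda x: model_01.density([x]), -15, 15)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_normalization_2d_grid(self):
        rng = np.random.default_rng(3)
        model = make_kde(rng.normal(0, 0.5, (12, 2)), 0.1 * np.eye(2))
        xs = np.linspace(-4, 4, 200)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        total = model.density_many(pts).sum() * (xs[1] - xs[0]) ** 2
        assert total == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_derivatives_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (15, 2))
        scales = np.exp(rng.normal(0, 0.3, 15))
        scales /= np.exp(np.mean(np.log(scales)))
        model = make_kde(pts, [[0.5, 0.1], [0.1, 0.8]], scales=scales, alpha=1.3)
        x = rng.normal(0, 1, 2)
        f, g, h = model.evaluate(x)
        eps = 1e-5
        for k in range(2):
            e = np.zeros(2)
            e[k] = eps
            fd_g = (model.density(x + e) - model.density(x - e)) / (2 * eps)
            assert g[k] == pytest.approx(fd_g, rel=1e-5, abs=1e-10)
            _, gp, _ = model.evaluate(x + e)
            _, gm, _ = model.evaluate(x - e)
            fd_h = (gp - gm) / (2 * eps)
            np.testing.assert_allclose(h[:, k], fd_h, rtol=1e-5, atol=1e-8)

    def test_kernel_weights_sum_to_density(self, model_01):
        x = [0.3]
        assert model_01.kernel_weights(x).sum() == pytest.approx(
            model_01.density(x), rel=1e-12
        )


class TestLeaveOneOut:
    def test_two_point_closed_form(self):
        ps = PointSet([[0.0], [1.0]], normalize=False)
        # each point sees only the other's kernel: log phi(1)
        assert loo_log_likelihood(ps, [[1.0]]) == pytest.approx(
            np.log(norm.pdf(1.0)), rel=1e-12
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 1, (9, 2))
        cov = [[0.7, 0.2], [0.2, 0.5]]
        base = loo_log_likelihood(PointSet(pts, normalize=False), cov)
        shuffled = pts[rng.permutation(9)]
        assert loo_log_likelihood(
            PointSet(shuffled, normalize=False), cov
        ) == pytest.approx(base, rel=1e-12)

    def test_matches_direct_summation(self):
        # brute-force double loop as an independent oracle
        pts = np.array([[0.0], [1.0], [2.0]])
        ps = PointSet(pts, normalize=False)
        total = 0.0
        for i in range(3):
            p = sum(
                norm.pdf(pts[i, 0] - pts[j, 0]) for j in range(3) if j != i
            ) / 2.0
            total += np.log(p)
        assert loo_log_likelihood(ps, [[1.0]]) == pytest.approx(
            total / 3.0, abs=1e-12
        )

    def test_requires_two_points(self):
        with pytest.raises(InsufficientDataError):
            PointSet([[0.0]], normalize=False)


class TestOptimizeCovariance:
    def test_two_points_exact_fixed_point(self):
        # with N=2 the weight ratios cancel and C = (Y1-Y2)^2 immediately
        ps = PointSet([[0.0], [1.0]], normalize=False)
        bw = optimize_covariance(ps)
        assert bw.pilot_covariance[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert bw.iterations_used == 1
        assert bw.converged

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (8, 2))
        c1 = optimize_covariance(PointSet(pts, normalize=False)).pilot_covariance
        c2 = optimize_covariance(
            PointSet(pts + np.array([3.7, -1.2]), normalize=False)
        ).pilot_covariance
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_fixed_point_self_consistency(self):
        rng = np.random.default_rng(9)
        ps = PointSet(rng.normal(0, 1, (10, 1)), normalize=True)
        bw = optimize_covariance(ps, tol=1e-10)
        cov = bw.pilot_covariance
        # substitute C into the update rule; it must reproduce itself
        pts = ps.points
        d = pts[:, None, :] - pts[None, :, :]
        q = np.einsum("ijk,kl,ijl->ij", d, np.linalg.inv(cov), d)
        np.fill_diagonal(q, np.inf)
        w = np.exp(-0.5 * (q - q.min(axis=1, keepdims=True)))
        np.fill_diagonal(w, 0.0)
        w /= w.sum(axis=1, keepdims=True)
        new = np.einsum("ij,ijk,ijl->kl", w, d, d) / pts.shape[0]
        assert abs(new[0, 0] - cov[0, 0]) / cov[0, 0] < 1e-6

    def test_matches_grid_search_oracle(self):
        # exhaustive scan over scalar C maximizing the LOO likelihood
        ps = PointSet(
            np.array([[0.0], [0.1], [0.4], [0.9], [1.0]]), normalize=False
        )
        grid = np.linspace(0.005, 1.0, 400)
        scores = [loo_log_likelihood(ps, [[c]]) for c in grid]
        c_grid = grid[int(np.argmax(scores))]
        c_fit = optimize_covariance(ps, tol=1e-10).pilot_covariance[0, 0]
        assert abs(c_fit - c_grid) < 1e-3 + (grid[1] - grid[0])

    def test_identical_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            optimize_covariance(PointSet([[1.0], [1.0]], normalize=False))


class TestAbramson:
    def test_symmetric_pair_gets_unit_factors(self, model_01):
        bw = abramson_rescale(model_01)
        np.testing.assert_allclose(bw.local_scales, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_geometric_mean_of_factors_is_one(self, seed):
        rng = np.random.default_rng(seed)
        model = make_kde(rng.normal(0, 1, (20, 2)), 0.2 * np.eye(2))
        bw = abramson_rescale(model)
        log_mean = np.mean(np.log(bw.local_scales))
        assert abs(log_mean) < 1e-10

    def test_sparse_region_broadens(self):
        model = make_kde([[0.0], [0.1], [0.2], [5.0]], [[0.05]])
        bw = abramson_rescale(model)
        assert bw.local_scales[3] > bw.local_scales[:3].max()


class TestPointSet:
    def test_normalization_maps_to_unit_interval(self):
        pts = np.array([[1.0, -5.0], [3.0, 5.0], [2.0, 0.0]])
        ps = PointSet(pts)
        assert ps.points.min(axis=0) == pytest.approx([0.0, 0.0])
        assert ps.points.max(axis=0) == pytest.approx([1.0, 1.0])
        np.testing.assert_allclose(ps.denormalize(ps.points), pts[:, ps.kept_columns])

    def test_constant_columns_dropped(self):
        ps = PointSet(np.array([[0.0, 7.0], [1.0, 7.0], [0.5, 7.0]]))
        assert ps.dim == 1
        assert list(ps.dropped_columns) == [1]

    def test_all_constant_rejected(self):
        with pytest.raises(InsufficientDataError):
            PointSet(np.full((4, 2), 3.0))


class TestModelExport:
    def test_bandwidth_round_trips_through_dict(self):
        rng = np.random.default_rng(2)
        model = make_kde(rng.normal(0, 1, (10, 2)), 0.3 * np.eye(2))
        bw = abramson_rescale(model)
        from donkey.kde import BandwidthModel

        clone = BandwidthModel.from_dict(bw.to_dict())
        np.testing.assert_allclose(clone.pilot_covariance, bw.pilot_covariance)
        np.testing.assert_allclose(clone.local_scales, bw.local_scales)
        rebuilt = KDEModel(model.point_set, clone)
        x = [0.2, -0.1]
        assert rebuilt.density(x) == pytest.approx(
            KDEModel(model.point_set, bw).density(x), rel=1e-14
        )
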