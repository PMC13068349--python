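"""Comparison estimators: linear (PCA/PR/PA), geometric (CorrDim/MLE/Two-NN),
and cross-validated PCA."""

import numpy as np
import pytest

import neurodim as nd
from neurodim.baselines import _pareto_fit


def _data_with_spectrum(variances, p=2000, seed=0):
    """Data whose covariance eigenvalues are exactly the given variances."""
    rng = np.random.default_rng(seed)
    n = len(variances)
    g = rng.normal(size=(p, n))
    u, _ = np.linalg.qr(g - g.mean(axis=0))  # zero-mean orthonormal columns
    return u * np.sqrt(np.asarray(variances) * (p - 1))


class TestPcaId:
    def test_dominant_eigenvalue(self):
        x = _data_with_spectrum([8.0, 1.0, 1.0])
        assert nd.pca_id(x, alpha=0.8) == 1

    def test_flat_spectrum_needs_all(self):
        x = _data_with_spectrum([1.0, 1.0, 1.0, 1.0])
        assert nd.pca_id(x, alpha=0.95) == 4

    def test_rank_three_plus_tiny_noise(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3000, 3)) @ rng.normal(size=(3, 20))
        x += 1e-4 * rng.normal(size=x.shape)
        assert nd.pca_id(x, alpha=0.99) == 3

    def test_monotone_in_alpha(self):
        x = _data_with_spectrum([5.0, 3.0, 1.0, 0.5, 0.1])
        ids = [nd.pca_id(x, a) for a in (0.5, 0.8, 0.9, 0.99)]
        assert ids == sorted(ids)

    def test_all_zero_data(self):
        assert nd.pca_id(np.zeros((10, 3))) == 0


class TestParticipationRatio:
    def test_isotropic_gives_ambient_dimension(self):
        x = _data_with_spectrum([2.0] * 6)
        assert nd.participation_ratio(x) == pytest.approx(6.0, rel=1e-9)

    def test_rank_one(self):
        rng = np.random.default_rng(0)
        x = np.outer(rng.normal(size=500), [1.0, 2.0, 3.0])
        assert nd.participation_ratio(x) == pytest.approx(1.0, rel=1e-9)

    def test_hand_computed_spectrum(self):
        x = _data_with_spectrum([2.0, 1.0, 1.0])
        assert nd.participation_ratio(x) == pytest.approx(8 / 3, rel=1e-9)

    def test_invariant_under_rotation_and_scaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert nd.participation_ratio(x) == pytest.approx(
            nd.participation_ratio(7.3 * x @ q), rel=1e-9
        )

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            nd.participation_ratio(np.ones((10, 3)))


class TestParallelAnalysis:
    def test_strong_factors_recovered(self):
        rng = np.random.default_rng(0)
        lat = 3.0 * rng.normal(size=(1000, 5))
        x = lat @ rng.normal(size=(5, 40)) + 0.1 * rng.normal(size=(1000, 40))
        assert nd.parallel_analysis(x, n_shuffles=30, seed=1) == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_iid_noise_near_zero(self, seed):
        x = np.random.default_rng(seed).normal(size=(400, 25))
        assert nd.parallel_analysis(x, n_shuffles=30, seed=seed) <= 2

    def test_constant_data(self):
        assert nd.parallel_analysis(np.ones((50, 5)), n_shuffles=10, seed=0) == 0


class TestCorrDim:
    def test_segment(self):
        pts = np.linspace(0, 1, 2000)[:, None]
        assert nd.corrdim(pts) == pytest.approx(1.0, abs=0.1)

    def test_disc(self, plane_cloud):
        assert nd.corrdim(plane_cloud) == pytest.approx(2.0, abs=0.3)

    def test_undersampled_cube_underestimates(self):
        pts = nd.uniform_hypercube(10, 1000, seed=0).points
        assert nd.corrdim(pts) < 10


class TestMleId:
    def test_matches_brute_force_oracle(self):
        pts = np.array([[0.0], [1.0], [2.0], [4.0]])
        K = 3
        # oracle: per-point estimate from sorted neighbor distances, Eq-style
        inv = []
        for i in range(4):
            r = np.sort(np.abs(pts[:, 0] - pts[i, 0]))[1 : K + 1]
            inv.append(np.log(r[-1] / r[:-1]).sum() / (K - 1))
        expected = 1.0 / np.mean(inv)
        assert nd.mle_id(pts, K=3) == pytest.approx(expected, rel=1e-9)
        # the point at 0 has neighbor distances (1, 2, 4): 2 / (3 ln 2)
        assert 1.0 / inv[0] == pytest.approx(2 / (3 * np.log(2)), rel=1e-9)

    def test_plane_recovery(self, plane_cloud):
        assert nd.mle_id(plane_cloud, K=20) == pytest.approx(2.0, abs=0.2)

    def test_five_cube_recovery(self):
        pts = nd.uniform_hypercube(5, 8000, seed=1).points
        assert nd.mle_id(pts, K=20) == pytest.approx(5.0, rel=0.1)

    def test_duplicates_collapsed_with_warning(self):
        pts = np.vstack([np.random.default_rng(0).normal(size=(300, 2))] * 2)
        with pytest.warns(UserWarning, match="duplicate"):
            nd.mle_id(pts, K=5)


class TestTwoNN:
    def test_exact_pareto_sample_matches_ml_closed_form(self):
        rng = np.random.default_rng(4)
        mu = (1 - rng.uniform(size=10_000)) ** (-1 / 3)  # Pareto(3)
        fitted = _pareto_fit(mu, 0.1)
        ml = mu.size / np.log(mu).sum()  # closed-form Pareto MLE
        assert fitted == pytest.approx(ml, rel=0.02)
        assert fitted == pytest.approx(3.0, rel=0.05)

    def test_plane_recovery(self, plane_cloud):
        assert nd.twonn(plane_cloud) == pytest.approx(2.0, abs=0.2)

    def test_ambient_noise_inflates_estimate(self):
        clean = nd.uniform_hyperplane(2, 10, 4000, seed=0).points
        noisy = clean + 0.05 * np.random.default_rng(1).normal(size=clean.shape)
        assert nd.twonn(noisy) > nd.twonn(clean) + 0.5

    def test_duplicate_points_excluded(self):
        pts = nd.uniform_hyperplane(2, 3, 500, seed=0).points
        with pytest.warns(UserWarning, match="duplicate"):
            nd.twonn(np.vstack([pts, pts[:50]]))


class TestTwoNNDecimated:
    def test_noiseless_plane_flat_curve(self, plane_cloud):
        est = nd.twonn_decimated(plane_cloud, fractions=(1.0, 0.5, 0.25), seed=0)
        assert est == pytest.approx(2.0, abs=0.25)

    def test_noisy_plane_decimation_deflates(self):
        clean = nd.uniform_hyperplane(2, 10, 6000, seed=2).points
        noisy = clean + 0.03 * np.random.default_rng(3).normal(size=clean.shape)
        plain = nd.twonn(noisy)
        dec = nd.twonn_decimated(
            noisy, fractions=(1.0, 0.3, 0.1, 0.03), n_rep=3, seed=0
        )
        assert dec < plain

    def test_tiny_fractions_skipped(self, plane_cloud):
        with pytest.warns(UserWarning, match="skipped"):
            nd.twonn_decimated(plane_cloud, fractions=(1.0, 0.5, 0.001), seed=0)


class TestCvPCA:
    def test_identical_repetitions_reduce_to_pca(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 30))
        proj = nd.cvpca_project(x, x, variance_fraction=0.999)
        assert proj.shape == (100, 5)

    def test_pure_noise_keeps_at_most_one_axis(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(200, 40)), rng.normal(size=(200, 40))
        assert nd.cvpca_project(a, b).shape[1] <= 1

    def test_shared_rank_five_signal(self):
        r1, r2 = nd.repeated_stimulus_responses(5, 200, 60, noise_sd=1.0, seed=0)
        assert nd.cvpca_project(r1, r2).shape[1] == 5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            nd.cvpca_project(np.zeros((3, 4)) + np.eye(3, 4), np.ones((4, 3)))


class TestCrossEstimatorConsistency:
    @pytest.mark.parametrize("d_true", [2, 3, 5])
    def test_knn_estimators_agree_with_fci_on_cubes(self, d_true):
        pts = nd.uniform_hypercube(d_true, 8000, seed=d_true).points
        fci_est = nd.fit_fci(pts, max_pairs=1_000_000, seed=0).d_id
        for est in (nd.mle_id(pts, K=20), nd.twonn(pts)):
            assert abs(est - fci_est) / fci_est < 0.15
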