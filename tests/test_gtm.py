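"""GTM core: Gaussian E-step, basis map, regularized M-step, degeneracy."""

import numpy as np
import pytest

import orientem as om
from orientem.emc import mstep_emc
from orientem.gtm import (
    GTMOrienter,
    basis_matrix,
    estep_gaussian,
    mstep_gtm,
    permutation_degeneracy,
    update_beta,
)


class TestBasisMatrix:
    def test_center_hit_is_one_and_monotone(self, grid24):
        phi = basis_matrix(grid24, grid24.nodes[:4], sigma_phi=0.5)
        assert np.allclose(np.diag(phi[:4, :4]), 1.0)
        # entries decrease with rotation angle
        ang = 2 * np.arccos(np.clip(np.abs(grid24.nodes @ grid24.nodes[:4].T), -1, 1))
        order = np.argsort(ang[:, 0])
        assert np.all(np.diff(phi[order, 0]) <= 1e-12)

    def test_delta_limit(self, grid24):
        phi = basis_matrix(grid24, grid24.nodes, sigma_phi=1e-4)
        assert np.allclose(phi, np.eye(len(grid24)), atol=1e-10)

    def test_rejects_bad_sigma(self, grid24):
        with pytest.raises(ValueError):
            basis_matrix(grid24, grid24.nodes, sigma_phi=0.0)


class TestEstepGaussian:
    def test_equidistant_gives_uniform(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.array([[0.5, 0.5]])
        R, _ = estep_gaussian(Y, T, beta=3.0)
        assert np.allclose(R, 0.5)

    def test_large_beta_hard_assignment(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.array([[0.9, 0.1]])
        R, _ = estep_gaussian(Y, T, beta=1e6)
        assert R[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_two_by_two(self):
        # brute-force Bayes posterior on a 2-node, 2-pixel instance
        Y = np.array([[1.0, 2.0], [2.0, 1.0]])
        T = np.array([[1.2, 1.6], [2.2, 0.8]])
        beta = 0.7
        R, ll = estep_gaussian(Y, T, beta)
        like = np.exp(-0.5 * beta * ((T[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
        like *= (beta / (2 * np.pi))  # (p/2) = 1 power of the normalizer
        post = (like / like.sum(axis=1, keepdims=True)).T
        assert np.allclose(R, post, atol=1e-12)
        assert ll == pytest.approx(np.log(0.5 * like.sum(axis=1)).sum(), abs=1e-10)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        R, _ = estep_gaussian(rng.random((5, 9)), rng.random((12, 9)), beta=2.0)
        assert np.allclose(R.sum(axis=0), 1.0, atol=1e-10)


class TestMstepGTM:
    def test_delta_basis_reduces_to_weighted_average(self):
        # alpha = 0, identity basis: the normal equations collapse to the
        # responsibility-weighted data mean, same as the Poisson M-step
        rng = np.random.default_rng(1)
        X = rng.random((30, 7))
        R = rng.random((6, 30))
        R /= R.sum(axis=0, keepdims=True)
        W = mstep_gtm(R, X, np.eye(6), alpha=0.0, beta=1.0)
        assert np.allclose(W, mstep_emc(R, X), atol=1e-10)

    def test_large_alpha_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 5))
        R = np.full((4, 20), 0.25)
        phi = np.eye(4)
        W = mstep_gtm(R, X, phi, alpha=1e12, beta=1.0)
        assert np.max(np.abs(W)) < 1e-6

    def test_normal_equation_residual(self, grid24):
        rng = np.random.default_rng(3)
        X = rng.random((40, 6))
        R = rng.random((24, 40))
        R /= R.sum(axis=0, keepdims=True)
        phi = basis_matrix(grid24, grid24.nodes[::2], sigma_phi=0.8)
        alpha, beta = 0.3, 2.0
        W = mstep_gtm(R, X, phi, alpha, beta)
        g = R.sum(axis=1)
        A = phi.T @ (g[:, None] * phi) + (alpha / beta) * np.eye(phi.shape[1])
        resid = A @ W - phi.T @ (R @ X)
        assert np.max(np.abs(resid)) < 1e-8

    def test_singular_alpha_zero_reports_rank_deficiency(self):
        # a basis column supported only on nodes with zero responsibility
        R = np.zeros((3, 5))
        R[0] = 1.0
        phi = np.eye(3)
        with pytest.raises(np.linalg.LinAlgError, match="alpha"):
            mstep_gtm(R, np.ones((5, 2)), phi, alpha=0.0, beta=1.0)


class TestUpdateBeta:
    def test_single_pair_mean_square_residual(self):
        T = np.array([[1.0, 3.0]])
        Y = np.array([[0.0, 1.0]])
        R = np.array([[1.0]])
        assert update_beta(R, T, Y) == pytest.approx(1.0 / ((1 + 4) / 2))

    def test_hand_computed_two_by_two(self):
        T = np.array([[1.0, 0.0], [3.0, 1.0]])
        Y = np.array([[1.0, 1.0], [0.0, 0.0]])
        R = np.array([[0.25, 0.5], [0.75, 0.5]])
        d2 = np.array([[1.0, 4.0], [1.0, 10.0]])  # ||T_n - Y_k||^2, (K, N)
        expect = 1.0 / ((R * d2).sum() / 4.0)
        assert update_beta(R, T, Y) == pytest.approx(expect)

    def test_perfect_fit_caps(self):
        T = np.ones((3, 4))
        R = np.full((1, 3), 1.0)
        assert update_beta(R, T, T[:1]) == pytest.approx(1e12)


class TestRunGTM:
    def test_penalized_loglik_monotone_at_fixed_beta(self, grid24, noisy_dataset):
        gt = GTMOrienter(grid=grid24, center_stride=2, alpha=0.1, fixed_beta=True,
                         max_iter=25, tol=0, random_state=0).fit(noisy_dataset)
        tr = np.array(gt.penalized_trace_)
        assert np.all(np.diff(tr) >= -1e-9 * np.abs(tr[1:]))

    def test_neighbor_continuity_of_map(self, grid24, noisy_dataset):
        # contiguity: tomograms at neighboring nodes are closer than at
        # random node pairs
        gt = GTMOrienter(grid=grid24, center_stride=2, alpha=0.1,
                         max_iter=40, tol=1e-6, random_state=0).fit(noisy_dataset)
        Y = gt.tomograms_
        pairs = grid24.neighbor_pairs()
        d_nbr = np.mean([np.linalg.norm(Y[i] - Y[j]) for i, j in pairs])
        rng = np.random.default_rng(4)
        ri = rng.integers(0, len(grid24), 200)
        rj = rng.integers(0, len(grid24), 200)
        keep = ri != rj
        d_rand = np.mean(np.linalg.norm(Y[ri[keep]] - Y[rj[keep]], axis=1))
        assert d_nbr < d_rand

    def test_perfect_clustering_on_node_aligned_data(self, grid24, geom16, phantom16):
        # noise-free duplicates at the nodes: a fine basis resolves the
        # patterns and every duplicate group lands on one distinct node
        # (ordering is fixed only up to the global gauge)
        from orientem.simulate import simulate_dataset

        vol, _ = phantom16
        quats = np.repeat(grid24.nodes, 10, axis=0)
        data = simulate_dataset(vol, geom16, N=len(quats), mean_photons=1e4,
                                seed=3, orientations=quats, noise_model="none")
        truth_idx = np.repeat(np.arange(len(grid24)), 10)
        gt = GTMOrienter(grid=grid24, center_stride=1,
                         sigma_phi=0.5 * grid24.min_spacing(), alpha=0.1,
                         max_iter=100, tol=1e-7, random_state=0).fit(data)
        groups = {}
        for lab, t in zip(gt.labels_, truth_idx):
            groups.setdefault(t, set()).add(lab)
        assert all(len(v) == 1 for v in groups.values())
        labels = [next(iter(v)) for v in groups.values()]
        assert len(set(labels)) == len(labels)

    def test_poisson_noise_robustness_via_clt(self):
        """Gaussian-model GTM refining an EMC start on Poisson counts at
        >= 1 photon/pixel keeps the median error within 2 Shannon angles:
        summing residuals over many pixels makes the Gaussian responsibility
        model valid regardless of the per-pixel noise law."""
        import logging

        logging.disable(logging.WARNING)
        from orientem.simulate import make_phantom, required_L, simulate_dataset

        g = om.build_grid(1000, seed=1, n_iter=200)
        geom = om.shannon_geometry(16, 1.0)
        vol, _ = make_phantom(n_blobs=8, seed=2, L=required_L(geom, 0.5),
                              voxel_spacing=0.5)
        data = simulate_dataset(vol, geom, N=1500, mean_photons=1.5 * geom.p, seed=4)
        assert data.counts.mean() >= 1.0
        warm = om.EMCOrienter(grid=g, geom=geom, max_iter=60, tol=1e-4,
                              random_state=0).fit(data)
        gt = GTMOrienter(grid=g, center_stride=2,
                         sigma_phi=0.75 * g.min_spacing(), alpha=0.1,
                         max_iter=60, tol=1e-6, random_state=0,
                         init_tomograms=warm.tomograms_).fit(data)
        rep = om.align_gauge(om.assign_orientations(gt.responsibilities_, g),
                             data.true_orientations)
        assert rep.median_error_shannon <= 2.0

    def test_determinism(self, grid24, noisy_dataset):
        a = GTMOrienter(grid=grid24, max_iter=10, random_state=5).fit(noisy_dataset)
        b = GTMOrienter(grid=grid24, max_iter=10, random_state=5).fit(noisy_dataset)
        assert np.array_equal(a.tomograms_, b.tomograms_)
        assert a.penalized_trace_ == b.penalized_trace_

    def test_predict_and_params(self, grid24, noisy_dataset):
        gt = GTMOrienter(grid=grid24, max_iter=10, random_state=0).fit(noisy_dataset)
        assert np.array_equal(gt.predict(noisy_dataset.counts), gt.labels_)
        p = gt.get_params()
        assert GTMOrienter().set_params(**p).alpha == gt.alpha


class TestDegeneracy:
    def test_delta_basis_likelihood_permutation_invariant(self, grid24, geom16, node_dataset):
        data, _ = node_dataset
        gt = GTMOrienter(grid=grid24, delta_basis=True, alpha=0.0,
                         max_iter=30, tol=1e-8, random_state=0).fit(data)
        out = permutation_degeneracy(gt, data, n_permutations=100, seed=0)
        assert out["max_abs_change"] <= 1e-9 * abs(out["baseline"])

    def test_contiguity_breaks_degeneracy(self, grid24, geom16, node_dataset):
        data, _ = node_dataset
        gt = GTMOrienter(grid=grid24, center_stride=2, alpha=0.1,
                         max_iter=50, tol=1e-8, random_state=0).fit(data)
        out = permutation_degeneracy(gt, data, n_permutations=100, seed=0)
        assert out["frac_decreased"] >= 0.95
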