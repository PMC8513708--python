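"""The joint embedding estimator: exact recovery, alignment, distances,
and qualitative behaviour on the benchmark scenarios."""

import numpy as np
import pytest
import scipy.optimize

import cosie
from cosie.mase import (
    mase_fit,
    out_of_sample_score,
    procrustes_align,
    reconstruct_P,
    score_matrices,
    subspace_distance,
)
from cosie.simulate import ScenarioSpec, make_scenario

from conftest import balanced_membership


def random_orthonormal(n, d, rng):
    Q, _ = np.linalg.qr(rng.normal(size=(n, d)))
    return Q


@pytest.fixture(scope="module")
def noiseless_ensemble():
    """Full-rank rank-3 COSIE probability matrices (no sampling noise)."""
    rng = np.random.default_rng(10)
    Z = balanced_membership(90, 3)
    B_list = []
    for _ in range(4):
        b = rng.uniform(size=(3, 3))
        B_list.append(np.triu(b) + np.triu(b, 1).T)
    cp = cosie.sbm_to_cosie(cosie.SbmParams(Z=Z, B_list=B_list))
    P_list = cosie.build_probability_matrices(cp)
    return cp, P_list


class TestMaseFit:
    def test_single_graph_reduces_to_ase(self):
        rng = np.random.default_rng(0)
        A = (rng.random((40, 40)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        fit = mase_fit([A], d=3)
        res = cosie.ase(A, d=3)
        assert subspace_distance(fit.V_hat, res.eigvecs) < 1e-10
        assert np.allclose(fit.R_hat_list[0], fit.V_hat.T @ A @ fit.V_hat)

    def test_noiseless_exact_recovery(self, noiseless_ensemble):
        """On the P-matrices themselves, the fitted subspace equals span(V)
        and scores equal the truth after one shared rotation."""
        cp, P_list = noiseless_ensemble
        fit = mase_fit(P_list, d=cp.d)
        assert subspace_distance(fit.V_hat, cp.V) < 1e-8
        W = procrustes_align(fit.V_hat, cp.V)
        for R_hat, R in zip(fit.R_hat_list, cp.R_list):
            assert np.linalg.norm(W @ R_hat @ W.T - R) < 1e-8

    def test_rotation_invariance_of_fit(self):
        """Sampling from an orthogonally reparameterised model with the
        same seed gives identical reconstructions and score distances."""
        rng = np.random.default_rng(2)
        Z = balanced_membership(60, 3)
        b = rng.uniform(size=(3, 3))
        B = np.triu(b) + np.triu(b, 1).T
        cp = cosie.sbm_to_cosie(cosie.SbmParams(Z=Z, B_list=[B, B * 0.5]))
        W = np.linalg.qr(rng.normal(size=(cp.d, cp.d)))[0]
        rotated = cosie.CosieParams(
            V=cp.V @ W, R_list=[W.T @ R @ W for R in cp.R_list]
        )
        g1 = cosie.sample_cosie(cp, seed=7)
        g2 = cosie.sample_cosie(rotated, seed=7)
        f1 = mase_fit(g1, d=cp.d)
        f2 = mase_fit(g2, d=cp.d)
        for P1, P2 in zip(reconstruct_P(f1), reconstruct_P(f2)):
            assert np.abs(P1 - P2).max() < 1e-10
        D1 = cosie.pairwise_score_distances(f1.R_hat_list)
        D2 = cosie.pairwise_score_distances(f2.R_hat_list)
        assert np.abs(D1 - D2).max() < 1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="vertex set"):
            mase_fit([np.zeros((4, 4)), np.zeros((5, 5))], d=1)

    def test_warns_beyond_numerical_rank(self):
        """Duplicated graphs give a rank-2 concatenated embedding; asking
        for d=4 exceeds it and is flagged."""
        rng = np.random.default_rng(13)
        A = (rng.random((30, 30)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        with pytest.warns(UserWarning, match="rank"):
            mase_fit([A, A], d=4, d_i_list=[2, 2])


class TestScoreMatrices:
    def test_projection_identity(self):
        rng = np.random.default_rng(3)
        V = random_orthonormal(12, 3, rng)
        S = rng.normal(size=(3, 3))
        S = S + S.T
        (R,) = score_matrices(V, [V @ S @ V.T])
        assert np.allclose(R, S)

    def test_zero_graph_zero_score(self):
        rng = np.random.default_rng(4)
        V = random_orthonormal(10, 2, rng)
        (R,) = score_matrices(V, [np.zeros((10, 10))])
        assert np.all(R == 0)

    def test_matches_numerical_least_squares(self):
        """V^T A V agrees with direct minimisation of ||A - V R V^T||_F
        over symmetric R (independent optimiser as oracle)."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 6))
        A = A + A.T
        V = random_orthonormal(6, 2, rng)

        def unpack(x):
            return np.array([[x[0], x[1]], [x[1], x[2]]])

        res = scipy.optimize.minimize(
            lambda x: np.linalg.norm(A - V @ unpack(x) @ V.T, "fro") ** 2,
            x0=np.zeros(3),
            method="BFGS",
        )
        (R,) = score_matrices(V, [A])
        assert np.abs(R - unpack(res.x)).max() < 1e-6


class TestReconstruction:
    def test_noiseless_reconstruction(self, noiseless_ensemble):
        cp, P_list = noiseless_ensemble
        fit = mase_fit(P_list, d=cp.d)
        for P_hat, P in zip(reconstruct_P(fit), P_list):
            assert np.linalg.norm(P_hat - P) < 1e-8

    def test_er_rank_one_concentration(self):
        """Single G(500, 0.5) graph: relative error of the rank-1
        reconstruction below 0.1."""
        n, p = 500, 0.5
        params = cosie.CosieParams(
            V=np.full((n, 1), n**-0.5), R_list=[np.array([[p * n]])]
        )
        g = cosie.sample_cosie(params, seed=11)
        fit = mase_fit(g, d=1)
        (P_hat,) = reconstruct_P(fit)
        P = np.full((n, n), p)
        assert np.linalg.norm(P_hat - P) / np.linalg.norm(P) < 0.1

    def test_four_class_relative_error(self):
        """Four-class scenario, alpha=1: average relative reconstruction
        error below 0.25."""
        (params, _), sample = make_scenario(
            ScenarioSpec("four-class", {"n": 256, "m": 40, "alpha": 1.0, "seed": 0})
        )
        fit = mase_fit(sample, d=2)
        P_hat = reconstruct_P(fit)
        errs = []
        for Ph, B in zip(P_hat, params.B_list):
            P = params.Z @ B @ params.Z.T
            errs.append(np.linalg.norm(Ph - P) / np.linalg.norm(P))
        assert np.mean(errs) < 0.25

    def test_probability_mode_clips(self):
        rng = np.random.default_rng(6)
        A = (rng.random((30, 30)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        fit = mase_fit([A], d=2)
        clipped = reconstruct_P(fit, mode="probability")[0]
        assert clipped.min() >= 0.0 and clipped.max() <= 1.0


class TestOutOfSample:
    def test_training_graph_reproduces_its_score(self, noiseless_ensemble):
        cp, P_list = noiseless_ensemble
        fit = mase_fit(P_list, d=cp.d)
        R_oos = out_of_sample_score(fit.V_hat, P_list[0])
        assert np.allclose(R_oos, fit.R_hat_list[0])

    def test_zero_graph(self, noiseless_ensemble):
        cp, P_list = noiseless_ensemble
        fit = mase_fit(P_list, d=cp.d)
        assert np.all(out_of_sample_score(fit.V_hat, np.zeros((cp.n, cp.n))) == 0)

    def test_nearest_neighbour_classifies_new_graphs(self):
        """New class-1 graphs from the four-class scenario at alpha=1 are
        matched to class-1 training scores by 1-NN at >= 90% accuracy."""
        (params, labels), sample = make_scenario(
            ScenarioSpec("four-class", {"n": 256, "m": 40, "alpha": 1.0, "seed": 1})
        )
        fit = cosie.mase_fit(sample, d=2)
        B1 = params.B_list[0]
        P1 = params.Z @ B1 @ params.Z.T
        hits = 0
        n_new = 50
        test_graphs = cosie.simulate.sample_bernoulli_graphs([P1] * n_new, seed=99)
        for A_new in test_graphs.adjacency:
            R_new = out_of_sample_score(fit.V_hat, A_new)
            dists = [np.linalg.norm(R_new - R, "fro") for R in fit.R_hat_list]
            hits += labels[int(np.argmin(dists))] == 1
        assert hits / n_new >= 0.9


class TestProcrustes:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(7)
        V = random_orthonormal(20, 3, rng)
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        W = procrustes_align(V @ Q, V)
        assert np.allclose(W, Q, atol=1e-10)
        assert np.linalg.norm(V @ Q - V @ W) < 1e-10

    def test_identity_for_equal_inputs(self):
        rng = np.random.default_rng(8)
        V = random_orthonormal(15, 2, rng)
        assert np.allclose(procrustes_align(V, V), np.eye(2), atol=1e-10)

    def test_beats_random_orthogonal_search(self):
        """The SVD solution is at least as good as 10^4 random rotations."""
        rng = np.random.default_rng(9)
        V1 = random_orthonormal(12, 3, rng)
        V2 = random_orthonormal(12, 3, rng)
        W = procrustes_align(V1, V2)
        best = np.linalg.norm(V1 - V2 @ W, "fro")
        unaligned = np.linalg.norm(V1 - V2, "fro")
        assert best <= unaligned + 1e-12
        for _ in range(10_000):
            Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            assert best <= np.linalg.norm(V1 - V2 @ Q, "fro") + 1e-12


class TestSubspaceDistance:
    def test_zero_for_equal_spans(self):
        rng = np.random.default_rng(11)
        V = random_orthonormal(20, 3, rng)
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        assert subspace_distance(V, V @ Q) < 1e-10

    def test_orthogonal_complement_spectral_one(self):
        V1 = np.eye(6)[:, :3]
        V2 = np.eye(6)[:, 3:]
        assert subspace_distance(V1, V2) == pytest.approx(1.0)

    def test_frobenius_closed_form(self):
        """||P1 - P2||_F = sqrt(2d - 2||V2^T V1||_F^2) for equal d."""
        rng = np.random.default_rng(12)
        V1 = random_orthonormal(25, 4, rng)
        V2 = random_orthonormal(25, 4, rng)
        closed = np.sqrt(2 * 4 - 2 * np.linalg.norm(V2.T @ V1, "fro") ** 2)
        assert subspace_distance(V1, V2, norm="frobenius") == pytest.approx(closed)


class TestConsistencyTrend:
    def test_error_decreases_with_sample_size(self, trend_study):
        """Median subspace error shrinks monotonically in m in both the
        homogeneous and heterogeneous 3-block scenarios."""
        for scen in ("homo-3block", "hetero-3block"):
            med = trend_study[scen]["mase"]
            errs = [med[m] for m in (1, 4, 16, 64)]
            assert all(a > b for a, b in zip(errs, errs[1:])), (scen, errs)

    def test_mean_embedding_fails_on_heterogeneous_graphs(self, trend_study):
        """Embedding the mean adjacency matrix stops improving when graphs
        have different expectations, while the joint embedding keeps
        gaining accuracy."""
        mase_med = trend_study["hetero-3block"]["mase"]
        mean_med = trend_study["hetero-3block"]["ase_mean"]
        assert mase_med[64] < 0.1
        assert mean_med[64] > 3 * mase_med[64]
        # ASE-of-mean is not monotone decreasing in m here
        errs = [mean_med[m] for m in (1, 4, 16, 64)]
        assert not all(a > b for a, b in zip(errs, errs[1:]))
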