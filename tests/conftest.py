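"""Shared fixtures.

The heavy Monte Carlo studies (subspace-error trend, score normality,
test calibration and power, community recovery) are session-scoped so the
property suite and the acceptance suite consume one computation each.
"""

import numpy as np
import pytest

import cosie
from cosie.embed import ase
from cosie.graphtest import asymptotic_null_test, bootstrap_null_test, vec_sym
from cosie.simulate import ScenarioSpec, make_scenario


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def balanced_membership(n, K):
    Z = np.zeros((n, K))
    Z[np.arange(n), np.repeat(np.arange(K), n // K)] = 1.0
    return Z


@pytest.fixture(scope="session")
def two_block_model():
    """Balanced 2-block SBM, n=300, B = 0.3I + 0.1*11^T (eigenvalues 75, 45)."""
    Z = balanced_membership(300, 2)
    B = 0.3 * np.eye(2) + 0.1 * np.ones((2, 2))
    return cosie.SbmParams(Z=Z, B_list=[B])


@pytest.fixture(scope="session")
def trend_study():
    """Median subspace error vs m for MASE and ASE-of-mean at n=243.

    25 replicates per (scenario, m); both the homogeneous and the
    heterogeneous 3-block scenarios.
    """
    ms = [1, 4, 16, 64]
    out = {}
    for scen in ("homo-3block", "hetero-3block"):
        med_mase, med_mean = {}, {}
        for m in ms:
            errs_m, errs_a = [], []
            for rep in range(25):
                params, sample = make_scenario(
                    ScenarioSpec(scen, {"n": 243, "m": m, "seed": 10_000 * m + rep})
                )
                cp = cosie.sbm_to_cosie(params)
                fit = cosie.mase_fit(sample, d=3)
                errs_m.append(cosie.subspace_distance(fit.V_hat, cp.V))
                abar = np.mean(sample.adjacency, axis=0)
                errs_a.append(cosie.subspace_distance(ase(abar, 3).eigvecs, cp.V))
            med_mase[m] = float(np.median(errs_m))
            med_mean[m] = float(np.median(errs_a))
        out[scen] = {"mase": med_mase, "ase_mean": med_mean}
    return out


@pytest.fixture(scope="session")
def normality_study(two_block_model):
    """Aligned, standardised score entries and eigenvalue biases vs m.

    200 replicates for each m in {1, 5, 20} of the n=300 two-block model;
    entries standardised by the exact Bernoulli covariance of the scores,
    eigenvalue bias measured against the hollow expected adjacency.
    """
    params = two_block_model
    cp = cosie.sbm_to_cosie(params)
    V, R = cp.V, cp.R_list[0]
    P = V @ R @ V.T
    P_hollow = P.copy()
    np.fill_diagonal(P_hollow, 0.0)
    sd = np.sqrt(np.diag(cosie.score_covariance(V, P_hollow).Sigma))
    eig_hollow = np.sort(np.linalg.eigvalsh(P_hollow))[-2:]
    out = {}
    for m in (1, 5, 20):
        sp_m = cosie.SbmParams(Z=params.Z, B_list=params.B_list * m)
        zs, eigs = [], []
        for rep in range(200):
            g = cosie.sample_multilayer_sbm(sp_m, seed=1000 * m + rep)
            fit = cosie.mase_fit(g, d=2)
            W = cosie.procrustes_align(fit.V_hat, V)
            zs.append(vec_sym(W @ fit.R_hat_list[0] @ W.T - R) / sd)
            eigs.append(np.sort(np.linalg.eigvalsh(fit.R_hat_list[0])))
        zs = np.asarray(zs)
        bias = np.asarray(eigs).mean(axis=0) - eig_hollow
        out[m] = {"z": zs, "eig_bias": bias}
    return out


@pytest.fixture(scope="session")
def null_calibration():
    """Both tests applied to 200 independent null pairs (n=150, d=3).

    Each pair is drawn from one mixed-membership model (equal
    distributions), bootstrap null with 200 resamples, asymptotic null
    with 1000 Gaussian draws.
    """
    boot_p, asym_p = [], []
    for rep in range(200):
        _, pair = make_scenario(
            ScenarioSpec("mmsbm-pair-a", {"n": 150, "b11_shift": 0.0, "seed": rep})
        )
        A1, A2 = pair.adjacency
        boot_p.append(bootstrap_null_test(A1, A2, d=3, n_boot=200, seed=rep).p_value)
        asym_p.append(asymptotic_null_test(A1, A2, d=3, n_mc=1000, seed=rep).p_value)
    return {"bootstrap": np.asarray(boot_p), "asymptotic": np.asarray(asym_p)}


@pytest.fixture(scope="session")
def power_study():
    """Bootstrap test on 100 well-separated alternative pairs (B11 + 0.4)."""
    pvals = []
    for rep in range(100):
        _, pair = make_scenario(
            ScenarioSpec("mmsbm-pair-a", {"n": 150, "b11_shift": 0.4, "seed": 500 + rep})
        )
        A1, A2 = pair.adjacency
        pvals.append(bootstrap_null_test(A1, A2, d=3, n_boot=200, seed=rep).p_value)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def community_study():
    """Misclustering fractions over 25 replicates (n=243, m=16, K=3)."""
    fracs = []
    for rep in range(25):
        params, sample = make_scenario(
            ScenarioSpec("homo-3block", {"n": 243, "m": 16, "seed": rep})
        )
        fit = cosie.mase_fit(sample, d=3)
        res = cosie.cluster_subspace(fit.V_hat, K=3, seed=rep)
        _, frac, _ = cosie.misclustering_error(res.Z_hat, params.Z)
        fracs.append(frac)
    return np.asarray(fracs)
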