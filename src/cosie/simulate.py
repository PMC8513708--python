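"""Samplers for COSIE and multilayer-SBM graph ensembles, plus named
simulation scenarios used throughout the test suite and examples.

All samplers draw each upper-triangular adjacency entry independently as
Bernoulli(P_uv), symmetrise, and zero the diagonal.  Randomness follows a
single root seed; each graph in an ensemble gets its own child stream
(spawned by index) so that graph i is reproducible regardless of how many
graphs are drawn or in what order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CosieParams, GraphSample, SbmParams, build_probability_matrices

__all__ = [
    "sample_cosie",
    "sample_multilayer_sbm",
    "sample_mmsbm",
    "sample_bernoulli_graphs",
    "ScenarioSpec",
    "make_scenario",
    "SCENARIOS",
]

logger = logging.getLogger("cosie.simulate")

# --------------------------------------------------------------------------
# Bernoulli graph sampling


def _child_rngs(seed, m):
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(m)]


def sample_bernoulli_graphs(P_list, seed) -> GraphSample:
    """Draw one symmetric hollow binary graph per probability matrix."""
    rngs = _child_rngs(seed, len(P_list))
    iu = None
    adjacency = []
    for P, rng in zip(P_list, rngs):
        P = np.asarray(P, dtype=float)
        n = P.shape[0]
        if iu is None or iu[0].size != n * (n - 1) // 2:
            iu = np.triu_indices(n, k=1)
        A = np.zeros((n, n))
        edges = (rng.random(iu[0].size) < P[iu]).astype(float)
        A[iu] = edges
        A = A + A.T
        adjacency.append(A)
    logger.debug("sampled %d Bernoulli graphs with seed %s", len(P_list), seed)
    return GraphSample(adjacency=adjacency)


def sample_cosie(params: CosieParams, seed) -> GraphSample:
    """Sample m independent graphs with E[A^(i)] = V R^(i) V^T."""
    return sample_bernoulli_graphs(build_probability_matrices(params), seed)


def sample_multilayer_sbm(params: SbmParams, seed) -> GraphSample:
    """Sample m independent graphs with E[A^(i)] = Z B^(i) Z^T."""
    P_list = [params.Z @ B @ params.Z.T for B in params.B_list]
    return sample_bernoulli_graphs(P_list, seed)


def sample_mmsbm(n, B, dirichlet_alpha, seed, Z=None):
    """Sample one graph from a mixed-membership SBM.

    Each vertex's membership row Z_i is drawn from a symmetric K-dimensional
    Dirichlet with concentration ``dirichlet_alpha`` (rows lie on the
    simplex rather than being one-hot), and P = Z B Z^T.

    Parameters
    ----------
    Z : (n, K) ndarray, optional
        Pre-drawn membership rows; when given, only the graph is sampled.

    Returns
    -------
    (GraphSample, Z) — a single-graph sample and the membership matrix used.
    """
    B = np.asarray(B, dtype=float)
    K = B.shape[0]
    if B.shape != (K, K) or not np.allclose(B, B.T):
        raise ValueError("B must be square symmetric")
    if B.min() < 0 or B.max() > 1:
        raise ValueError("B entries must lie in [0, 1]")
    if dirichlet_alpha is not None and not np.all(np.asarray(dirichlet_alpha) > 0):
        raise ValueError("dirichlet_alpha must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    z_seed, g_seed = ss.spawn(2)
    if Z is None:
        rng = np.random.default_rng(z_seed)
        Z = rng.dirichlet(np.full(K, float(dirichlet_alpha)), size=n)
    else:
        Z = np.asarray(Z, dtype=float)
    P = Z @ B @ Z.T
    sample = sample_bernoulli_graphs([P], g_seed)
    return sample, Z


# --------------------------------------------------------------------------
# Named scenarios
#
# Each scenario bundles the parameter values of a benchmark configuration:
# block-connectivity matrices, vertex counts and class labels are fixed at
# registered defaults so that downstream estimation, clustering and testing
# code can be exercised on a reproducible family of ensembles.

#: 3-community homogeneous connectivity (all graphs identical).
B_HOMO_3BLOCK = np.array([[0.4, 0.1, 0.1], [0.1, 0.4, 0.2], [0.1, 0.2, 0.3]])

#: 2-community four-class perturbations: B^(i) = 0.25*11^T + alpha*C^(class).
C_FOUR_CLASS = [
    np.array([[0.1, 0.0], [0.0, 0.1]]),
    np.array([[-0.1, 0.0], [0.0, -0.1]]),
    np.array([[0.1, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 0.1]]),
]

#: 3-community base connectivity for the two-sample testing scenarios.
B_MMSBM = 0.3 * np.eye(3) + 0.1 * np.ones((3, 3))


@dataclass
class ScenarioSpec:
    """A registered scenario name plus parameter overrides."""

    name: str
    params: dict = field(default_factory=dict)


def _balanced_Z(n, K):
    if n % K:
        raise ValueError(f"n={n} not divisible by K={K} for balanced blocks")
    Z = np.zeros((n, K))
    labels = np.repeat(np.arange(K), n // K)
    Z[np.arange(n), labels] = 1.0
    return Z


def _scenario_homo_3block(n=729, m=4, seed=0):
    """All graphs share the 3-block connectivity B_HOMO_3BLOCK."""
    Z = _balanced_Z(n, 3)
    params = SbmParams(Z=Z, B_list=[B_HOMO_3BLOCK.copy() for _ in range(m)])
    return params, sample_multilayer_sbm(params, seed)


def _scenario_hetero_3block(n=729, m=4, seed=0):
    """Each graph draws its own symmetric B^(i) with U(0,1) entries."""
    Z = _balanced_Z(n, 3)
    ss = np.random.SeedSequence([int(seed), 0x0B])
    rng = np.random.default_rng(ss)
    B_list = []
    for _ in range(m):
        b = rng.uniform(size=(3, 3))
        B = np.triu(b) + np.triu(b, 1).T
        B_list.append(B)
    params = SbmParams(Z=Z, B_list=B_list)
    return params, sample_multilayer_sbm(params, seed)


def _scenario_four_class(n=256, m=40, alpha=1.0, seed=0):
    """2-block multilayer SBM with four graph classes.

    B^(i) = 0.25*11^T + alpha*C^(y_i); graphs 1..m/4 are class 1, the next
    m/4 class 2, and so on.  alpha controls class separation and, at 0,
    collapses all classes onto the rank-1 matrix 0.25*11^T.
    """
    if m % 4:
        raise ValueError("four-class scenario needs m divisible by 4")
    Z = _balanced_Z(n, 2)
    labels = np.repeat(np.arange(1, 5), m // 4)
    base = 0.25 * np.ones((2, 2))
    B_list = [base + alpha * C_FOUR_CLASS[y - 1] for y in labels]
    params = SbmParams(Z=Z, B_list=B_list)
    sample = sample_multilayer_sbm(params, seed)
    sample.graph_ids = [f"class{y}_{i}" for i, y in enumerate(labels)]
    return (params, labels), sample


def _scenario_mmsbm_pair_a(n=300, b11_shift=0.0, dirichlet_alpha=0.1, seed=0):
    """Two mixed-membership graphs: same memberships, shifted connectivity.

    Graph 1 uses B^(1) = 0.3I + 0.1*11^T; graph 2 increases the (1,1) block
    probability by ``b11_shift``.  b11_shift = 0 is the equal-distribution
    null.
    """
    B1 = B_MMSBM.copy()
    B2 = B1.copy()
    B2[0, 0] += b11_shift
    if B2[0, 0] > 1:
        raise ValueError("b11_shift pushes the block probability above 1")
    ss = np.random.SeedSequence([int(seed), 0xA])
    s1, s2, sz = ss.spawn(3)
    rng = np.random.default_rng(sz)
    Z = rng.dirichlet(np.full(3, dirichlet_alpha), size=n)
    g1, _ = sample_mmsbm(n, B1, dirichlet_alpha, s1, Z=Z)
    g2, _ = sample_mmsbm(n, B2, dirichlet_alpha, s2, Z=Z)
    sample = GraphSample(adjacency=[g1.adjacency[0], g2.adjacency[0]])
    return {"B1": B1, "B2": B2, "Z": Z}, sample


def _scenario_mmsbm_pair_b(n=300, t=None, dirichlet_alpha=0.1, seed=0):
    """Two mixed-membership graphs: same connectivity, t memberships resampled.

    The first t vertices of graph 2 draw fresh Dirichlet membership rows;
    the remaining n - t rows are shared with graph 1.  Default t = n // 2.
    """
    if t is None:
        t = n // 2
    B = B_MMSBM.copy()
    ss = np.random.SeedSequence([int(seed), 0xB])
    s1, s2, sz1, sz2 = ss.spawn(4)
    rng1 = np.random.default_rng(sz1)
    rng2 = np.random.default_rng(sz2)
    Z1 = rng1.dirichlet(np.full(3, dirichlet_alpha), size=n)
    Z2 = Z1.copy()
    Z2[:t] = rng2.dirichlet(np.full(3, dirichlet_alpha), size=t)
    g1, _ = sample_mmsbm(n, B, dirichlet_alpha, s1, Z=Z1)
    g2, _ = sample_mmsbm(n, B, dirichlet_alpha, s2, Z=Z2)
    sample = GraphSample(adjacency=[g1.adjacency[0], g2.adjacency[0]])
    return {"B": B, "Z1": Z1, "Z2": Z2, "t": t}, sample


SCENARIOS = {
    "homo-3block": _scenario_homo_3block,
    "hetero-3block": _scenario_hetero_3block,
    "four-class": _scenario_four_class,
    "mmsbm-pair-a": _scenario_mmsbm_pair_a,
    "mmsbm-pair-b": _scenario_mmsbm_pair_b,
}


def make_scenario(spec: ScenarioSpec):
    """Instantiate a registered scenario.

    Returns ``(parameters, GraphSample)``; the parameter object is
    scenario-specific (an :class:`SbmParams`, a ``(SbmParams, labels)``
    pair, or a dict of model matrices for the mixed-membership pairs).
    """
    if spec.name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {spec.name!r}; registered: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[spec.name](**spec.params)
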