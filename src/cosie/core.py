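"""Core parameter containers for the common subspace independent-edge
(COSIE) model and the multilayer stochastic blockmodel (SBM).

A COSIE ensemble of ``m`` graphs on ``n`` aligned vertices is parameterised
by a shared basis ``V`` (n x d, orthonormal columns) and per-graph symmetric
score matrices ``R^(i)`` (d x d), inducing edge-probability matrices
``P^(i) = V R^(i) V^T``.  The multilayer SBM fixes a community partition
``Z`` (n x K, one-hot rows) shared across graphs and lets each graph carry
its own block-connectivity matrix ``B^(i)``; it is an exact sub-model of
COSIE, and :func:`sbm_to_cosie` performs the embedding constructively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CosieParams",
    "SbmParams",
    "GraphSample",
    "ValidationReport",
    "build_probability_matrices",
    "sbm_to_cosie",
    "validate_cosie",
    "delta_max_row_sum",
    "epsilon_stat",
]

#: Default floating-point slack on probability-range checks.
PROB_TOL = 1e-12

#: Relative singular-value threshold used for numerical rank decisions.
RANK_RTOL = 1e-10


def _as_matrix_list(mats) -> list[np.ndarray]:
    return [np.asarray(M, dtype=float) for M in mats]


@dataclass
class CosieParams:
    """Parameters of a COSIE ensemble: shared subspace + per-graph scores.

    Parameters
    ----------
    V : (n, d) ndarray
        Basis of the common invariant subspace; columns must be orthonormal.
    R_list : list of (d, d) ndarray
        Symmetric score matrices, one per graph.  Individual scores may be
        rank deficient; only the joint ensemble needs rank ``d``.
    """

    V: np.ndarray
    R_list: list[np.ndarray]

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.R_list = _as_matrix_list(self.R_list)
        if self.V.ndim != 2:
            raise ValueError("V must be a 2-d array")
        for R in self.R_list:
            if R.shape != (self.d, self.d):
                raise ValueError(
                    f"score matrix shape {R.shape} does not match d={self.d}"
                )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def d(self) -> int:
        return self.V.shape[1]

    @property
    def m(self) -> int:
        return len(self.R_list)


@dataclass
class SbmParams:
    """Parameters of a multilayer SBM: one partition, per-graph connectivity.

    Parameters
    ----------
    Z : (n, K) ndarray
        One-hot membership matrix (exactly one 1 per row).
    B_list : list of (K, K) ndarray
        Symmetric block-connectivity matrices with entries in [0, 1].
    """

    Z: np.ndarray
    B_list: list[np.ndarray]

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        self.B_list = _as_matrix_list(self.B_list)
        if self.Z.ndim != 2:
            raise ValueError("Z must be a 2-d array")
        rowsums = self.Z.sum(axis=1)
        if not np.all((self.Z == 0) | (self.Z == 1)) or not np.all(rowsums == 1):
            raise ValueError("Z must have one-hot rows")
        if np.any(self.community_sizes == 0):
            raise ValueError("every community must be nonempty")
        for B in self.B_list:
            B = np.asarray(B)
            if B.shape != (self.K, self.K):
                raise ValueError("B shape does not match K")
            if not np.allclose(B, B.T):
                raise ValueError("each B must be symmetric")
            if B.min() < -PROB_TOL or B.max() > 1 + PROB_TOL:
                raise ValueError("B entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    @property
    def m(self) -> int:
        return len(self.B_list)

    @property
    def community_sizes(self) -> np.ndarray:
        return self.Z.sum(axis=0).astype(int)

    @property
    def Xi(self) -> np.ndarray:
        """Diagonal matrix of community sizes, diag(n_1, ..., n_K)."""
        return np.diag(self.community_sizes.astype(float))

    @property
    def labels(self) -> np.ndarray:
        """Integer community label per vertex (argmax over one-hot rows)."""
        return np.argmax(self.Z, axis=1)


@dataclass
class GraphSample:
    """A sample of m adjacency matrices on a common, aligned vertex set.

    Matrices are symmetric and hollow (zero diagonal); binary {0, 1} unless
    the sample was read in weighted mode, in which case entries are
    nonnegative reals.
    """

    adjacency: list[np.ndarray]
    vertex_ids: list | None = None
    graph_ids: list | None = None

    def __post_init__(self):
        self.adjacency = _as_matrix_list(self.adjacency)
        n = self.n
        for A in self.adjacency:
            if A.shape != (n, n):
                raise ValueError("all graphs must share the vertex set")
        if self.vertex_ids is None:
            self.vertex_ids = list(range(n))
        if self.graph_ids is None:
            self.graph_ids = list(range(self.m))

    @property
    def n(self) -> int:
        return self.adjacency[0].shape[0]

    @property
    def m(self) -> int:
        return len(self.adjacency)


@dataclass
class ValidationReport:
    """Structured defect report for a set of COSIE parameters."""

    orthonormality_defect: float
    asymmetry_defect: float
    range_violation: float
    ok: bool = field(init=False)

    def __post_init__(self):
        self.ok = (
            self.orthonormality_defect < 1e-8
            and self.asymmetry_defect < 1e-8
            and self.range_violation <= PROB_TOL
        )


def build_probability_matrices(params: CosieParams) -> list[np.ndarray]:
    """Form the edge-probability matrices P^(i) = V R^(i) V^T.

    Raises
    ------
    ValueError
        If any resulting entry falls outside [0, 1] beyond floating-point
        tolerance, i.e. the parameters are not a valid probability model.
    """
    report = validate_cosie(params)
    if report.range_violation > PROB_TOL:
        raise ValueError(
            "V R V^T has entries outside [0, 1] "
            f"(worst violation {report.range_violation:.3e})"
        )
    V = params.V
    out = []
    for R in params.R_list:
        P = V @ R @ V.T
        P = (P + P.T) / 2.0
        out.append(np.clip(P, 0.0, 1.0))
    return out


def sbm_to_cosie(params: SbmParams, rank_rtol: float | None = None) -> CosieParams:
    """Embed a multilayer SBM exactly into the COSIE parameterisation.

    With community sizes Xi = diag(n_1,...,n_K), the scaled blocks
    ``Xi^{1/2} B^(i) Xi^{1/2}`` are concatenated into a K x (mK) matrix; an
    orthonormal basis ``W`` (K x d) of its column space gives

        V = Z Xi^{-1/2} W,    R^(i) = W^T Xi^{1/2} B^(i) Xi^{1/2} W,

    which satisfies ``V^T V = I`` and ``V R^(i) V^T = Z B^(i) Z^T`` exactly.
    The joint dimension d is the numerical rank of the concatenation and is
    at most K; it can exceed the rank of every individual B^(i).
    """
    K, m = params.K, params.m
    sizes = params.community_sizes.astype(float)
    xi_half = np.sqrt(sizes)
    scaled = [xi_half[:, None] * B * xi_half[None, :] for B in params.B_list]
    concat = np.hstack(scaled)
    U, s, _ = np.linalg.svd(concat, full_matrices=False)
    if rank_rtol is None:
        tol = max(K, m * K) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    else:
        tol = rank_rtol * (s[0] if s.size else 0.0)
    d = max(int(np.sum(s > tol)), 1)
    W = U[:, :d]
    V = (params.Z / xi_half[None, :]) @ W
    R_list = [W.T @ S @ W for S in scaled]
    R_list = [(R + R.T) / 2.0 for R in R_list]
    return CosieParams(V=V, R_list=R_list)


def validate_cosie(params: CosieParams) -> ValidationReport:
    """Report (without raising) how far parameters deviate from validity.

    Checks orthonormality of V's columns, symmetry of each score matrix,
    and the probability-range constraint 0 <= (V R V^T)_uv <= 1.
    """
    V = params.V
    # largest deviation of V's singular values from 1: a column scaled by c
    # contributes |c - 1|, exactly orthonormal columns contribute 0
    sv = np.linalg.svd(V, compute_uv=False)
    ortho = float(np.abs(sv - 1.0).max())
    asym = 0.0
    range_violation = 0.0
    for R in params.R_list:
        asym = max(asym, float(np.abs(R - R.T).max()))
        P = V @ R @ V.T
        range_violation = max(
            range_violation,
            float(max(0.0, P.max() - 1.0)),
            float(max(0.0, -P.min())),
        )
    return ValidationReport(
        orthonormality_defect=ortho,
        asymmetry_defect=asym,
        range_violation=range_violation,
    )


def delta_max_row_sum(P: np.ndarray) -> float:
    """Maximum row sum delta(P) — the largest expected degree of P."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("delta_max_row_sum expects a square matrix")
    return float(P.sum(axis=1).max())


def epsilon_stat(P_list, R_list, tol: float = 1e-12) -> float:
    """Per-graph spectral-embedding error scale of the ensemble.

    epsilon = (1/m) * sum_i delta(P^(i)) / lambda_min(R^(i))^2, with
    lambda_min the smallest-magnitude eigenvalue.  This is the quantity
    controlling the subspace estimation error of the joint embedding: it
    averages, over graphs, the ratio of maximum expected degree to the
    squared spectral floor of the score matrix.

    Raises
    ------
    ValueError
        If the lists differ in length or any score matrix is singular.
    """
    P_list = _as_matrix_list(P_list)
    R_list = _as_matrix_list(R_list)
    if len(P_list) != len(R_list):
        raise ValueError("P_list and R_list must have equal length")
    total = 0.0
    for P, R in zip(P_list, R_list):
        lam = np.linalg.eigvalsh((R + R.T) / 2.0)
        lam_min = float(np.abs(lam).min())
        scale = float(np.abs(lam).max())
        if lam_min <= tol * max(scale, 1.0):
            raise ValueError("score matrix is singular within tolerance")
        total += delta_max_row_sum(P) / lam_min**2
    return total / len(P_list)
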