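"""Multiple adjacency spectral embedding (MASE).

Given m graphs A^(1..m) on n aligned vertices, MASE estimates the common
invariant subspace and per-graph score matrices of the COSIE model:

1. embed each graph separately (ASE on d_i dimensions, unscaled V-hat or
   scaled X-hat variant);
2. concatenate the embeddings column-wise into U-hat (n x sum d_i);
3. take the d leading left singular vectors of U-hat as V-hat — the SVD
   aligns the per-graph embeddings, which are each only defined up to an
   orthogonal transformation;
4. score each graph in the common frame: R-hat^(i) = V-hat^T A^(i) V-hat,
   the least-squares minimiser of ||A^(i) - V-hat R V-hat^T||_F.

The subspace estimate averages information across graphs, so its error
shrinks as m grows even when the graphs have heterogeneous expectations —
unlike embedding the mean adjacency matrix, which requires identically
distributed graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GraphSample
from .embed import ase, fix_signs, select_dim_elbow

__all__ = [
    "MaseFit",
    "mase_fit",
    "score_matrices",
    "reconstruct_P",
    "out_of_sample_score",
    "procrustes_align",
    "subspace_distance",
]


@dataclass
class MaseFit:
    """Fitted MASE parameters for a graph ensemble."""

    V_hat: np.ndarray
    R_hat_list: list[np.ndarray]
    d_i_list: list[int]
    variant: str
    joint_singular_values: np.ndarray

    @property
    def n(self) -> int:
        return self.V_hat.shape[0]

    @property
    def d(self) -> int:
        return self.V_hat.shape[1]

    @property
    def m(self) -> int:
        return len(self.R_hat_list)


def _as_adjacency_list(graphs) -> list[np.ndarray]:
    if isinstance(graphs, GraphSample):
        return graphs.adjacency
    return [np.asarray(A, dtype=float) for A in graphs]


def mase_fit(
    graphs,
    d: int | None = None,
    d_i_list=None,
    variant: str = "unscaled",
    elbow: int = 1,
) -> MaseFit:
    """Fit the COSIE model to a graph ensemble by joint spectral embedding.

    Parameters
    ----------
    graphs : GraphSample or list of symmetric (n, n) arrays
    d : joint embedding dimension; selected by the profile-likelihood
        elbow on the singular values of the concatenated embeddings when
        omitted.
    d_i_list : per-graph embedding dimensions; defaults to d for every
        graph when d is given, otherwise each is selected by the elbow of
        that graph's eigenvalue-magnitude scree.
    variant : "unscaled" (eigenvectors only; the theoretically analysed
        choice) or "scaled" (eigenvalue-weighted positions, which can
        help when d_i is overestimated).
    elbow : which elbow of each scree to use when selecting dimensions.
    """
    A_list = _as_adjacency_list(graphs)
    m = len(A_list)
    if m < 1:
        raise ValueError("need at least one graph")
    n = A_list[0].shape[0]
    for A in A_list:
        if A.shape != (n, n):
            raise ValueError("graphs must share the vertex set")
    if variant not in ("unscaled", "scaled"):
        raise ValueError("variant must be 'unscaled' or 'scaled'")

    if d_i_list is None:
        if d is not None:
            d_i_list = [min(d, n)] * m
        else:
            d_i_list = []
            for A in A_list:
                k = min(n - 1, max(2, n // 2))
                res = ase(A, k)
                mags = np.abs(res.eigvals)
                d_i_list.append(select_dim_elbow(mags[mags > 0], which=elbow)
                                if np.any(mags > 0) else 1)
    else:
        d_i_list = [int(di) for di in d_i_list]
    for di in d_i_list:
        if not 1 <= di <= n:
            raise ValueError("each d_i must lie in [1, n]")

    blocks = []
    for A, di in zip(A_list, d_i_list):
        res = ase(A, di, scaled=(variant == "scaled"))
        blocks.append(res.scaled_positions if variant == "scaled" else res.eigvecs)
    U_hat = np.hstack(blocks)

    svecs, svals, _ = np.linalg.svd(U_hat, full_matrices=False)
    if d is None:
        pos = svals[svals > svals[0] * 1e-12] if svals.size else svals
        d = select_dim_elbow(pos, which=elbow) if pos.size else 1
    if d > sum(d_i_list):
        raise ValueError("d cannot exceed the total per-graph dimensions")
    rank = int(np.sum(svals > svals[0] * 1e-10)) if svals.size else 0
    if d > rank:
        warnings.warn(
            f"requested d={d} exceeds the numerical rank {rank} of the "
            "concatenated embeddings"
        )
    V_hat = fix_signs(svecs[:, :d])
    R_hat_list = score_matrices(V_hat, A_list)
    return MaseFit(
        V_hat=V_hat,
        R_hat_list=R_hat_list,
        d_i_list=list(d_i_list),
        variant=variant,
        joint_singular_values=svals,
    )


def score_matrices(V_hat: np.ndarray, graphs) -> list[np.ndarray]:
    """Project each graph into the common frame: R^(i) = V^T A^(i) V.

    For V with orthonormal columns this is the closed-form least-squares
    minimiser of ||A - V R V^T||_F over symmetric R.  Output is
    symmetrised to absorb floating-point asymmetry.
    """
    V_hat = np.asarray(V_hat, dtype=float)
    out = []
    for A in _as_adjacency_list(graphs):
        if A.shape[0] != V_hat.shape[0]:
            raise ValueError("graph size does not match the subspace basis")
        R = V_hat.T @ A @ V_hat
        out.append((R + R.T) / 2.0)
    return out


def reconstruct_P(fit: MaseFit, mode: str = "raw") -> list[np.ndarray]:
    """Reconstruct edge-probability estimates P^(i) = V R^(i) V^T.

    mode="probability" clips entries to [0, 1]; "raw" returns the
    unclipped low-rank reconstruction.
    """
    if mode not in ("raw", "probability"):
        raise ValueError("mode must be 'raw' or 'probability'")
    out = []
    for R in fit.R_hat_list:
        P = fit.V_hat @ R @ fit.V_hat.T
        P = (P + P.T) / 2.0
        if mode == "probability":
            P = np.clip(P, 0.0, 1.0)
        out.append(P)
    return out


def out_of_sample_score(V_hat: np.ndarray, A_new: np.ndarray) -> np.ndarray:
    """Score a new graph in an already-fitted common frame, without refitting."""
    return score_matrices(V_hat, [A_new])[0]


def procrustes_align(V_hat: np.ndarray, V_ref: np.ndarray) -> np.ndarray:
    """Orthogonal W minimising ||V_hat - V_ref W||_F.

    Computed from the SVD of V_ref^T V_hat = U S Q^T as W = U Q^T.
    Resolves the rotational non-identifiability of the subspace basis
    before estimates are compared with a reference.
    """
    V_hat = np.asarray(V_hat, dtype=float)
    V_ref = np.asarray(V_ref, dtype=float)
    if V_hat.shape != V_ref.shape:
        raise ValueError("shapes must match for Procrustes alignment")
    U, _, Qt = np.linalg.svd(V_ref.T @ V_hat)
    return U @ Qt


def subspace_distance(V_hat, V_ref, norm: str = "spectral") -> float:
    """Distance between column spans via the projection difference.

    ||V_hat V_hat^T - V_ref V_ref^T|| in spectral or Frobenius norm; zero
    iff the spans coincide, invariant to the basis chosen within each
    span.  The inputs may have different numbers of columns.
    """
    V_hat = np.asarray(V_hat, dtype=float)
    V_ref = np.asarray(V_ref, dtype=float)
    if V_hat.shape[0] != V_ref.shape[0]:
        raise ValueError("subspaces must live in the same ambient dimension")
    diff = V_hat @ V_hat.T - V_ref @ V_ref.T
    if norm == "spectral":
        return float(np.linalg.norm(diff, 2))
    if norm == "frobenius":
        return float(np.linalg.norm(diff, "fro"))
    raise ValueError("norm must be 'spectral' or 'frobenius'")
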