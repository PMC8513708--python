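"""Single-graph adjacency spectral embedding (ASE) and automatic
embedding-dimension selection via the profile-likelihood elbow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

__all__ = ["AseResult", "ase", "select_dim_elbow"]

#: Matrices at least this large use an iterative (Lanczos) eigensolver.
DENSE_EIG_CUTOFF = 2000


@dataclass
class AseResult:
    """Top-d eigenpairs of an adjacency matrix, ordered by |eigenvalue|.

    ``eigvecs`` (n x d) is the unscaled embedding; ``scaled_positions``
    is X = eigvecs * |eigvals|^(1/2) when the scaled variant was requested.
    ``degenerate`` flags an all-zero spectrum, where the eigenvector basis
    is arbitrary.
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    scaled_positions: np.ndarray | None = None
    degenerate: bool = False


def fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (first on ties)."""
    vecs = np.array(vecs, copy=True)
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            vecs[:, j] = -col
    return vecs


def _order_by_magnitude(vals: np.ndarray) -> np.ndarray:
    # magnitude desc, ties by signed value desc, then original index
    idx = np.arange(vals.size)
    order = sorted(idx, key=lambda i: (-np.abs(vals[i]), -vals[i], i))
    return np.asarray(order)


def ase(A: np.ndarray, d: int, scaled: bool = False, atol: float = 1e-8) -> AseResult:
    """Adjacency spectral embedding: top-d eigenpairs of A by magnitude.

    Parameters
    ----------
    A : (n, n) symmetric array
    d : embedding dimension, 1 <= d <= n
    scaled : also return X = V |D|^(1/2), the scaled positions

    A deterministic sign convention (largest-magnitude entry of each
    eigenvector positive) makes the output reproducible; the embedding is
    otherwise identifiable only up to column signs.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T, atol=atol):
        raise ValueError("A must be symmetric")
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension d={d} out of range [1, {n}]")

    if n < DENSE_EIG_CUTOFF or d > n - 2:
        vals, vecs = scipy.linalg.eigh((A + A.T) / 2.0)
        order = _order_by_magnitude(vals)[:d]
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = scipy.sparse.linalg.eigsh(
            (A + A.T) / 2.0, k=d, which="LM", v0=np.ones(n) / np.sqrt(n)
        )
        order = _order_by_magnitude(vals)
        vals, vecs = vals[order], vecs[:, order]

    vecs = fix_signs(vecs)
    degenerate = bool(np.allclose(vals, 0.0))
    if degenerate:
        warnings.warn("all retained eigenvalues are zero; embedding is arbitrary")
    scaled_pos = vecs * np.sqrt(np.abs(vals))[None, :] if scaled else None
    return AseResult(
        eigvecs=vecs, eigvals=vals, scaled_positions=scaled_pos, degenerate=degenerate
    )


def _profile_loglik(values: np.ndarray, q: int) -> float:
    """Gaussian profile log-likelihood of splitting values at position q.

    Both segments share one pooled variance; degenerate (zero-variance)
    splits get variance floored at a tiny epsilon so that constant inputs
    do not produce NaNs.
    """
    head, tail = values[:q], values[q:]
    mu1 = head.mean()
    mu2 = tail.mean() if tail.size else 0.0
    ss = ((head - mu1) ** 2).sum() + (((tail - mu2) ** 2).sum() if tail.size else 0.0)
    var = ss / values.size
    var = max(var, np.finfo(float).tiny * max(values[0] ** 2, 1.0))
    n = values.size
    return float(-0.5 * n * np.log(2 * np.pi * var) - 0.5 * ss / var)


def select_dim_elbow(values, n_elbows: int = 2, which: int = 1) -> int:
    """Pick an embedding dimension at an elbow of a scree of values.

    The elbow is the split point maximising a two-segment equal-variance
    Gaussian profile likelihood of the ordered values; with
    ``n_elbows > 1`` the search recurses on the values past the previous
    elbow, and ``which`` selects which elbow to return (the first by
    default).

    Parameters
    ----------
    values : nonincreasing positive sequence (singular or eigenvalues)
    n_elbows : how many successive elbows to locate
    which : 1-based elbow to report (clamped to the elbows found)

    Returns
    -------
    int — the selected dimension (count of values up to the chosen elbow).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("need at least one value")
    if values.size == 1:
        return 1
    if np.allclose(values, values[0]):
        warnings.warn("scree is constant; no elbow information, returning 1")
        return 1

    elbows = []
    offset = 0
    seg = values
    for _ in range(max(1, n_elbows)):
        if seg.size < 2:
            break
        lls = [_profile_loglik(seg, q) for q in range(1, seg.size + 1)]
        q = int(np.argmax(lls)) + 1
        elbows.append(offset + q)
        if q >= seg.size:
            break
        offset += q
        seg = seg[q:]
        if np.allclose(seg, seg[0]):
            break
    k = min(max(which - 1, 0), len(elbows) - 1)
    return elbows[k]
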