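"""Incomplete-network-alignment (iNEAT) stage.

Combines a Frobenius graph-matching objective ``||A2 - S^T A1 S||_F^2`` with a
Kronecker-product random-walk similarity fixed point

    s = alpha (A1 (x) A2) s + (1 - alpha) h,

where ``h`` is the vectorized prior similarity between group-mean adjacency
rows, solved with implicit Kronecker products (never materialising the
n^2 x n^2 operator).  A permutation is read off the similarity matrix by
maximum-weight linear assignment and used to reorganise channels.

Adjacencies are row-normalised (random-walk form) before the fixed point so
the iteration contracts for any alpha < 1.  Vectorization is column-major
(``order="F"``), matching the identity (A (x) B) vec(X) = vec(B X A^T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import EpochSet
from .errors import ConvergenceError, InvalidArgumentError

__all__ = [
    "matching_objective",
    "row_normalize",
    "build_prior",
    "kronecker_fixed_point",
    "ineat_objective",
    "extract_permutation",
    "reorganize_channels",
    "AlignmentResult",
    "align_graphs",
]


def matching_objective(S: np.ndarray, A1: np.ndarray, A2: np.ndarray) -> float:
    """Topology-consistency mismatch ||A2 - S^T A1 S||_F^2."""
    S, A1, A2 = (np.asarray(m, float) for m in (S, A1, A2))
    if S.shape[0] != A1.shape[0] or S.shape[1] != A2.shape[0]:
        raise InvalidArgumentError("S must map A1 nodes (rows) to A2 nodes (columns)")
    return float(np.linalg.norm(A2 - S.T @ A1 @ S, ord="fro") ** 2)


def row_normalize(A: np.ndarray) -> np.ndarray:
    """Random-walk normalization D^{-1} A; zero-degree rows stay zero."""
    A = np.asarray(A, float)
    deg = A.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(deg > 0, A / deg, 0.0)
    return out


def build_prior(meanA_group0: np.ndarray, meanA_group1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prior similarity H between the two groups' mean adjacency rows.

    H_ij = sin(pi/2 * cos+(row_i(A0), row_j(A1))) with cosine similarity
    clipped to [0, 1]; H is normalised to sum 1 and h = vec(H).
    """
    A0, A1 = np.asarray(meanA_group0, float), np.asarray(meanA_group1, float)
    if A0.shape != A1.shape:
        raise InvalidArgumentError("group-mean adjacencies must have the same shape")
    n0 = np.linalg.norm(A0, axis=1)
    n1 = np.linalg.norm(A1, axis=1)
    if n0.max() == 0.0 or n1.max() == 0.0:
        warnings.warn("all-zero group-mean adjacency: falling back to a uniform prior")
        H = np.full((A0.shape[0], A1.shape[0]), 1.0)
    else:
        denom = np.outer(np.where(n0 == 0, 1.0, n0), np.where(n1 == 0, 1.0, n1))
        cos = np.clip(A0 @ A1.T / denom, 0.0, 1.0)
        H = np.sin(0.5 * np.pi * cos)
        if H.sum() == 0.0:
            warnings.warn("degenerate (all-orthogonal) prior: falling back to uniform")
            H = np.full_like(H, 1.0)
    H = H / H.sum()
    return H, H.ravel(order="F")


def _kron_apply(A1: np.ndarray, A2: np.ndarray, s: np.ndarray) -> np.ndarray:
    """(A1 (x) A2) s with s = vec(X) column-major, X of shape (n2, n1)."""
    n1, n2 = A1.shape[0], A2.shape[0]
    X = s.reshape((n2, n1), order="F")
    return (A2 @ X @ A1.T).ravel(order="F")


def kronecker_fixed_point(
    A1: np.ndarray,
    A2: np.ndarray,
    h: np.ndarray,
    alpha: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    normalize: bool = True,
) -> tuple[np.ndarray, dict]:
    """Solve s = alpha (A1 (x) A2) s + (1 - alpha) h by fixed-point iteration.

    With row-normalised adjacencies the Kronecker operator has spectral radius
    <= 1, so the iteration contracts for alpha < 1.  Returns the solution and
    an info dict with the iteration count and final residual (inf-norm).
    """
    if not (0.0 <= alpha < 1.0):
        raise InvalidArgumentError("alpha must be in [0, 1)")
    A1, A2 = np.asarray(A1, float), np.asarray(A2, float)
    h = np.asarray(h, float).ravel()
    if h.size != A1.shape[0] * A2.shape[0]:
        raise InvalidArgumentError("h must have length n1 * n2")
    if normalize:
        A1, A2 = row_normalize(A1), row_normalize(A2)
    s = h.copy()
    if alpha == 0.0:
        return s, {"iterations": 0, "residual": 0.0}
    for it in range(1, max_iter + 1):
        s_new = alpha * _kron_apply(A1, A2, s) + (1.0 - alpha) * h
        residual = float(np.abs(s_new - s).max())
        s = s_new
        if residual <= tol:
            return s, {"iterations": it, "residual": residual}
    raise ConvergenceError(
        f"Kronecker fixed point did not reach tol={tol} in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def ineat_objective(
    s: np.ndarray,
    A1: np.ndarray,
    A2: np.ndarray,
    h: np.ndarray,
    alpha: float = 0.5,
) -> float:
    """alpha s^T (D - A1 (x) A2) s + (1 - alpha) ||D^{1/2} (s - h)||^2,
    with D = D1 (x) D2, evaluated via implicit Kronecker identities."""
    A1, A2 = np.asarray(A1, float), np.asarray(A2, float)
    s = np.asarray(s, float).ravel()
    h = np.asarray(h, float).ravel()
    if s.size != A1.shape[0] * A2.shape[0] or h.size != s.size:
        raise InvalidArgumentError("s and h must have length n1 * n2")
    d1 = A1.sum(axis=1)
    d2 = A2.sum(axis=1)
    d = np.multiply.outer(d1, d2).ravel(order="F")  # diag(D1 (x) D2), vec-consistent
    quad = float(s @ (d * s) - s @ _kron_apply(A1, A2, s))
    diff = s - h
    prior = float(diff @ (d * diff))
    return alpha * quad + (1.0 - alpha) * prior


def extract_permutation(S: np.ndarray) -> np.ndarray:
    """Maximum-weight linear assignment on S, returned as a 0/1 permutation
    matrix P maximising sum_ij S_ij P_ij.  Ties resolve deterministically
    (row-major, via the Hungarian algorithm's fixed scan order)."""
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidArgumentError("S must be square")
    if (S < 0).any():
        raise InvalidArgumentError("S must be nonnegative")
    rows, cols = linear_sum_assignment(-S)
    P = np.zeros_like(S)
    P[rows, cols] = 1.0
    return P


def reorganize_channels(obj: EpochSet | np.ndarray, P: np.ndarray):
    """Apply a channel permutation.

    Epochs: channel axis is permuted (x' = P x per sample).  Square matrices
    (connectivity/adjacency): rows and columns are permuted (W' = P W P^T).
    """
    P = np.asarray(P, float)
    n = P.shape[0]
    if isinstance(obj, EpochSet):
        if obj.n_channels != n:
            raise InvalidArgumentError("permutation size does not match channel count")
        perm = np.argmax(P, axis=1)
        labels = (
            [obj.channel_labels[j] for j in perm] if obj.channel_labels else []
        )
        out = obj.with_data(obj.data[:, perm, :])
        out.channel_labels = labels
        return out
    M = np.asarray(obj, float)
    if M.ndim == 2 and M.shape == (n, n):
        return P @ M @ P.T
    raise InvalidArgumentError("object must be an EpochSet or an n x n matrix")


@dataclass
class AlignmentResult:
    S: np.ndarray
    s: np.ndarray
    P: np.ndarray
    alpha: float
    matching_value: float
    objective_value: float
    iterations: int
    residual: float


def align_graphs(
    A1: np.ndarray,
    A2: np.ndarray,
    h: np.ndarray,
    alpha: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> AlignmentResult:
    """Full iNEAT pass for one subject: fixed point -> S -> permutation."""
    n = A1.shape[0]
    s, info = kronecker_fixed_point(A1, A2, h, alpha=alpha, tol=tol, max_iter=max_iter)
    S = s.reshape((A2.shape[0], n), order="F").T  # S maps A1 rows to A2 columns
    P = extract_permutation(S)
    return AlignmentResult(
        S=S,
        s=s,
        P=P,
        alpha=alpha,
        matching_value=matching_objective(P, A1, A2),
        objective_value=ineat_objective(s, A1, A2, h, alpha),
        iterations=info["iterations"],
        residual=info["residual"],
    )
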