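"""Chebyshev spectral graph-convolutional classifier.

Graph signals live on the channel graph; convolution is a truncated Chebyshev
polynomial filter y = sum_k theta_k T_k(L~) x on the scaled Laplacian
L~ = 2 L / lambda_max - I, evaluated by the three-term recursion so no
eigendecomposition is ever needed at run time (the spectral form
U g(Lambda) U^T x exists here only as a test oracle via ``spectrum``).

Architecture (parameter counts parametrised by the Chebyshev orders K1, K2):

    conv1  (K1, 64 -> 64) + ReLU        4096 K1 + 64 parameters
    pool1  node coarsening 1/2 (64 -> 32 nodes, parameter-free)
    conv2  (K2, 64 -> 32) + ReLU        2048 K2 + 32
    pool2  node coarsening 1/2 (32 -> 16 nodes)
    global mean over nodes -> 32
    fc     32 -> 32 + ReLU              1056
    out    32 -> M, softmax

Node input features are the subject's reorganised 64-dim connectivity rows.
The network is trained with full-batch Adam on the cross-entropy loss; the
forward/backward passes are explicit numpy so the guided-backprop gradient
overwrite is a first-class code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "laplacian",
    "spectrum",
    "GraphSpectrum",
    "graph_fourier",
    "inverse_fourier",
    "estimate_lmax",
    "scaled_laplacian",
    "cheb_filter",
    "coarsen",
    "ChebGCN",
    "SubjectInput",
    "prepare_subject",
    "cross_entropy",
    "train_model",
    "cross_validate",
    "evaluate",
    "auc_rank",
    "compare_models",
]


# ---------------------------------------------------------------------------
# graph spectra


def laplacian(A: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Combinatorial L = D - A or normalized L = I - D^{-1/2} A D^{-1/2}.

    Zero-degree (isolated) nodes get D^{-1/2} = 0, leaving a unit diagonal
    entry in the normalized form.
    """
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidArgumentError("A must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise InvalidArgumentError("A must be symmetric")
    if (A < 0).any() or np.abs(np.diag(A)).max(initial=0.0) > 1e-12:
        raise InvalidArgumentError("A must be nonnegative with zero diagonal")
    deg = A.sum(axis=1)
    if not normalized:
        return np.diag(deg) - A
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return np.eye(A.shape[0]) - (dinv[:, None] * A) * dinv[None, :]


@dataclass
class GraphSpectrum:
    """Eigendecomposition of a Laplacian (test oracle / Fourier basis)."""

    L: np.ndarray
    U: np.ndarray
    eigenvalues: np.ndarray
    L_scaled: np.ndarray


def spectrum(A: np.ndarray, normalized: bool = True) -> GraphSpectrum:
    L = laplacian(A, normalized=normalized)
    lam, U = np.linalg.eigh(L)
    return GraphSpectrum(L=L, U=U, eigenvalues=lam, L_scaled=scaled_laplacian(L, lam[-1]))


def graph_fourier(x: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Graph Fourier transform chi = U^T x."""
    x = np.asarray(x, float)
    if x.shape[0] != U.shape[0]:
        raise InvalidArgumentError("signal length must match the Fourier basis")
    return U.T @ x


def inverse_fourier(chi: np.ndarray, U: np.ndarray) -> np.ndarray:
    chi = np.asarray(chi, float)
    if chi.shape[0] != U.shape[1]:
        raise InvalidArgumentError("spectrum length must match the Fourier basis")
    return U @ chi


def estimate_lmax(L: np.ndarray, tol: float = 1e-6, max_iter: int = 10_000) -> float:
    """Largest Laplacian eigenvalue by power iteration (L is PSD, so the
    dominant eigenvalue is lambda_max)."""
    n = L.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        w = L @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        v_new = w / norm
        lam_new = float(v_new @ L @ v_new)
        if abs(lam_new - lam) <= tol * max(1.0, abs(lam_new)):
            return lam_new
        v, lam = v_new, lam_new
    return lam


def scaled_laplacian(L: np.ndarray, lmax: float | None = None) -> np.ndarray:
    """L~ = 2 L / lambda_max - I, mapping the spectrum into [-1, 1]."""
    if lmax is None:
        lmax = estimate_lmax(L)
    if lmax <= 0:
        return -np.eye(L.shape[0])  # edgeless graph: L = 0
    return 2.0 * L / lmax - np.eye(L.shape[0])


def cheb_filter(x: np.ndarray, L_scaled: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """y = sum_{k=0}^{K-1} theta_k T_k(L~) x via the recursion
    T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2}."""
    theta = np.atleast_1d(np.asarray(theta, float))
    if theta.size < 1:
        raise InvalidArgumentError("need at least one Chebyshev coefficient (K >= 1)")
    x = np.asarray(x, float)
    t_prev, t_cur = x, None
    y = theta[0] * x
    for k in range(1, theta.size):
        t_new = L_scaled @ t_prev if k == 1 else 2.0 * (L_scaled @ t_cur) - t_prev
        if k == 1:
            t_cur = t_new
        else:
            t_prev, t_cur = t_cur, t_new
        y = y + theta[k] * t_cur
    return y


def _cheb_basis(L_scaled: np.ndarray, K: int) -> np.ndarray:
    """Stack [T_0(L~), ..., T_{K-1}(L~)] as a (K, n, n) array."""
    n = L_scaled.shape[0]
    T = np.empty((K, n, n))
    T[0] = np.eye(n)
    if K > 1:
        T[1] = L_scaled
    for k in range(2, K):
        T[k] = 2.0 * L_scaled @ T[k - 1] - T[k - 2]
    return T


# ---------------------------------------------------------------------------
# pooling / coarsening


def coarsen(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Halve the node set by greedy heavy-edge matching.

    Nodes are paired along their heaviest untouched edge (ties by lower index
    pair); leftover nodes are paired by ascending index so the cluster count
    is ceil(n/2).  Returns (pooled adjacency, mean-pooling matrix C) with
    A' = B A B^T for the binary assignment B and C the row-normalised B.
    """
    A = np.asarray(A, float)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = A[iu, ju]
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
    matched = np.full(n, -1, dtype=int)
    pairs: list[tuple[int, int]] = []
    for idx in order:
        if w[idx] <= 0:
            break
        i, j = int(iu[idx]), int(ju[idx])
        if matched[i] < 0 and matched[j] < 0:
            matched[i] = j
            matched[j] = i
            pairs.append((i, j))
    leftovers = [i for i in range(n) if matched[i] < 0]
    for a, b in zip(leftovers[::2], leftovers[1::2]):
        pairs.append((a, b))
    clusters: list[tuple[int, ...]] = [tuple(p) for p in pairs]
    if len(leftovers) % 2:
        clusters.append((leftovers[-1],))
    clusters.sort(key=lambda c: c[0])
    m = len(clusters)
    B = np.zeros((m, n))
    C = np.zeros((m, n))
    for ci, members in enumerate(clusters):
        for node in members:
            B[ci, node] = 1.0
            C[ci, node] = 1.0 / len(members)
    A_pooled = B @ A @ B.T
    np.fill_diagonal(A_pooled, 0.0)
    return A_pooled, C


# ---------------------------------------------------------------------------
# model


@dataclass
class SubjectInput:
    """Per-subject graph data prepared for the network: node features plus
    Chebyshev bases and pooling operators for both coarsening levels."""

    X: np.ndarray  # (n_nodes, n_features)
    T0: np.ndarray  # (K1, n0, n0)
    T1: np.ndarray  # (K2, n1, n1)
    C1: np.ndarray  # (n1, n0) mean pooling
    C2: np.ndarray  # (n2, n1)
    subject_id: str = ""


def prepare_subject(
    A: np.ndarray,
    X: np.ndarray,
    K1: int,
    K2: int,
    subject_id: str = "",
    lmax_tol: float = 1e-6,
) -> SubjectInput:
    """Build the two-level Chebyshev/pooling structure from an adjacency."""
    L0 = laplacian(A, normalized=True)
    Ls0 = scaled_laplacian(L0, estimate_lmax(L0, tol=lmax_tol))
    A1, C1 = coarsen(A)
    L1 = laplacian(A1, normalized=True)
    Ls1 = scaled_laplacian(L1, estimate_lmax(L1, tol=lmax_tol))
    _, C2 = coarsen(A1)
    return SubjectInput(
        X=np.asarray(X, float),
        T0=_cheb_basis(Ls0, K1),
        T1=_cheb_basis(Ls1, K2),
        C1=C1,
        C2=C2,
        subject_id=subject_id,
    )


def cross_entropy(y_true: np.ndarray, y_pred_probs: np.ndarray) -> float:
    """Mean categorical cross-entropy; labels as ints or one-hot rows."""
    probs = np.atleast_2d(np.asarray(y_pred_probs, float))
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6) or (probs < 0).any():
        raise InvalidArgumentError("prediction rows must be probability vectors")
    y = np.asarray(y_true)
    if y.ndim == 1:
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(y)), y.astype(int)] = 1.0
    else:
        onehot = y
    return float(-(onehot * np.log(np.maximum(probs, 1e-12))).sum(axis=1).mean())


class ChebGCN:
    """Two Chebyshev convolution layers with pooling, a fully connected
    layer and a softmax output."""

    def __init__(
        self,
        K1: int = 3,
        K2: int = 3,
        M: int = 2,
        n_features: int = 64,
        dropout: float = 0.35,
        global_pool: str = "mean",
        seed: int = 0,
    ) -> None:
        if K1 < 1 or K2 < 1:
            raise InvalidArgumentError("Chebyshev orders must be >= 1")
        if M < 2:
            raise InvalidArgumentError("need at least two classes")
        if not (0.0 <= dropout < 1.0):
            raise InvalidArgumentError("dropout must be in [0, 1)")
        if global_pool not in ("mean", "max"):
            raise InvalidArgumentError("global_pool must be 'mean' or 'max'")
        self.K1, self.K2, self.M = K1, K2, M
        self.n_features = n_features
        self.dropout = dropout
        self.global_pool = global_pool
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            # ReLU-scaled init; conv fan-in counts all K polynomial bases
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "W1": he((K1, n_features, 64), K1 * n_features),
            "b1": np.zeros(64),
            "W2": he((K2, 64, 32), K2 * 64),
            "b2": np.zeros(32),
            "Wfc": he((32, 32), 32),
            "bfc": np.zeros(32),
            "Wout": he((32, M), 32),
            "bout": np.zeros(M),
        }

    # -- bookkeeping ---------------------------------------------------

    def param_counts(self) -> dict[str, int]:
        """Trainable parameter counts per layer (pooling carries none)."""
        return {
            "conv1": self.params["W1"].size + self.params["b1"].size,
            "conv2": self.params["W2"].size + self.params["b2"].size,
            "fc": self.params["Wfc"].size + self.params["bfc"].size,
            "out": self.params["Wout"].size + self.params["bout"].size,
        }

    # -- forward / backward --------------------------------------------

    def forward(
        self,
        sub: SubjectInput,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        p = self.params
        TH0 = np.einsum("knm,mf->knf", sub.T0, sub.X)
        Y1 = np.einsum("knf,kfo->no", TH0, p["W1"]) + p["b1"]
        A1 = np.maximum(Y1, 0.0)
        H1 = sub.C1 @ A1
        TH1 = np.einsum("knm,mf->knf", sub.T1, H1)
        Y2 = np.einsum("knf,kfo->no", TH1, p["W2"]) + p["b2"]
        A2 = np.maximum(Y2, 0.0)
        H2 = sub.C2 @ A2
        if self.global_pool == "max":
            argmax = H2.argmax(axis=0)
            g = H2[argmax, np.arange(H2.shape[1])]
        else:
            argmax = None
            g = H2.mean(axis=0)
        if train and self.dropout > 0.0:
            if rng is None:
                raise InvalidArgumentError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.dropout
            mask = (rng.random(g.shape) < keep) / keep
        else:
            mask = np.ones_like(g)
        gd = g * mask
        Yfc = p["Wfc"].T @ gd + p["bfc"]
        F = np.maximum(Yfc, 0.0)
        logits = p["Wout"].T @ F + p["bout"]
        z = logits - logits.max()
        probs = np.exp(z) / np.exp(z).sum()
        return {
            "sub": sub, "TH0": TH0, "Y1": Y1, "A1": A1, "H1": H1,
            "TH1": TH1, "Y2": Y2, "A2": A2, "H2": H2, "g": g,
            "argmax": argmax, "mask": mask, "gd": gd, "Yfc": Yfc, "F": F,
            "logits": logits, "probs": probs,
        }

    def _unpool_global(self, dg: np.ndarray, cache: dict) -> np.ndarray:
        """Route the pooled-vector gradient back onto the node axis."""
        H2 = cache["H2"]
        n2 = H2.shape[0]
        if self.global_pool == "max":
            dH2 = np.zeros_like(H2)
            dH2[cache["argmax"], np.arange(H2.shape[1])] = dg
            return dH2
        return np.tile(dg / n2, (n2, 1))

    def predict_proba(self, sub: SubjectInput) -> np.ndarray:
        return self.forward(sub)["probs"]

    # -- batched passes (trials sharing one graph) ---------------------

    def forward_batch(
        self,
        sub: SubjectInput,
        Xb: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Forward pass for a block of graph signals on one subject's graph.

        Xb is (batch, n_nodes, n_features); the Chebyshev bases and pooling
        operators come from ``sub`` and are shared across the block.
        """
        p = self.params
        B = Xb.shape[0]
        K1, K2 = self.K1, self.K2
        # conv as batched BLAS: stack the K polynomial bases into the
        # feature axis, then one (B, N, K*F) @ (K*F, O) product per layer
        TH0 = np.matmul(sub.T0[None], Xb[:, None])  # (B, K1, N, F)
        TH0r = TH0.transpose(0, 2, 1, 3).reshape(B, Xb.shape[1], -1)
        Y1 = TH0r @ p["W1"].reshape(K1 * p["W1"].shape[1], -1) + p["b1"]
        A1 = np.maximum(Y1, 0.0)
        H1 = np.matmul(sub.C1[None], A1)
        TH1 = np.matmul(sub.T1[None], H1[:, None])
        TH1r = TH1.transpose(0, 2, 1, 3).reshape(B, H1.shape[1], -1)
        Y2 = TH1r @ p["W2"].reshape(K2 * p["W2"].shape[1], -1) + p["b2"]
        A2 = np.maximum(Y2, 0.0)
        H2 = np.matmul(sub.C2[None], A2)
        if self.global_pool == "max":
            argmax = H2.argmax(axis=1)  # (B, F)
            g = np.take_along_axis(H2, argmax[:, None, :], axis=1)[:, 0, :]
        else:
            argmax = None
            g = H2.mean(axis=1)
        if train and self.dropout > 0.0:
            if rng is None:
                raise InvalidArgumentError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.dropout
            mask = (rng.random(g.shape) < keep) / keep
        else:
            mask = np.ones_like(g)
        gd = g * mask
        Yfc = gd @ p["Wfc"] + p["bfc"]
        F = np.maximum(Yfc, 0.0)
        logits = F @ p["Wout"] + p["bout"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return {
            "sub": sub, "TH0r": TH0r, "Y1": Y1, "H1": H1, "TH1r": TH1r,
            "Y2": Y2, "H2": H2, "argmax": argmax, "mask": mask, "gd": gd,
            "Yfc": Yfc, "F": F, "probs": probs,
        }

    def backward_batch(self, cache: dict, y_true: np.ndarray) -> dict:
        """Mean cross-entropy gradients over the block."""
        p = self.params
        sub: SubjectInput = cache["sub"]
        B = cache["probs"].shape[0]
        dlogits = cache["probs"].copy()
        dlogits[np.arange(B), np.asarray(y_true, int)] -= 1.0
        dlogits /= B
        grads = {
            "Wout": cache["F"].T @ dlogits,
            "bout": dlogits.sum(axis=0),
        }
        dF = dlogits @ p["Wout"].T
        dYfc = dF * (cache["Yfc"] > 0)
        grads["Wfc"] = cache["gd"].T @ dYfc
        grads["bfc"] = dYfc.sum(axis=0)
        dg = (dYfc @ p["Wfc"].T) * cache["mask"]
        H2 = cache["H2"]
        if self.global_pool == "max":
            dH2 = np.zeros_like(H2)
            np.put_along_axis(dH2, cache["argmax"][:, None, :], dg[:, None, :], axis=1)
        else:
            dH2 = np.repeat(dg[:, None, :] / H2.shape[1], H2.shape[1], axis=1)
        dA2 = np.matmul(sub.C2.T[None], dH2)
        dY2 = dA2 * (cache["Y2"] > 0)
        K2, F2, O2 = p["W2"].shape
        TH1r = cache["TH1r"]
        grads["W2"] = (
            TH1r.reshape(-1, K2 * F2).T @ dY2.reshape(-1, O2)
        ).reshape(K2, F2, O2)
        grads["b2"] = dY2.sum(axis=(0, 1))
        # dH1 = sum_k T_k (dY2 W2_k^T); T_k symmetric
        z2 = (dY2 @ p["W2"].reshape(K2 * F2, O2).T).reshape(
            dY2.shape[0], dY2.shape[1], K2, F2
        ).transpose(0, 2, 1, 3)  # (B, K, n1, F)
        dH1 = np.matmul(sub.T1[None], z2).sum(axis=1)
        dA1 = np.matmul(sub.C1.T[None], dH1)
        dY1 = dA1 * (cache["Y1"] > 0)
        K1, F1, O1 = p["W1"].shape
        TH0r = cache["TH0r"]
        grads["W1"] = (
            TH0r.reshape(-1, K1 * F1).T @ dY1.reshape(-1, O1)
        ).reshape(K1, F1, O1)
        grads["b1"] = dY1.sum(axis=(0, 1))
        return grads

    def backward(self, cache: dict, y_true: int) -> dict:
        """Gradients of the cross-entropy loss for one subject."""
        p = self.params
        sub: SubjectInput = cache["sub"]
        dlogits = cache["probs"].copy()
        dlogits[y_true] -= 1.0
        grads = {
            "Wout": np.outer(cache["F"], dlogits),
            "bout": dlogits,
        }
        dF = p["Wout"] @ dlogits
        dYfc = dF * (cache["Yfc"] > 0)
        grads["Wfc"] = np.outer(cache["gd"], dYfc)
        grads["bfc"] = dYfc
        dg = (p["Wfc"] @ dYfc) * cache["mask"]
        dH2 = self._unpool_global(dg, cache)
        dA2 = sub.C2.T @ dH2
        dY2 = dA2 * (cache["Y2"] > 0)
        grads["W2"] = np.einsum("knf,no->kfo", cache["TH1"], dY2)
        grads["b2"] = dY2.sum(axis=0)
        # dH1 = sum_k T_k^T (dY2 W2_k^T); T_k is symmetric
        dH1 = sum(sub.T1[k] @ (dY2 @ p["W2"][k].T) for k in range(self.K2))
        dA1 = sub.C1.T @ dH1
        dY1 = dA1 * (cache["Y1"] > 0)
        grads["W1"] = np.einsum("knf,no->kfo", cache["TH0"], dY1)
        grads["b1"] = dY1.sum(axis=0)
        return grads

    def guided_backward(self, cache: dict, class_index: int) -> dict:
        """Guided backpropagation from the class score to the input.

        At every ReLU the gradient is overwritten as
        (activation > 0) * (upstream > 0) * upstream, so only positive
        evidence flows back.  Returns the per-layer overwritten gradients,
        including the input-feature gradient under key ``"input"``.
        """
        p = self.params
        for v in p.values():
            if not np.isfinite(v).all():
                raise InvalidStateError("model parameters contain non-finite values")
        sub: SubjectInput = cache["sub"]
        dlogits = np.zeros(self.M)
        dlogits[class_index] = 1.0
        dF = p["Wout"] @ dlogits
        dYfc = (cache["Yfc"] > 0) * (dF > 0) * dF
        dg = (p["Wfc"] @ dYfc) * cache["mask"]
        dH2 = self._unpool_global(dg, cache)
        dA2 = sub.C2.T @ dH2
        dY2 = (cache["Y2"] > 0) * (dA2 > 0) * dA2
        dH1 = sum(sub.T1[k] @ (dY2 @ p["W2"][k].T) for k in range(self.K2))
        dA1 = sub.C1.T @ dH1
        dY1 = (cache["Y1"] > 0) * (dA1 > 0) * dA1
        dX = sum(sub.T0[k] @ (dY1 @ p["W1"][k].T) for k in range(self.K1))
        return {"fc": dYfc, "conv2": dY2, "conv1": dY1, "input": dX}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


def train_model(
    inputs: list[SubjectInput],
    labels: np.ndarray,
    K1: int = 3,
    K2: int = 3,
    M: int = 2,
    lr: float = 1e-3,
    epochs: int = 200,
    patience: int = 20,
    min_delta: float = 1e-5,
    dropout: float = 0.35,
    weight_decay: float = 1e-3,
    global_pool: str = "mean",
    feature_noise: float = 0.0,
    seed: int = 0,
) -> tuple[ChebGCN, TrainHistory]:
    """Full-batch Adam on the cross-entropy loss with plateau early stopping.

    ``weight_decay`` adds an L2 penalty on the weight matrices (not biases);
    with a few dozen training subjects and thousands of weights the net
    overfits without it.  ``feature_noise`` adds seeded Gaussian jitter to the
    node features each epoch (a cheap surrogate for trial-resampling
    augmentation).  Fixed seed => identical weights, dropout masks and
    metrics on every run.
    """
    from dataclasses import replace as _replace

    labels = np.asarray(labels, int)
    model = ChebGCN(K1=K1, K2=K2, M=M, n_features=inputs[0].X.shape[1],
                    dropout=dropout, global_pool=global_pool, seed=seed)
    opt = _Adam(model.params, lr)
    rng = np.random.default_rng(seed + 1)
    history = TrainHistory()
    best = np.inf
    wait = 0
    for epoch_i in range(epochs):
        total = {k: np.zeros_like(v) for k, v in model.params.items()}
        loss = 0.0
        for sub, y in zip(inputs, labels):
            if feature_noise > 0.0:
                sub = _replace(sub, X=sub.X + rng.normal(scale=feature_noise,
                                                         size=sub.X.shape))
            cache = model.forward(sub, train=True, rng=rng)
            loss += -np.log(max(cache["probs"][y], 1e-12))
            g = model.backward(cache, int(y))
            for k in total:
                total[k] += g[k]
        n = len(inputs)
        loss /= n
        for k in total:
            total[k] /= n
            if weight_decay > 0 and not k.startswith("b"):
                total[k] += weight_decay * model.params[k]
        opt.step(model.params, total)
        history.loss.append(float(loss))
        if loss < best - min_delta:
            best, wait = loss, 0
        else:
            wait += 1
            if wait >= patience:
                break
    history.stopped_epoch = len(history.loss)
    return model, history


# ---------------------------------------------------------------------------
# trial-level training (the classifier's native regime: the loss batches
# over trials, subjects are scored by aggregating their trials)


@dataclass
class TrialSet:
    """One subject's per-trial graph signals on a fixed graph."""

    template: SubjectInput
    X: np.ndarray  # (n_trials, n_nodes, n_features)
    label: int
    subject_id: str = ""


@dataclass
class TrialScaler:
    """Feature standardisation over all training trials."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, trial_sets: list[TrialSet]) -> "TrialScaler":
        X = np.concatenate([t.X for t in trial_sets], axis=0)
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd == 0, 1.0, sd))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def train_trial_model(
    trial_sets: list[TrialSet],
    K1: int = 3,
    K2: int = 3,
    M: int = 2,
    lr: float = 1e-3,
    epochs: int = 120,
    dropout: float = 0.35,
    weight_decay: float = 1e-3,
    scaler: TrialScaler | None = None,
    seed: int = 0,
) -> tuple[ChebGCN, TrainHistory]:
    """Mini-batch Adam over per-trial graph signals.

    Trials of one subject share the subject's Chebyshev basis, so they are
    processed as one vectorised block; every optimisation step accumulates a
    class-BALANCED group of blocks (one subject per class) before updating,
    so the output bias cannot oscillate with label-homogeneous batches.
    Deterministic given the seed.
    """
    model = ChebGCN(K1=K1, K2=K2, M=M, n_features=trial_sets[0].X.shape[2],
                    dropout=dropout, seed=seed)
    opt = _Adam(model.params, lr)
    rng = np.random.default_rng(seed + 1)
    history = TrainHistory()
    labels_arr = np.array([t.label for t in trial_sets])
    classes = np.unique(labels_arr)
    by_class = {c: np.flatnonzero(labels_arr == c) for c in classes}
    n_groups = max(len(v) for v in by_class.values())

    def _block_grads(ts: TrialSet) -> tuple[dict, float, int]:
        Xb = scaler.transform(ts.X) if scaler else ts.X
        cache = model.forward_batch(ts.template, Xb, train=True, rng=rng)
        y = np.full(Xb.shape[0], ts.label, int)
        block_loss = float(
            -np.log(np.maximum(cache["probs"][np.arange(len(y)), y], 1e-12)).sum()
        )
        return model.backward_batch(cache, y), block_loss, len(y)

    for _ in range(epochs):
        # one shuffled column of subjects per class; shorter classes recycle
        columns = {
            c: np.concatenate([rng.permutation(idx) for _ in
                               range(-(-n_groups // len(idx)))])[:n_groups]
            for c, idx in by_class.items()
        }
        loss = n_seen = 0
        for g_i in range(n_groups):
            total = None
            n_blocks = 0
            for c in classes:
                grads, bl, bn = _block_grads(trial_sets[columns[c][g_i]])
                loss += bl
                n_seen += bn
                n_blocks += 1
                if total is None:
                    total = grads
                else:
                    for k in total:
                        total[k] += grads[k]
            for k in total:
                total[k] /= n_blocks
                if weight_decay > 0 and not k.startswith("b"):
                    total[k] += weight_decay * model.params[k]
            opt.step(model.params, total)
        history.loss.append(loss / n_seen)
    history.stopped_epoch = len(history.loss)
    return model, history


def predict_subject_proba(
    model: ChebGCN, ts: TrialSet, scaler: TrialScaler | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(mean class probability over trials, per-trial hard labels)."""
    Xb = scaler.transform(ts.X) if scaler else ts.X
    probs = model.forward_batch(ts.template, Xb)["probs"]
    return probs.mean(axis=0), probs.argmax(axis=1)


def cross_validate_trials(
    trial_sets: list[TrialSet],
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    **train_kwargs,
) -> list["FoldResult"]:
    """Stratified subject-level k-fold with trial-level training.

    Subjects never straddle the split; the feature scaler is fitted on
    training trials only; held-out subjects are scored by their mean trial
    probability.
    """
    labels = np.asarray([t.label for t in trial_sets], int)
    if len(trial_sets) < 2 * n_folds:
        raise InvalidArgumentError("too few subjects for the requested fold count")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    results: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        tr_ids = {trial_sets[i].subject_id for i in tr}
        te_ids = {trial_sets[i].subject_id for i in te}
        assert not (tr_ids & te_ids), "subject leaked across the split"
        if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
            raise InvalidArgumentError(f"fold {fold_i} lost a class entirely")
        scaler = TrialScaler.fit([trial_sets[i] for i in tr]) if standardize else None
        model, _ = train_trial_model(
            [trial_sets[i] for i in tr], scaler=scaler, seed=seed + fold_i,
            **train_kwargs,
        )
        probs = np.stack(
            [predict_subject_proba(model, trial_sets[i], scaler)[0] for i in te]
        )
        results.append(
            FoldResult(
                metrics=evaluate(probs, labels[te]),
                test_ids=sorted(te_ids),
                test_probs=probs,
                model=model,
                scaler=None,
            )
        )
    return results


# ---------------------------------------------------------------------------
# evaluation


def auc_rank(scores: np.ndarray, labels: np.ndarray, positive_label: int = 0) -> float:
    """AUC as the Mann-Whitney rank statistic over the positive-class scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidArgumentError("AUC undefined: test set contains a single class")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def evaluate(
    probs: np.ndarray, labels: np.ndarray, positive_label: int = 0
) -> dict:
    """ACC / AUC / sensitivity / specificity / ROC for a labelled test set.

    The patient class (label 0) is the positive class: sensitivity is the
    detection rate of patients, specificity of controls.
    """
    probs = np.atleast_2d(np.asarray(probs, float))
    labels = np.asarray(labels, int)
    pred = probs.argmax(axis=1)
    scores = probs[:, positive_label]
    is_pos = labels == positive_label
    if is_pos.all() or (~is_pos).all():
        raise InvalidArgumentError("evaluation needs both classes present")
    acc = float((pred == labels).mean())
    sens = float((pred[is_pos] == positive_label).mean())
    spec = float((pred[~is_pos] != positive_label).mean())
    auc = auc_rank(scores, labels, positive_label)
    thresholds = np.unique(np.concatenate([[-np.inf], np.sort(scores), [np.inf]]))
    roc = []
    for th in thresholds[::-1]:
        called = scores >= th
        tpr = float(called[is_pos].mean())
        fpr = float(called[~is_pos].mean())
        roc.append((fpr, tpr))
    return {"ACC": acc, "AUC": auc, "sensitivity": sens, "specificity": spec,
            "roc": np.asarray(roc)}


@dataclass
class FeatureScaler:
    """Per-feature standardisation fitted on the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, inputs: list[SubjectInput]) -> "FeatureScaler":
        X = np.stack([s.X for s in inputs])
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd == 0, 1.0, sd))

    def transform(self, sub: SubjectInput) -> SubjectInput:
        from dataclasses import replace

        return replace(sub, X=(sub.X - self.mean) / self.sd)


@dataclass
class FoldResult:
    metrics: dict
    test_ids: list[str]
    test_probs: np.ndarray
    model: ChebGCN
    scaler: FeatureScaler | None = None


def cross_validate(
    inputs: list[SubjectInput],
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    **train_kwargs,
) -> list[FoldResult]:
    """Stratified subject-level k-fold: no subject appears in both splits.

    Node features are standardised per fold with training-split statistics
    (the group-mean connectivity pattern dwarfs the group difference, so raw
    correlation rows train poorly).
    """
    labels = np.asarray(labels, int)
    if len(inputs) < 2 * n_folds:
        raise InvalidArgumentError("too few subjects for the requested fold count")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    results: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        tr_ids = {inputs[i].subject_id for i in tr}
        te_ids = {inputs[i].subject_id for i in te}
        assert not (tr_ids & te_ids), "subject leaked across the split"
        if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
            raise InvalidArgumentError(f"fold {fold_i} lost a class entirely")
        scaler = FeatureScaler.fit([inputs[i] for i in tr]) if standardize else None
        prep = (lambda s: scaler.transform(s)) if scaler else (lambda s: s)
        model, _ = train_model(
            [prep(inputs[i]) for i in tr], labels[tr], seed=seed + fold_i, **train_kwargs
        )
        probs = np.stack([model.predict_proba(prep(inputs[i])) for i in te])
        results.append(
            FoldResult(
                metrics=evaluate(probs, labels[te]),
                test_ids=sorted(te_ids),
                test_probs=probs,
                model=model,
                scaler=scaler,
            )
        )
    return results


def compare_models(per_fold_metrics: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests with Bonferroni correction.

    Input: model name -> per-fold metric vector (equal lengths).  Output: a
    symmetric DataFrame of corrected p-values with unit diagonal.
    """
    names = list(per_fold_metrics)
    if len(names) < 2:
        raise InvalidArgumentError("need at least two models to compare")
    lengths = {len(v) for v in per_fold_metrics.values()}
    if len(lengths) != 1:
        raise InvalidArgumentError("all models must have the same fold count")
    (n_folds,) = lengths
    if n_folds < 3:
        import warnings

        warnings.warn("fewer than 3 folds: the rank test is underpowered")
    n_pairs = len(names) * (len(names) - 1) // 2
    P = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            va = np.asarray(per_fold_metrics[names[a]], float)
            vb = np.asarray(per_fold_metrics[names[b]], float)
            if np.array_equal(va, vb):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            p = min(1.0, p * n_pairs)
            P.iloc[a, b] = P.iloc[b, a] = p
    return P
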