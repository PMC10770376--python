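"""Sparse self-expressive graph reorganisation.

Each electrode's signal is reconstructed from the remaining electrodes
(a self-expressive dictionary), jointly over subjects, under an l2,1 row
penalty (shared electrode selection) and between-column smoothness penalties
weighted by subject-pair similarities:

    min_W  sum_i 1/2 ||x_i - X_i w_i||^2
           + l1 ||B_g . W||_{2,1} + l2 sum_{(i,j)} s_gij ||w_i - w_j||^2
           + l3 ||B_t . W||_{2,1} + l4 sum_{(i,j)} s_tij ||w_i - w_j||^2

solved by proximal gradient (ISTA) with backtracking line search: the
reconstruction and smoothness terms by gradient steps, the l2,1 terms by a
row-wise group soft-threshold.  Row norms that shrink to zero prune the
corresponding electrode from every reconstruction, which is what turns the
fit into an edge/node selection on the connectivity graph.

The group-smoothness pair set defaults to within-group subject pairs and the
trial-smoothness pair set to within-subject trial pairs when per-trial
columns are supplied; both index sets are caller-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, InvalidArgumentError

__all__ = [
    "build_dictionary",
    "pairwise_similarities",
    "sparse_objective",
    "fit_sparse_graph",
    "apply_sparse_graph",
    "fit_all_electrodes",
    "SparseGraphModel",
]


def build_dictionary(signals: np.ndarray, e: int) -> tuple[np.ndarray, np.ndarray]:
    """Split per-subject signals into target and dictionary for electrode e.

    signals : (n_subjects, n_channels, d) trial-averaged signals.
    Returns ``x`` (n_subjects, d) — electrode e — and ``X``
    (n_subjects, d, n_channels - 1) — the remaining electrodes.
    """
    signals = np.asarray(signals, float)
    if signals.ndim != 3:
        raise InvalidArgumentError("signals must be (n_subjects, n_channels, d)")
    n_ch = signals.shape[1]
    if n_ch < 2:
        raise InvalidArgumentError("the self-expressive dictionary needs >= 2 electrodes")
    if not (0 <= e < n_ch):
        raise InvalidArgumentError(f"electrode index {e} out of range")
    x = signals[:, e, :]
    rest = np.delete(np.arange(n_ch), e)
    X = np.transpose(signals[:, rest, :], (0, 2, 1))
    return x, X


def pairwise_similarities(signals: np.ndarray, e: int) -> np.ndarray:
    """Subject-pair similarity at electrode e: Pearson correlation between
    the subjects' electrode-e signals, clipped to [0, 1]; s_ii = 1."""
    x, _ = build_dictionary(np.asarray(signals, float), e)
    z = x - x.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(z, axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    corr = (z / sd[:, None]) @ (z / sd[:, None]).T
    sim = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _check_lambdas(lambdas) -> tuple[float, float, float, float]:
    lam = tuple(float(v) for v in lambdas)
    if len(lam) != 4:
        raise InvalidArgumentError("lambdas must be (l1, l2, l3, l4)")
    if any(v < 0 for v in lam):
        raise InvalidArgumentError("lambdas must be non-negative")
    return lam


def _pair_list(pairs, sim: np.ndarray | None, n: int):
    """Normalise a pair specification into (i, j, weight) arrays."""
    if pairs is None:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    i, j = np.asarray([p[0] for p in pairs], int), np.asarray([p[1] for p in pairs], int)
    if len(i) and (i.max() >= n or j.max() >= n):
        raise InvalidArgumentError("pair index out of range")
    w = sim[i, j] if sim is not None else np.ones(len(i))
    return i, j, np.asarray(w, float)


def _row_weights(B: np.ndarray | None, shape: tuple[int, int]) -> np.ndarray:
    """Per-row l2,1 weights.  B defaults to all-ones; a general B must be
    constant within each row for the proximal step to stay exact."""
    if B is None:
        return np.ones(shape[0])
    B = np.asarray(B, float)
    if B.shape != shape:
        raise InvalidArgumentError("weighting matrix B has the wrong shape")
    if not np.allclose(B, B[:, :1]):
        raise InvalidArgumentError(
            "the proximal solver requires row-constant weighting matrices B"
        )
    return B[:, 0].copy()


def sparse_objective(
    W: np.ndarray,
    x: np.ndarray,
    X: np.ndarray,
    lambdas,
    Bg: np.ndarray | None = None,
    Bt: np.ndarray | None = None,
    pairs_g=None,
    sim_g: np.ndarray | None = None,
    pairs_t=None,
    sim_t: np.ndarray | None = None,
) -> float:
    """Evaluate the full objective at W ((n_channels - 1) x n_columns)."""
    l1, l2, l3, l4 = _check_lambdas(lambdas)
    W = np.asarray(W, float)
    n_cols = W.shape[1]
    recon = 0.0
    for i in range(n_cols):
        recon += 0.5 * float(np.sum((x[i] - X[i] @ W[:, i]) ** 2))
    row_norms = np.linalg.norm(W, axis=1)
    bg = _row_weights(Bg, W.shape)
    bt = _row_weights(Bt, W.shape)
    value = recon + l1 * float(bg @ row_norms) + l3 * float(bt @ row_norms)
    for lam, (pi, pj, pw) in (
        (l2, _pair_list(pairs_g, sim_g, n_cols)),
        (l4, _pair_list(pairs_t, sim_t, n_cols)),
    ):
        if lam > 0 and len(pi):
            diffs = W[:, pi] - W[:, pj]
            value += lam * float(pw @ np.sum(diffs**2, axis=0))
    return value


@dataclass
class SparseGraphModel:
    W: np.ndarray  # (n_channels - 1, n_columns)
    electrode: int
    lambdas: tuple[float, float, float, float]
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def row_support(self) -> np.ndarray:
        return np.linalg.norm(self.W, axis=1) > 1e-10


def fit_sparse_graph(
    x: np.ndarray,
    X: np.ndarray,
    lambdas=(0.1, 0.01, 0.1, 0.01),
    Bg: np.ndarray | None = None,
    Bt: np.ndarray | None = None,
    pairs_g=None,
    sim_g: np.ndarray | None = None,
    pairs_t=None,
    sim_t: np.ndarray | None = None,
    electrode: int = -1,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> SparseGraphModel:
    """Proximal-gradient fit of the sparse self-expressive model.

    x : (n_cols, d) targets; X : (n_cols, d, p) dictionaries.  The objective
    is non-increasing by construction (backtracking ISTA); the iteration
    stops when the relative decrease falls below ``tol``.
    """
    l1, l2, l3, l4 = _check_lambdas(lambdas)
    x = np.asarray(x, float)
    X = np.asarray(X, float)
    n_cols, d, p = X.shape
    bg = _row_weights(Bg, (p, n_cols))
    bt = _row_weights(Bt, (p, n_cols))
    gi, gj, gw = _pair_list(pairs_g, sim_g, n_cols)
    ti, tj, tw = _pair_list(pairs_t, sim_t, n_cols)

    def smooth_value(W: np.ndarray) -> float:
        resid = np.einsum("idp,pi->id", X, W) - x
        v = 0.5 * float(np.sum(resid**2))
        if l2 > 0 and len(gi):
            v += l2 * float(gw @ np.sum((W[:, gi] - W[:, gj]) ** 2, axis=0))
        if l4 > 0 and len(ti):
            v += l4 * float(tw @ np.sum((W[:, ti] - W[:, tj]) ** 2, axis=0))
        return v

    def smooth_grad(W: np.ndarray) -> np.ndarray:
        resid = np.einsum("idp,pi->id", X, W) - x  # (n_cols, d)
        g = np.einsum("idp,id->pi", X, resid)
        for lam, (pi, pj, pw) in ((l2, (gi, gj, gw)), (l4, (ti, tj, tw))):
            if lam > 0 and len(pi):
                diff = (W[:, pi] - W[:, pj]) * pw
                np.add.at(g, (slice(None), pi), 2.0 * lam * diff)
                np.add.at(g, (slice(None), pj), -2.0 * lam * diff)
        return g

    def prox(W: np.ndarray, step: float) -> np.ndarray:
        thresh = step * (l1 * bg + l3 * bt)  # per-row
        norms = np.linalg.norm(W, axis=1)
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - thresh / np.where(norms > 0, norms, 1.0)), 0.0)
        return W * scale[:, None]

    def objective(W: np.ndarray) -> float:
        norms = np.linalg.norm(W, axis=1)
        return smooth_value(W) + l1 * float(bg @ norms) + l3 * float(bt @ norms)

    W = np.zeros((p, n_cols))
    step = 1.0
    trace = [objective(W)]
    scale0 = max(trace[0], 1.0)
    increases = 0
    for _ in range(max_iter):
        g = smooth_grad(W)
        f_w = smooth_value(W)
        # backtracking on the smooth majorisation; the slack is relative to
        # the current value so convergence is not floored at an absolute tol
        while True:
            W_new = prox(W - step * g, step)
            delta = W_new - W
            quad = f_w + float(np.sum(g * delta)) + float(np.sum(delta**2)) / (2.0 * step)
            if smooth_value(W_new) <= quad + 1e-12 * abs(f_w):
                break
            step *= 0.5
            if step < 1e-16:
                raise ConvergenceError("backtracking line search collapsed")
        obj = objective(W_new)
        if obj > trace[-1] + max(1e-9 * scale0, 1e-6 * abs(trace[-1])):
            increases += 1
            step *= 0.5
            if increases >= 3:
                raise ConvergenceError("objective increased on 3 consecutive steps")
        else:
            increases = 0
        rel_drop = (trace[-1] - obj) / max(abs(trace[-1]), 1e-12)
        trace.append(obj)
        W = W_new
        step *= 1.5  # allow recovery after conservative backtracks
        if 0 <= rel_drop < tol:
            return SparseGraphModel(W, electrode, (l1, l2, l3, l4), trace, True)
    return SparseGraphModel(W, electrode, (l1, l2, l3, l4), trace, False)


def fit_all_electrodes(
    signals: np.ndarray,
    lambdas=(0.1, 0.01, 0.1, 0.01),
    groups: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> dict[int, SparseGraphModel]:
    """Fit one sparse model per electrode over the subject columns.

    Group-smoothness pairs are all within-group subject pairs (when labels are
    given), weighted by the electrode-wise subject similarity.
    """
    signals = np.asarray(signals, float)
    n_subj, n_ch, _ = signals.shape
    pairs_g = None
    if groups is not None:
        groups = np.asarray(groups)
        pairs_g = [
            (i, j)
            for i in range(n_subj)
            for j in range(i + 1, n_subj)
            if groups[i] == groups[j]
        ]
    models: dict[int, SparseGraphModel] = {}
    for e in range(n_ch):
        x, X = build_dictionary(signals, e)
        sim = pairwise_similarities(signals, e) if pairs_g else None
        models[e] = fit_sparse_graph(
            x, X, lambdas, pairs_g=pairs_g, sim_g=sim,
            electrode=e, tol=tol, max_iter=max_iter,
        )
    return models


def apply_sparse_graph(models: dict[int, SparseGraphModel], n_channels: int) -> np.ndarray:
    """Reassemble electrode-level fits into a symmetric edge-weight matrix.

    Edge (e, e') carries the symmetrised mean |w| mass
    1/2 (mean_i |W^e[e', i]| + mean_i |W^{e'}[e, i]|); rows pruned by the
    l2,1 penalty zero out their edges.
    """
    for e in range(n_channels):
        if e not in models:
            raise InvalidArgumentError(f"no fitted model for electrode {e}")
    M = np.zeros((n_channels, n_channels))
    for e, model in models.items():
        rest = np.delete(np.arange(n_channels), e)
        M[e, rest] = np.abs(model.W).mean(axis=1)
    out = 0.5 * (M + M.T)
    np.fill_diagonal(out, 0.0)
    return out
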