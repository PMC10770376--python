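"""Guided-backprop saliency over a trained classifier.

The class-score gradient is propagated to the input node features with the
guided overwrite (only units whose forward activation AND upstream gradient
are positive pass gradient), then aggregated into per-channel and per-edge
contribution scores.  Saliency is computed on each subject's trial-averaged
input and averaged over the correctly classified subjects of the target
class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chebnet import ChebGCN, SubjectInput
from .errors import InvalidArgumentError

__all__ = ["SaliencyMap", "guided_backprop", "saliency_map", "cohort_saliency",
           "plot_topomap"]


@dataclass
class SaliencyMap:
    node_scores: np.ndarray  # per channel, in [0, 1]
    edge_scores: np.ndarray  # (n, n) symmetric, in [0, 1]
    class_index: int

    def top_nodes(self, k: int = 10) -> list[int]:
        return list(np.argsort(-self.node_scores)[:k])

    def top_edges(self, k: int = 20) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.edge_scores.shape[0], 1)
        order = np.argsort(-self.edge_scores[iu, ju])[:k]
        return [(int(iu[o]), int(ju[o])) for o in order]


def guided_backprop(model: ChebGCN, sub: SubjectInput, class_index: int) -> dict:
    """Layer-wise guided gradients for one subject (see ChebGCN.guided_backward)."""
    if not (0 <= class_index < model.M):
        raise InvalidArgumentError(f"class index {class_index} out of range")
    cache = model.forward(sub, train=False)
    return model.guided_backward(cache, class_index)


def saliency_map(
    input_gradient: np.ndarray, adjacency: np.ndarray, class_index: int = 0
) -> SaliencyMap:
    """Aggregate an input-layer gradient into node and edge contributions.

    Node score = L2 norm of the node's gradient row; edge score
    = |g_i| |g_j| A_ij; both max-normalised to [0, 1].
    """
    G = np.asarray(input_gradient, float)
    A = np.asarray(adjacency, float)
    node = np.linalg.norm(G, axis=1)
    if node.max() == 0.0:
        warnings.warn("all-zero saliency gradients")
        return SaliencyMap(node, np.zeros_like(A), class_index)
    mag = node
    edge = np.abs(A) * np.outer(mag, mag)
    np.fill_diagonal(edge, 0.0)
    node = node / node.max()
    if edge.max() > 0:
        edge = edge / edge.max()
    return SaliencyMap(node, edge, class_index)


def cohort_saliency(
    model: ChebGCN,
    inputs: list[SubjectInput],
    labels: np.ndarray,
    adjacency: np.ndarray,
    class_index: int = 0,
) -> SaliencyMap:
    """Mean saliency over the correctly classified subjects of one class."""
    labels = np.asarray(labels, int)
    grads = []
    for sub, y in zip(inputs, labels):
        if y != class_index:
            continue
        probs = model.predict_proba(sub)
        if int(probs.argmax()) != class_index:
            continue
        grads.append(guided_backprop(model, sub, class_index)["input"])
    if not grads:
        warnings.warn("no correctly classified subject in the target class")
        n = inputs[0].X.shape[0]
        return SaliencyMap(np.zeros(n), np.zeros_like(np.asarray(adjacency)), class_index)
    return saliency_map(np.mean(grads, axis=0), adjacency, class_index)


def plot_topomap(scores: np.ndarray, positions: np.ndarray, path: str) -> None:
    """Render per-channel scores on the flattened (x, y) sensor layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(positions[:, 0], positions[:, 1], c=scores, cmap="Reds",
                    s=80, edgecolors="k", linewidths=0.3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
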