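"""Cluster visualization: t-SNE embedding of the cell graph and heatmap ordering.

The embedding runs on the partial-correlation adjacency itself (converted
to a dissimilarity), not on the expression matrix, so the figure shows the
structure the clustering actually used.  Inter-cluster distances in a
t-SNE layout are not interpretable; only local neighborhoods are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE

from .community import Partition
from .graph import GraphModel

__all__ = ["Embedding", "embed", "heatmap_order", "plot_embedding", "plot_heatmap"]


@dataclass
class Embedding:
    coords: np.ndarray
    method: str = "tsne"
    settings: dict = field(default_factory=dict)


def _dissimilarity(model: GraphModel | np.ndarray) -> np.ndarray:
    W = model.W if isinstance(model, GraphModel) else np.asarray(model, dtype=np.float64)
    W = 0.5 * (W + W.T)
    W = np.where(W < 0, 0.0, W)
    np.fill_diagonal(W, 0.0)
    rng_w = W.max() - W.min()
    if rng_w > 0:
        Wt = (W - W.min()) / rng_w
    else:
        Wt = W
    D = 1.0 - Wt
    np.fill_diagonal(D, 0.0)
    return D


def embed(model: GraphModel | np.ndarray, seed: int = 0, perplexity: float = 30.0) -> Embedding:
    """2-D t-SNE of cells from the W-derived dissimilarity.

    W is symmetrized, clipped at zero and min-max scaled to [0, 1]; the
    dissimilarity is 1 - scaled weight with a zero diagonal.  Deterministic
    given ``seed``.  Perplexity is capped at (n - 1) / 3 as t-SNE requires.
    """
    D = _dissimilarity(model)
    n = D.shape[0]
    if n < 5:
        raise ValueError("embedding needs at least 5 cells")
    perp = min(perplexity, (n - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perp,
    )
    coords = ts.fit_transform(D)
    return Embedding(np.asarray(coords, dtype=np.float64), "tsne", {"perplexity": perp, "seed": seed})


def heatmap_order(model: GraphModel | np.ndarray, partition: Partition) -> np.ndarray:
    """Cell permutation that makes the cluster blocks contiguous in W.

    Cells are ordered by cluster id, then by within-cluster total edge
    weight descending (stable on ties), so a well-clustered W shows a
    block-diagonal checkerboard when rows and columns are permuted alike.
    """
    W = model.W if isinstance(model, GraphModel) else np.asarray(model, dtype=np.float64)
    labels = np.asarray(partition.labels)
    order = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        intra = W[np.ix_(idx, idx)].sum(axis=1)
        order.extend(idx[np.argsort(-intra, kind="stable")])
    return np.asarray(order, dtype=np.int64)


def plot_embedding(embedding: Embedding, partition: Partition, path=None):
    """Scatter the embedding colored by cluster; save to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    labels = np.asarray(partition.labels)
    for c in np.unique(labels):
        pts = embedding.coords[labels == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=f"cluster {c}")
    ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("tSNE 1")
    ax.set_ylabel("tSNE 2")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_heatmap(model: GraphModel | np.ndarray, partition: Partition, path=None):
    """Cluster-ordered heatmap of the adjacency W."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    W = model.W if isinstance(model, GraphModel) else np.asarray(model, dtype=np.float64)
    perm = heatmap_order(model, partition)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(W[np.ix_(perm, perm)], cmap="YlOrRd", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("cells (cluster-ordered)")
    ax.set_ylabel("cells (cluster-ordered)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
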