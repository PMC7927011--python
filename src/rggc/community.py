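"""Modularity maximization on the cell-cell adjacency with multi-restart Louvain.

The number of clusters is emergent: Louvain greedily maximizes Newman-Girvan
modularity

    Q = (1/2m) sum_ij [ w_ij - k_i k_j / (2m) ] delta(c_i, c_j),

with k_i the weighted degree and 2m the total weight, alternating a local
node-moving phase with graph aggregation until no move improves Q.  Louvain
is a heuristic that can stall in a local optimum, so the clusterer runs
several independently-shuffled restarts and keeps the partition with the
largest Q.

Negative partial correlations are handled either by clipping them before
clustering (the default) or by a signed generalization that scores the
positive and negative layers separately:

    Q_signed = (2m+ / (2m+ + 2m-)) Q+  -  (2m- / (2m+ + 2m-)) Q-.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import GraphModel

logger = logging.getLogger(__name__)

__all__ = ["Partition", "modularity", "louvain_cluster"]

_TOL = 1e-12


@dataclass
class Partition:
    """Cluster labels (1..n_clusters, no empty cluster) plus achieved Q."""

    labels: np.ndarray
    Q: float
    n_clusters: int
    restarts_used: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


def _as_W(W) -> np.ndarray:
    if isinstance(W, GraphModel):
        W = W.W
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("W must be symmetric")
    if np.abs(np.diag(W)).max(initial=0.0) > 0:
        raise ValueError("W must have a zero diagonal")
    return W


def _labels_array(labels) -> np.ndarray:
    arr = getattr(labels, "labels", labels)
    arr = np.asarray(arr)
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def _modularity_layer(W: np.ndarray, codes: np.ndarray) -> float:
    """Q of one nonnegative layer; 0 for an empty layer."""
    two_m = W.sum()
    if two_m <= 0:
        return 0.0
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(codes):
        idx = codes == c
        q += W[np.ix_(idx, idx)].sum() - k[idx].sum() ** 2 / two_m
    return q / two_m


def modularity(W, labels, mode: str = "standard") -> float:
    """Newman-Girvan modularity of a labelling on adjacency W.

    ``standard`` requires nonnegative weights; ``signed`` decomposes W
    into positive and negative parts and returns the weighted difference
    of the two layer modularities.
    """
    W = _as_W(W)
    codes = _labels_array(labels)
    if len(codes) != W.shape[0]:
        raise ValueError("labels length does not match W")
    if mode == "standard":
        if (W < 0).any():
            raise ValueError(
                "negative weights: use mode='signed' or clip W before clustering"
            )
        if W.sum() <= 0:
            raise ValueError("empty graph (total weight m = 0)")
        return _modularity_layer(W, codes)
    if mode == "signed":
        Wp = np.where(W > 0, W, 0.0)
        Wn = np.where(W < 0, -W, 0.0)
        tp, tn = Wp.sum(), Wn.sum()
        if tp + tn <= 0:
            raise ValueError("empty graph (total weight m = 0)")
        qp = _modularity_layer(Wp, codes) if tp > 0 else 0.0
        qn = _modularity_layer(Wn, codes) if tn > 0 else 0.0
        return (tp * qp - tn * qn) / (tp + tn)
    raise ValueError(f"unknown mode {mode!r}")


def _local_move(
    Wp: np.ndarray,
    Wn: np.ndarray,
    kp: np.ndarray,
    kn: np.ndarray,
    comm: np.ndarray,
    rng: np.random.Generator,
    signed: bool,
) -> bool:
    """One-level local-moving phase, in place on ``comm``.

    ``Wp``/``Wn`` carry zero diagonals (a node's self-loop never links it
    to other community members) while ``kp``/``kn`` are the full degrees
    including self-loops, as the null model requires at aggregated levels.
    Gains are computed against every community at once (vectorized over
    the dense row); ties resolve to the lowest community index, which is
    deterministic given the shuffled visiting order.
    """
    n = Wp.shape[0]
    two_mp = kp.sum()
    sig_p = np.bincount(comm, weights=kp, minlength=n)
    if signed:
        two_mn = kn.sum()
        sig_n = np.bincount(comm, weights=kn, minlength=n)
    improved_any = True
    moved = False
    while improved_any:
        improved_any = False
        for i in rng.permutation(n):
            ci = comm[i]
            sig_p[ci] -= kp[i]
            w_ic_p = np.bincount(comm, weights=Wp[i], minlength=n)
            gains = w_ic_p - kp[i] * sig_p / two_mp if two_mp > 0 else w_ic_p
            if signed:
                sig_n[ci] -= kn[i]
                w_ic_n = np.bincount(comm, weights=Wn[i], minlength=n)
                if two_mn > 0:
                    gains = gains - (w_ic_n - kn[i] * sig_n / two_mn)
            best = int(np.argmax(gains))
            if gains[best] <= gains[ci] + _TOL:
                best = ci
            sig_p[best] += kp[i]
            if signed:
                sig_n[best] += kn[i]
            if best != ci:
                comm[i] = best
                improved_any = True
                moved = True
    return moved


def _aggregate(W: np.ndarray, codes: np.ndarray, n_comm: int) -> np.ndarray:
    """Collapse communities into super-nodes; diagonal keeps internal weight."""
    C = np.zeros((W.shape[0], n_comm))
    C[np.arange(W.shape[0]), codes] = 1.0
    return C.T @ W @ C


def _louvain_once(
    Wp: np.ndarray, Wn: np.ndarray, rng: np.random.Generator, signed: bool
) -> np.ndarray:
    n = Wp.shape[0]
    membership = np.arange(n)
    Ap, An = Wp.copy(), Wn.copy()
    while True:
        comm = np.arange(Ap.shape[0])
        # zero-diagonal views for community links; full degrees (with
        # self-loops) for the null-model term
        kp = Ap.sum(axis=1)
        kn = An.sum(axis=1)
        Dp = Ap.copy()
        np.fill_diagonal(Dp, 0.0)
        Dn = An.copy()
        if signed:
            np.fill_diagonal(Dn, 0.0)
        moved = _local_move(Dp, Dn, kp, kn, comm, rng, signed)
        if not moved:
            break
        _, codes = np.unique(comm, return_inverse=True)
        membership = codes[membership]
        n_comm = codes.max() + 1
        Ap = _aggregate(Ap, codes, n_comm)
        if signed:
            An = _aggregate(An, codes, n_comm)
        if n_comm == Dp.shape[0]:
            break
    return membership


def louvain_cluster(
    model: GraphModel | np.ndarray,
    restarts: int = 10,
    seed: int = 0,
    mode: str = "standard",
) -> Partition:
    """Best-of-``restarts`` Louvain partition of the cell graph.

    Each restart shuffles the node visiting order with an independent
    stream derived from ``seed``; the partition with the largest Q wins.
    Ties between restarts keep the earliest restart, so identical
    (W, seed, restarts) always yield the identical Partition.  The
    resolution is fixed at 1 by design — the method exposes no tuning
    parameter.
    """
    W = _as_W(model)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if mode == "standard" and (W < 0).any():
        raise ValueError(
            "negative weights: use mode='signed' or clip W before clustering"
        )
    signed = mode == "signed"
    if mode not in ("standard", "signed"):
        raise ValueError(f"unknown mode {mode!r}")

    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    if Wp.sum() + Wn.sum() == 0:
        logger.warning("all-zero adjacency: returning a single cluster")
        return Partition(np.ones(n, dtype=np.int64), 0.0, 1, restarts, seed)

    best_q = -np.inf
    best_codes = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        membership = _louvain_once(Wp, Wn, rng, signed)
        q = modularity(W, membership, mode=mode)
        if q > best_q + _TOL:
            best_q = q
            best_codes = membership
    _, codes = np.unique(best_codes, return_inverse=True)
    return Partition(codes + 1, float(best_q), int(codes.max()) + 1, restarts, seed)
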