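"""External cluster-validation indices: NMI and adjusted Rand index.

Both are computed from the s x r contingency table between the true and
detected partitions, n_ij = |C_ti intersect C_dj|.  NMI normalizes the
mutual information by the geometric mean of the two partition entropies
(natural log; the base cancels).  ARI corrects the Rand index for chance
using the hypergeometric expectation of pair counts:

    ARI = [ sum_ij C(n_ij,2) - E ] / [ (1/2)(sum_i C(a_i,2) + sum_j C(b_j,2)) - E ],
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2).

1 means perfect agreement; 0 is the chance level for ARI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContingencyTable", "contingency_table", "nmi", "ari"]


@dataclass
class ContingencyTable:
    """Overlap counts between two partitions of the same n cells."""

    n_ij: np.ndarray
    a_i: np.ndarray  # row sums (truth class sizes)
    b_j: np.ndarray  # column sums (detected cluster sizes)
    n: int


def _codes(labels) -> np.ndarray:
    arr = getattr(labels, "labels", labels)
    _, codes = np.unique(np.asarray(arr), return_inverse=True)
    return codes


def contingency_table(truth, detected) -> ContingencyTable:
    t = _codes(truth)
    d = _codes(detected)
    if len(t) != len(d):
        raise ValueError(f"label lengths differ: {len(t)} vs {len(d)}")
    if len(t) == 0:
        raise ValueError("empty label vectors")
    s, r = t.max() + 1, d.max() + 1
    n_ij = np.zeros((s, r), dtype=np.int64)
    np.add.at(n_ij, (t, d), 1)
    return ContingencyTable(n_ij, n_ij.sum(axis=1), n_ij.sum(axis=0), len(t))


def _entropy(sizes: np.ndarray, n: int) -> float:
    p = sizes[sizes > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(truth, detected) -> float:
    """Normalized mutual information in [0, 1], geometric-mean normalization.

    Two identical single-class partitions are defined as 1 (they agree
    trivially); a single-class partition against a multi-class one gives 0.
    """
    ct = contingency_table(truth, detected)
    ht = _entropy(ct.a_i, ct.n)
    hd = _entropy(ct.b_j, ct.n)
    if ht == 0.0 and hd == 0.0:
        return 1.0
    if ht == 0.0 or hd == 0.0:
        return 0.0
    nz = ct.n_ij > 0
    nij = ct.n_ij[nz].astype(np.float64)
    outer = np.outer(ct.a_i, ct.b_j)[nz].astype(np.float64)
    mi = float((nij / ct.n * np.log(nij * ct.n / outer)).sum())
    val = mi / np.sqrt(ht * hd)
    return float(min(max(val, 0.0), 1.0))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.float64)
    return x * (x - 1.0) / 2.0


def ari(truth, detected) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 at chance.

    When both partitions are trivial (all singletons or one block) the
    denominator vanishes and the index is defined as 1 if the partitions
    agree pairwise, matching the usual convention.
    """
    ct = contingency_table(truth, detected)
    sum_ij = _comb2(ct.n_ij).sum()
    sum_a = _comb2(ct.a_i).sum()
    sum_b = _comb2(ct.b_j).sum()
    n2 = ct.n * (ct.n - 1.0) / 2.0
    if n2 == 0:
        return 1.0
    expected = sum_a * sum_b / n2
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        return 1.0 if sum_ij == sum_a == sum_b else 0.0
    return float((sum_ij - expected) / denom)
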