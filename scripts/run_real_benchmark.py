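#!/usr/bin/env python
"""Run the full clustering pipeline on a user-supplied real dataset.

Not part of the automated test suite: real benchmark scRNA-seq sets (e.g.
the embryonic stem cell, pluripotent cell, neural/blood and sensory-neuron
collections distributed via the Bioconductor `scRNAseq` experiment
package) must be downloaded separately.  Export a genes x cells count
matrix (mtx with sidecars, or dense CSV/TSV) and a label file, then:

    python scripts/run_real_benchmark.py \\
        --counts usoskin/matrix.mtx --labels usoskin/labels.tsv

The script clusters at a grid of regularization strengths and prints NMI
and ARI per lambda, so robustness over the grid can be read side by side.
"""

from __future__ import annotations

import argparse

import numpy as np

from rggc.community import louvain_cluster
from rggc.graph import compute_S, compute_W
from rggc.io import read_counts, read_labels
from rggc.metrics import ari, nmi
from rggc.preprocess import preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--counts", required=True)
    ap.add_argument("--labels", required=True)
    ap.add_argument("--lambdas", default="0.01,0.1,1,2,bic,100,1000",
                    help="Comma-separated lambda values; 'aic'/'bic' allowed.")
    ap.add_argument("--restarts", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--transpose", action="store_true",
                    help="Input matrix is cells x genes.")
    args = ap.parse_args()

    counts = read_counts(args.counts)
    if args.transpose:
        from rggc.io import CountMatrix
        counts = CountMatrix(counts.counts.T, counts.cell_ids, counts.gene_ids)
    truth = read_labels(args.labels, cell_ids=None)
    if truth.cell_ids is not None:
        truth = truth.aligned_to(counts.cell_ids)
    X = preprocess(counts)
    p = X.n_genes
    print(f"{p} genes x {X.n_cells} cells, {len(set(truth.labels))} true classes")
    print(f"{'lambda':>10} {'k':>4} {'Q':>8} {'NMI':>6} {'ARI':>6}")
    for tok in args.lambdas.split(","):
        tok = tok.strip()
        lam = {"aic": 2.0, "bic": float(np.log(p))}.get(tok, None)
        lam = float(tok) if lam is None else lam
        S = compute_S(X.X, lam)
        model = compute_W(S, lam, normalization="symmetric", clip_negative=False)
        part = louvain_cluster(model, restarts=args.restarts, seed=args.seed,
                               mode="signed")
        print(f"{lam:>10.3f} {part.n_clusters:>4} {part.Q:>8.4f} "
              f"{nmi(truth.labels, part.labels):>6.3f} "
              f"{ari(truth.labels, part.labels):>6.3f}")


if __name__ == "__main__":
    main()
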