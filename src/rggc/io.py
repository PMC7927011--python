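"""Reading and writing count matrices, label files and clustering results.

The on-disk formats are deliberately plain: MatrixMarket coordinate files
with ``genes.tsv``/``barcodes.tsv`` sidecars (the 10x-style text dialect),
dense CSV/TSV with gene rows and cell columns, one-label-per-line or
two-column label TSVs, and a JSON run summary.  Everything is genes x cells
internally; a matrix X with p gene rows and n cell columns is what the
downstream graph model consumes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "LabelVector",
    "read_counts",
    "read_labels",
    "write_counts",
    "write_results",
]


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, genes (rows) x cells (columns).

    Parameters
    ----------
    counts
        Dense integer array of shape ``(p, n)``; all entries nonnegative.
    gene_ids
        ``p`` unique gene identifiers.
    cell_ids
        ``n`` unique cell identifiers.
    """

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (genes x cells)")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        p, n = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(p)]
        if not self.cell_ids:
            self.cell_ids = [f"c{j + 1}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} gene rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cell columns")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class LabelVector:
    """Categorical label per cell, aligned to a matrix's cell order."""

    labels: list
    cell_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if self.cell_ids is not None:
            self.cell_ids = [str(c) for c in self.cell_ids]
            if len(self.cell_ids) != len(self.labels):
                raise ValueError("cell_ids and labels have different lengths")

    def __len__(self) -> int:
        return len(self.labels)

    def aligned_to(self, cell_ids: Sequence[str]) -> "LabelVector":
        """Reorder labels to match ``cell_ids``; error on missing ids."""
        if self.cell_ids is None:
            if len(self.labels) != len(cell_ids):
                raise ValueError(
                    f"label file has {len(self.labels)} rows for "
                    f"{len(cell_ids)} cells"
                )
            return LabelVector(self.labels, list(cell_ids))
        lut = dict(zip(self.cell_ids, self.labels))
        missing = [c for c in cell_ids if c not in lut]
        if missing:
            raise ValueError(f"labels missing for cell ids: {missing}")
        return LabelVector([lut[c] for c in cell_ids], list(cell_ids))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    raise ValueError(f"cannot infer format from extension {suffix!r}; pass format=")


def _read_sidecar_ids(directory: Path, names: Sequence[str]) -> Optional[list[str]]:
    for name in names:
        f = directory / name
        if f.exists():
            ids = [line.split("\t")[0].strip() for line in f.read_text().splitlines() if line.strip()]
            return ids
    return None


def read_counts(path, format: str = "auto") -> CountMatrix:
    """Read a genes x cells count matrix.

    ``mtx`` expects a MatrixMarket coordinate file with optional
    ``genes.tsv`` / ``features.tsv`` and ``barcodes.tsv`` sidecars next to
    it; missing sidecars get synthesized identifiers ``g1..gp`` /
    ``c1..cn``.  Dense CSV/TSV must carry a header row of cell ids and a
    first column of gene ids.  When a dense file's orientation is
    ambiguous the longer axis is treated as genes and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)

    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        gene_ids = _read_sidecar_ids(path.parent, ["genes.tsv", "features.tsv"]) or []
        cell_ids = _read_sidecar_ids(path.parent, ["barcodes.tsv", "cells.tsv"]) or []
        return CountMatrix(counts, gene_ids, cell_ids)

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        if counts.shape[0] < counts.shape[1]:
            logger.warning(
                "matrix in %s has fewer rows (%d) than columns (%d); rows are "
                "still treated as genes — pass a transposed file or use "
                "--transpose if cells are on rows",
                path, counts.shape[0], counts.shape[1],
            )
        return CountMatrix(counts, gene_ids, cell_ids)

    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, directory, format: str = "mtx") -> Path:
    """Write counts plus gene/cell sidecars; returns the matrix path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        out = directory / "matrix.mtx"
        scipy.io.mmwrite(out, scipy.sparse.coo_matrix(cm.counts))
        (directory / "genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        (directory / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
        return out
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        out = directory / f"matrix.{format}"
        pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids).to_csv(out, sep=sep)
        return out
    raise ValueError(f"unknown format {format!r}")


def read_labels(path, cell_ids: Optional[Sequence[str]] = None) -> LabelVector:
    """Read a label file: one label per line, or two-column (cell_id, label).

    A two-column file must have a header; when ``cell_ids`` is given the
    labels are realigned to that order, and any missing cell id raises.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty label file {path}")
    two_col = "\t" in lines[0]
    if two_col:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"two-column label file {path} has {df.shape[1]} columns")
        lv = LabelVector(df.iloc[:, 1].tolist(), df.iloc[:, 0].tolist())
    else:
        lv = LabelVector([ln.strip() for ln in lines])
    if cell_ids is not None:
        lv = lv.aligned_to(cell_ids)
    return lv


def write_results(
    partition,
    directory,
    coords: Optional[np.ndarray] = None,
    cell_ids: Optional[Sequence[str]] = None,
    summary_extra: Optional[dict] = None,
) -> dict:
    """Write the clustering output files into ``directory``.

    Produces ``clusters.tsv`` (cell_id, cluster), ``summary.json`` with the
    regularization strength, modularity Q, cluster count, restarts and
    seed, and — when 2-D coordinates are supplied — ``embedding.tsv``.
    Returns the summary dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(partition.labels)
    if cell_ids is None:
        cell_ids = [f"c{j + 1}" for j in range(n)]
    if len(cell_ids) != n:
        raise ValueError("cell_ids length does not match partition")

    pd.DataFrame({"cell_id": list(cell_ids), "cluster": partition.labels}).to_csv(
        directory / "clusters.tsv", sep="\t", index=False
    )

    summary = {
        "Q": float(partition.Q),
        "n_clusters": int(partition.n_clusters),
        "n_cells": n,
        "restarts": int(partition.restarts_used),
        "seed": int(partition.seed),
    }
    if summary_extra:
        summary.update(summary_extra)
    (directory / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    if coords is not None:
        coords = np.asarray(coords)
        if coords.size:
            if coords.shape != (n, 2):
                raise ValueError(f"coords must be (n, 2); got {coords.shape}")
            pd.DataFrame(
                {"cell_id": list(cell_ids), "x": coords[:, 0], "y": coords[:, 1]}
            ).to_csv(directory / "embedding.tsv", sep="\t", index=False)
    return summary
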