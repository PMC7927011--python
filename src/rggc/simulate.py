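"""Splatter-style synthetic scRNA-seq count generator with planted groups.

The generative chain follows the gamma-Poisson hierarchy popularized by the
splatter simulator:

1. baseline gene means  mu_g ~ Gamma(mean_shape, rate=mean_rate);
2. per group k, a gene is differentially expressed with probability
   de_prob[k]; DE genes draw a factor f ~ LogNormal(de_fac_loc,
   de_fac_scale), inverted to 1/f with probability 1/2 (down-regulation),
   giving the group mean mu_gk = mu_g * f;
3. cells are assigned to groups by a multinomial over group_prob;
4. each cell draws a library-size factor L_c ~ LogNormal(lib_loc,
   lib_scale) and its expected expression is the group mean profile
   rescaled so the cell's expected total equals L_c;
5. biological over-dispersion: the mean is jittered multiplicatively by
   Gamma(shape=1/bcv^2, scale=bcv^2) (unit mean, CV = bcv);
6. observed counts ~ Poisson(jittered mean);
7. optional dropout: a count is zeroed with probability
   pi_gc = 1 / (1 + exp(dropout_shape * (log(mean + 1) - dropout_mid))),
   a logistic in log-expression so weakly expressed genes drop out most.

This is an emulation of the statistical structure, not a byte-compatible
clone of the R package: outlier genes, batch effects and trajectory paths
are omitted.  Three presets reproduce the simulation designs used to
benchmark the clustering method: 600 cells x 5000 genes with 4-5 groups of
varying abundance, DE probability and dropout severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CountMatrix, LabelVector

__all__ = ["SimDesign", "simulate_counts", "presets"]


@dataclass
class SimDesign:
    """Parameter set for one simulated dataset.

    Defaults mirror the splatter defaults for everything except the group
    structure: gene-mean gamma (shape 0.6, rate 0.3), lognormal library
    sizes (meanlog 11 -> median ~60k counts/cell, sdlog 0.2), lognormal DE
    factors (meanlog 0.1, sdlog 0.4), BCV 0.18.  ``dropout_mid`` is the
    logistic midpoint in log(mean+1) units; ``None`` disables dropout.
    """

    n_cells: int = 600
    n_genes: int = 5000
    n_groups: int = 4
    group_prob: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    de_prob: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1)
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    bcv: float = 0.18
    dropout_mid: float | None = None
    dropout_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_prob = tuple(float(x) for x in self.group_prob)
        self.de_prob = tuple(float(x) for x in self.de_prob)
        self.validate()

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_groups < 1:
            raise ValueError("n_groups must be positive")
        if len(self.group_prob) != self.n_groups:
            raise ValueError("group_prob length must equal n_groups")
        if len(self.de_prob) != self.n_groups:
            raise ValueError("de_prob length must equal n_groups")
        if abs(sum(self.group_prob) - 1.0) > 1e-9:
            raise ValueError("group_prob must sum to 1")
        if any(q < 0 for q in self.group_prob):
            raise ValueError("group_prob entries must be nonnegative")
        if any(not 0.0 <= q <= 1.0 for q in self.de_prob):
            raise ValueError("de_prob entries must lie in [0, 1]")
        for name in ("de_fac_scale", "mean_shape", "mean_rate", "lib_scale", "bcv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_seed(self, seed: int) -> "SimDesign":
        return replace(self, seed=seed)


def simulate_counts(design: SimDesign) -> tuple[CountMatrix, LabelVector]:
    """Draw one genes x cells count matrix plus true group labels.

    Deterministic given the design (including its seed): the same design
    always yields bit-identical counts and labels.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    p, n, k = design.n_genes, design.n_cells, design.n_groups

    # (1) baseline gene means
    mu = rng.gamma(design.mean_shape, 1.0 / design.mean_rate, size=p)

    # (2) group mean profiles via DE factors
    group_means = np.empty((p, k))
    for g in range(k):
        is_de = rng.random(p) < design.de_prob[g]
        fac = rng.lognormal(design.de_fac_loc, design.de_fac_scale, size=p)
        fac = np.where(rng.random(p) < 0.5, 1.0 / fac, fac)
        group_means[:, g] = mu * np.where(is_de, fac, 1.0)

    # (3) group assignment and (4) library sizes
    groups = rng.choice(k, size=n, p=design.group_prob)
    lib = rng.lognormal(design.lib_loc, design.lib_scale, size=n)

    cell_means = group_means[:, groups]
    cell_means = cell_means / cell_means.sum(axis=0, keepdims=True) * lib[np.newaxis, :]

    # (5) over-dispersion and (6) Poisson sampling
    shape = 1.0 / design.bcv**2
    noisy = cell_means * rng.gamma(shape, 1.0 / shape, size=(p, n))
    counts = rng.poisson(noisy)

    # (7) logistic dropout on the underlying (pre-noise) expression
    if design.dropout_mid is not None:
        logit = design.dropout_shape * (np.log(cell_means + 1.0) - design.dropout_mid)
        pi = 1.0 / (1.0 + np.exp(logit))
        counts = np.where(rng.random((p, n)) < pi, 0, counts)

    gene_ids = [f"gene{i + 1}" for i in range(p)]
    cell_ids = [f"cell{j + 1}" for j in range(n)]
    labels = LabelVector([f"group{g + 1}" for g in groups], cell_ids)
    return CountMatrix(counts, gene_ids, cell_ids), labels


def presets() -> dict[str, SimDesign]:
    """The three benchmark simulation designs.

    * ``simdata1`` — 4 equally abundant groups, DE probabilities
      0.05/0.1/0.2/0.4, no dropout.
    * ``simdata2`` — 4 groups with abundances 0.35/0.4/0.15/0.1, uniform
      DE probability 0.1, dropout midpoint 2 (aggressive zero inflation).
    * ``simdata3`` — 5 groups with abundances 0.15/0.2/0.4/0.15/0.1, DE
      probabilities 0.15/0.1/0.1/0.1/0.2, dropout midpoint 1.
    """
    return {
        "simdata1": SimDesign(
            n_groups=4,
            group_prob=(0.25, 0.25, 0.25, 0.25),
            de_prob=(0.05, 0.1, 0.2, 0.4),
            dropout_mid=None,
        ),
        "simdata2": SimDesign(
            n_groups=4,
            group_prob=(0.35, 0.4, 0.15, 0.1),
            de_prob=(0.1, 0.1, 0.1, 0.1),
            dropout_mid=2.0,
        ),
        "simdata3": SimDesign(
            n_groups=5,
            group_prob=(0.15, 0.2, 0.4, 0.15, 0.1),
            de_prob=(0.15, 0.1, 0.1, 0.1, 0.2),
            dropout_mid=1.0,
        ),
    }
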