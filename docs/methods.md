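# Methods

## Model and pipeline

The clustering pipeline has four fixed stages.

1. **Preprocessing.**  Raw counts are transformed entrywise by log2(x+1);
   sequencing depth is equalized by quantile normalization across cells
   (every cell's sorted expression vector is replaced by the mean of the
   sorted columns); each cell is then z-scored to zero mean and unit
   variance.  The population standard deviation (divide by p) is used:
   Lemma-style grouping-effect arguments assume unit-norm columns up to a
   constant, and the constant cancels in every normalization of W, so the
   sample/population choice cannot change the clusters — population was
   fixed for determinism.  Quantile normalization averages the reference
   values over tied rank spans; scRNA-seq log counts tie massively at zero,
   and per-rank assignment would make the output depend on the arbitrary
   input order of tied entries.  Zero-variance cells are set to all-zero
   columns with a warning rather than raising.  No gene filtering is done
   by default (the method is designed to run on the raw matrix); a
   min-cells-expressing filter exists behind an off-by-default option.

2. **Graph construction.**  With X the p×n preprocessed matrix, the ridge
   self-representation problem min ‖X − XW‖²_F + λ‖W‖²_F, diag(W)=0, has
   the closed form W = I − λS with S = (XᵀX + λI)⁻¹.  S is computed by one
   Cholesky factorization of the n×n regularized Gram matrix (never an
   explicit per-column regression, and never a cofactor inverse); the
   result is symmetrized to remove round-off asymmetry.  Three adjacency
   scalings are implemented: `none` (w_ij = −λs_ij), `column`
   (−s_ij/s_jj, symmetrized by averaging since community detection expects
   a symmetric graph), and `symmetric` (−s_ij/√(s_ii s_jj)), the default —
   it is the standard precision-matrix-to-partial-correlation map and
   yields weights in (−1, 1).  diag(S) entries at or below 1e−12 raise
   rather than being silently regularized.  λ = 0 is accepted only when
   XᵀX is numerically nonsingular; otherwise the error message advises a
   positive λ.

3. **Community detection.**  Classic two-phase Louvain (local moving until
   no gain above 1e−12, then graph aggregation, repeated) with the
   resolution fixed at 1 — deliberately not exposed, to preserve the
   parameter-free posture.  The node visiting order is shuffled per
   restart from an independent stream derived from the seed; the best-Q
   partition over `restarts` (default 10) wins, ties keeping the earliest
   restart, so identical (W, seed, restarts) give identical output.  At
   equal gain a node joins the lowest-indexed candidate community; with
   the shuffled visit order this is deterministic and unbiased across
   restarts.  At aggregated levels self-loops count toward degrees and
   total weight but not toward a node's links to other community members.

4. **Validation.**  NMI with geometric-mean normalization
   I/√(H_t·H_d) (natural log; identical single-class partitions define
   NMI = 1, a single-class against a multi-class partition gives 0) and
   the standard chance-corrected ARI on the contingency table.  Both are
   cross-checked in the test suite against independent brute-force
   implementations and scikit-learn.

## Signed versus clipped modularity

The partial-correlation graph contains negative edges.  Two treatments are
implemented: clipping negatives to zero and running standard
Newman–Girvan modularity, or keeping both signs and maximizing the signed
modularity

Q_signed = (2m⁺ Q⁺ − 2m⁻ Q⁻) / (2m⁺ + 2m⁻),

where Q± are the layer modularities of the positive and negative parts,
each with its own total weight.  **Signed is the default.**  The reason is
empirical and reproducible with the shipped simulator: under heavy dropout
(the `simdata2` design) the clipped graph's modularity landscape becomes
so flat that Louvain — ours and the igraph reference implementation alike —
fragments into 8–9 communities with Q below that of the planted partition,
while the signed objective recovers the planted 4 groups exactly; negative
partial correlations act as repulsive edges that separate groups the
positive layer cannot.  On well-separated data the two treatments agree.
The clipped standard path remains available (`mode="standard"`,
`clip_negative=True`, CLI `--clip`).

## λ defaults

λ = ln p ("bic", the default) or λ = 2 ("aic").  Clustering depends on the
rank order of the off-diagonal weights, which is nearly λ-invariant: on
the simulated benchmark scale the Spearman correlation of the off-diagonal
entries of −λS between λ = 1 and λ = 100 exceeds 0.99, and NMI against
planted labels is flat (spread 0.0 observed) from λ = 0.01 to 1000.  The
rank invariance weakens at extreme λ ratios and small cell counts (S
interpolates between a partial- and a marginal-correlation structure), but
the clustering itself remains stable because modularity only needs the
coarse ordering.

## The count simulator

`rggc.simulate` is a gamma-Poisson hierarchy in the style of the splatter
simulator: gene means from Gamma(shape 0.6, rate 0.3); per-group DE genes
(probability `de_prob[k]`) scaled by LogNormal(0.1, 0.4) factors inverted
with probability ½; multinomial group assignment; LogNormal(11, 0.2)
library sizes (median ≈ 60k counts/cell) with per-cell renormalization;
multiplicative Gamma over-dispersion with constant biological CV 0.18;
Poisson sampling; and optional logistic dropout with probability
1/(1 + exp(shape·(log(mean+1) − mid))), so weakly expressed genes drop out
most.  The three presets fix the benchmark designs: 600 cells × 5000
genes; `simdata1` 4 equal groups, DE probabilities 0.05/0.1/0.2/0.4, no
dropout; `simdata2` abundances 0.35/0.4/0.15/0.1, dropout midpoint 2
(≈54% zeros); `simdata3` 5 groups 0.15/0.2/0.4/0.15/0.1, DE
0.15/0.1/0.1/0.1/0.2, midpoint 1 (≈39% zeros).

What the emulation does not reproduce: outlier genes, batch effects,
trajectory paths, mean-dependent BCV, and the exact random streams of the
R implementation.  A consequence worth knowing when reading test results:
a 30-component PCA + k-means baseline scores NMI 0.98–1.0 on all three
presets here, higher than published baseline values on the original
simulated sets — the emulated designs are somewhat easier than true
splatter output.  Recovery tests therefore check medians over five seeds
against the published reference values minus 0.05 rather than exact
equality, and passing them demonstrates correct behaviour of the pipeline
on data with this generative structure, not performance on real tissues.

## Problem sizes and numerics

The test suite and the acceptance script run the full 600 × 5000 benchmark
scale (a few seconds per run: the p·n² Gram product dominates, then a
600³ Cholesky).  Unit tests use smaller draws (n ≤ 30 for algebraic
identities, n ≤ 8 for exhaustive partition enumeration with Bell(8) = 4140
partitions).  Tolerances: the closed-form identity and ridge equivalence
are asserted at 1e−8 absolute; modularity recomputation at 1e−10; metric
cross-checks at 1e−10; S symmetry is enforced by construction.  t-SNE runs
on the W-derived dissimilarity (1 − min-max-scaled, symmetrized, clipped
W), perplexity 30 capped at (n−1)/3, fixed seed; inter-cluster distances
in the embedding are not interpretable and the embedding is strictly
downstream of clustering.

## Known limitations

- Dense n×n algebra: memory and time scale as n² and n³; the design targets
  hundreds to a few thousand cells, not 10⁵-cell atlases.
- Louvain is a greedy heuristic; on near-flat landscapes (weak structure,
  heavy clipping) it can fragment — mitigated by restarts and the signed
  default, but a partition with the globally maximal Q is not guaranteed.
- Quantile normalization assumes cells share one expression distribution;
  strong compositional shifts between cell types violate this silently.
- The simulator is an emulation; absolute benchmark numbers obtained on it
  do not transfer to real data (see above).
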