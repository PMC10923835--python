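# Methods

## Model and procedure

`cassidi` compares two independently clustered single-cell RNA-seq datasets
through their positive marker genes. The pipeline for one (res, nPCs)
parameter pair is:

1. **Per-dataset clustering** (`cassidi.clustering`). Library-size
   normalization to 10,000 counts/cell, `log1p`, selection of 2,000 highly
   variable genes (all genes when fewer are present), z-scaling capped at
   ±10, PCA to `nPCs` components (ARPACK), a shared-nearest-neighbor graph
   with k = 20 neighbors, and Leiden modularity community detection at
   resolution `res`. The two datasets are never merged and no batch
   correction is applied: separateness is the point of the method, since
   the post-hoc similarity matching replaces integration.
2. **Marker detection.** For each cluster, genes with
   max(pct_in, pct_bg) ≥ 0.1 and avg_log_fc ≥ 0.25 are tested with a
   two-sided Wilcoxon rank-sum test (cluster vs all other cells of the same
   dataset) on log-normalized expression, followed by Benjamini–Hochberg
   adjustment over the tested genes. Retained markers satisfy
   p_adj ≤ 0.05 and avg_log_fc > 0; negative markers are discarded because
   they are typically redundant across clusters. avg_log_fc is the natural
   log of (mean de-logged normalized expression + 1) in the cluster over the
   background; pct_in/pct_bg are raw-count expressing fractions.
3. **Similarity** (`cassidi.similarity`). Each marker gets a weight
   w = avg_log_fc · pct_in² / max(pct_bg, 0.001) and a uniqueness
   u = 1 − √(Lᵢ/Lₙ), where Lᵢ counts the clusters (across both datasets of
   this comparison only) for which the gene is a retained marker and
   Lₙ = m + n. CSS_enh is the weighted Jaccard-style ratio documented in the
   module; the m × n scores form the CSS matrix.
4. **Distinction index** (`cassidi.ranking`). Per row/column: maximum minus
   mean of the remaining entries. The matrix-level DI averages the m + n
   indices; conditions are ranked by descending DI.

## Statistical details and numerical choices

- **Wilcoxon implementation.** Tie-corrected normal approximation without
  continuity correction, computed from per-gene rank sums. The test suite
  cross-checks it against an independent Mann–Whitney U computation to
  1e-9.
- **pct floor 0.001.** The weight divides by the background expressing
  fraction, which can be exactly 0; the floor corresponds to the 3-decimal
  granularity of exported marker tables.
- **0/0 conventions.** Empty marker sets or all-zero uniqueness make both
  CSS numerator and denominator vanish; the score is defined as 0 ("most
  dissimilar"), the conservative anchoring. Clusters with no retained
  markers therefore yield a zero row/column (logged).
- **DI of length-1 rows/columns.** "Mean of the remaining elements" is
  undefined for a single entry; it is taken as 0, so the DI equals the
  entry itself. This is the only case where the DI is not shift-invariant;
  it is logged when it occurs.
- **Matrix-DI normalization.** Two variants exist — dividing the summed
  row/column DIs by m + n (a true mean over the m + n indices, the default)
  or by m·n. They agree only when m + n = m·n (e.g. 2 × 2) and can rank
  conditions differently, so both are implemented and selectable.
- **Grid construction.** Axis values are generated by integer index
  arithmetic (start + k·step) with a 1e-9 inclusive end tolerance, so
  binary floating-point error cannot drop the final grid value (the default
  res axis must include 2.0). The default search space, res 0.4–2.0 step
  0.2 × nPCs 10–75 step 5, has 9 × 14 = 126 cells; each extra axis
  multiplies the cell count (a 10-value third axis gives 1,260).
- **Determinism.** Every grid cell derives its seed from
  (base seed, res, nPCs) via `numpy.random.SeedSequence`; both datasets of
  a cell share that seed, so identical inputs produce identical outputs,
  and re-running a sweep reproduces the ranked table bit for bit.
- **Tie-breaking.** Equal DIs rank by fewer total clusters first
  (anti-over-clustering), then lower res, then lower nPCs — a declared
  convention, chosen because the method's intent is to keep the number of
  clusters as small as possible.
- **Failed grid cells** are recorded with status `failed` and rank after
  all successful cells; a sweep never aborts on a single cell.

## Nebula plot

For two clusters of one dataset, each displayed gene gets four violins
(cluster A, cluster B, and their backgrounds — all other cells of the same
dataset, mirroring marker detection), a diamond at the average expression
(same averaging convention as marker detection) and a bar with the
expressing fraction. Ordering: A-specific genes left, decreasing in the A
diamond; B-specific genes right, increasing in the B diamond; shared genes
center-out by the mean diamond with the maximum in the middle (alternating
right-then-left for even counts — deterministic). "Top" genes per block are
ranked by the marker weight w (mean of the two weights for shared genes),
the one ranking-compatible scalar the framework defines. SVG output is
byte-deterministic (fixed hash salt, no timestamp metadata).

## Synthetic data

`cassidi.simulate` generates the paired-dataset setting the method targets:
`k_shared` clusters present in both conditions plus optional
condition-exclusive clusters. Counts are negative-binomial
(var = μ + μ²/θ, gamma–Poisson sampling) with baseline mean 0.5 and shared
dispersion θ = 0.5; each cluster owns a disjoint block of 50 marker genes
whose mean is multiplied by `fold_change` (default 8) in that cluster's
cells. Shared clusters reuse identical marker sets in both conditions, so
the ground-truth mapping is the identity and planted uniqueness scores are
analytic (Lᵢ = 2 for shared-cluster markers, 1 for unique ones). A mean-one
log-normal library-size jitter (σ = 0.1) makes normalization non-trivial
without biasing gene means. The defaults — 1,000 genes, 200 cells/cluster,
4 shared + 1 B-only cluster — are the study condition used throughout the
tests and the acceptance script.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond cluster structure, realistic
library-size and gene-mean distributions. Passing tests therefore show that
the scoring and ranking machinery behaves as specified on clean planted
structure, not that any particular real dataset will yield a given optimal
parameter pair.

## Problem sizes

The end-to-end checks sweep a 3 × 3 grid (res {0.4, 0.8, 1.2} ×
nPCs {10, 15, 20}) over the default simulation (800 + 1,000 cells), five
seeds in the test suite and one seed in the acceptance script. These sizes
were chosen as the smallest grid that still contains clearly good and
clearly over-clustered conditions for the planted structure. Unit fixtures
use 300–750 cells per dataset.

## Known limitations

- Grid search only: optima between or outside grid points are approximated
  by the nearest cell.
- The DI presumes that one-to-one matches are expected to exist between the
  two cluster sets; it is not a general clustering-quality metric and not a
  trajectory-inference method.
- Ranking quality inherits everything from the upstream clustering: the
  backend (Leiden on an SNN graph) over-clusters clean planted structure at
  high resolutions, which the DI penalizes but cannot repair.
- Exact reproduction of cluster assignments from any specific external
  toolkit version is out of scope; the CSS/DI layers consume marker tables
  and are backend-agnostic.
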