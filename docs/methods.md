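# Methods

## Model

The annotation model is a collection of binary classifiers organized by a
cell-type hierarchy.

**Hierarchy construction.** Pseudo-bulk profiles — raw counts summed over
all cells sharing a label — are TP10K-normalized (every profile row scaled
to total 10,000) and agglomeratively clustered with Ward's method on
Euclidean distances. Ward merges produce a strictly binary tree: for *L*
cell types there are *L* − 1 internal nodes and 2*L* − 1 nodes in total. We
cluster raw TP10K rows rather than log-transformed ones by default; a
`log_transform` option applies log1p first, which compresses the influence
of a few very highly expressed genes and can be preferable for deep
references. Node numbering is breadth-first from the root (node 1), with
the left child defined as the subtree containing the alphabetically first
leaf label; this makes trees and numberings reproducible across platforms.
Hierarchies round-trip through Newick (internal labels = node numbers) and
a JSON adjacency form, and a user-supplied hierarchy can replace the
computed one as long as its leaves match the reference labels.

**Assumptions.** The hierarchy is a computational device for organizing
classification, not an ontology claim: it groups types by pseudo-bulk
transcriptional similarity. Every query cell is assumed to belong to one of
the reference types — there is no novelty detection, only per-node
probabilities a user can threshold post hoc.

**Node models.** For internal node *k* with children (*a*, *b*), every
reference cell whose leaf lineage passes through *k* is relabeled by the
child its lineage enters; the two groups always partition the cells at *k*.
Marker genes are selected by a two-sided Wilcoxon rank-sum test per gene on
per-cell TP10K + log1p expression, Bonferroni-adjusted over the full gene
universe, keeping adjusted *p* < 0.05 (α and an FDR alternative are
config). The test implementation is exact for tiny tie-free groups and
normal-approximated otherwise; constant genes get *p* = 1. All significant
genes are used, ordered by adjusted then raw *p*; there is no cap, and a
per-node override list is accepted.

**Feature transform.** Classifier features are *within-cell percentile
ranks over the node's marker genes*: zeros (and genes missing from a query)
become NaN, observed values are ranked with average ties and divided by the
number observed, giving values in (0, 1]. Consequences: any strictly
monotone per-cell count distortion (library-size scaling, depth
differences, many batch effects) leaves features bit-identical, and a tied
maximum shares an averaged rank below 1 — e.g. a two-gene cell (7, 7) maps
to (0.75, 0.75). Each node's training set is the transformed cells plus one
*sparsified* copy per cell: ⌊0.90 × n_genes⌋ entries (config 0–0.99) chosen
uniformly per cell are forced missing before ranking, emulating much
shallower sequencing. Boosters are XGBoost binary classifiers
(`max_depth=3`, 60 rounds, learning rate 0.3, hist method) with native
missing-value routing. Depth 3 is deliberate: deeper trees memorize
artifacts of the sparsified copies and lose held-out specificity in the
cancer setting, while node-level accuracy is unaffected. Training AUC is
recorded per node (resubstitution on the combined full + sparse set, so it
measures separability, not generalization).

**Annotation.** The query is embedded once: TP10K → log1p → PCA (10
components) → UMAP (15 neighbors, min-dist 0.3), then finely clustered with
Leiden on a neighbor graph built from the 2D coordinates, raising the
resolution until the cluster count reaches ≈10× the model's leaf count
(floor 10, capped by the cell count). Variable-gene subsetting and
unit-variance scaling exist as config options but default off: on panels
where a minority of genes is informative, per-gene variance equalization
drowns the discriminative axes and dispersion-based variable-gene selection
is unreliable; on atlas-scale data with dominant nuisance genes both can be
enabled. Precomputed 2D coordinates are accepted, making the annotation
machinery independent of any particular embedding.

Cells then descend the hierarchy. At each node, the booster scores the
cells currently routed there (probability ties at exactly 0.5 break to the
first child; an all-missing cell receives the booster's base response), and
the label-stabilizing step revises the binary calls before descent:

1. every fine cluster takes its modal label (ties break to the
   lexicographically smallest);
2. for each label with ≥ 25 cells, a Gaussian-KDE density (normal-reference
   bandwidth) is evaluated on a 100×100 grid spanning the embedding ± 5%,
   and the contour level is set to enclose 95% of that label's own cells
   (both config); membership is grid-interpolated at cell positions;
3. a cluster lying wholly inside exactly one *other* label's region and
   nowhere inside its own is a mislabeled island and adopts the enclosing
   label — this is applied per cluster, not per cell, because a 95%-mass
   contour excludes 5% of its own label's cells by construction and
   cell-level flipping steadily erodes small correct populations;
4. cells inside ≥ 2 labels' regions are grouped by their exact overlap
   signature and each group takes its modal label;
5. cluster modes are re-propagated.

The loop repeats until no contours overlap or labels stop changing, capped
at 10 iterations (non-convergence returns current labels with a warning).
Stabilization never introduces a label absent from its input, is idempotent
at its fixed point, and preserves the parent/child partition of cells. The
full per-node (node, predicted child, probability) record is retained per
cell; the 25-cell contour floor reflects that a 2D KDE from fewer points
does not define a stable level.

**Cancer layer.** An organ's cancer model is a single extra node trained by
the identical marker-selection/transform/sparsify pipeline to separate
malignant cells (cell lines or tumors) from that organ's normal epithelium,
whose leaf labels it records. At query time only cells whose terminal base
annotation is in that label set are scored (gating is structural:
non-epithelial cells cannot receive calls), the binary call is stabilized
on the same embedding, and each cancer cell's *cell of origin* is its
retained base terminal label — no additional model query, so origin and
base record agree by construction.

**Metrics.** One-vs-rest TP/FP/FN/TN per class with precision, recall,
specificity, F1 and balanced accuracy ((sensitivity + specificity)/2);
classes absent from both truth and prediction are omitted rather than
scored 0. Label similarity between two leaves is the shared lineage-prefix
length divided by the shorter lineage length — symmetric, in (0, 1], equal
to 1 exactly when one lineage is a prefix of the other; its per-cell mean
is therefore never below exact-match accuracy.

## Synthetic data generator

`GeneratorSpec` draws references with a known ground-truth tree: the label
tuple is recursively bisected (adjacent labels are siblings), each of the
2(*L* − 1) branches owns a disjoint block of marker genes multiplied by
`effect_size` in every type under that branch, and counts are negative
binomial with per-cell log-normal library factors followed by independent
Bernoulli dropout. Defaults: 8 pancreas-style types (immune vs non-immune
at the root), 200 cells/type, 2000 genes, 25 markers/branch, 4-fold
effects, NB mean 1.0 and size 8, 20% dropout, library σ = 0.3. The noise
level was chosen so that the 2D embedding of generated data shows the
blob-like local label purity of real scRNA-seq (≈96% same-type 10-NN
agreement at full size) — the property the stabilizer is premised on;
noisier settings produce embeddings no real pipeline would accept and make
any smoothing counterproductive. `make_tumor` derives malignant cells from
one type by copying source cells and overlaying an exclusive 50-gene
malignancy block at 8-fold — stronger than the 4-fold branch effects,
since malignant transcriptomes diverge from normal epithelium more than
sibling subtypes do — while preserving the source type's branch markers so
the origin is recoverable. Sources are sampled without replacement whenever
possible: duplicated rows concentrate repeated noise vectors into spurious
principal axes and visibly corrupt the whole query's embedding, so
query-side tumors should always come from distinct cells not present in
the query. What the generator does *not* emulate: gene–gene correlation
beyond block structure, continuous differentiation trajectories, ambient
RNA, doublets, or real marker-expression distributions — passing tests
show the pipeline's mechanics and invariants, not atlas-level performance.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` train on 70% of the default
1600-cell fixture and annotate the rest; the hyperparameter-robustness
sweep uses a 100-cell/type, 1500-gene fixture split in half (3×3 grid of
neighborhood size × min-dist, Kruskal–Wallis on per-type F1); the
cell-count sweep downsamples every type of a fresh 200-cell/type query to
{200, 100, 50, 20, 5}. Seeds: one master seed; every stochastic step
(sparsifier, boosters, PCA/UMAP/Leiden, simulations) uses a SHA-256-derived
child seed, so any artifact is reproducible from its recorded config alone.
Ties are broken deterministically throughout (first child at probability
0.5, lexicographically smallest modal label, alphabetical left-child rule).

## Known limitations

- **Small populations.** Degradation with few cells per type is driven
  entirely by the stabilizer, not the boosters: on downsampled queries raw
  per-node predictions stay essentially perfect, but below ~100 cells/type
  (at this panel size) the PCA/UMAP embedding no longer separates sibling
  types that differ in only ~50 genes, and modal propagation over impure
  fine clusters then costs more than it corrects — per-type F1 can fall
  >0.05 below full-data values at 20–50 cells/type. On very small queries
  (tens of cells) the stabilizer becomes inert instead (clusters approach
  singletons and every label is under the contour floor), so accuracy
  reverts to the raw boosters'. Disabling stabilization (`stabilize=False`)
  is advisable for small or rare-type-heavy queries.
- **Co-embedded types.** Two types overlapping in the 2D embedding cannot
  be disentangled by stabilization; sub-embedding (e.g. separate immune and
  epithelial embeddings) is the workaround.
- **No novelty detection.** Cells of types absent from the reference are
  forced into the nearest existing leaf; per-node probabilities are
  reported but no threshold is set, as a useful cutoff proved
  dataset-specific.
- Training AUC is a separability diagnostic, not a generalization estimate;
  on a label-permuted null it is far above 0.5 (boosted trees memorize),
  while held-out discrimination is at chance.
- Sarcoma/lymphoma-style malignancies (non-epithelial) are outside the
  cancer layer's gate by design; a custom model with the appropriate gate
  labels is required.
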