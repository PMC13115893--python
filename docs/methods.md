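# Methods

Conventions, model definitions, and numerical choices for the `oamethyl`
package. Nothing here asserts empirical performance beyond what the test
suite computes.

## Data model

A cohort is a `BetaMatrix`: probes × samples of beta values in [0, 1], with
sample labels (1 = case, 0 = control), batch assignments, and optional joint
annotations. Probe metadata lives in a `CpGAnnotation`: per-probe genomic
coordinates plus zero or more probe→gene links, each carrying the gene's
transcription-start-site (TSS) coordinate. Files are written as TSV (matrix,
sample sheet) and a 450K-manifest-style CSV (annotation, with semicolon-
joined multi-gene fields).

### Harmonization

`harmonize_datasets` intersects probe sets across datasets, drops probes with
any missing value, concatenates samples, mean-centers each batch per probe
re-anchored to the global probe mean, clips to [0, 1], rounds to 4 decimals,
and orders probes genomically (chr1–22, X, Y; then position; then probe id).
Because clipping at the bounds perturbs batch means, harmonization is exactly
idempotent only for probes whose values stay strictly inside (0, 1);
boundary-clipped probes can move by up to a few times the rounding quantum on
re-harmonization.

## Screening

- **Differential methylation**: per-probe Welch (unequal-variance) t-test,
  case vs. control; Δβ = mean(case) − mean(control); direction "hyper" iff
  Δβ > 0. Degenerate probes (zero variance in both groups, equal means)
  report t = 0, p = 1. p-values are Benjamini–Hochberg adjusted (step-up,
  order-preserving; verified against an independent oracle and
  statsmodels).
- **T-pool**: top-k probes by (adj_p ascending, |Δβ| descending, probe id).
- **Significant sites**: strict thresholds adj_p < 0.05 and |Δβ| > 0.2.
- **G-pool**: probes within a closed ±window (default 2000 bp) of an
  effector gene's TSS, with signed-distance provenance.

## Consensus feature selection

Per pool, two rankers: (1) SVM-RFE — features z-scored once, linear SVC
refit per round, the fraction (default 10%, at least one) of surviving
features with the smallest squared weights eliminated; rank is reverse
elimination order; (2) random-forest mean-decrease-in-impurity, probe id
breaking ties. A stratified 5-fold CV sweep over a size grid picks each
ranker's top-k (mean accuracy, then mean AUC, then smaller k); samples are
put in a canonical order before folding so results do not depend on input
row order. The per-pool intersection of the two rankers' selections gives
the consensus T-sites / G-sites; their union (with the inclusion–exclusion
cardinality identity asserted) is the U-sites.

## Fusion classifier

Input: n samples × L CpGs. Each CpG j becomes a d-dimensional token
`x[:, j] * value_weight[j] + value_bias[j] + position[j]` (a per-probe
affine embedding plus a learned position embedding).

- **Transformer branch**: post-norm encoder layers (multi-head
  self-attention over the L tokens, then a 2-layer feed-forward block,
  residual connections and LayerNorm after each sub-block), global average
  pooling over tokens, linear projection to the fusion width → `p_a`.
- **CNN branch**: stacked 1-D convolutions along the probe axis with same
  padding and ReLU, global average pooling, linear projection → `p_b`.
- **Gated fusion**: `g = σ(W2·ReLU(W1·[p_a; p_b] + b1) + b2)`,
  `fused = g ⊙ p_a + (1 − g) ⊙ p_b`; a final linear layer yields 2 logits.
  Since g ∈ (0, 1) elementwise, fused features are convex combinations of
  the branches, and mean(g) + mean(1 − g) = 1 exactly — the per-branch
  contribution statistic. Ablation modes replace the gate with
  concatenation or a single branch.

Training: class-weighted cross-entropy (weight n/(2·count) per class), Adam,
mini-batches from a seeded permutation, early stopping on the accuracy of an
internal stratified validation split with best-weights restoration.
Everything is seeded; same-seed runs reproduce weights bit-for-bit.

The network stack, including reverse-mode automatic differentiation, is
implemented in numpy; every primitive's gradient is verified against central
finite differences in the test suite.

## Panel selection

Features are ranked by gradient saliency: mean over samples of
|∂ logit₁ / ∂ input_j|. Nested prefix subsets over a size grid (default
100–320; the self-contained demo uses a desk-scale grid) are each retrained,
and the size with the best mean validation accuracy (smaller on ties) is the
panel. Provenance attributes each panel probe to T-sites or G-sites; probes
in both are credited to G ("assign-to-G"), percentages are rounded to one
decimal with the T share taken as the complement so the pair sums to 100.

## Downstream analysis

- **Gene mapping**: union of annotation links over panel probes, sorted;
  probes without links are reported as unmapped.
- **Effector status**: mapped genes partition into validated,
  database-reported (minus any overlap with validated), and novel.
- **Over-representation**: hypergeometric upper tail
  P(X ≥ k) = `hypergeom.sf(k−1, M, n, N)` per gene set, gene sets
  intersected with the background universe, BH adjustment across sets.
- **Network hubs**: STRING-style edge lists (combined score 0–1000); edges
  with score ≥ 500 (inclusive) are kept, self-loops dropped, duplicate
  undirected edges merged keeping the maximum score. Nodes are ranked by
  `0.5·minmax(degree centrality) + 0.5·minmax(betweenness centrality)`
  (weights configurable, must sum to 1), probe/gene id breaking ties.

## Synthetic cohort generator

Defaults mirror a small OA case/control study: 94 cases, 31 controls, three
batches assigned round-robin. Per-probe control means are Beta(0.8, 0.8)
clipped to [0.02, 0.98]; observed values are Beta-distributed around the
group mean with concentration 60. A chosen number of planted probes (default
100) get means drawn from a safe band ([0.15, 0.75] minus the shift) so a
±Δβ case shift (default 0.25, half hyper- half hypomethylated) never
truncates at the bounds; half the planted probes are placed inside effector
TSS windows. Batch effects are additive N(0, 0.02) per-batch/probe shifts;
optional missingness is uniform. Companion generators plant hubs in a scored
interaction network (hub degree ≥ 3× the median non-hub degree; raises if
infeasible, which needs roughly 3× more non-hubs than hubs) and enriched
gene sets (80% of members drawn from the query list).

## Determinism

Per-stage seeds derive from the global seed as
`(seed·1000003 + crc32(stage_name)) mod 2³¹`. The `RunReport` fingerprint is
a SHA-256 over the JSON-serialized configuration and stage outputs; repeat
runs with one seed are fingerprint-identical.

## Limitations

- The generator plants mean shifts only; it does not simulate probe-type
  chemistry differences, cell-type composition, or spatial correlation
  along the genome, so the cohort is easier than real array data and
  classifier metrics saturate at the default effect size.
- The demo pipeline runs a desk-scale fusion model (32-dim, one encoder
  layer) and reduced grids for runtime; the class defaults keep the full
  64-dim architecture.
- Positive-only evaluation reports accuracy on case-only cohorts; no
  specificity is estimable from it.
- Betweenness uses whole-graph pair normalization; on disconnected graphs
  cross-component pairs contribute zero rather than being renormalized per
  component.
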