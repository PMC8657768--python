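# Methods

## Problem setting

Given an undirected, unweighted protein–protein interaction network and
a set of genes with curated disease associations, the task is to rank
all remaining (unlabeled) genes by their likelihood of association with
the same disease.  The working hypothesis is guilt by association:
disease genes occupy characteristic neighborhoods of the network, so a
vector representation that preserves topological proximity should make
known disease genes separable from background genes, and the same
separator should surface hidden disease genes near the top of a
genome-wide ranking.

The framework is deliberately non-end-to-end: embeddings are learned
without labels, compressed without labels, and only the final
classifier sees the gene list.  This keeps the expensive stages
reusable across diseases and makes label leakage structurally
impossible before the classification step.

## Network model and input conventions

Networks are stored as two-column edge lists of gene identifier
strings.  On loading, duplicate lines and reversed duplicates collapse
to one undirected edge, self-loops are dropped, and extra columns
(e.g. confidence weights) are ignored — merged interactome datasets
are typically provided unweighted, and none of the embedders here uses
weights.  Gene lists are `gene_id  score` TSVs filtered at an
association-score threshold; the comparison is inclusive (score ≥
threshold, default 0.1) so boundary genes are retained, and duplicated
ids keep their maximum score.  Label genes absent from the network
cannot be embedded and are dropped at intersection time with a logged
warning.

## Random-walk embeddings (DeepWalk / Node2vec)

Walk corpus.  From every node we start `num_walks_per_node` walks
(default 10) of fixed length `walk_length` (default 80; the planted
fixture experiments use 10 × 40 — see *Problem sizes*).  Start order is
reshuffled every pass.  Isolated nodes emit length-1 walks.  The next
step from current node *v* with previous node *t* is sampled
proportionally to the second-order weights: 1/p for returning to *t*,
1 for neighbors shared with *t*, 1/q otherwise; the first step is
uniform.  With p = q = 1 every step is uniform over neighbors, which is
DeepWalk — the two embedders share one code path and differ only in
configuration.  Sampling uses the alias method; per-directed-edge alias
tables are precomputed when the graph has at most
`precompute_edge_cutoff` directed edges (default 2·10⁶) and built on
the fly otherwise, with bitwise-identical output either way since both
paths consume the same random draws.

Skip-gram with negative sampling.  Training pairs are all (center,
context) node pairs within a window (default 10) of each walk
position.  The per-pair objective is

    L = −log σ(u_ctx · v_c) − Σ_{k=1..K} log σ(−u_k · v_c)

with K = 5 negatives drawn from the unigram^0.75 distribution over
corpus node frequencies.  Defaults (window 10, 5 negatives, 5 epochs,
learning rate 0.025 decayed linearly to 10⁻⁴) are the canonical
word2vec choices; nothing in the disease-gene setting argues for
different ones, and all are config-exposed.  The input-vector
(hidden-layer) table is the exported embedding.  Input vectors
initialize uniformly in [−0.5/d, 0.5/d], context vectors at zero, so
the loss of an untouched pair is exactly (1+K)·ln 2.

Two numerical choices deviate from the original word2vec C
implementation, deliberately: (i) updates are plain sequential SGD with
per-epoch pair shuffling — no asynchronous threads — so runs are
bitwise reproducible; (ii) the center vector is updated after each
individual positive/negative term rather than once per pair with an
accumulated gradient.  Both are SGD on the same objective; analytic
gradients are verified against central finite differences to relative
error < 10⁻⁴.  The inner loop is numba-compiled with an explicit
xorshift64* RNG carried in the state array, which is what makes
"deterministic given seed" an exact statement rather than a
single-threaded-BLAS hope.

## LINE

LINE trains by edge sampling instead of walks: each SGD step draws one
edge (uniformly — for an unweighted graph this is the degree-weighted
vertex draw of the original method) in a random orientation, plus K = 5
negatives from the degree^0.75 distribution.  First-order proximity
ties the two endpoint vectors directly (shared table); second-order
uses a separate context table.  The default `order="concat"` trains
both at d/2 and concatenates the row-normalized halves, the
recommendation of the original method.  Total samples default to
100 × n_edges.  The per-sample objective and gradients are the same
logistic forms as SGNS and share the compiled kernel.  LINE is known to
underperform on low-degree vertices; the order choice is surfaced in
the CLI rather than hidden.

## Stacked autoencoder

Embeddings are standardized per feature (the constants are stored and
reused at prediction time), then compressed by a greedy stack of
one-hidden-layer autoencoders: sigmoid encoder, linear reconstruction,
mean-squared reconstruction error.  Each level trains on the previous
level's codes; there is no end-to-end fine-tuning pass — the stack is
exactly the greedy pretraining procedure.  Widths follow a halving
rule from the input dimension to the bottleneck (512 → 256 → 128 → 64
gives the three-level stack for 512-dimensional features; the fixture
experiments use 32 → 16 → 8).  The optimizer is mini-batch Adam
(batch 32, learning rate 10⁻³, 100 epochs by default): a plain-SGD
variant reached the same optima only with per-dataset learning-rate
tuning, and the choice of gradient-descent flavor is not part of the
scientific claim.  Training is seeded and deterministic; encoding is
strictly per-row, so a gene's compressed vector depends only on its own
input vector given the trained weights.

## Classification and evaluation

Dataset assembly draws |positives| negatives uniformly without
replacement from the unlabeled genes (seeded).  Negatives are drawn
once per experiment, not per fold — negative selection is part of
dataset assembly, not of the resampling protocol — but
`cross_validate(refresh_negatives=...)` provides the per-fold variant.

Classifiers.  The SVM is a soft-margin RBF-kernel machine with
Platt-style sigmoid calibration of decision values (scikit-learn's
`SVC(probability=True)`), which preserves the rank order of decision
values and yields scores in [0, 1]; the random forest reports the mean
class probability over trees (scikit-learn, default settings, seeded).
Both are used as commodity classifiers.  Logistic regression is
implemented natively — gradient ascent on the ridge-penalized
log-likelihood with an adaptive step size, stopping at gradient norm
10⁻⁶ — because its equation defines the score semantics.

Metrics are likewise native.  Confusion-count metrics follow the
closed forms (precision TP/(TP+FP), recall = TPR = TP/(TP+FN),
FPR = FP/(TN+FP), ACC = (TP+TN)/N, F1 = harmonic mean); any metric
with a zero denominator is reported as NaN, never silently 0.  ROC and
PR curves place one operating point per distinct score threshold
(predict positive at score ≥ threshold); ROC additionally carries the
(0,0) and (1,1) endpoints.  The PR curve uses achieved points only —
no synthetic (0,1) anchor — a convention that matters when comparing
AUPRC values across toolkits; if a degenerate all-tied score vector
produces a single PR point, its precision is reported as the area
(constant-precision curve).  Areas use the trapezoid rule.  On
tie-free data the resulting ROC-AUC equals the Mann–Whitney statistic
U/(n₁n₀) to numerical precision, which the tests assert.

Cross-validation is stratified k-fold (default 5, seeded shuffle), so
every fold contains both classes and fold class balance deviates from
global balance by at most one sample; per-fold metrics are reported
alongside their arithmetic mean.

## Ranking

The final model trains on all known positives plus one seeded balanced
negative draw, then scores every unlabeled gene.  The output table is
sorted by descending score with ties broken by gene id, and is a
permutation of the unlabeled gene set.  Genes that served as training
negatives remain in the table — they are unlabeled and therefore
legitimate candidates — flagged `used_as_negative` so the reader can
see potential training leakage instead of having it silently hidden
either way.  `top_k` and the subnetwork exporter (largest connected
component induced on top-predicted plus known genes, annotated
known/predicted) support downstream inspection.

## Synthetic study conditions

The fixture is a planted-partition (stochastic block model) graph:
within-block edge probability p_in, between-block p_out < p_in.  The
default study conditions are two blocks of 200 nodes with p_in = 0.1
and p_out = 0.005 (mean within-degree ≈ 20, between-degree ≈ 1), with
80% of one block planted as known disease genes and, for ranking
experiments, 20% of those hidden from training.  Block membership is
precisely the neighborhood structure guilt-by-association assumes, so
recovery of the planted block is the right end-to-end correctness
signal, and signal strength is tunable.

What the fixture does *not* emulate: the heavy-tailed degree
distribution of real interactomes, study bias (well-studied genes have
more recorded interactions *and* more recorded disease associations),
noisy or missing edges, and disease genes spread over several modules.
Passing the planted-signal tests therefore demonstrates that the
machinery recovers clean community signal, not that any particular
AUROC will be reached on a real disease.  One property of real data the
fixture does reproduce, intentionally: the unlabeled pool contains
hidden true positives (the unplanted 20% of the block), so measured
AUROC has a ceiling below 1 — with 160 of 200 block genes labeled,
40 of the 240 unlabeled genes are hidden positives, capping AUROC near
1 − ½·(40/240) ≈ 0.92 even for a perfect block separator.

## Problem sizes and determinism

The shipped experiments are sized for a single CPU: 400-node fixtures,
d = 32 embeddings from 10 walks of length 40 per node, a 32→16→8
stack, 5-fold CV, three seed replicates.  These sizes were chosen so
that the full planted-signal experiment, including three independent
seeds, completes in well under a minute while leaving the community
signal unambiguous; all of them scale up by configuration only.

Every stage derives its randomness from a single integer seed (numpy
PCG64 outside the compiled kernels, xorshift64* inside them), and all
training loops are sequential, so identical configuration and seed
reproduce every artifact bitwise.  Chi-square goodness-of-fit checks of
the walk transition distributions pool cells below expected count 5
(Cochran's rule), folding small remainders into the smallest retained
cell.

## Known limitations

- No identifier mapping between gene/protein namespaces; inputs must
  already share one namespace.
- Edge weights and directions are ignored by design.
- The SGNS/LINE kernels are single-threaded; embedding a full
  interactome (~10⁴ nodes, ~10⁵ edges) takes minutes, not seconds.
- No denoising corruption, sparsity penalties, or supervised
  fine-tuning in the autoencoder; no hyperparameter search beyond the
  exposed grid harness.
- Hidden-positive contamination of sampled negatives is inherent to
  the one-class-plus-background setting; the package surfaces it (flag
  column, documented ceiling) but does not correct for it.
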