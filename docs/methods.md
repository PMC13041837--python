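# Methods

## Problem and model

`perturbgraph` predicts whether perturbing (knocking out / knocking down) a
*source* gene g significantly affects a molecular phenotype P. The phenotype
is represented by one or more surrogate *target* nodes in a gene/protein
knowledge graph: an undirected interaction graph in the style of the STRING
physical subnetwork, with per-edge evidence channels E (experimental), D
(curated database), T (text mining) and a combined confidence score in
[0, 1], and per-node attributes (cellular abundances, subcellular
localization over a 41-term hierarchical compartment taxonomy, and GO
annotations).

A binary classifier f(x) -> {0, 1} is trained on a feature vector

    x(g, P) = [ n(g) | e(g -> P) | n(P) ]

where n(·) are node features (112 columns: 3 abundances + 3
measured-indicator bits + 41 localization bits + a 64-dim GO embedding + a
GO-presence bit) and e(g -> P) are source–target relation features (57
columns at the default maximum path length of 3): evidence n-gram counts
over all simple paths of length 1–3 (3 + 9 + 27 = 39 features), the best
path confidence max over paths of the product of edge combined scores, a
thermometer encoding of the shortest path length (bit i set iff s <= i),
path count and a path-existence indicator, the maximum over paths of
prod 1/degree(u_i) over interior-plus-terminal nodes, random-walk-with-
restart scores of the source under target-only seeding at restart
probability alpha in {0.2, 0.4, 0.6}, localization- and GO-block cosine
similarities to the targets, and signed/absolute abundance differences.

Labels come from published screen statistics consumed as given: pooled
labeling (positive iff any screen reports FDR < 0.1), per-target labeling
(q < 0.05 per source–target pair), and a stringent-negative variant
(negatives FDR > 0.9 or round-dropout; ambiguous middle dropped). All
thresholds are strict; boundary values are non-significant.

## Diffusion kernels

With unweighted adjacency A and degree matrix D:

* random walk: p_t = W^t p0, W = A D^-1 (column-normalized), computed by
  repeated sparse multiplication;
* random walk with restart: p = alpha (I - (1 - alpha) W)^-1 p0, solved as a
  sparse linear system and cross-checked against the fixed-point iteration
  p <- alpha p0 + (1 - alpha) W p;
* heat: p = exp(-alpha (D - A)) p0, dense matrix exponential below 500
  nodes, Krylov action of the exponential above.

Isolated nodes get a zero column in W (walk mass vanishes rather than
self-looping); this keeps W well defined without inventing self-loops.
Seeding is either *target* (targets only) or *positive* (targets plus
training-set positive sources). As baselines, an instance's score is its
source's post-diffusion score, with the best AUROC reported over the grids
t in {10, 20, 30}, RWR alpha in {0.2, 0.4, 0.6}, heat alpha in
{0.1, 0.2, 0.3}; the shortest-path baseline scores an instance by minus the
distance to the nearest target.

## GO embedding

Genes are linked by the Jaccard index J(u, v) of their GO annotation sets; a
directed graph keeps each annotated gene's top-k = 20 neighbors with J > 0
(ties broken lexicographically for determinism). Embeddings are learned with
node2vec-style walks (10 walks of length 30 per node, return/in-out
parameters p = q = 1 by default, walking along out-edges with transition
probabilities proportional to J) and a skip-gram model with negative
sampling (window 5, 5 negatives, 2 epochs, linearly decaying learning rate
from 0.025) implemented in numpy with minibatched SGD so that a fixed seed
gives a bit-identical embedding. Genes without annotations are excluded from
the graph and represented by the zero vector with presence bit 0. gensim is
not available in the supported environment; the in-package trainer is the
deliberate substitute and is validated by a community-recovery test.

## Training and evaluation

Four learner families: elastic-net logistic regression (saga, max 5000
iterations), random forest (1,000 trees), gradient boosting, and a
fully-connected neural network (one hidden layer, or two with the second a
quarter of the first; ReLU or sigmoid). The first two use sklearn's balanced
class weights; gradient boosting uses balanced sample weights. XGBoost is
not installable offline, so the gradient-boosting family is sklearn's
`GradientBoostingClassifier` (the L1-penalty grid axis has no analogue and
is omitted). The neural net is sklearn's `MLPClassifier`, which offers
neither dropout nor class weights: regularization falls to the default L2
term and imbalance is handled by seeded oversampling of the minority class.
These are the two places the implementation consciously diverges from an
ideal dropout-0.3, weighted-loss network.

Hyperparameters are tuned by exhaustive grid search with internal 5-fold
stratified cross-validation, selecting the best mean inner AUROC (the outer
evaluation metric), then refitting on the full training split. Default grids
are in `perturbgraph.learn`; every test and script may pass a smaller grid —
grid size trades compute for tuning quality and is not part of any
correctness property.

Outer evaluation is 5-fold cross-validation with folds either stratified by
label (per-fold positive counts differ by at most 1) or grouped by source
gene (no source spans two folds). One positive *target-as-source* instance
per target node is injected into every training fold — targets are known to
matter for their phenotype — flagged and never tested, and deduplicated
against screened positives. ROC curves pool test predictions across folds
(mid-rank tie handling via `sklearn.metrics.roc_auc_score`). Min-max
scaling is fitted on training rows only; test values are clipped to [0, 1];
a constant training column maps to 0. Protocols: learning curves
(unstratified subsampling of each training set at given fractions, with up
to 10 redraws if a subsample is single-class), feature-group ablations
(subgraph groups source / target / st_relation, or evidence-type groups
abundance / localization / go / ppi), and cross-phenotype transfer (train on
all of phenotype A, score all of B) with RWR diffusion columns — the only
phenotype-specific columns in the synthetic setting — dropped, optionally
restricted further to st_relation columns only.

## Numerical and design choices

* Maximum simple-path length L_max = 3: length-4 enumeration is
  combinatorial on dense interaction graphs. Paths are simple; cycles would
  make n-gram counts unbounded.
* No-path sentinels: confidence 0, inverse-degree product 0, thermometer
  all-zero, count 0 — "absent" is always the feature minimum.
* A source that is itself the sole target uses the identity convention
  (existence 1, thermometer all-ones, confidence 1, degree product 1,
  cosines 1); with other targets present, path features are computed
  against the remaining targets.
* Zero-norm cosine is 0. Abundances are log1p-transformed by default
  (`FeaturesConfig.log_abundance`) before differencing; this is a package
  choice, not an established convention.
* RWR relation features always use target-only seeding, so feature
  construction never touches labels.
* Missing abundances are imputed to 0 alongside an explicit measured bit.
  Localization bits are ancestor-closed under the taxonomy, making them
  monotone along the hierarchy.
* Similarity aggregation over multiple targets defaults to max
  (`sim_agg="mean"` available).

## Synthetic worlds: what they do and do not establish

The generator plants the one mechanism the method is built around: label
probability decays with shortest-path distance to the nearest target
(default rates {1: 0.8, 2: 0.4, 3: 0.1, else 0.02} on an Erdős–Rényi graph
with n = 300, p = 0.03, 2 targets, seed 7). FDRs are drawn so that label 1
<=> FDR < 0.1 exactly (positives ~ U(0, 0.1), negatives ~ U(0.1, 1)). GO
annotations optionally carry community structure keyed to target proximity;
abundances are log-normal with 10% missingness; localization terms are
drawn uniformly. Scores are U(0.4, 1); each evidence channel is present
independently (E 0.5, D 0.35, T 0.6) with at least one forced. Isolated
genes are removed from the world entirely.

Because the planted label depends on graph distance *alone*, ranking by
distance is Bayes-optimal on these worlds: a learner can at best match the
shortest-path baseline, and with the default Erdős–Rényi density (mean
degree ~9, so nearly all genes sit at distance 2–3 from a target) that
ceiling is itself moderate. Green end-to-end tests therefore establish that
the pipeline recovers the planted proximity signal, beats label-permuted
controls, and transfers across phenotypes sharing the mechanism — not that
it reaches any particular absolute AUROC, and not that it handles the
heavy-tailed degree distributions, correlated annotations, and assay noise
of real screens.

## Known limitations

* The neural-net family lacks dropout and weighted loss (see above).
* Diffusion uses the unweighted adjacency; combined scores are not used as
  edge weights in the kernels (they enter through path-confidence features).
* No identifier mapping: gene ids are opaque strings and must match across
  input tables.
* Simple-path enumeration beyond L_max = 4 is impractical on dense graphs.
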