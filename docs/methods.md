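# Methods

## Model

`pathprime` implements a feed-forward cell-type classifier over a cells ×
genes expression matrix whose first hidden layer is structured by prior
biological knowledge. Layer propagation is the standard

    x_i = a(W_i · x_{i-1} + b_i)

with elementwise activation `a` (tanh by default; relu, sigmoid and linear
are supported) and a softmax output over the M cell types, trained by
minimising the multi-class cross-entropy −Σ_c y_c log p_c averaged over
mini-batches.

The biological structure enters through a binary genes × nodes *prior
mask* built from a gene-set collection (GMT): the first hidden layer holds
one node per gene set, and the weight from gene g into node j is
constrained to zero unless g is a member of set j. A first layer may mix
freely connected dense nodes with biological nodes; the layout is
`[dense block | biological block]` and downstream layers see the
concatenation. Only the first hidden layer may carry a mask; deeper layers
are dense.

Masking is enforced in two redundant ways: the gradient of the first-layer
weight matrix is multiplied elementwise by the mask (so masked entries
receive no update, and momentum/Adam accumulators stay identically zero
there), and the weight matrix itself is re-multiplied by the mask after
every optimizer step as a defensive invariant. Masked entries are therefore
exactly 0.0 — not merely small — at every point of training, which the test
suite asserts via a per-step callback.

Because the full first-layer matrix is Glorot-initialised *before* masking,
a network with an all-ones mask is bit-for-bit identical to the dense
network of the same widths under shared seeds, including its entire
training trajectory. This equivalence is the strongest available check that
masking changes connectivity and nothing else.

## Training

- **Initialisation**: Glorot (uniform on ±√(6/(fan_in+fan_out))), seeded;
  biases start at zero.
- **Optimizers**: mini-batch SGD with classical momentum and a
  learning-rate schedule lr_t = lr/(1 + decay·t) over optimizer steps t
  (decay 0 by default), or Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).
  Defaults: SGD lr 0.01, momentum 0.9; Adam lr 0.001.
- **Schedule**: 100 epochs of shuffled mini-batches of 10, no early
  stopping, no dropout layers, no class weighting.
- **Determinism**: every random consumer (init, shuffling, splits, class
  sampling, hyperband) draws from a generator seeded by the relevant config
  seed plus a fixed stage offset; repeated runs are bitwise identical. The
  implementation is pure numpy, so no BLAS-threading nondeterminism arises
  at these sizes.
- Probabilities are clipped to [1e-12, 1] before the log in the loss;
  argmax ties in prediction resolve to the lowest class index; class order
  is the lexicographic sort of the training labels.

The network code is written in numpy with explicit backprop rather than on
top of a deep-learning framework: the masked layer *is* the core of the
package, the models involved are small (≤ ~10⁶ parameters), and an explicit
implementation keeps the mask invariant auditable and the arithmetic
deterministic on a single CPU thread.

## Preprocessing

Three transforms are provided, all fit on the training fold and reapplied
(never refit) to test folds:

- `zscore` (default "normalization"): per-gene (x−mean)/sd; genes with zero
  training variance map to 0,
- `log1p`: elementwise log(1+x) on non-negative input,
- `minmax_sym`: per-gene affine map of the training range onto [−1, 1],
  test values clipped.

The protocols fingerprint the fitted statistics so that train/test leakage
is structurally impossible; a dedicated test asserts that training-fold
statistics differ from test-inclusive recomputation.

## Unsupervised reuse of the classifier

- **Encoding**: activations of the last hidden layer with the output layer
  detached — the cell representation used for clustering, retrieval and
  2-D visualisation (t-SNE seeded with perplexity min(30, (n−1)/3), 1000
  iterations, PCA init; or exact-solver PCA).
- **Pathway activities**: first-hidden-layer activations restricted to the
  biological block, one column per gene set.
- **Node ranking** (`top_nodes_per_class`): for each cell type, hidden
  nodes ranked by the weight connecting them to that type's output neuron,
  descending, top n = 10 by default.

### Why ranked weights are orientation-corrected

A symmetric hidden unit is only identified up to sign: tanh(−z) = −tanh(z),
so a node can represent "member genes elevated" by firing at −1 with a
compensating negative output weight, and gradient descent picks either
orientation depending on initialisation. Raw signed output weights
therefore conflate "this pathway drives this cell type" with an arbitrary
internal sign choice — on synthetic data with known truth, the raw ranking
frequently placed a generative active pathway at the *bottom* of a class's
list while that same node carried the largest-magnitude output weight.

The default ranking removes the ambiguity using weights alone: each node is
oriented by the sign of its summed incoming weights (positive = the node
fires positive when its member genes are elevated), and the
orientation-corrected output weight is ranked descending. The literal raw
ranking (`orient="none"`) and magnitude ranking (`use_abs=True`) remain
available. For two-hidden-layer designs there is no single weight
connecting a pathway node to an output, so the default scores each pathway
node by total route strength Σ |W₂| |W₃| through the second layer
(`path_product`); ranking the last layer's (dense) nodes directly is also
exposed, since neither convention is canonical.

## Evaluation

- **Supervised**: accuracy, balanced accuracy, and precision/recall/F1
  under macro, micro and weighted averaging (scikit-learn backed;
  zero-division cases score 0 silently). Micro-averaged scores equal
  accuracy for single-label problems, which the tests exploit as an
  identity check.
- **Clustering**: homogeneity, completeness, V-measure, ARI, AMI
  (arithmetic-mean normalisation) and Fowlkes-Mallows between K-Means
  clusters of an encoding and the true labels, plus their arithmetic mean.
  K-Means uses n_init = 10 seeded restarts; K equals the number of distinct
  true cell types in the evaluated split — the only choice that keeps the
  comparison to supervised results meaningful.
- **Retrieval**: each query cell is matched to its k = 100 euclidean
  nearest reference encodings (distance ties broken by ascending reference
  index); average precision AP = (1/R) Σ precision@i·rel(i) with R the
  number of same-type neighbours within the top k (AP = 0 when R = 0;
  normalising by the reference-wide relevant count is available via
  config). APs are averaged within each query type, and the headline MAP is
  the *unweighted* mean over types. Under the reference/query protocol the
  two sets are disjoint, so no self-match exclusion applies by default; a
  flag enables it for self-retrieval uses.

All metric implementations are cross-checked in the test suite against
brute-force contingency-table oracles (including an exhaustive-tail
hypergeometric and a from-scratch expected-mutual-information sum) on
hundreds of random label vectors at 1e-9.

## Validation protocols

- **Repeated stratified holdout** (default 100 × test 0.30): per-class test
  counts are apportioned by largest remainder of test_size·n_c (ties by
  class order), guaranteeing every class at least one training cell; each
  repeat reseeds the split, the preprocessing fit and the network.
- **Leave-P-groups-out** (default 20 repeats, P ∈ {2,…,M−1}): P cell types
  drawn uniformly without replacement per repeat are fully held out; the
  network trains on the complement, the held-out cells are encoded and
  clustered with K = P, and the six clustering scores are recorded. The
  train/test class sets are asserted disjoint in every repeat.
- **Retrieval protocol**: train on the full learning set, encode both sets,
  score per-type MAP; k is clamped with a warning when the reference is
  smaller than k. Gene spaces must be intersected (and the mask rebuilt)
  before training.
- **Hyperband** over SGD learning rate (log-uniform), momentum (uniform)
  and decay (log-uniform): standard bracket arithmetic with resource =
  epochs — s_max = ⌊log_η R⌋ brackets, bracket s starting
  ⌈(B/R)·η^s/(s+1)⌉ configs at R·η^(−s) epochs and keeping the top 1/η per
  rung. The objective is accuracy on an internal stratified 80/20 split of
  the learning data (the evaluation sets are never touched); candidates are
  retrained from scratch at each rung's budget, which costs little at these
  model sizes and keeps rungs comparable.

## Interpretation

Member genes of a cell type's top-ranked pathways (restricted to the
model's input genes when mask-aware) are tested for annotation-term
overrepresentation: one-sided upper-tail hypergeometric p = P(X ≥ overlap)
with X ~ Hypergeom(N, K, n), Benjamini-Hochberg corrected across all tested
terms at α = 0.05. The universe defaults to the model's input gene space —
the genes the network could possibly have used — rather than a whole
genome, and zero-overlap terms are kept (p = 1) so the BH denominator is
the full number of tested terms.

## Synthetic data generator

The generator emulates the statistical skeleton the masked network is
designed to exploit: genes partitioned into disjoint pathway blocks (an
overlap knob exists) plus unassigned background; each cell type activates
a few pathways; counts drawn from a negative binomial with
log-mean = log(base_mean) + effect_size·1[gene in an active pathway] and
variance μ + dispersion·μ²; and dropout simulated by independent Bernoulli
zeroing.

Defaults — 5 cell types × 200 cells, 2000 genes, 20 pathways × 40 genes
(60% background), 3 active pathways per type, effect 2.0 (≈ 7.4-fold),
base mean 1.0, dispersion 0.3, dropout 0.2 — give a sparse, overdispersed,
zero-inflated matrix in the realistic range for counts-level scRNA-seq,
with class structure strong enough that recovery failures indicate
implementation defects rather than noise.

What the generator does **not** emulate: library-size variation, batch
effects, gene–gene correlation beyond shared pathway membership, biased
(expression-dependent) dropout, or overlapping pathway hierarchies. Passing
tests therefore demonstrate that the machinery is correct and that the
method behaves as designed when its assumptions hold — not that it attains
any particular performance on real tissue atlases.

## Problem sizes in tests and the acceptance script

The shipped validation runs use the generator defaults with scaled-down
repeat counts chosen to exercise every code path at meaningful size:
holdout 10 repeats, LPGO 5 repeats at P = 2 on a 6-type dataset, retrieval
on disjoint stratified halves (reference 500 cells, k = 100), and pathway
recovery over 5 independent generator/training seeds at 100 epochs. Unit
tests use smaller fixtures (3 types × 40 cells, 6 pathways).

## Known limitations

- A single mask level: no nested pathway hierarchies or gene-to-multiple-
  node weighting beyond binary membership.
- The orientation heuristic assumes a node's incoming weights are
  predominantly one sign; a node that splits its member genes into
  oppositely-signed subsets (possible with strongly anti-correlated genes
  inside one set) would be oriented by the majority direction.
- Hyperband tunes SGD only (the three hyperparameters it searches are
  SGD-specific); Adam runs with its standard defaults.
- No GPU path and no sparse-matrix training; dense numpy is ample at the
  intended scale (hundreds of pathways, thousands of genes and cells).
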