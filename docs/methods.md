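# Methods

## The model

`mangf` predicts missing edges in a heterogeneous molecular association
network (MAN): an undirected graph over five entity types — miRNA, lncRNA,
protein, drug, disease — joined by nine relation types (miRNA–lncRNA,
miRNA–disease, miRNA–protein, lncRNA–disease, lncRNA–protein,
protein–disease, drug–protein, drug–disease, protein–protein).  Every node is
represented by the concatenation of two 64-dimensional vectors:

* an **attribute vector** derived from what the node *is* — sequence
  composition, disease semantics, or chemical structure — and
* a **behavior vector** derived from what the node *does* — its edges —
  learned by graph factorization (GF).

A candidate edge becomes the 256-dimensional concatenation of its two
endpoint vectors (lower node index first, so undirected pairs have a unique
feature vector), scored by a binary classifier trained on known edges versus
sampled non-edges.

### Attribute vectors

* **ncRNA** (miRNA, lncRNA): normalized 3-mer frequencies over {A, C, G, U}
  (T is read as U), a 4³ = 64-dimensional simplex vector.  Windows containing
  ambiguous symbols are skipped; the denominator is the count of valid
  windows.
* **Protein**: the 20 amino acids are collapsed into four side-chain
  polarity groups — (A,V,L,I,M,F,W,P), (G,S,T,C,N,Q,Y), (R,K,H), (D,E) —
  and the reduced 4-letter sequence is encoded exactly like ncRNA (64 dims).
  Non-standard residues (X, U, B, ...) invalidate the windows containing
  them.
* **Disease**: each disease's MeSH tree numbers define a DAG containing the
  descriptors and all dot-prefix ancestors.  A node t of the DAG of disease D
  contributes `D1_D(t) = 1` if t is D itself, otherwise
  `max(Δ · D1_D(t'))` over children t', i.e. Δ^distance along the shortest
  descendant chain.  Two diseases are compared by the shared-ancestor
  similarity: the sum of both contributions over the intersection of their
  DAGs divided by the sum of their total semantic values.  A disease's raw
  attribute is its similarity row against all diseases; rows are compressed
  to 64 dims by a sparse autoencoder (SAE).
* **Drug**: a Morgan fingerprint (radius 2, 1024 bits by default, via rdkit
  when a SMILES is supplied; precomputed bitstrings are accepted so the
  chemistry backend is optional), compressed to 64 dims by a second SAE.

Δ defaults to 0.5, the standard attenuation factor in the MeSH-similarity
literature; it is configurable.  One SAE is trained per node type because
the raw input dimensions differ.

### Sparse autoencoder

A single hidden layer of 64 units.  The hidden activation is a sigmoid so
that mean activations are valid rates in (0, 1) for the KL sparsity penalty;
the output activation is ReLU.  The loss is

    J = (1/m) Σ ½‖x − x̂‖²  +  α Σ_j KL(ρ ‖ ρ̂_j)  +  β‖W‖²₂

with ρ̂_j the mean activation of hidden unit j over the batch.  Defaults:
ρ = 0.05, α = 1.0, β = 1e-4, 100 epochs of mini-batch gradient descent
(batch 32, learning rate 0.01), weights initialized U(−0.05, 0.05), seeded.
Inputs are min-max scaled to [0, 1] per feature (a no-op for similarity rows
and bit vectors).  Output thresholds are initialized at 0.5 — the midpoint
of the scaled target range — because ReLU output units initialized at zero
bias can be driven permanently inactive early in training (a unit whose
pre-activation is negative for every sample receives no gradient); starting
at the target midpoint removes this failure mode without changing the
architecture.  Analytic gradients are verified against central finite
differences in the test suite.

### Graph factorization

Behavior vectors are the rows of Z minimizing

    f(Y, Z, λ) = ½ Σ_{(i,j)∈E} (Y_ij − ⟨Z_i, Z_j⟩)² + (λ/2) Σ_i ‖Z_i‖²

where Y is the 0/1 adjacency (each undirected edge counted once, Y_ij = 1
for all known edges).  Training is sequential stochastic gradient descent:
edges are visited in a seeded shuffled order each epoch with learning rate
η = 1/√t for a global step counter t that is never reset; training stops
when the squared Frobenius change of Z between epochs falls to ε, or at the
epoch cap.  Two deliberate choices:

* **Regularizer sign.** The per-edge update applies the regularizer in the
  descent direction (−λZ_row), consistent with the gradient of f; the
  alternative sign would ascend the penalty term.  With λ = 0 both coincide.
* **Symmetric updates.** Each edge visit updates *both* endpoint rows from
  their pre-update values.  Each undirected edge is stored once, so updating
  only one side would make the result depend on storage order.

Defaults: rank r = 64, λ = 0.01, ε = 1e-4, at most 500 epochs,
Z₀ ~ U(−0.5/√r, 0.5/√r).  The epoch cap is set high enough that the
ε-criterion, not the cap, normally terminates training — on the default
synthetic network the optimizer converges after roughly 250–350 epochs and
under-fits badly if stopped an order of magnitude earlier.  The inner edge
loop is JIT-compiled (numba) when available, with an equivalent numpy
fallback.  Gradients are verified against finite differences; embeddings
are bit-reproducible for a fixed seed, and appending isolated nodes leaves
existing rows unchanged.

### Classifier

Random Forest by default; Extra Trees, logistic regression and Gaussian
naive Bayes are the compared alternates.  Hyperparameters are pinned
explicitly rather than inherited from a library version: RF/ET 100 trees,
Gini impurity, unlimited depth; LR with L2 penalty at unit regularization
strength; Gaussian NB.  The decision threshold for confusion-matrix metrics
is 0.5.  Pair features are plain concatenations — element-wise products or
averages were rejected because they discard per-node information and the
canonical endpoint order already resolves direction ambiguity.

## Evaluation protocols

Positives are all curated edges; an equal number of negatives is sampled
uniformly from unlinked, type-legal node pairs, **stratified by relation
type** (per-type negative counts match per-type positive counts) so the
classifier cannot score on relation-type priors alone.  One global negative
set is sampled and then split across folds.

* **k-fold cross-validation** (default k = 5): labeled edges are dealt into
  near-equal folds, stratified by label.  In every fold the embedding is
  re-fit on training positives only — test edges are stripped before
  factorization, and a runtime assertion verifies the test set never
  intersects the embedding input.  Node attributes are intrinsic to nodes
  (never edges) and the node set is constant across folds, so the per-fold
  SAE fit is identical in every fold and is computed once per experiment.
* **Feature ablation**: attribute-only (64), behavior-only (64), combined
  (128) representations on shared folds, negatives and per-fold embeddings.
* **Training-proportion sweep**: 20/40/60/80 % of edges retained; the
  embedding is fit on the retained network, the classifier trains on
  retained positives plus matched negatives and is tested on the held-out
  complement plus matched negatives (behavior-only representations).
* **Classifier comparison**: NB, LR, ET, RF on identical folds and features.
* **Local vs global** (single target relation, default miRNA–disease): four
  pipelines on shared folds — attribute-only; attribute ∥ Gaussian
  interaction-profile (GIP) kernel rows compressed to 64 dims by an SAE;
  attribute ∥ embedding of the target sub-network only; attribute ∥
  embedding of the whole network.  The GIP kernel is
  K(i,j) = exp(−γ‖y_i − y_j‖²) with γ = γ′ / mean‖y‖² over that side's
  training interaction profiles.
* **Leave-one-disease-out case study**: all *target-relation* edges of one
  disease are withheld; the disease keeps its other relation types, which is
  what lets the whole-network embedding still place it meaningfully.  The
  model is re-fit and every type-legal candidate is ranked (ties broken
  lexicographically for reproducibility).

Metrics: accuracy, sensitivity, specificity, precision and MCC at threshold
0.5 (MCC is 0 by convention when its denominator vanishes), ROC-AUC by
trapezoidal integration with tied scores grouped, and AUPR as average
precision without interpolation.  Tables are reported on the percent scale;
internal values are fractions.  The AUC implementation is cross-checked
against a brute-force pairwise-comparison estimator (ties counted ½) in the
tests.

## Synthetic study conditions

The generator plants a low-rank logistic edge model: every node gets a
latent u ~ N(0, I_d) with d = 8 (far below the embedding rank 64, so the
factorization can always express the planted structure), and each type-legal
pair is an edge with probability σ(a·⟨u_i, u_j⟩ + b_rel), the intercept
b_rel calibrated by bisection to a per-relation density target.  Defaults,
chosen once as the study conditions:

* node counts 120/100/150/80/90 (miRNA/lncRNA/protein/drug/disease),
  ≈ 540 nodes;
* per-relation density 0.05 → ≈ 5,500 edges and mean degree ≈ 20, the same
  order as curated association networks (the 6,528-node/105,546-edge
  network this design targets has mean degree ≈ 32);
* edge slope a = 2.0, at which the *oracle* discriminability (ranking pairs
  by the true latent inner product) is AUC ≈ 0.96 — the regime curated
  networks empirically support;
* attribute signal s = 0.9: sequence 3-mer emissions are tilted by a fixed
  linear map of the node's latent vector and mixed with a uniform
  background at weight 1 − s; fingerprint bits fire with probability
  σ(s·w_b·u) for fixed unit directions w_b.  s = 0 severs attributes from
  the link structure entirely, which the tests use to show the attribute
  pathway collapsing to chance while the behavior pathway is unaffected;
* structural noise 0 (a `noise_rate` knob can mix in latent-independent
  edges; curated positives are treated as ground truth here, matching how
  such networks are evaluated);
* disease MeSH descriptors are drawn from a random forest of tree numbers
  (depth 4, branching 3), **independent of the latents**.

What the generator deliberately does *not* emulate: scale-free degree
distributions, correlation between disease semantics and disease
associations, literature biases, or identifier noise.  Three consequences
for interpreting green tests: (1) passing recovery tests show the pipeline
recovers planted low-rank structure, not that real networks are low-rank;
(2) because synthetic disease attributes carry no link signal, per-anchor
candidate-ranking tests are run on the behavior pathway — on real data,
disease semantics correlate with associations and the combined
representation is the intended configuration; (3) the evaluation is
transductive (training and test edges share nodes), so even content-free
attribute vectors let a forest memorize node identity and degree — with the
attribute signal set to 0 the attribute-only AUC drops well below its
default-signal value but stays above 0.5; only the shuffled-label null
reaches the true chance floor.  The same identity effect exists on real
data and is inherent to this evaluation design, not an artifact of the
generator.

## Numerical choices and degenerate inputs

* Seeds: every randomized operation takes an explicit integer seed; derived
  stream seeds are `(seed · 1000003 + salt) mod 2³¹`.
* Negative sampling rejects self-loops, any pair linked under *any* relation
  type, and duplicates; a relation type whose non-edge space is exhausted
  raises an explicit error naming the type.
* Fold sizes differ by at most one overall and per label class (single
  rolling round-robin deal after per-label shuffles).
* KL arguments are clamped to [1e-8, 1 − 1e-8]; a boundary hit is logged.
* GF aborts with diagnostics if the epoch loss exceeds 10× the initial loss
  or any entry becomes non-finite.
* Sequences shorter than k (or with no valid window) encode to the zero
  vector with a warning; empty sequences are errors.
* Score ties in rankings are broken by candidate identifier so ranked output
  is bit-reproducible.

## Known limitations

* The SAE trains by plain mini-batch gradient descent with a fixed learning
  rate; it compresses adequately but is not tuned for reconstruction
  fidelity at the default 100 epochs.
* GF optimizes reconstruction of observed edges only (non-edges enter
  solely through the L2 penalty), so rank-deficient configurations can
  leave non-edge scores under-determined; the over-parameterized regime
  (rank ≫ planted dimension) is the intended operating point.
* Candidate ranking through a forest classifier quantizes scores to
  multiples of 1/n_trees; lexicographic tie-breaking keeps output stable
  but the resolution limit is inherited from the ensemble size.
* The loader performs no identifier normalization across source databases;
  inputs are expected to use consistent node identifiers.
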