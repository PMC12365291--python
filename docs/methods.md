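# Methods

## Problem and data model

The package predicts drug–target interactions (DTI) over a heterogeneous
biomedical network with four node types — drugs, proteins, diseases, side
effects — and six binary relations between them (drug–drug interaction,
protein–protein interaction, drug–protein interaction, drug–disease,
drug–side-effect and protein–disease associations), plus real-valued
drug–drug and protein–protein similarity matrices. Input directories follow
the DTINet dense-matrix dialect: whitespace-delimited 0/1 matrices, one row
per line, with plain-text identifier lists. On load, similarity entries
below a threshold (default 0.5, configurable) are zeroed while the unit
diagonal is kept, and self-loops are added to every within-type adjacency as
elementwise `max(A, I)` so matrices stay binary.

Every node receives a 128-dimensional initial feature vector:

* **drugs** — 167-bit MACCS fingerprints of their SMILES, PCA-reduced;
* **proteins** — 20 amino-acid composition fractions plus 400 dipeptide
  frequencies (each block row-normalized to sum 1), PCA-reduced;
* **diseases / side effects** — embeddings of biased second-order random
  walks (return parameter p, in–out parameter q, defaults p = q = 1, 10
  walks of length 80 per node, window 5) over the union association network.
  The walk co-occurrence matrix is factorized by truncated SVD of the
  shifted positive PMI matrix, the standard matrix-factorization form of
  skip-gram with negative sampling; this keeps the builder deterministic
  under a fixed seed.

PCA is fitted per node type on that type's rows only. When fewer than 128
informative components exist the matrix is zero-padded; component signs are
fixed by making the largest-magnitude loading positive, so outputs are
reproducible bit-for-bit. Non-standard residue letters (B, J, O, U, X, Z)
are dropped from the counts with a warning.

## Model

### Neighborhood-view (NV) encoder

Per layer and node type v, each incident relation (v,u) is aggregated as

    N_{v,u} = D_r^{-1/2} Ã_{v,u} D_c^{-1/2} · H_u · W_{v,u}

with Ã the self-loop-augmented adjacency and degrees taken from the block
itself (+1 smoothing for isolated nodes in rectangular cross-type blocks,
which the square-case normalization does not cover). Each relational
aggregate — and the self path — is fused with the projected base features by
elementwise multiplication ("Multiple" fusion), the fused views are
mean-pooled over the type's incident relations, and a PReLU is applied. Two
layers are stacked so nodes see their two-hop neighborhood. Feature-level
dropout (default 0.5) acts on the layer inputs during training.

### Deep-view (DV) encoder

For drugs and proteins, three meta-path graphs each (P–P, P–D–P, P–D–D–P;
mirrored D–D, D–P–D, D–P–P–D) are composed, binarized, self-looped and
symmetrically normalized to give propagation operators G. The graph-wavelet
transform propagates node signals over dyadic scales s_j = 2^{j-1}
(J = 3 ⇒ 1-, 2- and 4-hop), forms U = concat(X^(1), X^(2), X^(4)),
first-order differences |X^(s_i) − X^(s_{i+1})| between adjacent scales and
second-order differences |U^(t) − U^(t+1)| of the propagated concatenation
(M = 3 steps ⇒ two terms), and projects
concat(X^(s_J), F1, F2) through a PReLU-activated linear layer. The concat
width is d·(1 + (J−1) + (M−1)·J) — 9d at the defaults. Per-meta-path views
are fused with semantic attention: score_i = aᵀ mean_n tanh(W z + b),
α = softmax(scores), Z = Σ α_i Z_i, with attention-level dropout (0.2) on
the raw scores. Two DV layers are stacked with fresh parameters. Meta-path
products are binarized by default (a count-preserving flag exists) to keep
the operator's spectral radius controlled.

### Multi-level contrastive alignment

Positive pairs per type come from a composite multi-order similarity: the
row-normalized meta-path count matrices (drugs: D–D, D–P–D; proteins: P–P,
P–D–P) are summed and augmented with the identity. Per row, candidates with
positive similarity are kept in full when at most K exist, otherwise the K
most similar are kept (Top-10 for drugs, Top-5 for proteins; ties break
toward the lower index). NV and DV embeddings pass through per-view
projection heads (linear–PReLU–linear, width proj_dim, shared across layers
and types), and the temperature-scaled cosine similarity (τ = 0.5) feeds a
bidirectional InfoNCE objective per layer; all non-positive columns of the
full node set act as implicit negatives. Losses are summed over the two
layers and over drug and protein types; auxiliary node types are excluded
from the contrastive objective.

### DistMult decoder and joint objective

Final embeddings are the elementwise sum of the top-layer NV and DV
embeddings for drugs and proteins, and the top-layer NV embedding for
diseases and side effects. Each reconstructed relation r has a learnable
diagonal bilinear form Φ_src diag(θ_r) Φ_dstᵀ. The joint loss is

    L = Σ_r ‖G_r − Ĝ_r‖²  +  λ1 · L_contrast  +  λ2 · L_L2

with λ1 = 0.5 and λ2 = 20 000. L_L2 is the **mean** of squared entries over
all trainable tensors — with a sum convention λ2 = 20 000 would dwarf every
other term at any realistic parameter count. Held-out drug–protein pairs
(validation and test) are masked out of the reconstruction residual and
their positive edges are removed from the adjacency used to build the
normalized blocks, meta-path operators and positive-pair indicators, so no
label information leaks through the graph structure.

The reconstruction residual is computed on the **raw bilinear scores**
against the 0/1 targets. An optional sigmoid-output variant exists but is
not the default: with targets that are ~98 % zeros, squared error on
sigmoid outputs admits an all-negative saturated solution in which every
positive entry has a dead gradient, and full-batch training reliably falls
into it. Predicted interaction probabilities are always
sigmoid(score) ∈ [0, 1].

### Numerical choices

* Input features are standardized (zero mean, unit RMS per type) inside the
  model. Multiplicative fusion multiplies variances, so inputs that arrive
  at scale ≪ 1 would shrink activations geometrically with depth.
* DistMult diagonals are initialized uniform in ±1/d so initial scores are
  O(1); all weight matrices use Glorot-uniform initialization, PReLU slopes
  start at 0.25.
* InfoNCE terms use masked log-sum-exp throughout and are stable for
  similarity magnitudes up to at least 10³.
* Optimization is full-batch adaptive moment estimation (lr 0.001 default),
  validated every epoch on AUPR (the imbalance-sensitive metric), with best
  parameters restored and early stopping after 500 stale validation rounds
  at the defaults.
* AUPR is the step-wise (non-interpolated) area under the precision–recall
  curve; AUC counts ties as ½.

## Evaluation protocol

Labeled pairs are all observed interactions plus uniformly sampled
negatives at 1:10, excluding candidate pairs whose drug (or protein) has
similarity above 0.8 to a partner with a known interaction with the same
protein (or drug) — likely false negatives. Standard evaluation is
stratified 10-fold cross-validation with a further 90/10 train/validation
split. Cold-start modes partition the drug (or protein) entities into 10
folds; every pair touching a test entity is assigned to test, and cold runs
are repeated over 3 seeds. Bootstrap 95 % confidence intervals resample
prediction rows with replacement (B = 1000 default); single-class resamples
are redrawn.

## Synthetic benchmark

The generator plants rank-r structure: drug factors A (n_d × r) and protein
factors B (n_p × r) are standard normal, and interactions are Bernoulli
with success probability sigmoid(a·A Bᵀ + b), where a = 4/sd(A Bᵀ) makes
the pattern close to a threshold rule and b is bisected to hit the target
density. Drug–drug and protein–protein edges come from the same factors;
associations to diseases and side effects come from *independent* random
bipartite factors, so side information alone cannot reveal the interaction
matrix. Similarities are clipped cosines of the factors plus symmetric
noise; features are the factors zero-padded to 128 columns plus Gaussian
noise (σ = 0.1), forcing the encoders to use graph structure as well as
features. Label noise is a density-preserving exchange: a fraction
`noise_flip_prob` of edges is flipped off and an equal number of non-edges
flipped on (independent per-entry flips would swamp a 2 %-density relation
with false positives and change its density).

Edge probabilities use *row-normalized* factor directions. With raw
standard-normal rows, each node's factor norm becomes a popularity margin:
high-norm drugs interact with almost everything, and a plain degree or
feature-norm heuristic alone ranks held-out pairs at AUC ≈ 0.83 — a channel
that any model, including one trained on shuffled labels, can exploit. On
the unit sphere the planted signal is purely pair-level alignment, which is
what a recoverability benchmark should measure.

The recoverability benchmark uses 300 drugs × 400 proteins, rank 8, 2 % DTI
density and 1 % exchange noise, trained at hidden width 64, projection
width 16, lr 3e-3, ≤300 epochs with validation every 10 epochs and patience
20 evaluations, with light dropout (0.2 feature / 0.1 attention) — the full
architecture at benchmark-friendly sizes. The control re-trains the
identical pipeline after permuting the drug–protein labels of the training
and validation pairs (in the pair list and in the reconstruction target
alike); test pairs keep true labels. The control keeps its final trained
parameters rather than an early-stopping checkpoint: its validation metric
is shuffled noise, and checkpoint restoration would hand back a
barely-trained model whose random low-rank score surface has high-variance
chance performance. The ablation comparison (full model vs a deep view
replaced by a plain one-hop convolution per meta-path) runs on a
150 × 180-node network over 5 seeds. On these exchangeable synthetic
graphs the multi-scale wavelet view has no consistent advantage over the
plain one-hop deep view — the generated report flags whichever ordering is
observed; multi-scale structure in real biomedical networks (community
structure, hubs, long paths) is precisely what the synthetic benchmark does
not model.

What passing these benchmarks does and does not show: the synthetic
networks are exchangeable low-rank constructions with Gaussian factor
noise; they exercise every pipeline stage and the model's ability to
recover planted bilinear structure under class imbalance, but they contain
no real chemistry, no degree heavy-tails, no ontology structure in the
auxiliary nodes and no batch effects, so performance numbers on them do not
transfer to real biomedical networks.

## Known limitations

* Training is dense and full-batch; node counts in the tens of thousands
  (e.g. full disease/side-effect vocabularies) would need sparse targets
  and mini-batching of the reconstruction loss.
* The NV encoder treats relation sets as fixed; relations absent from a
  given network are silently skipped.
* The DV encoder covers drugs and proteins only; auxiliary types enter the
  decoder through their neighborhood view alone.
* Probability outputs are uncalibrated sigmoids of bilinear scores.
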