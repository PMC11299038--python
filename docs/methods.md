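# Methods

## Problem

A genome-scale metabolic model (GEM) is a hypergraph G = (V, E): vertices
are metabolites, and each reaction is a hyperedge e joining a substrate
vertex set V_S to a disjoint product vertex set V_P (signs of the
stoichiometric matrix H decide the roles: h_ij < 0 consumes, h_ij > 0
produces). Draft GEMs reconstructed from genome annotation miss reactions;
gap-filling asks which hyperedges from a universal reaction pool should be
added. The package learns a scoring function f over vertex subsets such
that known reactions score above a threshold s (default 0.5) and
non-reactions below it, then ranks the pool by score and filters the top
candidates by similarity to the reactions the draft already contains.

## Model

**Initial embeddings.** H is split into binary characteristic matrices HS
(substrate flags) and HP (product flags). Each of H, HS, HP passes
through its own single-layer linear map to d = 256 columns and the three
embedded matrices are summed into X_init (one row per metabolite).

Two variants of the split exist. The literal case rule flags h_ij <= 0 in
HS, which also marks every non-participating metabolite; with sparse
stoichiometry HS is then a near-all-ones matrix, so X_HS is essentially a
global offset whose weight matrix receives enormous common-mode gradients.
Under Adam this offset grows until the convolution activations saturate
and training collapses to a constant scorer (observed reproducibly at the
n = 300, m = 400 scale). The pipeline therefore defaults to the
participation variant (h_ij < 0), keeping the literal rule available as
`zeros_as_substrates=True` on the model config and as the default of the
`split_characteristics` primitive itself.

**Dual-scale convolution.** Each hyperedge is modelled as a heterogeneous
complete graph on its k + l vertices and decomposed into three complete
subgraphs: substrate-substrate (K_k), product-product (K_l), and the
substrate-product complete bipartite graph. One symmetrically normalized
graph convolution D^{-1/2} A D^{-1/2} X W with hard-tanh activation runs
per subgraph: the two homogeneous ones share the "intra-domain" role (own
weight per role), the bipartite one is the "inter-domain" pass. No
self-loops are added; a single-member side therefore receives a zero
intra-domain message and relies on the fused initial embedding for its own
signal. On complete graphs the normalized adjacency has the closed form
A/(k-1) (and 1/sqrt(kl) entries for the bipartite block), which the
batched implementation uses directly; tests assert equality with the
explicit adjacency route.

**Fusion, pooling, scoring.** A softmax attention over three per-edge
views — linear(X_init rows), intra output, inter output — produces
weights (β1, β2, β3); each view's scalar attention score is a learned
linear functional of its mean vertex row. The fused per-vertex table is
pooled into a root-mean-square vector and a max-minus-min vector
(elementwise over vertices, hence permutation-invariant), concatenated
(512 wide) and scored by a two-layer MLP (hidden 128, leaky-ReLU slope
0.01, dropout 0.2) with a sigmoid output in (0, 1).

## Training

Positives are the draft's reactions. Each epoch every positive gets a
fresh group of negatives built by swapping vertices for uniform
non-members of the same role: epochs before `stage2_start_epoch` (18)
swap ceil(|e|/2) vertices (easy negatives), later epochs swap one
(near-miss negatives). The loss is the mean over positives of
softplus(mean(group) − positive), computed by default on the pre-sigmoid
logits: on the (0, 1) score scale the softplus margin saturates once the
early common-mode updates push all scores toward an endpoint, after which
every gradient vanishes and training freezes at loss log 2 (observed
reproducibly at the 300-metabolite scale; `loss_on="score"` keeps the
squashed form available and works on small problems). Because a pure
ranking loss anchors only score differences, the returned model's output
head is calibrated afterwards: a class-balanced one-dimensional logistic
fit of the validation logits is folded into the MLP output weights, so
the sigmoid scores are probability-like and the 0.5 selection threshold
is meaningful. Two related robustness choices: the MLP hidden layer is a
leaky rectifier (slope 0.01; a hard ReLU died wholesale under the early
common-mode push), and the propagation weight matrices (both intra-domain
maps, the inter-domain map, and the attention pre-map) start as identity
matrices — a parameter-free-propagation start in the spirit of LightGCN —
so the convolution views begin as meaningful smoothed embeddings rather
than random projections. For the same reason the two characteristic-
matrix maps start at zero: the initial embeddings begin as the
stoichiometry view and the substrate/product role views train in. The
published learning rate 0.01 is the initial rate of a cosine schedule.
In max/min pooling, exactly tied rows share the gradient evenly (ties
really occur: the two fused rows of a one-substrate/one-product edge
coincide under identity-initialised maps).

Under the `no_hetero` ablation the model is a plain single-layer GCN
feature extractor: the pooled features are the convolution output over
the complete graph on all edge vertices, with no fusion views — matching
the ablation baseline it reproduces.

Optimisation is Adam (lr 0.01, 35 epochs, global gradient-norm clip 5)
with one update per minibatch of 16 positives plus their negative groups;
35 full-batch steps underfit badly. 10 % of positives are held out
(seeded) and the checkpoint with the best validation AUROC is returned
(ties prefer the later epoch). All randomness — weight init, splits,
negative sampling, dropout — derives from one seed; identical seeds give
identical checkpoints.

## Gap-filling

Pool reactions are scored in evaluation mode (deterministic). Candidates
scoring above s = 0.5 are ranked (ties: id-lexicographic) and the top
`first_round` = 300 kept; the second round computes each candidate's
similarity to the known reactions and keeps the `k_top` = 200 *least
similar*, so high-scoring near-duplicates of existing reactions are not
re-added. Similarity is the maximum over known reactions of the distance
correlation between signed incidence vectors (+1 product, −1 substrate,
0 absent) over the universe vertex set; Jaccard overlap of participant
sets is available as an alternative metric. Distance correlation is
computed exactly on the joint value distribution of the two sparse
vectors (O(t²) for t distinct value pairs, t ≤ 17 here) and is validated
against the dense doubly-centered distance-matrix definition in tests.

## Synthetic data

The generator emulates the inputs the method needs without any downloads:
n metabolites in `n_communities` groups, m reactions drawing each
participant from the reaction's home community with probability 0.8
(mixing 0.2), 1–4 substrates and 1–4 products per reaction, coefficients
in {1, 2}. Within a community metabolites are drawn with 1/rank weights,
which produces hub ("currency") metabolites — top-decile vertex degree
exceeds twice the median. A seeded fraction of reactions is held out as
planted "missing" reactions and decoys are single/double vertex swaps of
training reactions, giving the candidate pool realistic near-miss
structure. What a green test on this world establishes: that the model
learns the planted structure and that the two-round filter behaves as
intended. Two structural caveats matter when reading results on this
world. First, because planted reactions draw their members with hub
weights while negative swaps are uniform, the dominant separable signal
at test time is vertex degree, not fine co-participation structure.
Second, substrates and products are drawn from identical distributions,
so the two roles are statistically interchangeable: the role-aware
dual-scale decomposition has no extra information to exploit here, and
its single-layer-GCN ablation — which convolves over the full complete
graph instead of role-restricted subgraphs (whose single-member sides
receive zero intra-domain messages) — is not expected to underperform
the full model on this generator, unlike on real GEMs where the
substrate/product distinction is chemically meaningful. What a green
test also does not establish: performance on real BiGG-scale GEMs,
chemistry-aware realism (no mass balance, no thermodynamics), or the
published benchmark numbers, which require the curated model collection
and phenotype simulation.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| embed_dim | 256 | embedding width (published) |
| lr / epochs / dropout / MLP depth | 0.01 / 35 / 0.2 / 2 | published hyperparameters |
| negatives_per_positive | 20 | negative-group size per positive; experiments in this repo use 5 to fit CPU budgets |
| stage2_start_epoch | 18 | switch to near-miss negatives (epochs/2) |
| batch_positives | 16 | positives per Adam update |
| mlp_hidden | 128 | hidden width (512 → 128 → 1) |
| score_threshold / first_round / k_top | 0.5 / 300 / 200 | selection pipeline |
| val_fraction | 0.1 | edge-wise validation split for checkpoint selection |

## Degenerate inputs and edge cases

Exchange-style hyperedges may have one empty side: the empty blocks
produce zero messages and the guarded D^{-1/2} never divides by zero.
The RMS pooling adds 1e-12 inside the square root to keep the gradient
finite on an all-zero feature row (error < 1e-6 on values of order 1).
Metabolites on both sides of a reaction are classified by net
coefficient; net zero counts as substrate. Reversible reactions stay a
single hyperedge in the written direction.

## Known limitations

The training loop is numpy-based (autograd) and CPU-bound: desk-scale
instances (hundreds of reactions) train in about a minute; BiGG-scale
models are out of reach without a GPU tensor framework. The two-stage
negative curriculum, the split protocol, and the exact vectors behind the
similarity coefficients are this package's own choices where the original
descriptions were unavailable; they are configurable.
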