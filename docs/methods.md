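# Methods

## Problem setting

A knowledge graph is a triple store G = (E, R, T). Plant-domain graphs
are dominated by *compositional* structure: taxonomic chains
(species → genus → family → order → class), ecological association
chains (host → pathogen → vector → predator), and sparse, highly
imbalanced relation vocabularies. The queries that matter — "which class
does this species belong to", "which organism ultimately controls this
pest" — require composing four or more relation hops, and new species
appear constantly, so the reasoner must be *inductive*: it may not learn
per-entity embeddings, because test-time entities were never seen.

`krgai` implements a dual-channel graph network for this setting, plus
everything needed to measure it: a synthetic benchmark generator,
random-walk inductive splits, a negative-sampling training loop and the
standard ranking protocol (Hits@10, AUC-PR over 50-candidate sets).

## Model

**Query conditioning.** For a query (h, q, ?), node states `E ∈ R^{|E|×d}`
are initialized to zero except row h, which receives the query relation's
embedding. All information about an entity therefore comes from where it
sits relative to the query head — the property that makes the network
transfer to disjoint entity sets, and that our relabeling-invariance
tests check bitwise.

**Inverse augmentation.** Each triple (h, r, t) contributes a message
edge carrying t's state into h under relation r, and one carrying h's
state into t under the inverse relation r + |R|. Reachability over
message edges is then symmetric, matching the undirected distance
statistics used to characterize the benchmarks.

**Local channel** (attentive relational message passing). Edge (u, r, v)
carries the message `m = W_φ (e_v + r_r)`; attention logits
`γ = LeakyReLU(W_att · m)` are softmax-normalized over N(u) and the node
aggregates `Σ β m`. Isolated nodes get a zero row. The additive message
form is the simplest composition that keeps the 1×d attention row
well-shaped while letting relation semantics gate propagation.

**Global channel** (kernelized linear attention). Per head,
`Q = E W_Q, K = E W_K, V = E W_V`, and the output is
`φ(Q) (φ(K)ᵀ V)` with φ(x) = ELU(x) + 1 elementwise. Associating the
product right-to-left avoids the |E|×|E| score matrix, making the cost
linear in |E| while remaining *exactly* equal to the quadratic-order
computation — an identity the test suite verifies to 1e-5 relative error
on random inputs, and whose cost contract (multiply-accumulates at most
double when |E| doubles) is asserted by instrumented op counting. Head
outputs are concatenated back to width d and projected by `W_m`.

φ is evaluated as `exp(min(x,0)) + relu(x)`: identical to ELU(x)+1 in
exact arithmetic but strictly positive in float64 down to x = −50 and
beyond, where the naive `(e^x − 1) + 1` rounds to zero.

The plain associative product is the default. It has no row
normalization, so state magnitude grows roughly with |E| per layer;
`normalize_global` opts into the standard `φ(Q)·(φ(K)ᵀ1)` row
denominator. All training presets and harnesses enable it — on graphs of
a few hundred nodes the unnormalized form overflows within a few layers
— while equivalence and invariance tests exercise the default path.

**Fusion.** Per node, the self, global and local vectors are combined
with attention weights `α_i ∝ exp(LeakyReLU(w·e_i))` normalized over the
active branches (`sum` and `concat` fusion exist as comparators).
Ablations zero the corresponding α before renormalization, so an ablated
branch is exactly absent rather than merely down-weighted.

**Two-stage depth.** The first `n_base_gnn_layers` layers run the local
channel only. Global attention over the nearly-empty initial states
cannot carry query-specific signal (all zero-state nodes project to the
same query vector), so structure is accumulated locally first; the base
GNN reuses the local channel rather than introducing a second GNN
flavor. Relation states are refreshed between layers by `R ← R W_rel`
(layer-independent free tables are available behind a flag).

**Scoring and loss.** A two-layer MLP (3d → 64, ReLU; 64 → 1, sigmoid)
scores `concat(e_h, r_q, e_t)` from the final states. Training minimizes
`−log p(pos) − (1/n) Σ log(1 − p(neg))` over n filtered corrupted-tail
negatives per positive (probabilities clamped at 1e-7; inside the
training loop the same objective is computed in softplus form, which
needs no clamp). Adam with additive L2 weight decay, single-threaded
float64 throughout: two runs with one seed are bitwise identical.

Defaults (and why): d = 32 (the width used throughout the experiments
this package mirrors), 4 heads (head width 8), L = 5 total layers with 2
base layers (≥ 4 local hops available, matching the 4-hop target rule),
lr 1e-3, weight decay 1e-5, 64 negatives, batch 32, 20 epochs — each the
midpoint of the standard grids for this protocol. Xavier-uniform
initialization, LeakyReLU slope 0.01, no dropout or layer norm.

## Numerical core

PyTorch is not a dependency: gradients come from `krgai.autodiff`, a
~300-line reverse-mode tape over numpy float64 arrays implementing
exactly the primitives the model needs (broadcast arithmetic, batched
matmul, gathers, segment sums, the nonlinearities). Segment softmax
subtracts a detached per-segment max (the shift cancels in the softmax,
so it carries no gradient). Every primitive is checked against central
finite differences.

## Synthetic benchmark generator

The generator emulates the structural signature of plant KGs built from
public taxonomies and ecological databases:

- **Taxonomy forest**: `n_orders` chains species → genus → family →
  order → class; every order-group carries its own class-level root so
  a ≥4-hop chain exists even in minimal configurations.
- **Clade backbone**: optionally, order-trees are grouped into clades
  whose class roots are joined in a `sister_clade` ring, the way sister
  taxa meet at the top of real phylogenies. This matters for benchmark
  hardness: each component then contains many *type-identical*
  class-level nodes, and only composing the actual k-hop path — not a
  one-hop "looks like a class root" signature — identifies the right
  ancestor. Ring size also sets internal path lengths.
- **Ecological chains**: pendant paths of 4–6 hops anchored at random
  species, relations drawn with power-law frequencies (plant KG relation
  distributions are highly imbalanced).
- **Noise edges**: a configurable fraction of schema edges, drawn
  power-law over relation types, confined to organism-level entities
  (species and ecological nodes) within a component — mirroring real
  plant KGs, where curated taxonomic backbones are clean and noise lives
  in observational and ecological assertions — and keeping the component
  structure (hence the partition) intact.

**Prediction targets.** The rule instances are all pairs
(species, `taxon_ancestor_k`, ancestor) obtained by composing exactly k
taxonomy edges (default k = 4, landing on the class root). They are
*never* graph edges; the target relation exists only in the queries, so
the model must learn it purely from the training queries and prove it at
test time by path composition. Every test query is provable by a k-hop
path inside the test graph (asserted as an invariant).

**Inductive splits.** Subgraphs are carved by random walks with restart
(walk length 50, 10 walks per node, restart 0.3 — at each step the
walker teleports home with the restart probability, else moves to a
uniform undirected neighbor). Each start's visited set is a candidate
subgraph; overlapping candidates are merged by union-find until
disjoint. Subgraphs are assigned 75/25 to train/test; test entities get
a fresh vocabulary, and entity-label disjointness plus query/edge
non-leakage are verified on every construction. Relations are shared
between the sides (the standard inductive setting is entity-inductive,
relation-transductive; the target relation could not otherwise be
queried on the test side). 10% of train-side rule instances become the
validation split used for checkpoint selection.

**Distance regimes.** The two presets reproduce the two regimes observed
in real plant benchmarks: `pnkg-like` test graphs are the *longer*-range
side (test average reachable-pair distance > train), `dps-like` the
reverse. A purely exchangeable random assignment cannot produce a
systematic ordering — both sides would have the same expected mix — and
the real pipelines did not assign exchangeably either (test sets traced
complete chains in one case and were sampled for local taxonomic density
in the other). The benchmark assembler therefore supports a structural
assignment bias: `test_side="long"` gives the test side the
longest-average-distance subgraphs, `"short"` the densest, `"random"`
(the default) the seeded shuffle. The presets combine this with
heterogeneous clade sizes; average distances land at roughly 3.5–8 hops.

## Evaluation protocol

Per test query, the true tail is ranked against 49 sampled filtered
negative tails (uniform over entities, never a known-true triple).
Ranking is pessimistic under ties: rank = 1 + #(strictly better) +
#(tied) — a constant scorer earns rank 50, not rank 1, so trivial
solutions score zero. Hits@10 is the fraction of ranks ≤ 10. AUC-PR is
average precision over pooled scores: each query contributes its
positive and its first sampled negative (1:1 prevalence); pooling across
queries (rather than per-query averaging) is recorded in the report
metadata. Metrics are computed by `sklearn.metrics.average_precision_score`
(ties grouped at threshold boundaries) and cross-checked in the tests
against brute-force reimplementations.

## What the synthetic benchmark does and does not show

The generator produces the *structural* challenges of plant KGs —
long compositional chains, type-identical distractors, imbalanced
relations, unseen test entities — under a known ground truth, which is
what makes exact recovery measurable: the full model's Hits@10 ≥ 0.9 on
the 4-hop task, the ablation ordering (full ≥ global-ablated ≥
local-ablated, with the local channel indispensable), and the depth
effect (4 layers ≫ 1 layer) are all asserted at fixed seeds. It does not
emulate textual/semantic entity features, relation polysemy, annotation
error correlated with entity popularity, or graphs at the scale where
the linear-vs-quadratic attention distinction becomes a wall-clock
rather than an op-count statement. Absolute metric values on synthetic
graphs are therefore not comparable to published numbers on scraped
datasets; the package asserts directions, invariants and exact
identities instead. Problem sizes (≈350-entity graphs, ≈40 training
queries, 20 epochs) are the package's default study conditions; they are
large enough that a 2-layer or local-ablated model demonstrably cannot
solve the task its full model solves.

## Degenerate inputs and edge handling

Empty triple files, edgeless graphs, all-true negative pools,
single-class AUC-PR label sets, queries whose true tail is missing from
the candidate list, and all-ablated fusion all raise typed errors rather
than returning silent values. `avg_reachable_distance` excludes
unreachable pairs from numerator and denominator, and switches to seeded
source sampling (flagged in logs) above a 5,000-node cap. Non-finite
states abort the forward pass naming the layer; a non-finite loss aborts
training naming epoch and batch.
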