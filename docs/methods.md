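# Methods

## Problem and model

`ddanet` treats drug repositioning as balanced binary link prediction on a
three-layer heterogeneous network. Nodes are drugs, diseases and proteins;
the three bipartite association layers (drug–disease, drug–protein,
disease–protein) are undirected, unweighted, and free of self-loops and
within-type edges — associations carry no direction, and walks must be able
to traverse edges both ways for a symmetric meta-path to cycle.
Identifiers are namespaced by node type, so a drug and a protein may share
a raw identifier.

Every drug and disease receives two representations:

1. **Intrinsic attributes.** Drugs: explicit substructure matches against
   the public 166-key MACCS dictionary (no folding or hashing; bit = exact
   match). Unparsable SMILES are dropped with a warning by default
   (configurable to raise). Diseases: the contribution-weighted DAG
   similarity of the README, with decay factor `gamma` (default 0.5, the
   common convention for this family of measures; any value in (0,1) is
   accepted). Contributions are computed by dynamic programming in
   reverse-topological order from the disease; DAG nodes with no child
   chain down to the disease are excluded with a warning. Diseases with
   several descriptor tree numbers get one merged DAG (ancestor sets
   unioned); diseases with no descriptor coverage receive an identity
   similarity row plus a warning. A plain Jaccard index on ancestor sets is
   available as an alternative (`method="jaccard"`) for comparison; the
   contribution-weighted form is the default and is what the pipeline
   uses.

2. **Network embeddings.** Meta-path constrained uniform random walks
   (default meta-path drug–disease–protein–disease–drug; defaults 1000
   walks per start node of length 100) feed a skip-gram model with
   negative sampling: 64 dimensions, window 5, 5 negatives drawn from the
   unigram distribution to the 3/4 power, 5 epochs of mini-batch SGD with
   the standard word2vec linear learning-rate decay. Training is
   single-threaded, vectorised numpy with seeded RNGs, so embeddings are
   bit-reproducible; walk dead ends truncate the walk rather than
   restarting, and nodes absent from every walk get a zero vector with a
   warning. A dual-corpus variant that also walks
   drug–protein–disease–protein–drug was evaluated during development and
   rejected: it dilutes the direct drug–disease co-occurrence signal and
   lowered benchmark AUC, so the single disease-mediated meta-path remains
   the default (it is configurable, and corpora from several meta-paths
   can be concatenated by the caller).

## Feature compression and fusion

Attribute blocks are compressed by a single-hidden-layer symmetric
autoencoder (sigmoid activation, mean-squared reconstruction error, plain
full-batch gradient descent, learning rate 0.01, 100 epochs, seeded
initialisation). The loss gradient is averaged over samples — not over all
matrix entries — so update magnitudes do not vanish for wide inputs. The
hidden width defaults to 64 to match the embedding dimension and is
clamped to input width − 1 when the attribute matrix is narrower (e.g. a
20-disease similarity matrix), since a compressing bottleneck is a hard
precondition. Drugs and diseases are compressed by two separately trained
encoders with identical machinery.

LMF combines the encoded attribute vector and the embedding of each node:
rank-4 factor stacks (default) over 1-augmented inputs, output width 64,
sigmoid, bias added outside the nonlinearity. Because drug and disease
attribute widths differ, one parameter set is fitted per node type. The
factors are **seeded random projections by default** — training-free and
reproducible; an optional `mode="learned"` tunes factors, bias and a
logistic head by full-batch gradient descent on labelled pairs. The
learned mode is not used inside cross-validation because the features are
built once before folding; tuning them on all labels would leak test-fold
information.

A pair's feature vector is the concatenation drug‖disease of the two fused
vectors, in that fixed order. The default classifier is a 100-tree random
forest with default split criteria (seeded); AdaBoost, GNB, KNN and LR are
available with library defaults.

## Evaluation protocol

Negatives are sampled once per experiment, uniformly without replacement
from the enumerated unobserved drug×disease pairs, one per positive;
folding then acts on the assembled balanced set (stratified 10-fold,
shuffled, seeded). Per-fold Acc/Prec/Recall/F1 come from the 0.5-threshold
confusion matrix; F1 is defined as 0 when precision + recall is 0; AUC is
the Mann–Whitney rank statistic with tie mid-ranks. Reports carry per-fold
rows plus mean ± sd at full float precision so byte-level comparison
detects any nondeterminism. Known test-fold positive edges are **not**
removed from the walk graph — the embedding step is transductive and this
default is optimistic; callers wanting a strict protocol can rebuild the
graph per fold. Cross-dataset validation fits once on one labelled set and
evaluates once on another; it requires disjoint positives and some shared
nodes, and flags the degenerate train==test run with a leakage warning
rather than an error so it can serve as an upper-bound sanity check.

## Synthetic universe

The generator emulates the structure of public DDA benchmark collections
at desk scale. Defaults are the benchmark study conditions used throughout
the tests: 20 drugs, 20 diseases, 10 proteins, 2 latent clusters,
within-cluster association probability 0.8, cross-cluster 0.05. Remaining
knobs were chosen once as realistic: each cluster-dedicated bridge protein
connects to 4 drugs and 4 diseases of its cluster (a modest hub degree);
10% of the drawn within-cluster associations are held out as planted truth
(excluded from the observed network, so recovering them is genuine link
prediction); drugs draw SMILES from per-cluster pools split from a fixed
embedded list of 50 small valid molecules (aliphatic vs aromatic halves,
so substructure bits carry cluster signal); diseases of one cluster share
a cluster-root descriptor ancestor and three-way subgroup ancestors.
Benchmark pipeline runs use a reduced walk budget (50 walks per node,
length 20) so the whole suite runs in minutes on one CPU.

What the generator does **not** emulate: the heavy-tailed degree
distributions, incomplete descriptor coverage and correlated noise of real
curated databases, or realistic medicinal chemistry (pools are toy
molecules). Passing the planted-signal benchmark therefore shows the
pipeline recovers a community-plus-adjacency signal end to end; it does
not certify performance on real benchmark data.

## Observed behaviour on the planted benchmark

Under the conditions above, attribute-only features reach roughly the
ceiling imposed by cluster structure (with p_in = 0.8, about a fifth of
within-cluster pairs are genuine non-edges, capping purely cluster-level
separability near AUC 0.82). Walk-embedding dot products carry pair-level
signal to about 0.91–0.93 (verified independently with a PPMI-SVD
factorisation of the same walk co-occurrence counts), but the
concatenation-plus-random-forest scoring reads that interaction signal
only partially, landing the full pipeline at about 0.84–0.88 depending on
the seed, with the aggregated mode typically at or slightly above the
network mode — margins between the two are smaller than fold-to-fold
noise. These levels are consistent with what this model family reports on
real benchmarks of comparable balance.

## Numerical choices and degenerate inputs

Seeds for every stage (autoencoders, walks, skip-gram, LMF, negative
sampling, classifier) are derived from one master seed via a seed
sequence. Sigmoid arguments are clipped to ±30. Ranking ties break by
candidate identifier. Degenerate cases are errors, not silent defaults:
empty edge files, duplicate ids, contradictory positive/negative pairs,
single-class training sets, saturated negative-sampling universes, cyclic
DAGs, meta-paths referencing absent edge layers. Warnings (not errors)
cover dropped duplicates, unparsable SMILES, descriptor-less diseases,
walk-absent nodes and train==test leakage.

## Known limitations

Transductive embeddings (see above) make CV optimistic relative to a
strict edge-holdout protocol. The meta-path is a modelling choice the data
cannot identify on its own. The negative-sampling enumeration of
unobserved pairs is quadratic in node counts and intended for desk-scale
studies. The learned-LMF mode uses a shared-factor approximation of the
rank decomposition during tuning.
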