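"""Meta-path constrained random walks and skip-gram node embeddings.

A meta-path M is an ordered node-type sequence whose first and last types
coincide (e.g. drug-disease-protein-disease-drug), so a walk can cycle
through it indefinitely. At each step the walker moves uniformly at random
to a neighbor of the next required type:

    P(v_{i+1} | v_i, M) = 1 / |N_{t+1}(v_i)|   if v_{i+1} is adjacent and of type t+1
                        = 0                     otherwise

where N_{t+1}(v_i) is the set of neighbors of v_i with the next type on M.
Walks truncate at dead ends. The walk corpus is fed to a skip-gram model
trained with negative sampling (implemented here with vectorised numpy SGD,
single-threaded and fully seeded, so embeddings are bit-reproducible).

The evaluation-time conditional probability p(context | center) is the full
softmax over the vocabulary of exp(u_o . v_c); negative sampling is only the
training-time approximation of that objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigError
from .hetnet import NODE_TYPES, HeteroGraph, NodeRef


@dataclass(frozen=True)
class MetaPath:
    """Ordered node-type sequence constraining a random walk."""

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ConfigError("meta-path needs at least two types")
        if self.types[0] != self.types[-1]:
            raise ConfigError("meta-path must be symmetric (first type == last type)")
        for t in self.types:
            if t not in NODE_TYPES:
                raise ConfigError(f"unknown node type {t!r} in meta-path")
        for a, b in zip(self.types, self.types[1:]):
            if a == b:
                raise ConfigError(f"meta-path repeats type {a!r} consecutively")

    @classmethod
    def from_string(cls, s: str) -> "MetaPath":
        """Parse a hyphenated type string, e.g. ``drug-disease-protein-disease-drug``."""
        return cls(tuple(s.split("-")))

    def __str__(self) -> str:
        return "-".join(self.types)

    def type_at(self, step: int) -> str:
        """Node type required at walk position ``step`` (cycling, 0-based)."""
        period = len(self.types) - 1  # last type == first type
        return self.types[step % period]


DEFAULT_METAPATH = MetaPath(("drug", "disease", "protein", "disease", "drug"))


def transition_distribution(
    graph: HeteroGraph, current: NodeRef, next_type: str
) -> dict[NodeRef, float]:
    """One-step transition probabilities to neighbors of ``next_type``.

    Uniform over the valid neighbors; empty when the walk dead-ends.
    """
    nbrs = graph.neighbors_of_type(current, next_type)  # raises on unknown node
    if not nbrs:
        return {}
    p = 1.0 / len(nbrs)
    return {v: p for v in sorted(nbrs)}


def step(
    graph: HeteroGraph, current: NodeRef, next_type: str, rng: np.random.Generator
) -> NodeRef | None:
    """Draw the next walk node, or None at a dead end."""
    nbrs = sorted(graph.neighbors_of_type(current, next_type))
    if not nbrs:
        return None
    return nbrs[rng.integers(len(nbrs))]


@dataclass(frozen=True)
class WalkCorpus:
    """Meta-path conforming walks; each walk is a node sequence."""

    walks: tuple[tuple[NodeRef, ...], ...]
    metapath: MetaPath

    def __len__(self) -> int:
        return len(self.walks)

    def validate_types(self) -> bool:
        """Every walk's type sequence must match the cycled meta-path."""
        for walk in self.walks:
            for i, node in enumerate(walk):
                if node.node_type != self.metapath.type_at(i):
                    return False
        return True

    def vocabulary(self) -> list[NodeRef]:
        return sorted({n for w in self.walks for n in w})


def generate_walks(
    graph: HeteroGraph,
    metapath: MetaPath = DEFAULT_METAPATH,
    walks_per_node: int = 1000,
    walk_length: int = 100,
    seed: int = 0,
) -> WalkCorpus:
    """Meta-path constrained random walks from every node of the start type.

    ``walk_length`` counts nodes; walks truncate (do not restart) at dead
    ends, so an isolated start node yields a singleton walk. The corpus is a
    deterministic function of the seed.
    """
    for a, b in zip(metapath.types, metapath.types[1:]):
        if not graph.has_edge_layer(a, b):
            raise ConfigError(f"meta-path edge layer {a}-{b} absent from the graph")
    rng = np.random.default_rng(seed)
    walks = []
    for start in graph.nodes_of_type(metapath.types[0]):
        for _ in range(walks_per_node):
            walk = [start]
            while len(walk) < walk_length:
                nxt = step(graph, walk[-1], metapath.type_at(len(walk)), rng)
                if nxt is None:
                    break
                walk.append(nxt)
            walks.append(tuple(walk))
    return WalkCorpus(tuple(walks), metapath)


@dataclass(frozen=True)
class SkipGramConfig:
    dim: int = 64
    window: int = 5
    negative: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negative < 0 or self.epochs < 1:
            raise ConfigError("invalid skip-gram configuration")


class EmbeddingTable:
    """Node -> vector map holding skip-gram input and output matrices."""

    def __init__(self, nodes: Sequence[NodeRef], W_in: np.ndarray, W_out: np.ndarray):
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.W_in = W_in
        self.W_out = W_out
        self.dim = W_in.shape[1]

    def __contains__(self, node: NodeRef) -> bool:
        return node in self.index

    def vector(self, node: NodeRef) -> np.ndarray:
        return self.W_in[self.index[node]]

    def vector_or_zero(self, node: NodeRef) -> np.ndarray:
        """Zero vector (with a warning) for nodes absent from every walk."""
        if node not in self.index:
            warnings.warn(f"{node} absent from walk corpus; zero embedding", stacklevel=2)
            return np.zeros(self.dim)
        return self.vector(node)

    def softmax_probability(self, context: NodeRef, center: NodeRef) -> float:
        """p(context | center) under the full-softmax skip-gram definition."""
        v = self.vector(center)
        logits = self.W_out @ v
        logits -= logits.max()  # numerical stability
        expl = np.exp(logits)
        return float(expl[self.index[context]] / expl.sum())

    def cosine(self, a: NodeRef, b: NodeRef) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))

    # word2vec text format ------------------------------------------------

    def save_word2vec(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.nodes)} {self.dim}\n")
            for node in self.nodes:
                vec = " ".join(f"{x:.8g}" for x in self.vector(node))
                fh.write(f"{node.node_type}::{node.identifier} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with Path(path).open() as fh:
            n, dim = map(int, fh.readline().split())
            nodes, rows = [], []
            for line in fh:
                fields = line.split()
                ntype, ident = fields[0].split("::", 1)
                nodes.append(NodeRef(ntype, ident))
                rows.append([float(x) for x in fields[1:]])
        W = np.array(rows)
        if W.shape != (n, dim):
            raise ConfigError(f"word2vec file shape mismatch: header {n}x{dim}, got {W.shape}")
        return cls(nodes, W, np.zeros_like(W))


def _corpus_pairs(corpus: WalkCorpus, index: Mapping[NodeRef, int], window: int) -> np.ndarray:
    """All (center, context) index pairs within the sliding window."""
    pairs = []
    for walk in corpus.walks:
        idx = [index[n] for n in walk]
        L = len(idx)
        for i in range(L):
            for j in range(max(0, i - window), min(L, i + window + 1)):
                if j != i:
                    pairs.append((idx[i], idx[j]))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def train_skipgram(corpus: WalkCorpus, config: SkipGramConfig = SkipGramConfig()) -> EmbeddingTable:
    """Fit skip-gram embeddings on a walk corpus by negative-sampling SGD.

    Every node that occurs in the corpus receives an input and an output
    vector of ``config.dim``. Noise nodes are drawn from the unigram
    distribution raised to 3/4. Training is full-batch-shuffled mini-batch
    SGD; with a fixed seed the result is bit-identical across runs.
    """
    vocab = corpus.vocabulary()
    if not vocab:
        raise ConfigError("empty walk corpus")
    index = {n: i for i, n in enumerate(vocab)}
    V = len(vocab)

    counts = np.zeros(V)
    for walk in corpus.walks:
        for node in walk:
            counts[index[node]] += 1
    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(config.seed)
    W_in = rng.uniform(-0.5, 0.5, size=(V, config.dim)) / config.dim
    W_out = np.zeros((V, config.dim))

    pairs = _corpus_pairs(corpus, index, config.window)
    if len(pairs) == 0:
        # corpus of singleton walks: vectors stay at initialisation
        return EmbeddingTable(vocab, W_in, W_out)

    k = config.negative
    batch = 1024
    n_batches = -(-len(pairs) // batch) * config.epochs
    done = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        for s in range(0, len(order), batch):
            # linear learning-rate decay over all updates (word2vec schedule)
            lr = config.learning_rate * max(1.0 - done / n_batches, 1e-4)
            done += 1
            sel = pairs[order[s : s + batch]]
            c, o = sel[:, 0], sel[:, 1]
            B = len(c)
            v = W_in[c]  # (B, d)
            u_pos = W_out[o]  # (B, d)
            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0  # (B,)
            grad_v = g_pos[:, None] * u_pos
            if k > 0:
                neg = rng.choice(V, size=(B, k), p=noise)  # (B, k)
                u_neg = W_out[neg]  # (B, k, d)
                g_neg = _sigmoid(np.einsum("bkd,bd->bk", u_neg, v))  # (B, k)
                grad_v += np.einsum("bk,bkd->bd", g_neg, u_neg)
                np.add.at(
                    W_out,
                    neg.ravel(),
                    (-lr * g_neg[:, :, None] * v[:, None, :]).reshape(-1, config.dim),
                )
            np.add.at(W_out, o, -lr * g_pos[:, None] * v)
            np.add.at(W_in, c, -lr * grad_v)

    return EmbeddingTable(vocab, W_in, W_out)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def embed_graph(
    graph: HeteroGraph,
    metapath: MetaPath = DEFAULT_METAPATH,
    walks_per_node: int = 1000,
    walk_length: int = 100,
    config: SkipGramConfig = SkipGramConfig(),
    walk_seed: int = 0,
) -> EmbeddingTable:
    """Convenience wrapper: walks then skip-gram."""
    corpus = generate_walks(graph, metapath, walks_per_node, walk_length, walk_seed)
    return train_skipgram(corpus, config)
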