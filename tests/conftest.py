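"""Shared fixtures and independent brute-force oracles used across tests."""

from __future__ import annotations

import numpy as np
import pytest

from ddanet import (
    AssociationTable,
    DiseaseDAG,
    HeteroGraph,
    NodeRef,
    PipelineConfig,
    SynthConfig,
    build_graph,
    generate_universe,
)

# ---------------------------------------------------------------------------
# graphs


@pytest.fixture
def triangle_graph() -> HeteroGraph:
    """One drug, one disease, one protein, pairwise associated."""
    return build_graph(
        [
            AssociationTable("drug", "disease", frozenset({("r1", "d1")})),
            AssociationTable("drug", "protein", frozenset({("r1", "p1")})),
            AssociationTable("disease", "protein", frozenset({("d1", "p1")})),
        ]
    )


@pytest.fixture
def star_graph() -> HeteroGraph:
    """One drug associated with four diseases."""
    return build_graph(
        [AssociationTable("drug", "disease", frozenset({("r1", f"d{i}") for i in range(4)}))]
    )


# ---------------------------------------------------------------------------
# planted-signal universe at the benchmark study conditions (expensive bits
# are module-scoped where they are used; the universe itself is cheap)

BENCH_SEED = 0


@pytest.fixture(scope="session")
def bench_universe():
    return generate_universe(SynthConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_config() -> PipelineConfig:
    # reduced walk budget for desk-scale runs; other knobs at model defaults
    return PipelineConfig(walks_per_node=50, walk_length=20, seed=BENCH_SEED)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_contributions(dag: DiseaseDAG, gamma: float) -> dict[str, float]:
    """Contribution map by exhaustive enumeration of all child chains to the root.

    D(t) = max over downward paths t -> ... -> root of gamma^(path length);
    independent of the dynamic-programming implementation under test.
    """

    def path_lengths(t: str) -> list[int]:
        if t == dag.root:
            return [0]
        out = []
        for c in dag.children(t):
            out.extend(1 + l for l in path_lengths(c))
        return out

    result = {}
    for t in dag.nodes:
        lengths = path_lengths(t)
        if lengths:
            result[t] = max(gamma**l for l in lengths)
    return result


def brute_force_pair_similarity(dag_t: DiseaseDAG, dag_r: DiseaseDAG, gamma: float) -> float:
    ct = brute_force_contributions(dag_t, gamma)
    cr = brute_force_contributions(dag_r, gamma)
    shared = set(ct) & set(cr)
    return sum(ct[d] + cr[d] for d in shared) / (sum(ct.values()) + sum(cr.values()))


def random_dag(rng: np.random.Generator, root: str, pool: list[str], max_nodes: int = 8) -> DiseaseDAG:
    """Random ancestor DAG: every node has a child chain down to the root."""
    n_extra = int(rng.integers(0, max_nodes))
    others = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    order = others + [root]  # topological order, root last (descendant-most)
    edges = set()
    for i, node in enumerate(order[:-1]):
        # at least one edge toward the root side so the node reaches the root
        j = int(rng.integers(i + 1, len(order)))
        edges.add((node, order[j]))
        for j in range(i + 1, len(order)):
            if rng.random() < 0.3:
                edges.add((node, order[j]))
    return DiseaseDAG(root, frozenset(order), frozenset(edges))


def brute_force_confusion(labels, scores, threshold=0.5):
    """Counting-loop confusion matrix and metrics; no vectorised shortcuts."""
    tp = fp = fn = tn = 0
    for y, s in zip(labels, scores):
        pred = 1 if s >= threshold else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 1 and y == 0:
            fp += 1
        elif pred == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    acc = (tp + tn) / (tp + fp + fn + tn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def brute_force_auc(labels, scores) -> float:
    """AUC as the explicit pairwise-comparison probability with half ties."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_force_lmf(attr_vec, net_vec, params):
    """Term-by-term assembly of the rank-r fusion map with explicit loops."""
    z_a = list(attr_vec) + [1.0]
    z_e = list(net_vec) + [1.0]
    out = []
    for o in range(params.out_dim):
        total = 0.0
        for i in range(params.rank):
            for d, z in enumerate(z_a):
                total += params.W_a[i][o][d] * z
            for d, z in enumerate(z_e):
                total += params.W_e[i][o][d] * z
        out.append(1.0 / (1.0 + np.exp(-np.clip(total, -30, 30))) + params.b[o])
    return np.array(out)
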