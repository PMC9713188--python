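"""Disease semantic similarity over MeSH-style descriptor DAGs.

Each disease r is modelled by a DAG ``(r, N_r, E_r)`` where ``N_r`` is the set
of descriptor nodes relevant to r (r itself included) and ``E_r`` holds the
directed parent->child links among them; r is the descendant-most node of its
own DAG. An ancestor t contributes

    D_r(t) = 1                                        if t = r
    D_r(t) = max{ gamma * D_r(t') : t' in children(t) }  otherwise

with semantic contribution factor 0 < gamma < 1, so contributions decay
geometrically with distance from the disease. The semantic value is
``DV(r) = sum_t D_r(t)`` and the similarity of two diseases is the shared
contribution mass normalised by the total:

    sim(t, r) = sum_{d in N_t ∩ N_r} (D_t(d) + D_r(d)) / (DV(t) + DV(r))

which is symmetric, 1 on identical DAGs, and 0 when the ancestor sets are
disjoint. An alternative Jaccard index on ancestor sets is provided for
comparison but the contribution-weighted form above is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, GraphError


@dataclass(frozen=True)
class DiseaseDAG:
    """Per-disease ancestor DAG; ``root`` is the disease itself (a sink)."""

    root: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # directed parent -> child

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise GraphError(f"root {self.root!r} not in node set")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise GraphError(f"edge ({p!r}, {c!r}) references unregistered node")
        # acyclicity check via topological sort
        ts = TopologicalSorter({n: set() for n in self.nodes})
        for p, c in self.edges:
            ts.add(c, p)
        try:
            ts.prepare()
        except CycleError as exc:
            raise GraphError(f"cycle in DAG of {self.root!r}: {exc}") from exc

    def children(self, node: str) -> set[str]:
        return {c for p, c in self.edges if p == node}


def _reaches_root(dag: DiseaseDAG) -> set[str]:
    """Nodes from which the root is reachable via child chains (root included)."""
    parents_of: dict[str, set[str]] = {n: set() for n in dag.nodes}
    for p, c in dag.edges:
        parents_of[c].add(p)
    reach = {dag.root}
    stack = [dag.root]
    while stack:
        n = stack.pop()
        for p in parents_of[n]:
            if p not in reach:
                reach.add(p)
                stack.append(p)
    return reach


def contributions(dag: DiseaseDAG, gamma: float = 0.5) -> dict[str, float]:
    """Semantic contribution D_r(t) of every DAG node t to the root disease.

    Computed by dynamic programming in reverse-topological order from the
    root; nodes with no child chain down to the root are excluded with a
    warning. Requires 0 < gamma < 1.
    """
    if not (0.0 < gamma < 1.0):
        raise ConfigError(f"gamma must be in (0, 1), got {gamma}")
    reach = _reaches_root(dag)
    dropped = dag.nodes - reach
    if dropped:
        warnings.warn(
            f"DAG of {dag.root!r}: {len(dropped)} node(s) cannot reach the root "
            f"through child chains; excluded: {sorted(dropped)}",
            stacklevel=2,
        )
    contrib: dict[str, float] = {dag.root: 1.0}
    # order nodes so that every child is resolved before its parents
    ts = TopologicalSorter({n: set() for n in reach})
    for p, c in dag.edges:
        if p in reach and c in reach:
            ts.add(p, c)  # p depends on c
    for node in ts.static_order():
        if node == dag.root:
            continue
        kids = [c for c in dag.children(node) if c in contrib]
        contrib[node] = max(gamma * contrib[c] for c in kids)
    return contrib


def semantic_value(contribs: Mapping[str, float]) -> float:
    """DV(r): total contribution mass of the disease's DAG; always >= 1."""
    if not contribs:
        raise ConfigError("empty contribution map")
    return float(sum(contribs.values()))


def pair_similarity(dag_t: DiseaseDAG, dag_r: DiseaseDAG, gamma: float = 0.5) -> float:
    """Contribution-weighted semantic similarity sim(t, r) in [0, 1]."""
    ct = contributions(dag_t, gamma)
    cr = contributions(dag_r, gamma)
    shared = set(ct) & set(cr)
    num = sum(ct[d] + cr[d] for d in shared)
    den = semantic_value(ct) + semantic_value(cr)
    return float(num / den)


def pair_jaccard(dag_t: DiseaseDAG, dag_r: DiseaseDAG) -> float:
    """Plain Jaccard index on the two ancestor sets (comparison mode)."""
    inter = len(dag_t.nodes & dag_r.nodes)
    union = len(dag_t.nodes | dag_r.nodes)
    return inter / union if union else 0.0


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric disease similarity matrix with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def row(self, disease: str) -> np.ndarray:
        return self.values[self.ids.index(disease)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def similarity_matrix(
    dags: Sequence[DiseaseDAG], gamma: float = 0.5, method: str = "semantic"
) -> SimilarityMatrix:
    """Pairwise similarity of all diseases: the disease attribute matrix D_a.

    Row i is disease i's attribute vector. ``method`` is ``"semantic"``
    (contribution-weighted, default) or ``"jaccard"``.
    """
    if not dags:
        raise ConfigError("similarity_matrix requires at least one DAG")
    ids = [d.root for d in dags]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate disease ids in DAG list")
    n = len(dags)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if method == "semantic":
                s = pair_similarity(dags[i], dags[j], gamma)
            elif method == "jaccard":
                s = pair_jaccard(dags[i], dags[j])
            else:
                raise ConfigError(f"unknown similarity method {method!r}")
            mat[i, j] = mat[j, i] = s
    return SimilarityMatrix(tuple(ids), mat)


def dags_from_tree_numbers(table: Mapping[str, Iterable[str]]) -> list[DiseaseDAG]:
    """Build per-disease DAGs from MeSH-style dot-delimited tree numbers.

    Every dot-prefix of every code becomes an ancestor node, with parent->child
    edges following prefix nesting. The disease is identified with the leaves
    of its codes: each full code node is replaced by the disease's own id, so
    a disease with several tree numbers gets one merged DAG whose ancestor
    sets are unioned. Codes form the shared node namespace across diseases.
    """
    dags = []
    for disease, codes in table.items():
        codes = [c.strip() for c in codes]
        if not codes or any(not c for c in codes):
            raise ConfigError(f"disease {disease!r}: empty tree-number code")
        nodes = {disease}
        edges: set[tuple[str, str]] = set()
        for code in codes:
            parts = code.split(".")
            if any(not p for p in parts):
                raise ConfigError(f"disease {disease!r}: malformed tree number {code!r}")
            prefixes = [".".join(parts[: i + 1]) for i in range(len(parts))]
            # the full code IS the disease
            chain = prefixes[:-1] + [disease]
            nodes.update(chain)
            edges.update(zip(chain[:-1], chain[1:]))
        dags.append(DiseaseDAG(disease, frozenset(nodes), frozenset(edges)))
    return dags


def load_tree_number_table(path: str | Path, delimiter: str = "\t") -> dict[str, list[str]]:
    """Read a 2-column table: disease id, comma-separated tree numbers."""
    table: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            disease, codes = line.rstrip("\n").split(delimiter)[:2]
            table[disease] = [c for c in codes.split(",") if c]
    return table
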