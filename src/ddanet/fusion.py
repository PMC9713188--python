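"""Low-rank multimodal fusion (LMF) of attribute and network representations,
drug-disease pair construction, classification, and candidate ranking.

LMF combines a node's encoded attribute vector and its network embedding.
Both inputs are augmented with a constant 1 (the standard LMF convention, so
bias-like interactions are expressible), giving tensors z_a and z_e, and the
fused representation of node i is

    R_i = sigma( sum_{j=1..r} W_a^j z_a + sum_{j=1..r} W_e^j z_e ) + b

with rank r weight factor stacks W_a, W_e and bias b. By default the factors
are a seeded random projection; an optional mode tunes them jointly with a
logistic head on labelled pairs.

A drug-disease pair is represented by the concatenation drug||disease of the
two fused vectors and scored by a classifier (random forest by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .exceptions import ConfigError
from .hetnet import AssociationTable, NodeRef


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


@dataclass
class LMFParams:
    """Rank-r factor stacks and bias of the fusion map."""

    rank: int
    W_a: np.ndarray  # (rank, out_dim, attr_dim + 1)
    W_e: np.ndarray  # (rank, out_dim, net_dim + 1)
    b: np.ndarray  # (out_dim,)
    out_dim: int
    attr_dim: int
    net_dim: int


def lmf_fuse(attr_vec: np.ndarray, net_vec: np.ndarray, params: LMFParams) -> np.ndarray:
    """Fused representation of one node (see module docstring for the form)."""
    attr_vec = np.asarray(attr_vec, dtype=float)
    net_vec = np.asarray(net_vec, dtype=float)
    if attr_vec.shape != (params.attr_dim,) or net_vec.shape != (params.net_dim,):
        raise ConfigError(
            f"input dims ({attr_vec.shape}, {net_vec.shape}) do not match params "
            f"({params.attr_dim}, {params.net_dim})"
        )
    z_a = np.append(attr_vec, 1.0)
    z_e = np.append(net_vec, 1.0)
    pre = np.einsum("rod,d->o", params.W_a, z_a) + np.einsum("rod,d->o", params.W_e, z_e)
    return _sigmoid(pre) + params.b


def fit_lmf(
    attr_table: Mapping[Hashable, np.ndarray],
    embed_table: Mapping[Hashable, np.ndarray],
    rank: int = 4,
    out_dim: int = 64,
    seed: int = 0,
    mode: str = "random",
    labelled_pairs: Sequence[tuple[Hashable, Hashable, int]] | None = None,
    learn_epochs: int = 50,
    learn_rate: float = 0.1,
) -> LMFParams:
    """Initialise (and optionally tune) the LMF factors.

    ``mode="random"`` (default): seeded Gaussian random-projection factors —
    reproducible, training-free. ``mode="learned"``: starting from the random
    initialisation, the factors, bias and a logistic head are tuned by
    full-batch gradient descent on binary cross-entropy over
    ``labelled_pairs`` (triples of drug id, disease id, 0/1 label).

    Both tables must cover the same node ids.
    """
    missing = set(attr_table) ^ set(embed_table)
    if missing:
        raise ConfigError(f"attr/embedding tables disagree on ids: {sorted(map(str, missing))[:5]}")
    if rank < 1:
        raise ConfigError(f"rank must be >= 1, got {rank}")
    if mode not in ("random", "learned"):
        raise ConfigError(f"unknown LMF mode {mode!r}")
    some = next(iter(attr_table))
    attr_dim = len(attr_table[some])
    net_dim = len(embed_table[some])
    rng = np.random.default_rng(seed)
    scale_a = 1.0 / np.sqrt(rank * (attr_dim + 1))
    scale_e = 1.0 / np.sqrt(rank * (net_dim + 1))
    params = LMFParams(
        rank=rank,
        W_a=rng.normal(0.0, scale_a, size=(rank, out_dim, attr_dim + 1)),
        W_e=rng.normal(0.0, scale_e, size=(rank, out_dim, net_dim + 1)),
        b=np.zeros(out_dim),
        out_dim=out_dim,
        attr_dim=attr_dim,
        net_dim=net_dim,
    )
    if mode == "learned":
        if not labelled_pairs:
            raise ConfigError("mode='learned' requires labelled_pairs")
        _tune_lmf(params, attr_table, embed_table, labelled_pairs, rng, learn_epochs, learn_rate)
    return params


def _tune_lmf(params, attr_table, embed_table, labelled_pairs, rng, epochs, lr) -> None:
    """Gradient-descent tuning of the factors with a logistic head (in place)."""
    Za_u = np.stack([np.append(attr_table[u], 1.0) for u, _, _ in labelled_pairs])
    Ze_u = np.stack([np.append(embed_table[u], 1.0) for u, _, _ in labelled_pairs])
    Za_v = np.stack([np.append(attr_table[v], 1.0) for _, v, _ in labelled_pairs])
    Ze_v = np.stack([np.append(embed_table[v], 1.0) for _, v, _ in labelled_pairs])
    y = np.array([lab for _, _, lab in labelled_pairs], dtype=float)
    n, o = len(y), params.out_dim
    w = rng.normal(0.0, 0.01, size=2 * o)
    c = 0.0
    Wa_sum = params.W_a.sum(axis=0)  # gradient flows equally to each rank factor
    We_sum = params.W_e.sum(axis=0)
    for _ in range(epochs):
        pre_u = Za_u @ Wa_sum.T + Ze_u @ We_sum.T
        pre_v = Za_v @ Wa_sum.T + Ze_v @ We_sum.T
        Ru = _sigmoid(pre_u) + params.b
        Rv = _sigmoid(pre_v) + params.b
        F = np.hstack([Ru, Rv])
        p = _sigmoid(F @ w + c)
        g = (p - y) / n  # (n,)
        gw = F.T @ g
        gc = g.sum()
        gF = np.outer(g, w)  # (n, 2o)
        gRu, gRv = gF[:, :o], gF[:, o:]
        gb = (gRu + gRv).sum(axis=0)
        d_pre_u = gRu * _sigmoid(pre_u) * (1 - _sigmoid(pre_u))
        d_pre_v = gRv * _sigmoid(pre_v) * (1 - _sigmoid(pre_v))
        gWa = d_pre_u.T @ Za_u + d_pre_v.T @ Za_v
        gWe = d_pre_u.T @ Ze_u + d_pre_v.T @ Ze_v
        Wa_sum -= lr * gWa
        We_sum -= lr * gWe
        params.b -= lr * gb
        w -= lr * gw
        c -= lr * gc
    params.W_a = Wa_sum[None, :, :] / params.rank * np.ones((params.rank, 1, 1))
    params.W_e = We_sum[None, :, :] / params.rank * np.ones((params.rank, 1, 1))


def fuse_tables(
    attr_table: Mapping[Hashable, np.ndarray],
    embed_table: Mapping[Hashable, np.ndarray],
    params: LMFParams,
) -> dict[Hashable, np.ndarray]:
    """Apply :func:`lmf_fuse` to every node shared by the two tables."""
    return {
        node: lmf_fuse(attr_table[node], embed_table[node], params) for node in attr_table
    }


@dataclass(frozen=True)
class PairSample:
    """A labelled (or unlabelled) drug-disease pair with its joint feature."""

    drug_id: str
    disease_id: str
    features: np.ndarray  # concatenation drug || disease
    label: int | None = None


def make_pairs(
    fused: Mapping[NodeRef, np.ndarray],
    positives: AssociationTable,
    negatives: AssociationTable,
) -> list[PairSample]:
    """Labelled pair samples: positives get label 1, negatives 0.

    Every endpoint must have a fused vector; a pair listed both positive and
    negative is a contradiction.
    """
    overlap = positives.pairs & negatives.pairs
    if overlap:
        raise ConfigError(f"pairs listed as both positive and negative: {sorted(overlap)[:5]}")
    samples = []
    for table, label in ((positives, 1), (negatives, 0)):
        for u, v in table.edges():
            drug, disease = (u, v) if u.node_type == "drug" else (v, u)
            if drug not in fused or disease not in fused:
                raise ConfigError(f"no fused representation for endpoint of ({u}, {v})")
            feat = np.concatenate([fused[drug], fused[disease]])
            samples.append(PairSample(drug.identifier, disease.identifier, feat, label))
    return samples


CLASSIFIERS = ("RF", "AdaBoost", "GNB", "KNN", "LR")


def _make_classifier(name: str, seed: int):
    # default hyperparameters throughout; RF uses 100 trees (sklearn default)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    if name == "GNB":
        return GaussianNB()
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "LR":
        return LogisticRegression(random_state=seed, max_iter=1000)
    raise ConfigError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def train_classifier(samples: Sequence[PairSample], classifier_name: str = "RF", seed: int = 0):
    """Fit a classifier on labelled pair samples; needs both classes present."""
    labels = [s.label for s in samples]
    if any(l is None for l in labels):
        raise ConfigError("all samples must be labelled for training")
    if len(set(labels)) < 2:
        raise ConfigError("training set contains a single class")
    X = np.stack([s.features for s in samples])
    y = np.asarray(labels)
    model = _make_classifier(classifier_name, seed)
    model.fit(X, y)
    return model


def predict_scores(model, samples: Sequence[PairSample]) -> np.ndarray:
    """Association probability for each pair sample."""
    X = np.stack([s.features for s in samples])
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return model.predict_proba(X)[:, pos_col]


def rank_candidates(
    model,
    query: NodeRef,
    candidates: Sequence[NodeRef],
    fused: Mapping[NodeRef, np.ndarray],
    k: int = 10,
) -> list[tuple[NodeRef, float]]:
    """Top-k candidates for a query node, descending by predicted probability.

    The pair feature always concatenates drug||disease regardless of which
    side the query is on, so a disease query ranking drugs is supported.
    Known associations of the query must be excluded by the caller. Ties are
    broken by candidate identifier (lexicographic).
    """
    if not candidates:
        raise ConfigError("empty candidate list")
    if query not in fused:
        raise ConfigError(f"no fused representation for query {query}")
    samples = []
    for cand in candidates:
        if cand not in fused:
            raise ConfigError(f"no fused representation for candidate {cand}")
        if query.node_type == "drug":
            feat = np.concatenate([fused[query], fused[cand]])
            samples.append(PairSample(query.identifier, cand.identifier, feat))
        else:
            feat = np.concatenate([fused[cand], fused[query]])
            samples.append(PairSample(cand.identifier, query.identifier, feat))
    scores = predict_scores(model, samples)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i].identifier))
    return [(candidates[i], float(scores[i])) for i in order[:k]]
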