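"""End-to-end orchestration: from raw association tables, SMILES and disease
descriptors to fused per-node features, cross-validated reports and
candidate rankings.

The feature pipeline has three switchable modes:

``attribute``
    only the autoencoder-compressed intrinsic features (drug substructure
    bits, disease semantic similarity rows);
``network``
    only the meta-path random-walk skip-gram embeddings;
``aggregated``
    LMF fusion of both blocks (the full model).

All stage seeds are derived from one master seed, so a fixed seed gives a
byte-identical report end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import disease_sim, drug_features, encoder
from .embeddings import DEFAULT_METAPATH, MetaPath, SkipGramConfig, embed_graph
from .evaluation import MetricsReport, kfold_cv, sample_negatives
from .exceptions import ConfigError
from .fusion import fit_lmf, fuse_tables, make_pairs, rank_candidates, train_classifier
from .hetnet import AssociationTable, HeteroGraph, NodeRef, build_graph

MODES = ("attribute", "network", "aggregated")


@dataclass(frozen=True)
class Dataset:
    """The raw inputs of one study: three edge layers plus node descriptors."""

    drug_disease: AssociationTable
    drug_protein: AssociationTable
    disease_protein: AssociationTable
    smiles: tuple[drug_features.SmilesRecord, ...]
    tree_numbers: Mapping[str, tuple[str, ...]]

    def graph(self) -> HeteroGraph:
        return build_graph([self.drug_disease, self.drug_protein, self.disease_protein])


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the full pipeline with the model's defaults."""

    gamma: float = 0.5  # semantic contribution factor
    attr_hidden_dim: int = 64  # autoencoder width (clamped below input width)
    attr_epochs: int = 100
    attr_lr: float = 0.01
    metapath: MetaPath = DEFAULT_METAPATH
    walks_per_node: int = 1000
    walk_length: int = 100
    embed_dim: int = 64
    window: int = 5
    negative: int = 5
    sg_epochs: int = 5
    sg_lr: float = 0.025
    lmf_rank: int = 4
    lmf_out_dim: int = 64
    lmf_mode: str = "random"
    classifier: str = "RF"
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage seeds derived from the master seed."""
        names = ("drug_ae", "disease_ae", "walks", "skipgram", "lmf", "clf", "neg")
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % (2**31)) for n, s in zip(names, state)}


def disease_attribute_rows(
    disease_ids: Sequence[str],
    tree_numbers: Mapping[str, Sequence[str]],
    gamma: float,
) -> np.ndarray:
    """Disease similarity matrix D_a over ``disease_ids`` (row per disease).

    Diseases without descriptor coverage get a zero row with a unit diagonal
    entry, with a warning.
    """
    covered = [d for d in disease_ids if d in tree_numbers and tree_numbers[d]]
    missing = [d for d in disease_ids if d not in covered]
    if missing:
        warnings.warn(
            f"{len(missing)} disease(s) lack descriptor DAGs; identity similarity rows: "
            f"{missing[:5]}",
            stacklevel=2,
        )
    n = len(disease_ids)
    mat = np.eye(n)
    if covered:
        dags = disease_sim.dags_from_tree_numbers({d: list(tree_numbers[d]) for d in covered})
        sub = disease_sim.similarity_matrix(dags, gamma)
        pos = {d: i for i, d in enumerate(disease_ids)}
        for a, da in enumerate(sub.ids):
            for b, db in enumerate(sub.ids):
                mat[pos[da], pos[db]] = sub.values[a, b]
    return mat


def _encode_block(matrix: np.ndarray, cfg: PipelineConfig, seed: int) -> np.ndarray:
    hidden = min(cfg.attr_hidden_dim, matrix.shape[1] - 1)
    if hidden < 1:
        raise ConfigError("attribute matrix too narrow to compress")
    params = encoder.train_autoencoder(
        matrix, hidden, cfg.attr_epochs, cfg.attr_lr, seed=seed
    )
    return encoder.encode(matrix, params)


def build_feature_tables(
    dataset: Dataset, config: PipelineConfig = PipelineConfig(), mode: str = "aggregated"
) -> dict[NodeRef, np.ndarray]:
    """Per-node feature vectors for all drugs and diseases in the graph."""
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; choose from {MODES}")
    seeds = config.stage_seeds()
    graph = dataset.graph()
    drug_nodes = graph.nodes_of_type("drug")
    disease_nodes = graph.nodes_of_type("disease")

    attr: dict[NodeRef, np.ndarray] = {}
    if mode in ("attribute", "aggregated"):
        records = [r for r in dataset.smiles if NodeRef("drug", r.drug_id) in graph.nodes]
        ra = drug_features.build_attribute_matrix(records)
        enc_drugs = _encode_block(ra.values, config, seeds["drug_ae"])
        for did, vec in zip(ra.ids, enc_drugs):
            attr[NodeRef("drug", did)] = vec
        disease_ids = [n.identifier for n in disease_nodes]
        da = disease_attribute_rows(disease_ids, dataset.tree_numbers, config.gamma)
        enc_dis = _encode_block(da, config, seeds["disease_ae"])
        for did, vec in zip(disease_ids, enc_dis):
            attr[NodeRef("disease", did)] = vec

    net: dict[NodeRef, np.ndarray] = {}
    if mode in ("network", "aggregated"):
        table = embed_graph(
            graph,
            config.metapath,
            config.walks_per_node,
            config.walk_length,
            SkipGramConfig(
                dim=config.embed_dim,
                window=config.window,
                negative=config.negative,
                epochs=config.sg_epochs,
                learning_rate=config.sg_lr,
                seed=seeds["skipgram"],
            ),
            walk_seed=seeds["walks"],
        )
        for node in drug_nodes + disease_nodes:
            net[node] = table.vector_or_zero(node)

    if mode == "attribute":
        return attr
    if mode == "network":
        return net
    # drugs and diseases are fused by the same machinery but separately
    # (their attribute widths differ), one LMF parameter set per node type
    fused: dict[NodeRef, np.ndarray] = {}
    for i, ntype in enumerate(("drug", "disease")):
        a = {n: attr[n] for n in attr if n.node_type == ntype and n in net}
        e = {n: net[n] for n in a}
        params = fit_lmf(
            a,
            e,
            rank=config.lmf_rank,
            out_dim=config.lmf_out_dim,
            seed=seeds["lmf"] + i,
            mode=config.lmf_mode,
        )
        fused.update(fuse_tables(a, e, params))
    return fused


def _usable_positives(
    positives: AssociationTable, fused: Mapping[NodeRef, np.ndarray]
) -> AssociationTable:
    pairs = frozenset(
        (d, i)
        for d, i in positives.pairs
        if NodeRef("drug", d) in fused and NodeRef("disease", i) in fused
    )
    if not pairs:
        raise ConfigError("no positive pair has feature vectors for both endpoints")
    return AssociationTable("drug", "disease", pairs)


def prepare_samples(
    dataset: Dataset,
    config: PipelineConfig = PipelineConfig(),
    mode: str = "aggregated",
):
    """Features, balanced negatives and labelled pair samples for a dataset."""
    seeds = config.stage_seeds()
    fused = build_feature_tables(dataset, config, mode)
    positives = _usable_positives(dataset.drug_disease, fused)
    drugs = sorted({n.identifier for n in fused if n.node_type == "drug"})
    diseases = sorted({n.identifier for n in fused if n.node_type == "disease"})
    negatives = sample_negatives(positives, drugs, diseases, seeds["neg"])
    samples = make_pairs(fused, positives, negatives)
    return fused, samples


def run_cv_experiment(
    dataset: Dataset,
    config: PipelineConfig = PipelineConfig(),
    mode: str = "aggregated",
    k: int = 10,
) -> MetricsReport:
    """Full pipeline to a stratified k-fold cross-validation report."""
    seeds = config.stage_seeds()
    _, samples = prepare_samples(dataset, config, mode)
    return kfold_cv(samples, k, config.classifier, seeds["clf"])


def ablation_run(
    dataset: Dataset,
    mode: str,
    config: PipelineConfig = PipelineConfig(),
    k: int = 10,
) -> MetricsReport:
    """Cross-validated report using only the selected feature block(s)."""
    if mode not in MODES:
        raise ConfigError(f"unknown ablation mode {mode!r}; choose from {MODES}")
    return run_cv_experiment(dataset, config, mode, k)


def rank_for_query(
    dataset: Dataset,
    query: NodeRef,
    config: PipelineConfig = PipelineConfig(),
    k: int = 10,
    mode: str = "aggregated",
) -> list[tuple[NodeRef, float]]:
    """Top-k novel candidates for one drug or disease query.

    The classifier is trained on all known associations (plus sampled
    negatives); candidates already associated with the query are excluded.
    """
    seeds = config.stage_seeds()
    fused, samples = prepare_samples(dataset, config, mode)
    model = train_classifier(samples, config.classifier, seeds["clf"])
    known = {
        pair for pair in dataset.drug_disease.pairs
    }
    cand_type = "disease" if query.node_type == "drug" else "drug"
    candidates = []
    for node in sorted(n for n in fused if n.node_type == cand_type):
        pair = (
            (query.identifier, node.identifier)
            if query.node_type == "drug"
            else (node.identifier, query.identifier)
        )
        if pair not in known:
            candidates.append(node)
    return rank_candidates(model, query, candidates, fused, k)


def load_dataset(directory: str | Path, delimiter: str = "\t") -> Dataset:
    """Read a dataset directory written by :mod:`ddanet.synthetic` or by hand.

    Expects ``drug_disease.tsv``, ``drug_protein.tsv``, ``disease_protein.tsv``,
    ``smiles.tsv`` and ``tree_numbers.tsv``.
    """
    from .hetnet import load_edge_list

    directory = Path(directory)
    return Dataset(
        drug_disease=load_edge_list(directory / "drug_disease.tsv", "drug", "disease", delimiter),
        drug_protein=load_edge_list(directory / "drug_protein.tsv", "drug", "protein", delimiter),
        disease_protein=load_edge_list(
            directory / "disease_protein.tsv", "disease", "protein", delimiter
        ),
        smiles=tuple(drug_features.load_smiles_table(directory / "smiles.tsv", delimiter)),
        tree_numbers={
            k: tuple(v)
            for k, v in disease_sim.load_tree_number_table(
                directory / "tree_numbers.tsv", delimiter
            ).items()
        },
    )
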