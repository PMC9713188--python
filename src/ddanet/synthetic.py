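"""Seeded synthetic universes with a planted drug-disease signal.

The generator emulates the structure of real drug-disease-protein benchmark
collections: three typed node sets, three bipartite edge layers, per-drug
SMILES strings and per-disease descriptor tree numbers. Drugs and diseases
are partitioned into latent clusters; drug-disease associations are drawn
Bernoulli(p_in) within a cluster and Bernoulli(p_out) across clusters, each
cluster gets dedicated bridge proteins wired to its own drugs and diseases,
SMILES are drawn from per-cluster pools of chemically distinct molecules
(aliphatic vs aromatic), and diseases of one cluster share descriptor
ancestors. A fraction of the within-cluster associations is held out of the
observed network as the planted truth, so recovering them is a genuine
link-prediction test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .disease_sim import DiseaseDAG
from .drug_features import SmilesRecord
from .exceptions import ConfigError
from .hetnet import AssociationTable
from .pipeline import Dataset

# ~50 small valid molecules; first block aliphatic, second aromatic, so
# per-cluster pools are chemically distinct and substructure bits carry
# cluster signal.
SMILES_POOL: tuple[str, ...] = (
    # aliphatic / non-aromatic
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCO", "CCN", "CO", "CC(C)O", "CC(=O)O",
    "CC(=O)C", "C=C", "C#N", "CCl", "CBr", "C=O", "OCC(O)CO", "CC(N)C(=O)O",
    "NCC(=O)O", "CC(=O)N", "CCOC(C)=O", "CSC", "CS(=O)C", "C1CCCCC1",
    "C1CCNCC1", "C1CCOC1", "O=C1CCCCC1", "CC1CCCCC1", "CN1CCCC1", "OC1CCCCC1",
    # aromatic
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "c1ccncc1", "c1ccoc1",
    "c1ccsc1", "c1cc[nH]c1", "Clc1ccccc1", "COc1ccccc1", "CC(=O)Nc1ccccc1",
    "O=C(O)c1ccccc1", "Cc1ccncc1", "c1ccc2ccccc2c1", "OC(=O)c1ccccc1O",
    "CC(=O)Oc1ccccc1C(=O)O", "N#Cc1ccccc1", "O=Cc1ccccc1", "CC(C)Cc1ccccc1",
    "Fc1ccccc1",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the planted-signal benchmark."""

    n_drugs: int = 20
    n_diseases: int = 20
    n_proteins: int = 10
    n_clusters: int = 2
    p_in: float = 0.8
    p_out: float = 0.05
    bridge_degree: int = 4
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ConfigError(f"need 0 <= p_out < p_in <= 1, got {self.p_out}, {self.p_in}")
        if self.n_clusters > min(self.n_drugs, self.n_diseases):
            raise ConfigError("more clusters than drugs or diseases")
        if self.n_clusters < 1 or self.n_proteins < self.n_clusters:
            raise ConfigError("need at least one protein per cluster")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise ConfigError("holdout_fraction must be in [0, 1)")


@dataclass(frozen=True)
class Universe:
    """A generated study: observed dataset plus the planted ground truth."""

    dataset: Dataset
    truth: AssociationTable  # held-out within-cluster positives
    drug_clusters: Mapping[str, int]
    disease_clusters: Mapping[str, int]
    config: SynthConfig


def _block_assign(n: int, k: int) -> list[int]:
    return [i * k // n for i in range(n)]


def generate_universe(config: SynthConfig = SynthConfig()) -> Universe:
    """Draw one synthetic universe under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    drugs = [f"DR{i:03d}" for i in range(config.n_drugs)]
    diseases = [f"DI{i:03d}" for i in range(config.n_diseases)]
    proteins = [f"PR{i:03d}" for i in range(config.n_proteins)]
    drug_cl = dict(zip(drugs, _block_assign(config.n_drugs, config.n_clusters)))
    dis_cl = dict(zip(diseases, _block_assign(config.n_diseases, config.n_clusters)))
    prot_cl = dict(zip(proteins, _block_assign(config.n_proteins, config.n_clusters)))

    # drug-disease layer with per-pair Bernoulli draw
    within, cross = [], []
    for d in drugs:
        for i in diseases:
            p = config.p_in if drug_cl[d] == dis_cl[i] else config.p_out
            if rng.random() < p:
                (within if drug_cl[d] == dis_cl[i] else cross).append((d, i))
    n_hold = int(round(config.holdout_fraction * len(within)))
    hold_idx = set(rng.choice(len(within), size=n_hold, replace=False).tolist()) if n_hold else set()
    truth = frozenset(within[j] for j in sorted(hold_idx))
    observed = frozenset(p for j, p in enumerate(within) if j not in hold_idx) | frozenset(cross)
    if not observed:
        raise ConfigError("no observed drug-disease edges drawn; raise p_in or sizes")

    # cluster-dedicated bridge proteins
    dp_pairs, ip_pairs = set(), set()
    for pr in proteins:
        c = prot_cl[pr]
        c_drugs = [d for d in drugs if drug_cl[d] == c]
        c_dis = [i for i in diseases if dis_cl[i] == c]
        for d in rng.choice(c_drugs, size=min(config.bridge_degree, len(c_drugs)), replace=False):
            dp_pairs.add((str(d), pr))
        for i in rng.choice(c_dis, size=min(config.bridge_degree, len(c_dis)), replace=False):
            ip_pairs.add((str(i), pr))

    # per-cluster SMILES pools (aliphatic vs aromatic blocks of SMILES_POOL)
    chunk = len(SMILES_POOL) // config.n_clusters
    pools = [
        SMILES_POOL[c * chunk : (c + 1) * chunk if c < config.n_clusters - 1 else None]
        for c in range(config.n_clusters)
    ]
    smiles = tuple(
        SmilesRecord(d, str(rng.choice(pools[drug_cl[d]]))) for d in drugs
    )

    # shared per-cluster descriptor ancestors: cluster root C{c}, subgroup level
    tree_numbers = {
        i: (f"C{dis_cl[i] + 1:02d}.{500 + int(i[2:]) // 3:03d}.{int(i[2:]):03d}",)
        for i in diseases
    }

    dataset = Dataset(
        drug_disease=AssociationTable("drug", "disease", observed),
        drug_protein=AssociationTable("drug", "protein", frozenset(dp_pairs)),
        disease_protein=AssociationTable("disease", "protein", frozenset(ip_pairs)),
        smiles=smiles,
        tree_numbers=tree_numbers,
    )
    return Universe(dataset, AssociationTable("drug", "disease", truth), drug_cl, dis_cl, config)


def write_universe(universe: Universe, directory: str | Path) -> None:
    """Write the full input file set (and the truth table) as TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = universe.dataset
    for name, table in (
        ("drug_disease", ds.drug_disease),
        ("drug_protein", ds.drug_protein),
        ("disease_protein", ds.disease_protein),
        ("truth", universe.truth),
    ):
        with (directory / f"{name}.tsv").open("w") as fh:
            for s, t in sorted(table.pairs):
                fh.write(f"{s}\t{t}\n")
    with (directory / "smiles.tsv").open("w") as fh:
        for rec in ds.smiles:
            fh.write(f"{rec.drug_id}\t{rec.smiles}\n")
    with (directory / "tree_numbers.tsv").open("w") as fh:
        for disease, codes in sorted(ds.tree_numbers.items()):
            fh.write(f"{disease}\t{','.join(codes)}\n")


@dataclass(frozen=True)
class ToyDagCase:
    """A hand-built DAG pair with its hand-computed similarity."""

    name: str
    dag_t: DiseaseDAG
    dag_r: DiseaseDAG
    gamma: float
    expected_sim: float


def toy_dag_suite() -> list[ToyDagCase]:
    """Hand-evaluated DAG similarity cases for oracle tests.

    Includes the two-sibling case (each DAG is {self, parent}, shared parent,
    gamma=0.5, similarity (0.5+0.5)/(1.5+1.5) = 1/3), the identical-DAG case
    (similarity 1) and the disjoint-ancestry case (similarity 0).
    """
    sib_t = DiseaseDAG("t", frozenset({"t", "P"}), frozenset({("P", "t")}))
    sib_r = DiseaseDAG("r", frozenset({"r", "P"}), frozenset({("P", "r")}))
    same = DiseaseDAG("x", frozenset({"x", "A", "B"}), frozenset({("A", "B"), ("B", "x")}))
    disj_t = DiseaseDAG("u", frozenset({"u", "Q"}), frozenset({("Q", "u")}))
    disj_r = DiseaseDAG("v", frozenset({"v", "R"}), frozenset({("R", "v")}))
    return [
        ToyDagCase("two-sibling", sib_t, sib_r, 0.5, 1.0 / 3.0),
        ToyDagCase("identical", same, same, 0.5, 1.0),
        ToyDagCase("disjoint", disj_t, disj_r, 0.5, 0.0),
    ]
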