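"""Cross-validated recovery of a planted drug-disease signal.

Generates a synthetic two-community drug-disease-protein universe, then runs
the full pipeline (substructure + DAG attributes, meta-path walk embeddings,
LMF fusion, random forest) under balanced 10-fold cross-validation in each
of the three feature modes. The aggregated mode uses both feature blocks;
attribute/network use one block each.
"""

import warnings

from ddanet import PipelineConfig, SynthConfig, generate_universe, run_cv_experiment

warnings.simplefilter("ignore")

universe = generate_universe(SynthConfig(seed=1))
print(
    f"universe: {len(universe.dataset.drug_disease)} drug-disease, "
    f"{len(universe.dataset.drug_protein)} drug-protein, "
    f"{len(universe.dataset.disease_protein)} disease-protein edges; "
    f"{len(universe.truth)} held-out truth pairs"
)

config = PipelineConfig(walks_per_node=50, walk_length=20, seed=1)
print(f"{'mode':<12}{'Acc':>8}{'AUC':>8}{'Prec':>8}{'Recall':>8}{'F1':>8}")
for mode in ("attribute", "network", "aggregated"):
    r = run_cv_experiment(universe.dataset, config, mode, k=10).mean
    print(f"{mode:<12}{r.acc:>8.4f}{r.auc:>8.4f}{r.prec:>8.4f}{r.recall:>8.4f}{r.f1:>8.4f}")

print()
print(
    "AUC well above the 0.5 chance level means held-out within-community\n"
    "associations are recovered; the aggregated mode draws on both the\n"
    "intrinsic (chemistry/ontology) and the network signal."
)
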