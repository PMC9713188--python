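"""Top-k novel disease candidates for one drug.

Trains the classifier on all observed associations, then ranks the diseases
NOT yet associated with the query drug by predicted association probability.
Because the generator held out some true within-community associations, we
can check how many of the top hits are planted truth.
"""

import warnings

from ddanet import NodeRef, PipelineConfig, SynthConfig, generate_universe, rank_for_query

warnings.simplefilter("ignore")

universe = generate_universe(SynthConfig(seed=1))
config = PipelineConfig(walks_per_node=50, walk_length=20, seed=1)

query = NodeRef("drug", "DR000")
truth = {i for d, i in universe.truth.pairs if d == "DR000"}
ranked = rank_for_query(universe.dataset, query, config, k=5)

print(f"top-5 novel disease candidates for {query.identifier} (truth: {sorted(truth)})")
for disease, score in ranked:
    marker = " <- planted truth" if disease.identifier in truth else ""
    print(f"  {disease.identifier}  {score:.3f}{marker}")
print()
print(
    "Scores are predicted association probabilities; candidates already\n"
    "linked to the query in the observed network are excluded."
)
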