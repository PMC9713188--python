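"""Semantic similarity of diseases from MeSH-style descriptor tree numbers.

Builds the ancestor DAG of each disease from dot-delimited tree numbers,
computes the contribution-weighted similarity (decay factor gamma = 0.5) and
prints the resulting disease attribute matrix. Rows of this matrix are the
intrinsic disease feature vectors fed to the autoencoder in the full model.
"""

from ddanet import dags_from_tree_numbers, similarity_matrix

tree_numbers = {
    "lung neoplasm": ["C04.588.894", "C08.785"],
    "colonic neoplasm": ["C04.588.274"],
    "kidney injury": ["C12.777.419"],
}

dags = dags_from_tree_numbers(tree_numbers)
matrix = similarity_matrix(dags, gamma=0.5)

print(matrix.to_dataframe().round(3))
print()
print(
    "The two neoplasms share the C04.588 ancestry and score well above zero;\n"
    "kidney injury shares no ancestor with either, so its off-diagonals are 0."
)
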