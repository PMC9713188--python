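"""Meta-path walks, transition probabilities and skip-gram embeddings."""

import numpy as np
import pytest

from ddanet import (
    AssociationTable,
    ConfigError,
    EmbeddingTable,
    MetaPath,
    NodeRef,
    SkipGramConfig,
    SynthConfig,
    build_graph,
    generate_universe,
    generate_walks,
    train_skipgram,
    transition_distribution,
)
from ddanet.embeddings import DEFAULT_METAPATH, WalkCorpus, embed_graph


class TestMetaPath:
    @pytest.mark.parametrize(
        "types",
        [
            ("drug",),
            ("drug", "disease"),  # asymmetric
            ("drug", "gene", "drug"),  # unknown type
            ("drug", "drug", "drug"),  # consecutive repeat
        ],
    )
    def test_invalid_paths_rejected(self, types):
        with pytest.raises(ConfigError):
            MetaPath(tuple(types))

    def test_type_cycling(self):
        m = DEFAULT_METAPATH  # drug-disease-protein-disease-drug
        expect = ["drug", "disease", "protein", "disease"] * 3
        assert [m.type_at(i) for i in range(12)] == expect

    def test_string_round_trip(self):
        s = "drug-disease-protein-disease-drug"
        assert str(MetaPath.from_string(s)) == s


class TestTransitions:
    def test_uniform_over_four_neighbors(self, star_graph):
        dist = transition_distribution(star_graph, NodeRef("drug", "r1"), "disease")
        assert len(dist) == 4
        assert all(p == pytest.approx(0.25) for p in dist.values())
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_wrong_type_neighbor_gets_zero(self, triangle_graph):
        # r1 is adjacent to d1 (disease) and p1 (protein); restricting the
        # next type to protein must exclude the disease neighbor entirely
        dist = transition_distribution(triangle_graph, NodeRef("drug", "r1"), "protein")
        assert dist == {NodeRef("protein", "p1"): 1.0}
        assert NodeRef("disease", "d1") not in dist

    def test_dead_end_is_empty_distribution(self, star_graph):
        assert transition_distribution(star_graph, NodeRef("drug", "r1"), "protein") == {}


class TestWalks:
    def test_forced_walk_on_path_graph(self):
        g = build_graph(
            [
                AssociationTable("drug", "disease", frozenset({("r", "d")})),
                AssociationTable("disease", "protein", frozenset({("d", "p")})),
            ]
        )
        corpus = generate_walks(g, DEFAULT_METAPATH, walks_per_node=1, walk_length=5, seed=0)
        assert corpus.walks == (
            (
                NodeRef("drug", "r"),
                NodeRef("disease", "d"),
                NodeRef("protein", "p"),
                NodeRef("disease", "d"),
                NodeRef("drug", "r"),
            ),
        )

    def test_isolated_start_gives_singleton_walk(self):
        g = build_graph(
            [
                AssociationTable("drug", "disease", frozenset({("r", "d")})),
                AssociationTable("disease", "protein", frozenset({("d", "p")})),
                AssociationTable("drug", "protein", frozenset({("lonely", "px")})),
            ]
        )
        corpus = generate_walks(g, DEFAULT_METAPATH, 1, 5, seed=0)
        by_start = {w[0].identifier: w for w in corpus.walks}
        assert len(by_start["lonely"]) == 1  # no disease neighbor: truncates at once

    def test_same_seed_identical_corpus(self, bench_universe):
        g = bench_universe.dataset.graph()
        c1 = generate_walks(g, DEFAULT_METAPATH, 3, 10, seed=9)
        c2 = generate_walks(g, DEFAULT_METAPATH, 3, 10, seed=9)
        assert c1.walks == c2.walks

    def test_missing_edge_layer_is_config_error(self, star_graph):
        with pytest.raises(ConfigError, match="layer"):
            generate_walks(star_graph, DEFAULT_METAPATH, 1, 5, seed=0)

    def test_corpus_conforms_to_metapath_types(self, bench_universe):
        g = bench_universe.dataset.graph()
        corpus = generate_walks(g, DEFAULT_METAPATH, 2, 20, seed=1)
        assert corpus.validate_types()


class TestSkipGram:
    def test_degenerate_corpus_converges(self):
        a, b = NodeRef("drug", "a"), NodeRef("disease", "b")
        corpus = WalkCorpus(
            tuple([(a, b)] * 500), MetaPath(("drug", "disease", "drug"))
        )
        table = train_skipgram(
            corpus, SkipGramConfig(dim=8, window=1, epochs=30, seed=0)
        )
        assert table.softmax_probability(b, a) > 0.9

    def test_default_dimension_is_64(self):
        a, b = NodeRef("drug", "a"), NodeRef("disease", "b")
        corpus = WalkCorpus(tuple([(a, b)] * 10), MetaPath(("drug", "disease", "drug")))
        table = train_skipgram(corpus, SkipGramConfig(epochs=1))
        assert table.vector(a).shape == (64,)

    def test_same_seed_identical_table(self):
        a, b = NodeRef("drug", "a"), NodeRef("disease", "b")
        corpus = WalkCorpus(tuple([(a, b)] * 50), MetaPath(("drug", "disease", "drug")))
        cfg = SkipGramConfig(dim=16, epochs=3, seed=4)
        t1 = train_skipgram(corpus, cfg)
        t2 = train_skipgram(corpus, cfg)
        assert np.array_equal(t1.W_in, t2.W_in) and np.array_equal(t1.W_out, t2.W_out)

    def test_empty_corpus_is_error(self):
        with pytest.raises(ConfigError):
            train_skipgram(WalkCorpus((), DEFAULT_METAPATH))

    def test_absent_node_gets_zero_vector_with_warning(self):
        a, b = NodeRef("drug", "a"), NodeRef("disease", "b")
        corpus = WalkCorpus(tuple([(a, b)] * 10), MetaPath(("drug", "disease", "drug")))
        table = train_skipgram(corpus, SkipGramConfig(dim=8, epochs=1))
        with pytest.warns(UserWarning, match="zero embedding"):
            v = table.vector_or_zero(NodeRef("drug", "ghost"))
        assert np.array_equal(v, np.zeros(8))

    def test_word2vec_text_round_trip(self, tmp_path):
        a, b = NodeRef("drug", "a"), NodeRef("disease", "b")
        corpus = WalkCorpus(tuple([(a, b)] * 20), MetaPath(("drug", "disease", "drug")))
        table = train_skipgram(corpus, SkipGramConfig(dim=8, epochs=2))
        path = tmp_path / "emb.txt"
        table.save_word2vec(path)
        loaded = EmbeddingTable.load_word2vec(path)
        assert loaded.nodes == table.nodes
        assert np.allclose(loaded.W_in, table.W_in, atol=1e-6)


class TestPlantedStructure:
    def test_within_community_cosine_exceeds_cross(self):
        """Two weakly bridged drug-disease communities separate in embedding space."""
        uni = generate_universe(
            SynthConfig(n_drugs=10, n_diseases=10, n_proteins=4, p_in=0.9, p_out=0.02, seed=3)
        )
        g = uni.dataset.graph()
        table = embed_graph(
            g,
            walks_per_node=30,
            walk_length=20,
            config=SkipGramConfig(dim=32, epochs=5, seed=0),
            walk_seed=0,
        )
        drugs = [n for n in g.nodes_of_type("drug") if n in table]
        within, cross = [], []
        for i, u in enumerate(drugs):
            for v in drugs[i + 1 :]:
                same = uni.drug_clusters[u.identifier] == uni.drug_clusters[v.identifier]
                (within if same else cross).append(table.cosine(u, v))
        assert np.mean(within) > np.mean(cross)
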