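"""LMF fusion, pair construction, classifiers and candidate ranking."""

import numpy as np
import pytest

from ddanet import (
    AssociationTable,
    ConfigError,
    LMFParams,
    NodeRef,
    fit_lmf,
    lmf_fuse,
    make_pairs,
    predict_scores,
    rank_candidates,
    train_classifier,
)

from conftest import brute_force_lmf


def zero_params(rank=1, out_dim=3, attr_dim=2, net_dim=2) -> LMFParams:
    return LMFParams(
        rank=rank,
        W_a=np.zeros((rank, out_dim, attr_dim + 1)),
        W_e=np.zeros((rank, out_dim, net_dim + 1)),
        b=np.zeros(out_dim),
        out_dim=out_dim,
        attr_dim=attr_dim,
        net_dim=net_dim,
    )


class TestLmfFuse:
    def test_zero_weights_give_half_everywhere(self):
        out = lmf_fuse(np.zeros(2), np.zeros(2), zero_params())
        assert np.allclose(out, 0.5)

    def test_rank_one_scalar_hand_computation(self):
        # 1-d inputs, out_dim 1: pre = wa*[z,1] + we*[z,1]
        p = LMFParams(
            rank=1,
            W_a=np.array([[[2.0, 1.0]]]),
            W_e=np.array([[[-1.0, 0.5]]]),
            b=np.array([0.25]),
            out_dim=1,
            attr_dim=1,
            net_dim=1,
        )
        # pre = 2*0.5 + 1 + (-1*2) + 0.5 = 0.5 ; sigmoid(0.5)+0.25
        out = lmf_fuse(np.array([0.5]), np.array([2.0]), p)
        assert out[0] == pytest.approx(1.0 / (1.0 + np.exp(-0.5)) + 0.25, abs=1e-12)

    def test_matches_brute_force_assembly_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            rank = int(rng.integers(1, 5))
            attr_dim, net_dim, out_dim = (int(rng.integers(1, 6)) for _ in range(3))
            p = LMFParams(
                rank=rank,
                W_a=rng.normal(size=(rank, out_dim, attr_dim + 1)),
                W_e=rng.normal(size=(rank, out_dim, net_dim + 1)),
                b=rng.normal(size=out_dim),
                out_dim=out_dim,
                attr_dim=attr_dim,
                net_dim=net_dim,
            )
            a, e = rng.normal(size=attr_dim), rng.normal(size=net_dim)
            assert np.allclose(lmf_fuse(a, e, p), brute_force_lmf(a, e, p), atol=1e-10)

    def test_deterministic(self):
        p = zero_params()
        a, e = np.ones(2), np.ones(2)
        assert np.array_equal(lmf_fuse(a, e, p), lmf_fuse(a, e, p))

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            lmf_fuse(np.zeros(3), np.zeros(2), zero_params())


class TestFitLmf:
    def _tables(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"n{i}" for i in range(n)]
        return (
            {i: rng.normal(size=6) for i in ids},
            {i: rng.normal(size=4) for i in ids},
        )

    def test_seed_reproducible(self):
        a, e = self._tables()
        p1 = fit_lmf(a, e, rank=4, out_dim=8, seed=3)
        p2 = fit_lmf(a, e, rank=4, out_dim=8, seed=3)
        assert np.array_equal(p1.W_a, p2.W_a) and np.array_equal(p1.W_e, p2.W_e)

    def test_rank_zero_rejected(self):
        a, e = self._tables()
        with pytest.raises(ConfigError):
            fit_lmf(a, e, rank=0)

    def test_id_mismatch_rejected(self):
        a, e = self._tables()
        del e["n0"]
        with pytest.raises(ConfigError, match="n0"):
            fit_lmf(a, e)

    def test_smoke_fuse_runs_on_fitted_params(self):
        a, e = self._tables()
        p = fit_lmf(a, e, rank=4, out_dim=64, seed=0)
        out = lmf_fuse(a["n0"], e["n0"], p)
        assert out.shape == (64,) and np.isfinite(out).all()

    def test_learned_mode_tunes_and_stays_finite(self):
        a, e = self._tables()
        pairs = [("n0", "n1", 1), ("n2", "n3", 0), ("n4", "n5", 1), ("n6", "n7", 0)]
        p = fit_lmf(a, e, rank=2, out_dim=8, seed=0, mode="learned", labelled_pairs=pairs)
        assert np.isfinite(p.W_a).all() and np.isfinite(p.b).all()

    def test_learned_mode_requires_pairs(self):
        a, e = self._tables()
        with pytest.raises(ConfigError):
            fit_lmf(a, e, mode="learned")


def _fused_fixture(dim=4):
    rng = np.random.default_rng(0)
    fused = {}
    for i in range(3):
        fused[NodeRef("drug", f"r{i}")] = rng.normal(size=dim)
        fused[NodeRef("disease", f"d{i}")] = rng.normal(size=dim)
    return fused


class TestMakePairs:
    def test_balanced_labels_and_feature_length(self):
        fused = _fused_fixture(dim=4)
        pos = AssociationTable("drug", "disease", frozenset({("r0", "d0"), ("r1", "d1")}))
        neg = AssociationTable("drug", "disease", frozenset({("r0", "d1"), ("r2", "d2")}))
        samples = make_pairs(fused, pos, neg)
        assert len(samples) == 4
        assert sum(s.label for s in samples) == 2
        assert all(s.features.shape == (8,) for s in samples)

    def test_contradictory_pair_rejected(self):
        fused = _fused_fixture()
        t = AssociationTable("drug", "disease", frozenset({("r0", "d0")}))
        with pytest.raises(ConfigError, match="both"):
            make_pairs(fused, t, t)

    def test_missing_endpoint_rejected(self):
        fused = _fused_fixture()
        pos = AssociationTable("drug", "disease", frozenset({("ghost", "d0")}))
        neg = AssociationTable("drug", "disease", frozenset({("r0", "d1")}))
        with pytest.raises(ConfigError, match="representation"):
            make_pairs(fused, pos, neg)


def _separable_samples(n=40, dim=6, seed=0):
    from ddanet.fusion import PairSample

    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        label = i % 2
        feat = rng.normal(size=2 * dim) + 5.0 * label
        samples.append(PairSample(f"r{i}", f"d{i}", feat, label))
    return samples


class TestClassifiers:
    def test_rf_fits_separable_data_perfectly(self):
        samples = _separable_samples()
        model = train_classifier(samples, "RF", seed=0)
        scores = predict_scores(model, samples)
        assert np.all((scores >= 0.5) == np.array([s.label for s in samples], bool))

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigError):
            train_classifier(_separable_samples(), "SVM-ish", seed=0)

    def test_single_class_rejected(self):
        samples = [s for s in _separable_samples() if s.label == 1]
        with pytest.raises(ConfigError):
            train_classifier(samples, "RF", seed=0)

    def test_same_seed_same_predictions(self):
        samples = _separable_samples()
        s1 = predict_scores(train_classifier(samples, "RF", seed=7), samples)
        s2 = predict_scores(train_classifier(samples, "RF", seed=7), samples)
        assert np.array_equal(s1, s2)

    @pytest.mark.parametrize("name", ["AdaBoost", "GNB", "KNN", "LR"])
    def test_alternative_classifiers_fit_and_score(self, name):
        samples = _separable_samples()
        scores = predict_scores(train_classifier(samples, name, seed=0), samples)
        assert scores.shape == (len(samples),)
        assert np.all((scores >= 0) & (scores <= 1))


class _ConstantModel:
    classes_ = np.array([0, 1])

    def predict_proba(self, X):
        return np.tile([0.5, 0.5], (len(X), 1))


class TestRanking:
    def _setup(self):
        fused = _fused_fixture(dim=6)
        from ddanet.fusion import PairSample

        rng = np.random.default_rng(1)
        samples = []
        for i in range(3):
            for j in range(3):
                label = 1 if i == j else 0
                feat = np.concatenate(
                    [fused[NodeRef("drug", f"r{i}")], fused[NodeRef("disease", f"d{j}")]]
                ) + (3.0 * label)
                samples.append(PairSample(f"r{i}", f"d{j}", feat, label))
        model = train_classifier(samples, "RF", seed=0)
        return fused, model

    def test_k_larger_than_candidates_returns_all(self):
        fused, model = self._setup()
        cands = [NodeRef("disease", f"d{i}") for i in range(3)]
        ranked = rank_candidates(model, NodeRef("drug", "r0"), cands, fused, k=10)
        assert len(ranked) == 3

    def test_scores_are_probabilities_and_sorted(self):
        fused, model = self._setup()
        cands = [NodeRef("disease", f"d{i}") for i in range(3)]
        ranked = rank_candidates(model, NodeRef("drug", "r0"), cands, fused, k=3)
        scores = [s for _, s in ranked]
        assert all(0 <= s <= 1 for s in scores)
        assert scores == sorted(scores, reverse=True)

    def test_empty_candidates_rejected(self):
        fused, model = self._setup()
        with pytest.raises(ConfigError):
            rank_candidates(model, NodeRef("drug", "r0"), [], fused)

    def test_ties_break_lexicographically(self):
        fused, _ = self._setup()
        cands = [NodeRef("disease", d) for d in ("d2", "d0", "d1")]
        ranked = rank_candidates(_ConstantModel(), NodeRef("drug", "r0"), cands, fused, k=3)
        assert [c.identifier for c, _ in ranked] == ["d0", "d1", "d2"]

    def test_disease_query_ranks_drugs(self):
        fused, model = self._setup()
        cands = [NodeRef("drug", f"r{i}") for i in range(3)]
        ranked = rank_candidates(model, NodeRef("disease", "d0"), cands, fused, k=2)
        assert len(ranked) == 2 and all(c.node_type == "drug" for c, _ in ranked)
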