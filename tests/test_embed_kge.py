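"""Triple scoring, margin loss, negative sampling, and gradient correctness
for the translational/bilinear embedding methods."""

import itertools

import numpy as np
import pytest

from embedpvp.embed_kge import (
    KGEChannel,
    NegativeBatch,
    Triple,
    _dissim_and_contribs,
    init_kge_model,
    margin_loss,
    pair_loss_and_grads,
    sample_negatives,
    score_triple,
    triple_plausibility,
)
from embedpvp.knowledge_base import KnowledgeGraph
from embedpvp.model_core import EmbeddingModel, TrainConfig


def _model(method, params, entities=("e0", "e1"), relations=("r0",)):
    dim = params["ent_emb"].shape[1]
    return EmbeddingModel(method, dim, list(entities), list(relations), params)


class TestScoreTriple:
    def test_transe_exact_translation_scores_zero(self):
        params = {
            "ent_emb": np.array([[1.0, 0.0], [1.0, 1.0]]),
            "rel_emb": np.array([[0.0, 1.0]]),
        }
        model = _model("transe", params)
        assert score_triple(model, Triple("e0", "r0", "e1")) == pytest.approx(0.0)

    def test_transe_l2_norm_value(self):
        # h=(1,0), r=(0,1), t=(0,0) -> ||(1,1)|| = sqrt(2)
        params = {
            "ent_emb": np.array([[1.0, 0.0], [0.0, 0.0]]),
            "rel_emb": np.array([[0.0, 1.0]]),
        }
        model = _model("transe", params)
        assert score_triple(model, Triple("e0", "r0", "e1")) == pytest.approx(
            1.414214, abs=1e-6
        )

    def test_distmult_trilinear_value(self):
        # h=(1,2), r=(1,1), t=(3,4) -> 1*1*3 + 2*1*4 = 11
        params = {
            "ent_emb": np.array([[1.0, 2.0], [3.0, 4.0]]),
            "rel_emb": np.array([[1.0, 1.0]]),
        }
        model = _model("distmult", params)
        assert score_triple(model, Triple("e0", "r0", "e1")) == pytest.approx(11.0)

    def test_transd_with_zero_projections_reduces_to_transe(self):
        rng = np.random.default_rng(0)
        ent = rng.normal(size=(4, 5))
        rel = rng.normal(size=(2, 5))
        transe = {"ent_emb": ent.copy(), "rel_emb": rel.copy()}
        transd = {
            "ent_emb": ent.copy(), "rel_emb": rel.copy(),
            "ent_proj": np.zeros((4, 5)), "rel_proj": np.zeros((2, 5)),
        }
        h = np.array([0, 1, 2])
        r = np.array([0, 1, 0])
        t = np.array([3, 2, 1])
        se, _ = _dissim_and_contribs("transe", transe, h, r, t)
        sd, _ = _dissim_and_contribs("transd", transd, h, r, t)
        np.testing.assert_allclose(se, sd, rtol=0, atol=1e-12)

    def test_unknown_id_raises(self):
        model = init_kge_model("transe", ["a", "b"], ["r"], 4, seed=0)
        with pytest.raises(KeyError):
            score_triple(model, Triple("missing", "r", "b"))


class TestMarginLoss:
    @pytest.mark.parametrize(
        "pos,neg,gamma,expected",
        [
            (3.0, 3.0, 1.0, 1.0),     # equal scores leave the full margin
            (0.0, 5.0, 1.0, 0.0),     # margin satisfied
            (2.0, 0.5, 0.5, 2.0),     # 2 - 0.5 + 0.5
        ],
    )
    def test_values(self, pos, neg, gamma, expected):
        assert margin_loss(pos, neg, gamma) == pytest.approx(expected)

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(0)
        vals = margin_loss(rng.normal(size=100), rng.normal(size=100), 0.3)
        assert (np.asarray(vals) >= 0).all()


class TestSampleNegatives:
    def test_two_entity_single_triple_enumeration(self):
        # brute force: the only corruptions of (a, r, b) over {a, b} that are
        # not the positive itself are (b, r, b) and (a, r, a)
        positives = [Triple("a", "r", "b")]
        possible = set()
        for repl, spot in itertools.product(["a", "b"], ["head", "tail"]):
            cand = ("a", "r", repl) if spot == "tail" else (repl, "r", "b")
            if cand != ("a", "r", "b"):
                possible.add(cand)
        batch = sample_negatives(positives, ["a", "b"], seed=0)
        assert isinstance(batch, NegativeBatch)
        neg = batch.negatives[0]
        assert (neg.head, neg.relation, neg.tail) in possible

    def test_negatives_avoid_existing_edges(self):
        entities = [f"e{i}" for i in range(6)]
        existing = {("e0", "r", "e1"), ("e0", "r", "e2"), ("e3", "r", "e1")}
        positives = [Triple("e0", "r", "e1")] * 200
        batch = sample_negatives(positives, entities, seed=1, existing=existing)
        for neg in batch.negatives:
            assert (neg.head, neg.relation, neg.tail) not in existing

    def test_seeded_determinism(self):
        positives = [Triple("a", "r", "b"), Triple("b", "r", "c")]
        one = sample_negatives(positives, ["a", "b", "c", "d"], seed=5)
        two = sample_negatives(positives, ["a", "b", "c", "d"], seed=5)
        assert one.negatives == two.negatives

    def test_too_few_entities_raises(self):
        with pytest.raises(ValueError):
            sample_negatives([Triple("a", "r", "a")], ["a"], seed=0)


class TestGradients:
    @pytest.mark.parametrize("method", ["transe", "transd", "distmult"])
    def test_analytic_gradients_match_finite_differences(self, method):
        rng = np.random.default_rng(42)
        dim, n_ent, n_rel = 5, 6, 2
        params = {
            "ent_emb": rng.normal(size=(n_ent, dim)),
            "rel_emb": rng.normal(size=(n_rel, dim)),
        }
        if method == "transd":
            params["ent_proj"] = rng.normal(scale=0.5, size=(n_ent, dim))
            params["rel_proj"] = rng.normal(scale=0.5, size=(n_rel, dim))
        pos = (np.array([0, 1, 2]), np.array([0, 1, 0]), np.array([3, 4, 5]))
        neg = (np.array([1, 1, 2]), np.array([0, 1, 0]), np.array([5, 0, 4]))
        gamma = 10.0  # comfortably inside the active region of the hinge
        _, grads = pair_loss_and_grads(method, params, pos, neg, gamma)

        def loss_at(p):
            value, _ = pair_loss_and_grads(method, p, pos, neg, gamma)
            return value

        h = 1e-6
        for key in params:
            numeric = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                bumped = {k: v.copy() for k, v in params.items()}
                bumped[key][idx] += h
                up = loss_at(bumped)
                bumped[key][idx] -= 2 * h
                down = loss_at(bumped)
                numeric[idx] = (up - down) / (2 * h)
            np.testing.assert_allclose(
                grads[key], numeric, atol=1e-4, rtol=1e-4,
                err_msg=f"{method}:{key}",
            )


class TestPlausibility:
    def test_exact_translation_attains_maximum(self):
        params = {
            "ent_emb": np.array([[1.0, 0.0], [1.0, 1.0], [0.3, -0.4]]),
            "rel_emb": np.array([[0.0, 1.0]]),
        }
        model = _model("transe", params, entities=("g", "d", "x"))
        best = triple_plausibility(model, Triple("g", "r0", "d"))
        assert best == pytest.approx(0.5)  # sigma(0)
        for h, t in itertools.permutations(("g", "d", "x"), 2):
            assert triple_plausibility(model, Triple(h, "r0", t)) <= best + 1e-12

    @pytest.mark.parametrize("method", ["transe", "transd", "distmult"])
    def test_plausibility_ranking_reverses_dissimilarity(self, method):
        model = init_kge_model(
            method, [f"e{i}" for i in range(10)], ["r"], 6, seed=3
        )
        rng = np.random.default_rng(1)
        pairs = [
            Triple(f"e{a}", "r", f"e{b}")
            for a, b in rng.integers(0, 10, size=(20, 2))
            if a != b
        ]
        sign = -1.0 if method == "distmult" else 1.0
        by_dissim = sorted(pairs, key=lambda t: sign * score_triple(model, t))
        by_plaus = sorted(
            pairs, key=lambda t: -triple_plausibility(model, t)
        )
        assert [t for t in by_dissim] == [t for t in by_plaus]

    def test_distmult_symmetry(self):
        model = init_kge_model("distmult", ["g", "d"], ["r"], 8, seed=0)
        assert triple_plausibility(model, Triple("g", "r", "d")) == pytest.approx(
            triple_plausibility(model, Triple("d", "r", "g"))
        )

    def test_unscorable_returns_none(self):
        g = KnowledgeGraph()
        g.add_edge("g1", "is_associated_with", "d1")
        channel = KGEChannel("transe", dim=4, cfg=TrainConfig(epochs=2, seed=0)).fit(g)
        assert channel.score_gene_disease("g1", "d1") is not None
        assert channel.score_gene_disease("nope", "d1") is None
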