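"""Geometric inclusion losses, their gradients, and EL training behavior."""

import numpy as np
import pytest

from embedpvp.embed_el import (
    ELChannel,
    _neg_loss_contribs,
    _pos_loss_contribs,
    inclusion_loss,
    init_el_model,
    train_el,
)
from embedpvp.knowledge_base import Axiom
from embedpvp.model_core import EmbeddingModel, TrainConfig


def _ball_model(centers, radii, roles=None):
    n, dim = np.asarray(centers).shape
    roles = roles if roles is not None else {}
    params = {
        "ent_c": np.asarray(centers, dtype=float),
        "ent_r": np.asarray(radii, dtype=float),
        "rel_v": np.asarray(
            [roles[k] for k in sorted(roles)] or np.zeros((0, dim)), dtype=float
        ).reshape(-1, dim),
    }
    return EmbeddingModel(
        "elem", dim, [f"c{i}" for i in range(n)], sorted(roles), params
    )


def _box_model(centers, offsets, roles=None):
    n, dim = np.asarray(centers).shape
    roles = roles if roles is not None else {}
    params = {
        "ent_c": np.asarray(centers, dtype=float),
        "ent_off": np.asarray(offsets, dtype=float),
        "rel_v": np.asarray(
            [roles[k] for k in sorted(roles)] or np.zeros((0, dim)), dtype=float
        ).reshape(-1, dim),
    }
    return EmbeddingModel(
        "elbox", dim, [f"c{i}" for i in range(n)], sorted(roles), params
    )


class TestBallInclusion:
    def test_self_inclusion_is_zero(self):
        model = _ball_model([[0.3, 0.1], [0.3, 0.1]], [0.2, 0.2])
        assert inclusion_loss(model, Axiom("nf1", ("c0", "c1"))) == 0.0

    def test_separated_balls_value(self):
        # ||c_C - c_D|| + r_C - r_D = 3 + 1 - 1 = 3
        model = _ball_model([[0.0, 0.0], [3.0, 0.0]], [1.0, 1.0])
        assert inclusion_loss(model, Axiom("nf1", ("c0", "c1"))) == pytest.approx(3.0)

    def test_point_on_ball_boundary_is_zero(self):
        # radius-0 gene exactly on the disease ball boundary
        model = _ball_model([[1.0, 0.0], [0.0, 0.0]], [0.0, 1.0])
        assert inclusion_loss(model, Axiom("nf1", ("c0", "c1"))) == pytest.approx(0.0)

    def test_nf3_translated_containment_is_zero(self):
        roles = {"R": np.array([1.0, 0.0])}
        model = _ball_model([[0.0, 0.0], [1.0, 0.0]], [0.1, 0.5], roles)
        axiom = Axiom("nf3", ("c0", "c1"), role="R")
        assert inclusion_loss(model, axiom) == 0.0

    def test_nf3_invariant_under_joint_center_translation(self):
        rng = np.random.default_rng(0)
        roles = {"R": rng.normal(size=3)}
        centers = rng.normal(size=(2, 3))
        radii = [0.3, 0.2]
        axiom = Axiom("nf3", ("c0", "c1"), role="R")
        base = inclusion_loss(_ball_model(centers, radii, roles), axiom)
        shifted = inclusion_loss(
            _ball_model(centers + rng.normal(size=3), radii, roles), axiom
        )
        assert shifted == pytest.approx(base)


class TestBoxInclusion:
    def test_strict_containment_is_zero(self):
        model = _box_model([[0.0, 0.0], [0.1, 0.0]], [[0.2, 0.2], [0.8, 0.8]])
        assert inclusion_loss(model, Axiom("nf1", ("c0", "c1"))) == 0.0

    def test_disjoint_boxes_are_positive(self):
        model = _box_model([[0.0, 0.0], [2.0, 0.0]], [[0.2, 0.2], [0.2, 0.2]])
        assert inclusion_loss(model, Axiom("nf1", ("c0", "c1"))) > 0

    def test_nf2_contained_intersection_is_zero(self):
        # identical small boxes C=D inside the big box E
        model = _box_model(
            [[0.0, 0.0], [0.0, 0.0], [0.1, 0.1]],
            [[0.1, 0.1], [0.1, 0.1], [0.9, 0.9]],
        )
        assert inclusion_loss(model, Axiom("nf2", ("c0", "c1", "c2"))) == 0.0


class TestGradients:
    @pytest.mark.parametrize("variant", ["elem", "elbox"])
    @pytest.mark.parametrize("form", ["nf1", "nf2", "nf3", "nf4"])
    def test_positive_loss_gradients_match_finite_differences(self, variant, form):
        rng = np.random.default_rng(7)
        dim, n_ent = 4, 6
        params = {
            "ent_c": rng.normal(size=(n_ent, dim)),
            "rel_v": rng.normal(size=(2, dim)),
        }
        if variant == "elem":
            params["ent_r"] = rng.uniform(0.1, 0.5, size=n_ent)
        else:
            params["ent_off"] = rng.uniform(0.1, 0.5, size=(n_ent, dim))
        if form == "nf2":
            arrays = (np.array([0, 1]), np.array([2, 3]), np.array([4, 5]))
        elif form == "nf1":
            arrays = (np.array([0, 1, 2]), np.array([3, 4, 5]))
        else:
            arrays = (np.array([0, 1]), np.array([0, 1]), np.array([2, 3]))
        gamma = -5.0  # keep every hinge strictly active, away from the kink

        def total(p):
            loss, _ = _pos_loss_contribs(variant, p, form, arrays, gamma)
            return float(np.sum(loss))

        _, contribs = _pos_loss_contribs(variant, params, form, arrays, gamma)
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        for key, idx, g in contribs:
            np.add.at(grads[key], idx, g)
        h = 1e-6
        for key in params:
            numeric = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                bumped = {k: v.copy() for k, v in params.items()}
                bumped[key][i] += h
                up = total(bumped)
                bumped[key][i] -= 2 * h
                numeric[i] = (up - total(bumped)) / (2 * h)
            np.testing.assert_allclose(
                grads[key], numeric, atol=1e-4, rtol=1e-4,
                err_msg=f"{variant}:{form}:{key}",
            )

    @pytest.mark.parametrize("variant", ["elem", "elbox"])
    def test_negative_loss_gradients_match_finite_differences(self, variant):
        rng = np.random.default_rng(11)
        dim, n_ent = 4, 4
        params = {
            "ent_c": rng.normal(size=(n_ent, dim)),
            "rel_v": rng.normal(size=(1, dim)),
        }
        if variant == "elem":
            params["ent_r"] = rng.uniform(0.1, 0.5, size=n_ent)
        else:
            params["ent_off"] = rng.uniform(0.1, 0.5, size=(n_ent, dim))
        arrays = (np.array([0, 1]), np.array([0, 0]), np.array([2, 3]))
        margin = 50.0  # hinge active for every sample

        def total(p):
            loss, _ = _neg_loss_contribs(variant, p, "nf3", arrays, margin)
            return float(np.sum(loss))

        _, contribs = _neg_loss_contribs(variant, params, "nf3", arrays, margin)
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        for key, idx, g in contribs:
            np.add.at(grads[key], idx, g)
        h = 1e-6
        for key in params:
            numeric = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                bumped = {k: v.copy() for k, v in params.items()}
                bumped[key][i] += h
                up = total(bumped)
                bumped[key][i] -= 2 * h
                numeric[i] = (up - total(bumped)) / (2 * h)
            np.testing.assert_allclose(
                grads[key], numeric, atol=1e-4, rtol=1e-4,
                err_msg=f"{variant}:{key}",
            )


class TestTraining:
    @pytest.mark.parametrize("variant", ["elem", "elbox"])
    def test_single_axiom_loss_decreases(self, variant):
        axioms = [Axiom("nf1", ("C", "D"))]
        cfg = TrainConfig(epochs=80, seed=0, patience=100, lr=0.05)
        channel = train_el(axioms, cfg, variant=variant, dim=8)
        initial = init_el_model(variant, ["C", "D"], ["is_associated_with"], 8, 0)
        before = inclusion_loss(initial, axioms[0], gamma=0.0)
        after = inclusion_loss(channel.model, axioms[0], gamma=0.0)
        assert after < before

    def test_subclass_chain_transfers_in_latent_space(self):
        # C ⊑ D ⊑ E trained to convergence: the unseen composite C ⊑ E gets a
        # smaller loss than random concept pairs
        axioms = [
            Axiom("nf1", ("C", "D")), Axiom("nf1", ("D", "E")),
            Axiom("nf1", ("X1", "X2")), Axiom("nf1", ("X3", "X4")),
        ]
        cfg = TrainConfig(epochs=150, seed=0, patience=200, lr=0.05)
        channel = train_el(axioms, cfg, variant="elem", dim=8)
        composite = inclusion_loss(channel.model, Axiom("nf1", ("C", "E")))
        rng = np.random.default_rng(0)
        names = ["C", "D", "E", "X1", "X2", "X3", "X4"]
        random_losses = [
            inclusion_loss(channel.model, Axiom("nf1", tuple(rng.choice(names, 2, replace=False))))
            for _ in range(30)
        ]
        assert composite < np.mean(random_losses)

    @pytest.mark.parametrize("variant", ["elem", "elbox"])
    def test_zero_epochs_keeps_initialization(self, variant):
        axioms = [Axiom("nf1", ("C", "D"))]
        cfg = TrainConfig(epochs=0, seed=3, patience=0)
        channel = train_el(axioms, cfg, variant=variant, dim=6)
        fresh = init_el_model(
            variant, channel.model.entities, channel.model.relations, 6, 3
        )
        from embedpvp.embed_el import apply_el_constraints

        apply_el_constraints(fresh)
        for key in fresh.params:
            np.testing.assert_array_equal(channel.model.params[key], fresh.params[key])


class TestScoring:
    def test_zero_loss_scores_half_the_maximum(self):
        roles = {"is_associated_with": np.array([0.5, 0.0])}
        model = _ball_model([[0.0, 0.0], [0.5, 0.0]], [0.1, 0.5], roles)
        channel = ELChannel(variant="elem", dim=2)
        channel.model = model
        assert channel.score_gene_disease("c0", "c1") == pytest.approx(0.5)

    def test_score_ordering_reverses_loss_ordering(self):
        model = init_el_model(
            "elem", [f"c{i}" for i in range(10)], ["is_associated_with"], 5, seed=2
        )
        channel = ELChannel(variant="elem", dim=5)
        channel.model = model
        rng = np.random.default_rng(4)
        pairs = [
            (f"c{a}", f"c{b}") for a, b in rng.integers(0, 10, size=(20, 2)) if a != b
        ]
        losses = [
            inclusion_loss(model, Axiom("nf3", p, role="is_associated_with"))
            for p in pairs
        ]
        scores = [channel.score_gene_disease(*p) for p in pairs]
        for i in range(len(pairs)):
            for j in range(len(pairs)):
                if losses[i] < losses[j]:
                    assert scores[i] > scores[j]

    def test_unscorable_is_none(self):
        channel = ELChannel(variant="elbox", dim=4)
        channel.model = init_el_model("elbox", ["a"], ["is_associated_with"], 4, 0)
        assert channel.score_gene_disease("a", "missing") is None
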