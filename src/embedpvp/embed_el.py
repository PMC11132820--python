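"""Geometric (model-theoretic) EL embeddings: n-balls and boxes.

Concepts are embedded as geometric regions — an n-ball (center ``c``, radius
``r >= 0``) or an axis-aligned box (center ``c``, non-negative per-dimension
offset ``o``) — and roles as translation vectors ``v``.  Each EL normal form
gets an *inclusion loss* that is zero exactly when the (margin-relaxed)
geometric containment holds, so that minimizing the loss drives the regions
toward a geometric model of the axioms.  The implemented loss families follow
the ball/box embedding tradition; the exact formulas are documented next to
each function and covered by the finite-difference tests.

Negatives corrupt the right-hand concept of an axiom and are pushed to an
inclusion distance of at least ``neg_margin``.  Gene–disease/patient
plausibility is the score of the axiom ``g ⊑ ∃is_associated_with.d`` mapped
through ``sigma(-loss)`` at margin 0 (so 0.5 — loss zero — is the maximum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .knowledge_base import (
    HAS_PHENOTYPE,
    IS_ASSOCIATED_WITH,
    AnnotationSet,
    Axiom,
    NF1,
    NF2,
    NF3,
    NF4,
    Ontology,
)
from .model_core import Adam, EmbeddingModel, TrainConfig, fit, init_uniform

EL_VARIANTS = ("elem", "elbox")
_EPS = 1e-12

Contribs = list[tuple[str, np.ndarray, np.ndarray]]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Ball losses
#
# Inclusion distances delta (zero/negative when containment holds):
#   NF1  C ⊑ D      delta = ||c_C - c_D|| + r_C - r_D
#   NF3  C ⊑ ∃R.D   delta = ||c_C + v_R - c_D|| + r_C - r_D
#   NF4  ∃R.C ⊑ D   delta = ||c_C - v_R - c_D|| + r_C - r_D
# positive loss = max(0, delta - gamma); negative loss = max(0, gamma_n - delta).
# NF2 (C ⊓ D ⊑ E) uses a midpoint-intersection surrogate:
#   max(0, ||c_C - c_D|| - r_C - r_D - gamma)                (C, D intersect)
# + max(0, ||m - c_E|| + min(r_C, r_D) - r_E - gamma),  m = (c_C + c_D)/2
# ---------------------------------------------------------------------------


def _unit(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(d, axis=1)
    return norm, d / np.maximum(norm, _EPS)[:, None]


def _ball_delta(
    params: dict[str, np.ndarray], form: str, arrays: tuple[np.ndarray, ...]
) -> tuple[np.ndarray, Contribs]:
    C = params["ent_c"]
    R = params["ent_r"]
    if form == NF1:
        ic, id_ = arrays
        norm, u = _unit(C[ic] - C[id_])
        delta = norm + R[ic] - R[id_]
        contribs: Contribs = [
            ("ent_c", ic, u),
            ("ent_c", id_, -u),
            ("ent_r", ic, np.ones_like(delta)),
            ("ent_r", id_, -np.ones_like(delta)),
        ]
        return delta, contribs
    if form in (NF3, NF4):
        ic, ir, id_ = arrays
        sign = 1.0 if form == NF3 else -1.0
        norm, u = _unit(C[ic] + sign * params["rel_v"][ir] - C[id_])
        delta = norm + R[ic] - R[id_]
        contribs = [
            ("ent_c", ic, u),
            ("rel_v", ir, sign * u),
            ("ent_c", id_, -u),
            ("ent_r", ic, np.ones_like(delta)),
            ("ent_r", id_, -np.ones_like(delta)),
        ]
        return delta, contribs
    raise ValueError(f"no scalar inclusion distance for form {form!r}")


def _ball_nf2_loss(
    params: dict[str, np.ndarray],
    arrays: tuple[np.ndarray, ...],
    gamma: float,
) -> tuple[np.ndarray, Contribs]:
    C, R = params["ent_c"], params["ent_r"]
    ic, id_, ie = arrays
    one = np.ones(len(ic))
    norm1, u1 = _unit(C[ic] - C[id_])
    term1 = norm1 - R[ic] - R[id_] - gamma
    m1 = (term1 > 0).astype(float)
    mid = 0.5 * (C[ic] + C[id_])
    norm2, u2 = _unit(mid - C[ie])
    rmin = np.minimum(R[ic], R[id_])
    term2 = norm2 + rmin - R[ie] - gamma
    m2 = (term2 > 0).astype(float)
    c_is_min = (R[ic] <= R[id_]).astype(float)
    loss = np.maximum(term1, 0.0) + np.maximum(term2, 0.0)
    contribs: Contribs = [
        ("ent_c", ic, m1[:, None] * u1 + 0.5 * m2[:, None] * u2),
        ("ent_c", id_, -m1[:, None] * u1 + 0.5 * m2[:, None] * u2),
        ("ent_c", ie, -m2[:, None] * u2),
        ("ent_r", ic, -m1 * one + m2 * c_is_min),
        ("ent_r", id_, -m1 * one + m2 * (1.0 - c_is_min)),
        ("ent_r", ie, -m2 * one),
    ]
    return loss, contribs


# ---------------------------------------------------------------------------
# Box losses
#
# Per-dimension inclusion excess e = |c_C - c_D| + o_C - o_D (translated for
# NF3/NF4); positive loss = sum_d max(0, e_d - gamma) — zero exactly when box C
# (shifted by the role vector where applicable) lies inside box D with margin.
# The scalar inclusion distance for negatives is max_d(e_d) (boxes separated in
# at least one dimension once it exceeds the margin).  NF2 mirrors the ball
# surrogate with the midpoint box (center (c_C+c_D)/2, offset min(o_C, o_D)).
# ---------------------------------------------------------------------------


def _box_excess(
    params: dict[str, np.ndarray], form: str, arrays: tuple[np.ndarray, ...]
) -> tuple[np.ndarray, np.ndarray, tuple]:
    C, O = params["ent_c"], params["ent_off"]
    if form == NF1:
        ic, id_ = arrays
        diff = C[ic] - C[id_]
        return np.abs(diff) + O[ic] - O[id_], np.sign(diff), (ic, None, id_)
    ic, ir, id_ = arrays
    sign = 1.0 if form == NF3 else -1.0
    diff = C[ic] + sign * params["rel_v"][ir] - C[id_]
    return np.abs(diff) + O[ic] - O[id_], np.sign(diff), (ic, ir, id_)


def _box_pos_loss(
    params: dict[str, np.ndarray],
    form: str,
    arrays: tuple[np.ndarray, ...],
    gamma: float,
) -> tuple[np.ndarray, Contribs]:
    e, sgn, (ic, ir, id_) = _box_excess(params, form, arrays)
    mask = (e - gamma > 0).astype(float)
    loss = np.sum(np.maximum(e - gamma, 0.0), axis=1)
    g_c = mask * sgn
    contribs: Contribs = [
        ("ent_c", ic, g_c),
        ("ent_c", id_, -g_c),
        ("ent_off", ic, mask),
        ("ent_off", id_, -mask),
    ]
    if ir is not None:
        role_sign = 1.0 if form == NF3 else -1.0
        contribs.append(("rel_v", ir, role_sign * g_c))
    return loss, contribs


def _box_neg_delta(
    params: dict[str, np.ndarray], form: str, arrays: tuple[np.ndarray, ...]
) -> tuple[np.ndarray, Contribs]:
    """Scalar separation distance max_d(e_d) with subgradient at the argmax."""
    e, sgn, (ic, ir, id_) = _box_excess(params, form, arrays)
    arg = np.argmax(e, axis=1)
    rows = np.arange(len(e))
    delta = e[rows, arg]
    onehot = np.zeros_like(e)
    onehot[rows, arg] = 1.0
    g_c = onehot * sgn
    contribs: Contribs = [
        ("ent_c", ic, g_c),
        ("ent_c", id_, -g_c),
        ("ent_off", ic, onehot),
        ("ent_off", id_, -onehot),
    ]
    if ir is not None:
        role_sign = 1.0 if form == NF3 else -1.0
        contribs.append(("rel_v", ir, role_sign * g_c))
    return delta, contribs


def _box_nf2_loss(
    params: dict[str, np.ndarray],
    arrays: tuple[np.ndarray, ...],
    gamma: float,
) -> tuple[np.ndarray, Contribs]:
    C, O = params["ent_c"], params["ent_off"]
    ic, id_, ie = arrays
    diff = C[ic] - C[id_]
    e1 = np.abs(diff) - O[ic] - O[id_] - gamma
    m1 = (e1 > 0).astype(float)
    s1 = np.sign(diff)
    mid = 0.5 * (C[ic] + C[id_])
    omin = np.minimum(O[ic], O[id_])
    c_is_min = (O[ic] <= O[id_]).astype(float)
    diff2 = mid - C[ie]
    e2 = np.abs(diff2) + omin - O[ie] - gamma
    m2 = (e2 > 0).astype(float)
    s2 = np.sign(diff2)
    loss = np.sum(np.maximum(e1, 0.0), axis=1) + np.sum(np.maximum(e2, 0.0), axis=1)
    contribs: Contribs = [
        ("ent_c", ic, m1 * s1 + 0.5 * m2 * s2),
        ("ent_c", id_, -m1 * s1 + 0.5 * m2 * s2),
        ("ent_c", ie, -m2 * s2),
        ("ent_off", ic, -m1 + m2 * c_is_min),
        ("ent_off", id_, -m1 + m2 * (1.0 - c_is_min)),
        ("ent_off", ie, -m2),
    ]
    return loss, contribs


# ---------------------------------------------------------------------------
# Unified per-axiom API
# ---------------------------------------------------------------------------


def _pos_loss_contribs(
    variant: str,
    params: dict[str, np.ndarray],
    form: str,
    arrays: tuple[np.ndarray, ...],
    gamma: float,
) -> tuple[np.ndarray, Contribs]:
    if form == NF2:
        fn = _ball_nf2_loss if variant == "elem" else _box_nf2_loss
        return fn(params, arrays, gamma)
    if variant == "elem":
        delta, contribs = _ball_delta(params, form, arrays)
        mask = (delta - gamma > 0).astype(float)
        loss = np.maximum(delta - gamma, 0.0)
        gated = [(k, i, _gate(g, mask)) for k, i, g in contribs]
        return loss, gated
    loss, contribs = _box_pos_loss(params, form, arrays, gamma)
    return loss, contribs


def _neg_loss_contribs(
    variant: str,
    params: dict[str, np.ndarray],
    form: str,
    arrays: tuple[np.ndarray, ...],
    neg_margin: float,
) -> tuple[np.ndarray, Contribs]:
    if variant == "elem":
        delta, contribs = _ball_delta(params, form, arrays)
    else:
        delta, contribs = _box_neg_delta(params, form, arrays)
    mask = (neg_margin - delta > 0).astype(float)
    loss = np.maximum(neg_margin - delta, 0.0)
    gated = [(k, i, _gate(g, -mask)) for k, i, g in contribs]
    return loss, gated


def _gate(g: np.ndarray, coef: np.ndarray) -> np.ndarray:
    return g * (coef[:, None] if g.ndim == 2 else coef)


def _accumulate(
    grads: dict[str, np.ndarray], contribs: Contribs, scale: float
) -> None:
    for key, idx, g in contribs:
        np.add.at(grads[key], idx, scale * g)


def inclusion_loss(model: EmbeddingModel, axiom: Axiom, gamma: float = 0.0) -> float:
    """Per-axiom inclusion loss (>= 0; zero when the margin-relaxed geometric
    containment holds) for a trained ball ("elem") or box ("elbox") model."""
    variant = model.method
    if variant not in EL_VARIANTS:
        raise ValueError(f"not an EL model: {variant!r}")
    idx = [model.entity_index(c) for c in axiom.concepts]
    if axiom.form in (NF3, NF4):
        arrays = (
            np.array([idx[0]]),
            np.array([model.relation_index(axiom.role)]),
            np.array([idx[1]]),
        )
    else:
        arrays = tuple(np.array([i]) for i in idx)
    loss, _ = _pos_loss_contribs(variant, model.params, axiom.form, arrays, gamma)
    return float(loss[0])


# ---------------------------------------------------------------------------
# KB -> axiom conversion
# ---------------------------------------------------------------------------


def axioms_from_kb(
    ontology: Ontology,
    annotations: AnnotationSet | None = None,
    patients: list[tuple[str, list[str]]] | None = None,
    include_axioms: bool = True,
) -> list[Axiom]:
    """Assemble the EL training corpus: ontology axioms (unless ablated), one
    ``x ⊑ ∃rel.cls`` axiom per annotation row, one ``g ⊑ ∃assoc.d`` axiom per
    training association, and patient phenotype axioms."""
    axioms: list[Axiom] = list(ontology.axioms) if include_axioms else []
    if annotations is not None:
        for table in (annotations.gene_annotations, annotations.disease_phenotypes):
            for entity, relation, cls in table.itertuples(index=False):
                axioms.append(Axiom(NF3, (entity, cls), role=relation))
        for gene, disease in annotations.associations[
            ["gene_id", "disease_id"]
        ].itertuples(index=False):
            axioms.append(Axiom(NF3, (gene, disease), role=IS_ASSOCIATED_WITH))
    for pid, phenotypes in patients or []:
        for cls in sorted(set(phenotypes)):
            axioms.append(Axiom(NF3, (pid, cls), role=HAS_PHENOTYPE))
    return axioms


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------


def _group_axioms(
    axioms: list[Axiom], eidx: dict[str, int], ridx: dict[str, int]
) -> dict[str, np.ndarray]:
    grouped: dict[str, list[list[int]]] = {NF1: [], NF2: [], NF3: [], NF4: []}
    for ax in axioms:
        row = [eidx[c] for c in ax.concepts]
        if ax.form in (NF3, NF4):
            row = [row[0], ridx[ax.role], row[1]]
        grouped[ax.form].append(row)
    return {
        form: np.array(rows, dtype=np.int64)
        for form, rows in grouped.items()
        if rows
    }


class _ELObjective:
    def __init__(
        self,
        model: EmbeddingModel,
        grouped: dict[str, np.ndarray],
        cfg: TrainConfig,
        gamma: float,
        val_grouped: dict[str, np.ndarray] | None,
        axiom_keys: set[tuple],
        corrupt_role_idx: set[int] | None = None,
        size_reg: float = 0.0,
    ) -> None:
        # L2 shrinkage on box offsets / ball radii: keeps region sizes
        # comparable across entities so that scores reflect position, not
        # how often an entity appeared on the right-hand side in training
        self.size_reg = size_reg
        self.model = model
        self.params = model.params
        self.grouped = grouped
        self.cfg = cfg
        self.gamma = gamma
        self.axiom_keys = axiom_keys
        # roles whose NF3/NF4 axioms receive corrupted negatives; None = all
        self.corrupt_role_idx = corrupt_role_idx
        self.val_pairs: list[tuple[str, tuple, tuple]] = []
        if val_grouped:
            rng = np.random.default_rng(cfg.seed + 101)
            for form, rows in sorted(val_grouped.items()):
                if form == NF2:
                    continue
                neg = self._corrupt(form, rows, rng, n_neg=10)
                pos = np.repeat(rows, 10, axis=0)
                self.val_pairs.append((form, tuple(pos.T), tuple(neg.T)))

    def _corrupt(
        self, form: str, rows: np.ndarray, rng: np.random.Generator, n_neg: int
    ) -> np.ndarray:
        n_ent = len(self.model.entities)
        out = np.repeat(rows, n_neg, axis=0).copy()
        pending = np.arange(len(out))
        for _ in range(200):
            repl = rng.integers(n_ent, size=len(pending))
            cand = out[pending].copy()
            cand[:, -1] = repl  # corrupt the right-hand concept
            bad = np.fromiter(
                (
                    (form, *map(int, row)) in self.axiom_keys
                    or row[-1] == out[p, -1]
                    for p, row in zip(pending, cand)
                ),
                dtype=bool,
                count=len(pending),
            )
            out[pending[~bad]] = cand[~bad]
            pending = pending[bad]
            if not len(pending):
                return out
        raise RuntimeError("could not corrupt EL axioms (concept pool too small)")

    def _corruptible(self, form: str, rows: np.ndarray) -> np.ndarray:
        """Mask of axioms that receive corrupted negatives."""
        if form == NF2:
            return np.zeros(len(rows), dtype=bool)
        if self.corrupt_role_idx is None:
            return np.ones(len(rows), dtype=bool)
        if form == NF1:
            return np.zeros(len(rows), dtype=bool)
        return np.isin(rows[:, 1], sorted(self.corrupt_role_idx))

    def epoch_batches(self, rng: np.random.Generator):
        bs = self.cfg.batch_size
        for form in sorted(self.grouped):
            rows = self.grouped[form]
            order = rng.permutation(len(rows))
            for start in range(0, len(rows), bs):
                batch = rows[order[start : start + bs]]
                neg = None
                mask = self._corruptible(form, batch)
                if mask.any():
                    neg = self._corrupt(form, batch[mask], rng, self.cfg.negatives)
                yield form, batch, neg

    def loss_grad(self, batch):
        form, pos, neg = batch
        variant = self.model.method
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        loss_p, contribs = _pos_loss_contribs(
            variant, self.params, form, tuple(pos.T), self.gamma
        )
        n = len(loss_p)
        _accumulate(grads, contribs, 1.0 / n)
        total = float(np.sum(loss_p)) / n
        if neg is not None:
            loss_n, contribs_n = _neg_loss_contribs(
                variant, self.params, form, tuple(neg.T), self.cfg.margin
            )
            m = len(loss_n)
            _accumulate(grads, contribs_n, 1.0 / m)
            total += float(np.sum(loss_n)) / m
        if self.size_reg > 0:
            key = "ent_r" if variant == "elem" else "ent_off"
            size = self.params[key]
            total += self.size_reg * float(np.mean(size**2))
            grads[key] += (2.0 * self.size_reg / size.size) * size
        return total, grads

    def val_loss(self) -> float | None:
        # margin-ranking loss of held-out axioms against fixed corruptions:
        # measures whether unseen associations outrank corrupted ones
        if not self.val_pairs:
            return None
        variant = self.model.method
        total, count = 0.0, 0
        for form, pos, neg in self.val_pairs:
            lp, _ = _pos_loss_contribs(variant, self.params, form, pos, self.gamma)
            ln, _ = _neg_loss_contribs(variant, self.params, form, neg, self.cfg.margin)
            total += float(np.sum(lp) + np.sum(ln))
            count += len(lp)
        return total / count

    def apply_constraints(self) -> None:
        apply_el_constraints(self.model)


def apply_el_constraints(model: EmbeddingModel) -> None:
    """Keep the geometry bounded: centers inside the unit ball, radii in [0,1]
    (balls) / offsets in [0,1] and centers in [-1,1]^d (boxes)."""
    c = model.params["ent_c"]
    if model.method == "elem":
        norms = np.linalg.norm(c, axis=1, keepdims=True)
        np.divide(c, np.maximum(norms, 1.0), out=c)
        np.clip(model.params["ent_r"], 0.0, 1.0, out=model.params["ent_r"])
    else:
        np.clip(c, -1.0, 1.0, out=c)
        np.clip(model.params["ent_off"], 0.0, 1.0, out=model.params["ent_off"])


def init_el_model(
    variant: str,
    entities: list[str],
    relations: list[str],
    dim: int,
    seed: int,
) -> EmbeddingModel:
    if variant not in EL_VARIANTS:
        raise ValueError(f"unknown EL variant {variant!r}")
    rng = np.random.default_rng(seed)
    params = {
        "ent_c": init_uniform(rng, (len(entities), dim), dim),
        "rel_v": init_uniform(rng, (len(relations), dim), dim),
    }
    if variant == "elem":
        params["ent_r"] = rng.uniform(0.05, 0.25, size=len(entities))
    else:
        params["ent_off"] = rng.uniform(0.05, 0.2, size=(len(entities), dim))
    return EmbeddingModel(variant, dim, entities, relations, params)


class ELChannel:
    """Geometric EL channel: fit on an axiom corpus, score the association
    axiom for gene–subject pairs, and support the inductive update."""

    def __init__(
        self,
        variant: str = "elem",
        dim: int = 50,
        cfg: TrainConfig | None = None,
        gamma: float = 0.1,
        corrupt_roles: tuple[str, ...] | None = None,
        size_reg: float | None = None,
    ) -> None:
        # default shrinkage chosen per geometry: box offsets are per-dimension
        # and need a stronger pull than the scalar ball radii
        self.size_reg = size_reg if size_reg is not None else (
            1.0 if variant == "elem" else 20.0
        )
        self.variant = variant
        self.dim = dim
        self.cfg = cfg or TrainConfig()
        self.gamma = gamma
        # negatives corrupt the RHS of axioms over these roles only (the
        # prediction relation by default); None corrupts every axiom
        self.corrupt_roles = corrupt_roles
        self.model: EmbeddingModel | None = None
        self.axiom_keys: set[tuple] = set()
        self.trace: list[dict[str, float]] = []

    def fit(
        self, axioms: list[Axiom], val_axioms: list[Axiom] | None = None
    ) -> "ELChannel":
        if not axioms:
            raise ValueError("cannot train on an empty axiom list")
        entities = sorted({c for ax in axioms for c in ax.concepts})
        relations = sorted({ax.role for ax in axioms if ax.role is not None})
        if IS_ASSOCIATED_WITH not in relations:
            relations = sorted(set(relations) | {IS_ASSOCIATED_WITH})
        self.model = init_el_model(
            self.variant, entities, relations, self.dim, self.cfg.seed
        )
        apply_el_constraints(self.model)
        eidx, ridx = self.model._eidx, self.model._ridx
        grouped = _group_axioms(axioms, eidx, ridx)
        self.axiom_keys = {
            (form, *map(int, row)) for form, rows in grouped.items() for row in rows
        }
        val_grouped = None
        if val_axioms:
            usable = [
                ax
                for ax in val_axioms
                if all(c in eidx for c in ax.concepts)
                and (ax.role is None or ax.role in ridx)
            ]
            if usable:
                val_grouped = _group_axioms(usable, eidx, ridx)
        corrupt_role_idx = None
        if self.corrupt_roles is not None:
            corrupt_role_idx = {ridx[r] for r in self.corrupt_roles if r in ridx}
        objective = _ELObjective(
            self.model, grouped, self.cfg, self.gamma, val_grouped,
            self.axiom_keys, corrupt_role_idx, size_reg=self.size_reg,
        )
        self.trace = fit(objective, self.cfg)
        return self

    # -- scoring ------------------------------------------------------------
    def has_entity(self, entity_id: str) -> bool:
        return self.model is not None and self.model.has_entity(entity_id)

    def score_gene_disease(
        self, gene: str, target: str, relation: str = IS_ASSOCIATED_WITH
    ) -> float | None:
        """sigma(-inclusion_loss(g ⊑ ∃assoc.target)) at margin 0; None when an
        endpoint is unembedded.  0.5 (zero loss) is the model's maximum."""
        assert self.model is not None, "fit() first"
        if not (self.model.has_entity(gene) and self.model.has_entity(target)):
            return None
        loss = inclusion_loss(
            self.model, Axiom(NF3, (gene, target), role=relation), gamma=0.0
        )
        return float(sigmoid(-loss))

    def score_many(
        self, genes: list[str], target: str, relation: str = IS_ASSOCIATED_WITH
    ) -> np.ndarray:
        assert self.model is not None
        arrays = (
            np.array([self.model.entity_index(g) for g in genes]),
            np.full(len(genes), self.model.relation_index(relation)),
            np.full(len(genes), self.model.entity_index(target)),
        )
        loss, _ = _pos_loss_contribs(self.variant, self.model.params, NF3, arrays, 0.0)
        return sigmoid(-loss)

    # -- inductive ----------------------------------------------------------
    def add_entity(self, entity_id: str, rng: np.random.Generator) -> None:
        assert self.model is not None
        blocks = {"ent_c": init_uniform(rng, (self.dim,), self.dim)}
        if self.variant == "elem":
            blocks["ent_r"] = np.asarray(rng.uniform(0.05, 0.25))
        else:
            blocks["ent_off"] = rng.uniform(0.05, 0.2, size=self.dim)
        self.model.add_entity(entity_id, blocks)

    def finetune_entity(
        self,
        entity_id: str,
        edges: list[tuple[str, str, str]],
        iters: int,
        freeze_existing: bool,
        rng: np.random.Generator,
    ) -> None:
        """Run ``iters`` update steps whose positives are the entity's own
        ``(entity, role, class)`` edges read as NF3 axioms."""
        assert self.model is not None
        model = self.model
        rows = []
        for h, r, t in edges:
            if h in model._eidx and t in model._eidx and r in model._ridx:
                rows.append([model._eidx[h], model._ridx[r], model._eidx[t]])
            else:
                warnings.warn(f"skipping edge with unknown IDs: {(h, r, t)}")
        if not rows:
            warnings.warn(f"no usable edges for inductive update of {entity_id!r}")
            return
        pos = np.array(rows, dtype=np.int64)
        keys = self.axiom_keys | {(NF3, *map(int, row)) for row in rows}
        new_idx = model._eidx[entity_id]
        objective = _ELObjective(model, {NF3: pos}, self.cfg, self.gamma, None, keys)
        opt = Adam(model.params, self.cfg.lr)
        for _ in range(iters):
            neg = objective._corrupt(NF3, pos, rng, self.cfg.negatives)
            _, grads = objective.loss_grad((NF3, pos, neg))
            if freeze_existing:
                for key in list(grads):
                    if key.startswith("ent_"):
                        row = grads[key][new_idx].copy()
                        grads[key][:] = 0.0
                        grads[key][new_idx] = row
                    else:
                        grads[key][:] = 0.0
            opt.step(grads)
            # constraints are idempotent on already-feasible rows, so applying
            # them globally keeps frozen parameters bit-identical
            apply_el_constraints(model)


def train_el(
    axioms: list[Axiom],
    cfg: TrainConfig,
    variant: str = "elem",
    dim: int = 50,
    val_axioms: list[Axiom] | None = None,
    gamma: float = 0.1,
) -> ELChannel:
    """Train a geometric EL model on an axiom corpus; returns the channel."""
    channel = ELChannel(variant=variant, dim=dim, cfg=cfg, gamma=gamma)
    return channel.fit(axioms, val_axioms=val_axioms)
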