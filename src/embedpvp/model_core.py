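"""Shared embedding-model machinery: parameter container, Adam, the training
loop with validation-based early stopping, association splitting, and the
inductive update for entities added after training.

All trainers in this package (translational/bilinear KGE, geometric EL, and
the walk/skip-gram channel's fine-tune path) drive their parameters through
:func:`fit`, which owns the convergence criterion: training stops once the
validation loss has not improved for ``patience`` epochs and the parameters
from the best-validation epoch (possibly the initialization) are restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np
import pandas as pd


@dataclass
class TrainConfig:
    """Hyperparameters shared by every embedding trainer.

    ``margin`` is the gamma of the margin-ranking loss separating positive
    from corrupted (negative) triples/axioms; ``negatives`` is the number of
    corruptions drawn per positive; ``patience`` the number of epochs without
    validation-loss improvement tolerated before stopping.
    """

    lr: float = 0.01
    epochs: int = 200
    batch_size: int = 128
    margin: float = 1.0
    negatives: int = 1
    seed: int = 0
    patience: int = 10

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("lr and batch_size must be positive")
        if self.epochs < 0 or self.patience < 0 or self.negatives < 1:
            raise ValueError("epochs/patience must be >= 0, negatives >= 1")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class SplitSpec:
    """Association split fractions; defaults 80% train / 15% validation / 5% test."""

    fractions: tuple[float, float, float] = (0.80, 0.15, 0.05)
    seed: int = 0


def split_associations(
    associations: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation/test partition of association rows.

    Sizes are ``round(f_train*n)`` and ``round(f_val*n)`` with the remainder
    going to test; the shuffle is deterministic under ``spec.seed``.
    """
    spec = spec or SplitSpec()
    if abs(sum(spec.fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(associations)
    if n < 3:
        raise ValueError("need at least 3 associations to split")
    n_train = round(spec.fractions[0] * n)
    n_val = round(spec.fractions[1] * n)
    if n_train + n_val > n:
        n_val = n - n_train
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = associations.iloc[order].reset_index(drop=True)
    train = shuffled.iloc[:n_train].reset_index(drop=True)
    val = shuffled.iloc[n_train : n_train + n_val].reset_index(drop=True)
    test = shuffled.iloc[n_train + n_val :].reset_index(drop=True)
    return train, val, test


# ---------------------------------------------------------------------------
# Parameter container
# ---------------------------------------------------------------------------


class EmbeddingModel:
    """Per-entity / per-relation numeric parameters with a method tag.

    Parameters are stored as dense arrays keyed by name; keys starting with
    ``ent_`` have one row per entity (in ``entities`` order) and keys starting
    with ``rel_`` one row per relation.  ``entity_params``/``relation_params``
    expose the per-ID blocks the scoring functions consume.
    """

    def __init__(
        self,
        method: str,
        dim: int,
        entities: list[str],
        relations: list[str],
        params: dict[str, np.ndarray],
    ) -> None:
        if dim <= 0:
            raise ValueError("dimension must be positive")
        self.method = method
        self.dim = dim
        self.entities = list(entities)
        self.relations = list(relations)
        self.params = params
        self._eidx = {e: i for i, e in enumerate(self.entities)}
        self._ridx = {r: i for i, r in enumerate(self.relations)}

    # -- lookups ------------------------------------------------------------
    def has_entity(self, entity_id: str) -> bool:
        return entity_id in self._eidx

    def entity_index(self, entity_id: str) -> int:
        return self._eidx[entity_id]

    def relation_index(self, relation_id: str) -> int:
        return self._ridx[relation_id]

    def entity_params(self, entity_id: str) -> dict[str, np.ndarray]:
        i = self._eidx[entity_id]
        return {k: v[i] for k, v in self.params.items() if k.startswith("ent_")}

    def relation_params(self, relation_id: str) -> dict[str, np.ndarray]:
        i = self._ridx[relation_id]
        return {k: v[i] for k, v in self.params.items() if k.startswith("rel_")}

    # -- growth (inductive updates) -----------------------------------------
    def add_entity(self, entity_id: str, blocks: dict[str, np.ndarray]) -> int:
        if entity_id in self._eidx:
            raise ValueError(f"entity {entity_id!r} already present")
        for key in list(self.params):
            if key.startswith("ent_"):
                self.params[key] = np.concatenate(
                    [self.params[key], np.asarray(blocks[key])[None]], axis=0
                )
        self.entities.append(entity_id)
        self._eidx[entity_id] = len(self.entities) - 1
        return self._eidx[entity_id]

    def copy(self) -> "EmbeddingModel":
        return EmbeddingModel(
            self.method,
            self.dim,
            list(self.entities),
            list(self.relations),
            {k: v.copy() for k, v in self.params.items()},
        )

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "dim": self.dim,
            "entities": self.entities,
            "relations": self.relations,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        payload = json.loads(Path(path).read_text())
        params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(
            payload["method"], payload["dim"], payload["entities"],
            payload["relations"], params,
        )


def init_uniform(rng: np.random.Generator, shape: tuple[int, ...], dim: int) -> np.ndarray:
    """KGE-convention initialization: uniform in [-1/sqrt(dim), 1/sqrt(dim)]."""
    bound = 1.0 / np.sqrt(dim)
    return rng.uniform(-bound, bound, size=shape)


# ---------------------------------------------------------------------------
# Optimizer and training loop
# ---------------------------------------------------------------------------


class Adam:
    """Plain Adam on a dict of dense parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            p = self.params[key]
            m = self.m[key]
            v = self.v[key]
            # parameter arrays may have been grown by add_entity
            if m.shape != p.shape:
                pad = [(0, ps - ms) for ps, ms in zip(p.shape, m.shape)]
                m = self.m[key] = np.pad(m, pad)
                v = self.v[key] = np.pad(v, pad)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Objective(Protocol):
    """Contract a trainer exposes to :func:`fit`."""

    params: dict[str, np.ndarray]

    def epoch_batches(self, rng: np.random.Generator) -> Iterable[object]: ...

    def loss_grad(self, batch: object) -> tuple[float, dict[str, np.ndarray]]: ...

    def val_loss(self) -> float | None: ...

    def apply_constraints(self) -> None: ...


def _snapshot(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in params.items()}


def fit(
    objective: Objective, cfg: TrainConfig
) -> list[dict[str, float]]:
    """Run mini-batch Adam with validation-based early stopping.

    After return ``objective.params`` holds the parameters of the epoch with
    the minimal validation loss (the initialization counts as epoch 0), never
    the final epoch when the two differ.  Returns the per-epoch loss trace as
    ``[{"epoch", "train_loss", "val_loss"}, ...]``.  Raises on NaN loss.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(objective.params, cfg.lr)
    best_val = objective.val_loss()
    best_params = _snapshot(objective.params)
    trace: list[dict[str, float]] = []
    bad_epochs = 0
    for epoch in range(1, cfg.epochs + 1):
        losses = []
        for batch in objective.epoch_batches(rng):
            loss, grads = objective.loss_grad(batch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            opt.step(grads)
            objective.apply_constraints()
            losses.append(loss)
        train_loss = float(np.mean(losses)) if losses else 0.0
        val = objective.val_loss()
        trace.append(
            {"epoch": epoch, "train_loss": train_loss,
             "val_loss": float("nan") if val is None else float(val)}
        )
        if val is None:
            continue  # no validation set: run to max epochs, keep last params
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        if best_val is None or val < best_val:
            best_val = val
            best_params = _snapshot(objective.params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    if best_val is not None:
        for k in objective.params:
            objective.params[k][...] = best_params[k]
    return trace


# ---------------------------------------------------------------------------
# Inductive update
# ---------------------------------------------------------------------------


class InductiveChannel(Protocol):
    def has_entity(self, entity_id: str) -> bool: ...

    def add_entity(self, entity_id: str, rng: np.random.Generator) -> None: ...

    def finetune_entity(
        self,
        entity_id: str,
        edges: list[tuple[str, str, str]],
        iters: int,
        freeze_existing: bool,
        rng: np.random.Generator,
    ) -> None: ...


def inductive_update(
    channel: InductiveChannel,
    new_entity: str,
    edges: list[tuple[str, str, str]],
    iters: int = 30,
    freeze_existing: bool = False,
    seed: int = 0,
) -> InductiveChannel:
    """Add an unseen entity (new disease or patient) to a trained model.

    The new entity receives a randomly initialized parameter block; ``iters``
    mini-batch steps are then run using only the entity's own edges as
    positives.  With ``iters=0`` every pre-existing parameter is untouched;
    with ``freeze_existing=True`` only the new entity's block may change.
    """
    if channel.has_entity(new_entity):
        raise ValueError(f"entity {new_entity!r} already embedded")
    rng = np.random.default_rng(seed)
    channel.add_entity(new_entity, rng)
    if iters > 0:
        channel.finetune_entity(new_entity, list(edges), iters, freeze_existing, rng)
    return channel
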