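"""Edge-label-aware random walks and skip-gram embeddings.

The walk generator is a DeepWalk variant that emits the edge label between
consecutive vertices, so a walk visiting ``n`` vertices contains exactly
``2n - 1`` tokens (``v0, l0, v1, l1, ..., v_{n-1}``).  Walks terminate early
at sink vertices (the projected graph is directed).  The walk corpus is fed
to a skip-gram model with negative sampling (the standard practical surrogate
for the full-softmax skip-gram objective), trained single-threaded with a
seeded generator so results are bitwise reproducible.

Gene–subject relatedness is scored as ``sigma(g . d)`` on the learned input
vectors — a symmetric similarity in (0, 1), monotone in the dot product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .knowledge_base import KnowledgeGraph
from .model_core import EmbeddingModel


@dataclass
class WalkConfig:
    """Walk and skip-gram hyperparameters.

    ``walks_per_node`` (k) walks start at every vertex; each visits at most
    ``nodes_per_walk`` (n) vertices; ``window`` (c) is the skip-gram context
    radius measured in tokens of the mixed vertex/label sequence.
    """

    walks_per_node: int = 10
    nodes_per_walk: int = 20
    window: int = 5
    dim: int = 100
    epochs: int = 10
    negatives: int = 5
    lr: float = 0.025
    min_lr: float = 1e-4
    batch_size: int = 256
    subsample: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.walks_per_node, self.nodes_per_walk, self.window) < 1:
            raise ValueError("walks_per_node, nodes_per_walk and window must be >= 1")


def generate_walks(
    graph: KnowledgeGraph,
    cfg: WalkConfig,
    start_vertices: list[str] | None = None,
) -> list[list[str]]:
    """k random walks from every vertex; the next vertex is uniform among
    outgoing edges and the traversed edge label is emitted between vertices."""
    if not graph.vertices:
        warnings.warn("empty graph: returning an empty walk corpus")
        return []
    rng = np.random.default_rng(cfg.seed)
    adjacency = graph.adjacency()
    starts = sorted(graph.vertices) if start_vertices is None else list(start_vertices)
    corpus: list[list[str]] = []
    for vertex in starts:
        for _ in range(cfg.walks_per_node):
            walk = [vertex]
            current = vertex
            for _step in range(cfg.nodes_per_walk - 1):
                nbrs = adjacency.get(current, [])
                if not nbrs:
                    break
                label, nxt = nbrs[int(rng.integers(len(nbrs)))]
                walk.extend([label, nxt])
                current = nxt
            corpus.append(walk)
    return corpus


def _subsample_probs(counts: np.ndarray, threshold: float) -> np.ndarray:
    """word2vec-style keep probability for frequent tokens (edge labels occur
    in nearly every walk and would otherwise dominate the updates)."""
    if threshold <= 0:
        return np.ones(len(counts))
    freq = counts / max(counts.sum(), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = np.sqrt(threshold / freq) + threshold / freq
    return np.clip(np.nan_to_num(keep, nan=1.0, posinf=1.0), 0.0, 1.0)


def _context_pairs(
    corpus: list[list[str]],
    vocab: dict[str, int],
    window: int,
    keep: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for sentence in corpus:
        idx = [vocab[tok] for tok in sentence]
        if keep is not None and rng is not None:
            idx = [i for i in idx if rng.random() < keep[i]]
        for i, center in enumerate(idx):
            lo = max(0, i - window)
            hi = min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(center)
                    contexts.append(idx[j])
    return (
        np.asarray(centers, dtype=np.int64),
        np.asarray(contexts, dtype=np.int64),
    )


def _negative_table(counts: np.ndarray, size: int = 1 << 17) -> np.ndarray:
    freq = counts.astype(float) ** 0.75
    cum = np.cumsum(freq / freq.sum())
    return np.searchsorted(cum, (np.arange(size) + 0.5) / size).astype(np.int64)


def _sgns_epochs(
    w_in: np.ndarray,
    w_out: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    table: np.ndarray,
    cfg: WalkConfig,
    rng: np.random.Generator,
    epochs: int,
    update_rows: np.ndarray | None = None,
) -> None:
    """Mini-batched SGNS updates in place.  ``update_rows`` restricts which
    vector rows may change (used by the freeze-existing inductive path)."""
    n_pairs = len(centers)
    if n_pairs == 0:
        return
    total_steps = max(1, epochs * ((n_pairs + cfg.batch_size - 1) // cfg.batch_size))
    step = 0
    mask_in = mask_out = None
    if update_rows is not None:
        mask_in = np.zeros(len(w_in), dtype=bool)
        mask_in[update_rows] = True
        mask_out = mask_in
    for _epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, cfg.batch_size):
            lr = cfg.lr + (cfg.min_lr - cfg.lr) * (step / total_steps)
            step += 1
            b = order[start : start + cfg.batch_size]
            c_idx, o_idx = centers[b], contexts[b]
            neg_idx = table[rng.integers(len(table), size=(len(b), cfg.negatives))]
            c = w_in[c_idx]
            o = w_out[o_idx]
            neg = w_out[neg_idx]
            g_pos = 1.0 / (1.0 + np.exp(-np.sum(c * o, axis=1))) - 1.0  # (B,)
            g_neg = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", c, neg)))  # (B,K)
            grad_c = g_pos[:, None] * o + np.einsum("bk,bkd->bd", g_neg, neg)
            grad_o = g_pos[:, None] * c
            grad_neg = g_neg[..., None] * c[:, None, :]
            if mask_in is not None:
                grad_c *= mask_in[c_idx][:, None]
                grad_o *= mask_out[o_idx][:, None]
                grad_neg *= mask_out[neg_idx][..., None]
            np.add.at(w_in, c_idx, -lr * grad_c)
            np.add.at(w_out, o_idx, -lr * grad_o)
            np.add.at(
                w_out, neg_idx.ravel(), -lr * grad_neg.reshape(-1, w_out.shape[1])
            )
            # batched scatter-adds can overshoot for very frequent tokens;
            # a generous norm cap keeps the optimization stable
            for w in (w_in, w_out):
                norms = np.linalg.norm(w, axis=1, keepdims=True)
                np.divide(w, np.maximum(norms / 10.0, 1.0), out=w)


def train_skipgram(
    corpus: list[list[str]], cfg: WalkConfig
) -> EmbeddingModel:
    """Train skip-gram with negative sampling on a walk corpus.

    Every token occurring in the corpus receives an input vector ``ent_in``
    and an output (context) vector ``ent_out``; similarity scoring uses the
    input vectors.  A corpus with no context pairs (e.g. one 1-token walk)
    yields initialized vectors untouched by training.
    """
    tokens = sorted({tok for sentence in corpus for tok in sentence})
    if not tokens:
        raise ValueError("empty corpus")
    vocab = {tok: i for i, tok in enumerate(tokens)}
    counts = np.zeros(len(tokens), dtype=np.int64)
    for sentence in corpus:
        for tok in sentence:
            counts[vocab[tok]] += 1
    rng = np.random.default_rng(cfg.seed)
    w_in = (rng.random((len(tokens), cfg.dim)) - 0.5) / cfg.dim
    w_out = np.zeros((len(tokens), cfg.dim))
    keep = _subsample_probs(counts, cfg.subsample)
    centers, contexts = _context_pairs(corpus, vocab, cfg.window, keep, rng)
    table = _negative_table(counts)
    _sgns_epochs(w_in, w_out, centers, contexts, table, cfg, rng, cfg.epochs)
    return EmbeddingModel(
        "skipgram", cfg.dim, tokens, [], {"ent_in": w_in, "ent_out": w_out}
    )


def score_similarity(g_vec: np.ndarray, d_vec: np.ndarray) -> float:
    """sigma(g . d): symmetric plausibility in (0, 1)."""
    g = np.asarray(g_vec, dtype=float)
    d = np.asarray(d_vec, dtype=float)
    if g.shape != d.shape:
        raise ValueError(f"dimension mismatch: {g.shape} vs {d.shape}")
    return float(1.0 / (1.0 + np.exp(-float(g @ d))))


class WalksChannel:
    """Random-walk + skip-gram channel over the projected graph."""

    def __init__(self, cfg: WalkConfig | None = None) -> None:
        self.cfg = cfg or WalkConfig()
        self.model: EmbeddingModel | None = None
        self.graph: KnowledgeGraph | None = None

    def fit(self, graph: KnowledgeGraph, val_triples=None) -> "WalksChannel":
        # val_triples accepted for interface parity; skip-gram runs a fixed
        # number of epochs (word2vec convention) rather than early stopping
        self.graph = graph.copy()
        corpus = generate_walks(graph, self.cfg)
        self.model = train_skipgram(corpus, self.cfg)
        return self

    def has_entity(self, entity_id: str) -> bool:
        return self.model is not None and self.model.has_entity(entity_id)

    def _vector(self, entity_id: str) -> np.ndarray:
        assert self.model is not None
        return self.model.params["ent_in"][self.model.entity_index(entity_id)]

    def score_gene_disease(self, gene: str, target: str) -> float | None:
        if not (self.has_entity(gene) and self.has_entity(target)):
            return None
        return score_similarity(self._vector(gene), self._vector(target))

    def score_many(self, genes: list[str], target: str) -> np.ndarray:
        assert self.model is not None
        W = self.model.params["ent_in"]
        g = W[[self.model.entity_index(x) for x in genes]]
        d = W[self.model.entity_index(target)]
        return 1.0 / (1.0 + np.exp(-(g @ d)))

    # -- inductive ----------------------------------------------------------
    def add_entity(self, entity_id: str, rng: np.random.Generator) -> None:
        assert self.model is not None
        self.model.add_entity(
            entity_id,
            {
                "ent_in": (rng.random(self.cfg.dim) - 0.5) / self.cfg.dim,
                "ent_out": np.zeros(self.cfg.dim),
            },
        )

    def finetune_entity(
        self,
        entity_id: str,
        edges: list[tuple[str, str, str]],
        iters: int,
        freeze_existing: bool,
        rng: np.random.Generator,
    ) -> None:
        """Continue skip-gram training on walks started at the new entity.

        ``iters`` plays the role of extra epochs over the new-entity pairs.
        Tokens absent from the trained vocabulary are skipped with a warning.
        """
        assert self.model is not None and self.graph is not None
        model = self.model
        graph = self.graph
        for h, r, t in edges:
            graph.add_edge(h, r, t)
        import dataclasses

        walk_cfg = dataclasses.replace(self.cfg, seed=int(rng.integers(2**31)))
        corpus = generate_walks(graph, walk_cfg, start_vertices=[entity_id])
        vocab_corpus = []
        known = set(model.entities)
        for sentence in corpus:
            kept = [tok for tok in sentence if tok in known]
            if len(kept) < len(sentence):
                warnings.warn("dropping walk tokens absent from the vocabulary")
            if len(kept) > 1:
                vocab_corpus.append(kept)
        if not vocab_corpus:
            warnings.warn(f"no usable walks for inductive update of {entity_id!r}")
            return
        vocab = {tok: i for i, tok in enumerate(model.entities)}
        centers, contexts = _context_pairs(vocab_corpus, vocab, self.cfg.window)
        counts = np.bincount(
            np.concatenate([centers, contexts]), minlength=len(model.entities)
        )
        counts = np.maximum(counts, 1)
        table = _negative_table(counts)
        rows = (
            np.array([model.entity_index(entity_id)]) if freeze_existing else None
        )
        _sgns_epochs(
            model.params["ent_in"],
            model.params["ent_out"],
            centers,
            contexts,
            table,
            walk_cfg,
            rng,
            epochs=iters,
            update_rows=rows,
        )
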