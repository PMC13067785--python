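"""Fusion model: joint semantic+graph embeddings trained to rank.

Each entity gets a semantic vector (bag-of-tokens over its description)
and a structural vector (relational graph convolution); the fusion head
concatenates the two and projects them linearly to a common space.  A
microbe–material pair is scored by

    score(m1, m2) = 1 / (1 + ||m1 - m2||)

so smaller embedding distance means higher synthesis plausibility.  The
model is trained listwise: each training query is a microbe, its candidate
list is a set of materials containing its known products, and the loss is
a differentiable surrogate of mean reciprocal rank over the negated
distances (softmax cross-entropy restricted to the positives by default; a
sigmoid rank approximation and the degenerate all-candidates variant are
available behind ``mode``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor, concat, logsumexp
from .graph_encoder import (
    DEFAULT_RELATIONS,
    GraphEmbeddingTable,
    RGCNEncoder,
    build_adjacency,
)
from .kg_core import KnowledgeGraph
from .semantic_encoder import BagOfTokensEncoder, TextEmbeddingTable

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "biosynkg-checkpoint-v1"

#: Distance used to pad ragged candidate lists; exp(-PAD) underflows to 0.
_PAD = 1.0e6


@dataclass
class FusedEmbeddingTable:
    """Joint per-entity vectors; the m1/m2 inputs of the scoring formula."""

    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for eid, v in self.vectors.items():
            if v.shape != (self.dim,) or not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {eid!r} not a finite {self.dim}-vector")


@dataclass
class Query:
    """One ranking query: candidates, its positives, per-candidate distances."""

    query_id: str
    candidates: list[str]
    positives: frozenset[str]
    distances: np.ndarray   # lower = better, aligned with candidates

    def validate(self, training: bool = True) -> None:
        if len(self.candidates) < 2:
            raise ValueError(f"query {self.query_id!r}: needs >= 2 candidates")
        if training:
            n_pos = len(self.positives & set(self.candidates))
            if n_pos < 1:
                raise ValueError(f"query {self.query_id!r}: empty positive set")
            if n_pos >= len(self.candidates):
                raise ValueError(f"query {self.query_id!r}: no negatives")
        if len(self.distances) != len(self.candidates):
            raise ValueError(f"query {self.query_id!r}: distance/candidate length mismatch")


@dataclass
class QueryBatch:
    queries: list[Query]

    def validate(self, training: bool = True) -> None:
        if not self.queries:
            raise ValueError("empty query batch")
        for q in self.queries:
            q.validate(training)


@dataclass
class RankingResult:
    """Scored candidates for one query, sorted best-first.

    Ties in score are broken by candidate id for a deterministic order, but
    the *rank* assigned to a relevant candidate is pessimistic: the worst
    rank within its tie group, so reported metrics are lower bounds.
    """

    query_id: str
    candidates: list[str]          # sorted by (-score, id)
    scores: list[float]            # aligned, nonincreasing
    positives: frozenset[str]

    @property
    def relevant_ranks(self) -> list[int]:
        out = []
        arr = np.array(self.scores)
        for i, c in enumerate(self.candidates):
            if c in self.positives:
                s = arr[i]
                out.append(int(np.sum(arr > s) + np.sum(arr == s)))
        return sorted(out)

    @property
    def first_relevant_rank(self) -> int | None:
        ranks = self.relevant_ranks
        return ranks[0] if ranks else None

    def rank_of(self, candidate: str) -> int:
        i = self.candidates.index(candidate)
        s = self.scores[i]
        arr = np.array(self.scores)
        return int(np.sum(arr > s) + np.sum(arr == s))


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the fusion model and its training loop."""

    d: int = 64
    d_s: int = 64
    d_g: int = 64
    n_layers: int = 2
    learning_rate: float = 0.01
    weight_decay: float = 0.1
    epochs: int = 60
    snapshot_start: int = 15
    tail_lr_factor: float = 0.3
    batch_size: int = 0            # 0 = full batch
    negatives_per_positive: int = 10
    candidate_sampling: str = "type-matched"
    loss_mode: str = "softmax-positive"
    min_token_count: int = 2
    bidirectional_queries: bool = True
    graph_input: str = "semantic"
    normalize_embeddings: bool = True
    temperature: float = 0.05
    relations_to_use: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.d, self.d_s, self.d_g, self.n_layers, self.epochs) < 1:
            raise ValueError("dimensions, layers and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be positive")
        if self.candidate_sampling not in ("type-matched", "uniform-material"):
            raise ValueError(f"unknown candidate sampling {self.candidate_sampling!r}")
        if self.graph_input not in ("semantic", "learned"):
            raise ValueError(f"unknown graph_input {self.graph_input!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.snapshot_start < 0:
            raise ValueError("snapshot_start must be >= 0")
        if not 0.0 < self.tail_lr_factor <= 1.0:
            raise ValueError("tail_lr_factor must be in (0, 1]")

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# scoring and loss
# ---------------------------------------------------------------------------


def score_pair(m1: np.ndarray, m2: np.ndarray) -> float:
    """Similarity 1/(1+||m1-m2||): symmetric, in (0,1], 1 iff m1 == m2."""
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    if m1.shape != m2.shape:
        raise ValueError(f"dimension mismatch: {m1.shape} vs {m2.shape}")
    return float(1.0 / (1.0 + np.linalg.norm(m1 - m2)))


def _listwise_loss(D: Tensor, pos_mask: np.ndarray, valid_mask: np.ndarray,
                   mode: str, tau: float = 1.0) -> Tensor:
    """Listwise ranking loss over a padded distance matrix (n_queries × c).

    ``softmax-positive``: -mean log(Σ_pos exp(-d) / Σ_all exp(-d)).
    ``sigmoid-rank``: 1 - mean 1/r̂ of the currently best positive, with
    r̂ = 1 + Σ_k σ((d_pos - d_k)/τ) (the classic smooth-rank surrogate).
    ``literal``: the degenerate published form, numerator over all
    candidates — identically zero (kept for documentation/regression).
    """
    if mode == "literal":
        lse_all = logsumexp(-D, axis=1, mask=valid_mask)
        return (lse_all - lse_all).mean()
    if mode == "softmax-positive":
        lse_all = logsumexp(-D, axis=1, mask=valid_mask)
        lse_pos = logsumexp(-D, axis=1, mask=pos_mask)
        return (lse_all - lse_pos).mean()
    if mode == "sigmoid-rank":
        nq, c = D.shape
        d_np = np.where(pos_mask > 0, D.data, np.inf)
        best = np.argmin(d_np, axis=1)            # detached choice of positive
        onehot = np.zeros((nq, c))
        onehot[np.arange(nq), best] = 1.0
        d_sel = (D * Tensor(onehot)).sum(axis=1).reshape(nq, 1)
        others = valid_mask * (1.0 - onehot)
        rhat = 1.0 + (((d_sel - D) * (1.0 / tau)).sigmoid() * Tensor(others)).sum(axis=1)
        return 1.0 - (1.0 / rhat).mean()
    raise ValueError(f"unknown loss mode {mode!r}")


def _batch_matrices(batch: QueryBatch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cmax = max(len(q.candidates) for q in batch.queries)
    nq = len(batch.queries)
    D = np.full((nq, cmax), _PAD)
    pos = np.zeros((nq, cmax))
    valid = np.zeros((nq, cmax))
    for i, q in enumerate(batch.queries):
        k = len(q.candidates)
        D[i, :k] = q.distances
        valid[i, :k] = 1.0
        pos[i, :k] = [1.0 if c in q.positives else 0.0 for c in q.candidates]
    return D, pos, valid


def approx_mrr_loss(batch: QueryBatch, mode: str = "softmax-positive") -> float:
    """Listwise MRR surrogate on a batch of scored queries.

    Query scores are *distances* (lower = better), matching the exp(-s)
    weighting of the training objective.  See :func:`_listwise_loss` for
    the modes; the default positive-restricted softmax is the trainable
    reading of the published objective, whose literal form is identically
    zero.
    """
    batch.validate(training=True)
    D, pos, valid = _batch_matrices(batch)
    return float(_listwise_loss(Tensor(D), pos, valid, mode).data)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def fuse(
    sem: TextEmbeddingTable,
    gra: GraphEmbeddingTable,
    dim: int | None = None,
    projection: str = "learned",
    seed: int = 0,
) -> FusedEmbeddingTable:
    """Concatenate semantic and graph vectors, then project linearly.

    ``projection='identity'`` requires dim == d_s + d_g and returns the
    exact concatenation; ``'learned'`` applies a seeded linear map (the
    trainer owns the trained version of this map).
    """
    sem_ids, gra_ids = set(sem.vectors), set(gra.vectors)
    if sem_ids != gra_ids:
        missing = sorted(sem_ids ^ gra_ids)
        raise ValueError(f"semantic/graph tables disagree on ids: {missing[:10]}")
    order = sorted(sem_ids)
    X = np.concatenate([sem.matrix(order), gra.matrix(order)], axis=1)
    d_in = sem.dim + gra.dim
    dim = d_in if dim is None else dim
    if projection == "identity":
        if dim != d_in:
            raise ValueError("identity projection requires dim == d_s + d_g")
        out = X
    elif projection == "learned":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        W = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, dim))
        out = X @ W
    else:
        raise ValueError(f"unknown projection {projection!r}")
    return FusedEmbeddingTable(dim, {e: out[i].copy() for i, e in enumerate(order)})


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class FusionModel:
    """Semantic encoder + graph encoder + fusion head, trained jointly."""

    def __init__(self, g: KnowledgeGraph, cfg: TrainConfig):
        cfg.validate()
        self.cfg = cfg
        self.graph = g
        self.order = sorted(g.entities)
        self.index = {e: i for i, e in enumerate(self.order)}
        texts = {e.id: e.description for e in g.entities.values()}
        self.semantic = BagOfTokensEncoder(
            texts, cfg.d_s, cfg.seed, min_count=cfg.min_token_count
        )
        relations = cfg.relations_to_use
        if relations is None:
            relations = tuple(
                r for r in DEFAULT_RELATIONS if any(t.relation == r for t in g.triples)
            )
        adj = build_adjacency(g, relations, entity_ids=self.order)
        self.encoder = RGCNEncoder(
            adj, dim=cfg.d_g, n_layers=cfg.n_layers, seed=cfg.seed,
            learned_input=(cfg.graph_input == "learned"),
        )
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 32]))
        d_in = cfg.d_s + cfg.d_g
        self.W_in: Tensor | None = None
        if cfg.graph_input == "semantic":
            # graph module runs on (projected) text features: all capacity is
            # shared, so single edges cannot be memorized entity-by-entity
            self.W_in = Tensor(
                rng.normal(0.0, 1.0 / np.sqrt(cfg.d_s), size=(cfg.d_s, cfg.d_g)),
                requires_grad=True,
            )
        self.W_f = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, cfg.d)),
                          requires_grad=True)
        self.b_f = Tensor(np.zeros(cfg.d), requires_grad=True)
        self.loss_history: list[float] = []
        self.epoch = 0
        # running sum of post-warmup fused snapshots (tail averaging):
        # single late checkpoints oscillate between sharp minima; the
        # epoch-averaged geometry ranks held-out pairs far more stably
        self._snapshot_sum: np.ndarray | None = None
        self._snapshot_n = 0

    @property
    def parameters(self) -> list[Tensor]:
        extra = [] if self.W_in is None else [self.W_in]
        return self.semantic.parameters + self.encoder.parameters + extra + [self.W_f, self.b_f]

    def forward(self) -> Tensor:
        S = self.semantic.forward()
        # semantic rows are in self.semantic.order == sorted ids == self.order
        G = self.encoder.forward(None if self.W_in is None else S @ self.W_in)
        F = concat([S, G], axis=1) @ self.W_f + self.b_f
        if self.cfg.normalize_embeddings:
            norms = (F.square().sum(axis=1, keepdims=True) + 1e-12).sqrt()
            F = F / norms
        return F

    # -- training data ---------------------------------------------------
    def _training_queries(self, rng: np.random.Generator) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """(query index, candidate indices, positive mask) per query.

        Queries are microbes over material candidates and — because the
        scoring formula is symmetric and predictions run both ways —
        materials over microbe candidates as well (``bidirectional_queries``).
        """
        synth = self.graph.triples_with("synthesizes")
        if not synth:
            raise ValueError("training graph has no synthesizes triples")
        by_head: dict[str, set[str]] = {}
        by_tail: dict[str, set[str]] = {}
        for t in synth:
            by_head.setdefault(t.head, set()).add(t.tail)
            by_tail.setdefault(t.tail, set()).add(t.head)
        materials = sorted(e.id for e in self.graph.materials())
        microbes = sorted(e.id for e in self.graph.microbes())
        directions = [(by_head, materials)]
        if self.cfg.bidirectional_queries:
            directions.append((by_tail, microbes))
        out = []
        for positives, pool in directions:
            for q in sorted(positives):
                pos = sorted(positives[q] & set(pool))
                if not pos:
                    continue
                budget = len(pos) * self.cfg.negatives_per_positive
                negs = [x for x in pool if x not in positives[q]]
                if not negs:
                    continue
                if len(negs) > budget:
                    negs = sorted(rng.choice(negs, size=budget, replace=False))
                cands = pos + negs
                cand_idx = np.array([self.index[c] for c in cands])
                mask = np.array([1.0] * len(pos) + [0.0] * len(negs))
                out.append((self.index[q], cand_idx, mask))
        if not out:
            raise ValueError("no trainable queries (no microbe has material positives)")
        return out

    def _epoch_loss(self, queries) -> Tensor:
        F = self.forward()
        cmax = max(len(c) for _, c, _ in queries)
        nq = len(queries)
        cand_idx = np.zeros((nq, cmax), dtype=int)
        pos = np.zeros((nq, cmax))
        valid = np.zeros((nq, cmax))
        q_idx = np.zeros(nq, dtype=int)
        for i, (qi, ci, mask) in enumerate(queries):
            k = len(ci)
            q_idx[i] = qi
            cand_idx[i, :k] = ci
            pos[i, :k] = mask
            valid[i, :k] = 1.0
        Fq = F.gather_rows(q_idx).reshape(nq, 1, self.cfg.d)
        Fc = F.gather_rows(cand_idx)
        D = ((Fq - Fc).square().sum(axis=2) + 1e-12).sqrt()
        # temperature sharpens exp(-d) contrasts on the (bounded) normalized
        # embedding geometry; padded slots get a huge constant distance
        D = D * Tensor(valid / self.cfg.temperature) + Tensor((1.0 - valid) * _PAD)
        return _listwise_loss(D, pos, valid, self.cfg.loss_mode)

    def fit(self, epochs: int | None = None) -> "FusionModel":
        """Gradient-descend the listwise objective.

        Two phases: full learning rate until ``snapshot_start``, then a
        reduced tail (``tail_lr_factor``) during which per-epoch fused
        snapshots are accumulated for tail averaging.
        """
        epochs = self.cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(np.random.SeedSequence([self.cfg.seed, 33]))
        opt = Adam(self.parameters, lr=self.cfg.learning_rate,
                   weight_decay=self.cfg.weight_decay)
        in_tail = self.epoch > self.cfg.snapshot_start
        if in_tail:
            opt.lr = self.cfg.learning_rate * self.cfg.tail_lr_factor
        queries = self._training_queries(rng)
        for _ in range(epochs):
            opt.zero_grad()
            loss = self._epoch_loss(queries)
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite loss at epoch {self.epoch}")
            loss.backward()
            opt.step()
            self.loss_history.append(val)
            self.epoch += 1
            if self.epoch > self.cfg.snapshot_start:
                if not in_tail:
                    # entering the averaging phase: damp the step size
                    # (fresh moments avoid carrying large warmup momenta)
                    opt = Adam(self.parameters,
                               lr=self.cfg.learning_rate * self.cfg.tail_lr_factor,
                               weight_decay=self.cfg.weight_decay)
                    in_tail = True
                F = self.forward().data
                self._snapshot_sum = F if self._snapshot_sum is None else self._snapshot_sum + F
                self._snapshot_n += 1
            if self.epoch % 50 == 0:
                logger.info("epoch %d: loss %.5f", self.epoch, val)
        return self

    # -- inference -------------------------------------------------------
    def fused_table(self) -> FusedEmbeddingTable:
        """Inference-time embeddings: the tail-averaged snapshots when
        training ran past ``snapshot_start``, else the current forward."""
        if self._snapshot_n > 0:
            F = self._snapshot_sum / self._snapshot_n
            if self.cfg.normalize_embeddings:
                F = F / np.maximum(np.linalg.norm(F, axis=1, keepdims=True), 1e-12)
        else:
            F = self.forward().data
        return FusedEmbeddingTable(
            self.cfg.d, {e: F[i].copy() for i, e in enumerate(self.order)}
        )

    # -- persistence -----------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        """JSON checkpoint: self-describing header plus all parameters."""
        params = [p.data.tolist() for p in self.parameters]
        payload = {
            "format": CHECKPOINT_FORMAT,
            "config": dataclasses.asdict(self.cfg),
            "config_hash": self.cfg.content_hash(),
            "epoch": self.epoch,
            "loss_history": self.loss_history,
            "entity_order": self.order,
            "parameters": params,
            "snapshot_sum": None if self._snapshot_sum is None else self._snapshot_sum.tolist(),
            "snapshot_n": self._snapshot_n,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load_checkpoint(cls, path: str | Path, g: KnowledgeGraph) -> "FusionModel":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"corrupt checkpoint {path}: unknown format")
        cfg_d = payload["config"]
        if cfg_d.get("relations_to_use") is not None:
            cfg_d["relations_to_use"] = tuple(cfg_d["relations_to_use"])
        model = cls(g, TrainConfig(**cfg_d))
        if model.order != payload["entity_order"]:
            raise ValueError(f"checkpoint {path} does not match the given graph's entities")
        for p, saved in zip(model.parameters, payload["parameters"]):
            arr = np.asarray(saved, dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError(f"corrupt checkpoint {path}: parameter shape mismatch")
            p.data = arr
        model.epoch = payload["epoch"]
        model.loss_history = list(payload["loss_history"])
        if payload.get("snapshot_sum") is not None:
            model._snapshot_sum = np.asarray(payload["snapshot_sum"], dtype=float)
            model._snapshot_n = int(payload["snapshot_n"])
        return model


def train_model(g: KnowledgeGraph, cfg: TrainConfig) -> tuple[FusionModel, FusedEmbeddingTable]:
    """Train the fusion model on a knowledge graph's synthesizes edges."""
    model = FusionModel(g, cfg).fit()
    return model, model.fused_table()


def predict_ranking(
    table: FusedEmbeddingTable,
    query: str,
    candidates: list[str],
    positives: frozenset[str] | set[str] = frozenset(),
) -> RankingResult:
    """Score and sort candidates for a query entity (either direction).

    Materials can be ranked for a microbe or microbes for a material; the
    scoring formula is symmetric.  Ties are broken by candidate id.
    """
    if query not in table.vectors:
        raise KeyError(f"query {query!r} has no embedding")
    missing = [c for c in candidates if c not in table.vectors]
    if missing:
        raise KeyError(f"unembedded candidates: {missing[:10]}")
    qv = table.vectors[query]
    scored = sorted(
        ((score_pair(qv, table.vectors[c]), c) for c in candidates),
        key=lambda sc: (-sc[0], sc[1]),
    )
    return RankingResult(
        query_id=query,
        candidates=[c for _, c in scored],
        scores=[s for s, _ in scored],
        positives=frozenset(positives),
    )
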