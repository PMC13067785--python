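"""Graph module: relational graph convolution over the knowledge graph.

One learned transform per relation type plus a self-loop transform; node
updates average incoming messages per relation (normalizer c_{i,r} = the
node's in-degree under relation r).  Inverse relations are added for every
relation so that tail-only entities still receive messages.  Entities are
indexed in sorted-id order, which makes the encoder invariant to input row
order and equivariant under id relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .kg_core import KnowledgeGraph

INVERSE_SUFFIX = "__inv"

#: Relations fed to the encoder by default.  Ontology-typing edges and
#: methods participate only if explicitly requested.
DEFAULT_RELATIONS = ("synthesizes", "composed_of", "taxon_parent")


@dataclass
class RelationalAdjacency:
    """Per-relation edge lists plus in-degree normalizers over n nodes."""

    order: list[str]                       # entity ids, sorted
    relations: list[str]                   # includes __inv companions
    edges: dict[str, tuple[np.ndarray, np.ndarray]]   # relation -> (head_idx, tail_idx)
    norm: dict[str, np.ndarray]            # relation -> per-node in-degree (c_{i,r})

    @property
    def n(self) -> int:
        return len(self.order)

    def message_matrix(self, relation: str) -> np.ndarray:
        """Dense (n × n) matrix M with M[i, j] = 1/c_{i,r} for j ∈ N_r(i)."""
        heads, tails = self.edges[relation]
        M = np.zeros((self.n, self.n))
        c = self.norm[relation]
        for h, t in zip(heads, tails):
            M[t, h] += 1.0 / c[t]
        return M


def build_adjacency(
    g: KnowledgeGraph,
    relations_to_use: tuple[str, ...] | None = None,
    add_inverse: bool = True,
    entity_ids: list[str] | None = None,
) -> RelationalAdjacency:
    """Index entities (sorted ids) and collect per-relation edges.

    With ``add_inverse``, every relation r gets a companion ``r__inv`` with
    head/tail swapped.  Unknown relations present in the graph are kept as
    distinct types when listed in ``relations_to_use``.
    """
    order = sorted(entity_ids if entity_ids is not None else g.entities)
    idx = {e: i for i, e in enumerate(order)}
    use = relations_to_use if relations_to_use is not None else tuple(
        r for r in DEFAULT_RELATIONS if any(t.relation == r for t in g.triples)
    )
    edges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    norm: dict[str, np.ndarray] = {}
    relations: list[str] = []
    for r in use:
        pairs = [
            (idx[t.head], idx[t.tail])
            for t in g.triples
            if t.relation == r and t.head in idx and t.tail in idx
        ]
        variants = [(r, pairs)]
        if add_inverse:
            variants.append((r + INVERSE_SUFFIX, [(b, a) for a, b in pairs]))
        for name, pr in variants:
            heads = np.array([a for a, _ in pr], dtype=int)
            tails = np.array([b for _, b in pr], dtype=int)
            c = np.ones(len(order))
            if len(tails):
                counts = np.bincount(tails, minlength=len(order))
                c = np.maximum(counts, 1).astype(float)
            relations.append(name)
            edges[name] = (heads, tails)
            norm[name] = c
    return RelationalAdjacency(order, relations, edges, norm)


@dataclass
class GraphEmbeddingTable:
    """Per-entity structural vectors of fixed dimension ``dim``."""

    dim: int
    vectors: dict[str, np.ndarray]
    n_layers: int = 0

    def __post_init__(self) -> None:
        for eid, v in self.vectors.items():
            if v.shape != (self.dim,) or not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {eid!r} not a finite {self.dim}-vector")

    def matrix(self, order: list[str]) -> np.ndarray:
        return np.stack([self.vectors[e] for e in order])


def rgcn_layer(h, adj: RelationalAdjacency, weights: dict, activation=None):
    """One relational convolution: h'_i = act(Σ_r Σ_{j∈N_r(i)} W_r h_j / c_{i,r} + W_0 h_i).

    ``weights`` maps each relation name to its W_r (d_in × d_out) plus the
    self transform under key ``"self"``.  Works on plain numpy arrays or on
    autodiff Tensors (``h`` and the weights decide).  ``activation`` may be
    None (linear), "tanh" or "relu".
    """
    if "self" not in weights:
        raise ValueError("weights must include the 'self' transform")
    self_shape = tuple(weights["self"].shape)
    h_shape = tuple(h.shape)
    if h_shape[-1] != self_shape[0]:
        raise ValueError(f"input dim {h_shape[-1]} != self-weight rows {self_shape[0]}")
    out = h @ weights["self"]
    for r in adj.relations:
        if r not in weights:
            raise ValueError(f"missing weight matrix for relation {r!r}")
        W = weights[r]
        if tuple(W.shape) != self_shape:
            raise ValueError(f"weight shape mismatch for relation {r!r}")
        heads, _ = adj.edges[r]
        if len(heads) == 0:
            continue
        M = adj.message_matrix(r)
        M = Tensor(M) if isinstance(h, Tensor) else M
        out = out + (M @ h) @ W
    if activation is None:
        return out
    if activation == "tanh":
        return out.tanh() if isinstance(out, Tensor) else np.tanh(out)
    if activation == "relu":
        return out.relu() if isinstance(out, Tensor) else np.maximum(out, 0.0)
    raise ValueError(f"unknown activation {activation!r}")


class RGCNEncoder:
    """L stacked relational convolutions over learned input embeddings."""

    def __init__(
        self,
        adj: RelationalAdjacency,
        dim: int = 64,
        n_layers: int = 2,
        seed: int = 0,
        activation: str = "tanh",
        learned_input: bool = True,
    ):
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if adj.n == 0:
            raise ValueError("cannot encode an empty graph")
        self.adj = adj
        self.dim = dim
        self.n_layers = n_layers
        self.activation = activation
        rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
        scale = 1.0 / np.sqrt(dim)
        self.input_embeddings: Tensor | None = None
        if learned_input:
            self.input_embeddings = Tensor(
                rng.normal(0.0, scale, size=(adj.n, dim)), requires_grad=True
            )
        self.layer_weights: list[dict[str, Tensor]] = []
        for _ in range(n_layers):
            w = {"self": Tensor(rng.normal(0.0, scale, size=(dim, dim)), requires_grad=True)}
            for r in adj.relations:
                w[r] = Tensor(rng.normal(0.0, scale, size=(dim, dim)), requires_grad=True)
            self.layer_weights.append(w)

    @property
    def parameters(self) -> list[Tensor]:
        params = [] if self.input_embeddings is None else [self.input_embeddings]
        for w in self.layer_weights:
            params.extend(w.values())
        return params

    def forward(self, h0: Tensor | None = None) -> Tensor:
        """Run the stack; ``h0`` supplies externally computed node features
        (e.g. the semantic vectors), otherwise the learned input table."""
        h = h0 if h0 is not None else self.input_embeddings
        if h is None:
            raise ValueError("encoder built without learned input; pass h0")
        for li, w in enumerate(self.layer_weights):
            act = self.activation if li < self.n_layers - 1 else None
            h = rgcn_layer(h, self.adj, w, activation=act)
        return h

    def table(self) -> GraphEmbeddingTable:
        mat = self.forward().data
        return GraphEmbeddingTable(
            self.dim,
            {e: mat[i].copy() for i, e in enumerate(self.adj.order)},
            self.n_layers,
        )


def encode_graph(
    g: KnowledgeGraph,
    dim: int = 64,
    n_layers: int = 2,
    seed: int = 0,
    relations_to_use: tuple[str, ...] | None = None,
) -> GraphEmbeddingTable:
    """Structural embeddings at encoder initialization (untrained).

    Deterministic given the seed; isolated nodes receive self-loop-only
    updates.  Training happens jointly in the fusion trainer.
    """
    adj = build_adjacency(g, relations_to_use)
    return RGCNEncoder(adj, dim=dim, n_layers=n_layers, seed=seed).table()
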