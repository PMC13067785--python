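"""Semantic module: entity description text → fixed-dimension vectors.

The reference architecture uses a transformer sentence encoder for this
step, but names no checkpoint or fine-tuning regime, so the encoder is a
pluggable contract.  The default backend is a trainable bag-of-tokens
model: a learned token-embedding matrix mean-pooled over each entity's
tokens, trained jointly end-to-end with the graph module and fusion head.
A ``pretrained`` backend adapts any user-supplied ``text -> vector``
callable by a seeded linear projection to the working dimension.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from ._autodiff import Tensor

logger = logging.getLogger(__name__)

UNK = "<unk>"
_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class Vocab:
    """Deterministic token → index map; index 0 is the shared UNK slot."""

    index: Mapping[str, int]

    @property
    def size(self) -> int:
        return max(self.index.values()) + 1

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, 0)


@dataclass
class TextEmbeddingTable:
    """Per-entity semantic vectors of fixed dimension ``dim``."""

    dim: int
    vectors: dict[str, np.ndarray]
    vocab: Vocab | None = None

    def __post_init__(self) -> None:
        for eid, v in self.vectors.items():
            if v.shape != (self.dim,) or not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {eid!r} not a finite {self.dim}-vector")

    def matrix(self, order: list[str]) -> np.ndarray:
        return np.stack([self.vectors[e] for e in order])


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def build_vocab(texts: list[str], min_count: int = 1) -> Vocab:
    """Build a vocabulary; tokens rarer than ``min_count`` share UNK.

    Ordering is deterministic: by descending count, then alphabetically.
    """
    counts: Counter[str] = Counter()
    for t in texts:
        counts.update(tokenize(t))
    if not counts:
        raise ValueError("cannot build a vocabulary from all-empty texts")
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count),
        key=lambda tok: (-counts[tok], tok),
    )
    index = {UNK: 0}
    for tok in kept:
        index[tok] = len(index)
    return Vocab(index)


def pooling_matrix(texts_by_id: Mapping[str, str], vocab: Vocab,
                   order: list[str], idf_weight: bool = False) -> np.ndarray:
    """Weighted-mean pooling matrix P: P @ E gives per-entity text vectors.

    Plain mode averages token embeddings uniformly; ``idf_weight`` scales
    each token by log(N/df) before renormalizing, damping ubiquitous
    template words in favor of discriminative ones.  Rows of empty texts
    are zero (flagged with a warning).
    """
    tokens_per_entity = {eid: tokenize(texts_by_id.get(eid, "")) for eid in order}
    weights = np.ones(vocab.size)
    if idf_weight:
        df = np.zeros(vocab.size)
        for toks in tokens_per_entity.values():
            for j in {vocab[t] for t in toks}:
                df[j] += 1.0
        n_docs = max(1, sum(bool(t) for t in tokens_per_entity.values()))
        with np.errstate(divide="ignore"):
            weights = np.log(n_docs / np.maximum(df, 1.0)) + 1e-3
    P = np.zeros((len(order), vocab.size))
    for i, eid in enumerate(order):
        toks = tokens_per_entity[eid]
        if not toks:
            logger.warning("entity %s has an empty description; zero semantic vector", eid)
            continue
        for tok in toks:
            P[i, vocab[tok]] += weights[vocab[tok]]
        total = P[i].sum()
        if total > 0:
            P[i] /= total
    return P


class BagOfTokensEncoder:
    """Trainable backend: mean-pooled learned token embeddings.

    The token-embedding matrix is the only parameter; pooling is a fixed
    linear map, so the initial entity vector of e.g. "gold nanoparticle" is
    exactly the mean of the two initialized token rows, and token order
    never matters.
    """

    def __init__(self, texts_by_id: Mapping[str, str], dim: int, seed: int,
                 min_count: int = 1, vocab: Vocab | None = None,
                 idf_weight: bool = False):
        self.dim = dim
        self.order = sorted(texts_by_id)
        self.vocab = vocab or build_vocab([texts_by_id[e] for e in self.order], min_count)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        self.token_embeddings = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(dim), size=(self.vocab.size, dim)),
            requires_grad=True,
        )
        self._pool = pooling_matrix(texts_by_id, self.vocab, self.order, idf_weight)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.token_embeddings]

    def forward(self) -> Tensor:
        """(n_entities × dim) semantic matrix, rows in ``self.order``."""
        return Tensor(self._pool) @ self.token_embeddings

    def table(self) -> TextEmbeddingTable:
        mat = self.forward().data
        return TextEmbeddingTable(
            self.dim, {e: mat[i].copy() for i, e in enumerate(self.order)}, self.vocab
        )


class PretrainedAdapter:
    """Adapter backend: any sentence encoder, projected to ``dim``.

    The projection is a fixed seeded random linear map (not trained); use
    it to slot a pretrained transformer behind the same table contract.
    """

    def __init__(self, texts_by_id: Mapping[str, str], dim: int, seed: int,
                 encode_fn: Callable[[str], np.ndarray]):
        self.dim = dim
        self.order = sorted(texts_by_id)
        raw = []
        for eid in self.order:
            text = texts_by_id[eid]
            if not text.strip():
                logger.warning("entity %s has an empty description; zero semantic vector", eid)
                raw.append(None)
            else:
                raw.append(np.asarray(encode_fn(text), dtype=float))
        src_dim = next((v.shape[0] for v in raw if v is not None), dim)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
        self._proj = rng.normal(0.0, 1.0 / np.sqrt(src_dim), size=(src_dim, dim))
        self._raw = [np.zeros(src_dim) if v is None else v for v in raw]

    def table(self) -> TextEmbeddingTable:
        mat = np.stack(self._raw) @ self._proj
        return TextEmbeddingTable(
            self.dim, {e: mat[i].copy() for i, e in enumerate(self.order)}
        )


def encode_text(
    texts_by_id: Mapping[str, str],
    dim: int = 64,
    seed: int = 0,
    backend: str = "trainable",
    min_count: int = 1,
    encode_fn: Callable[[str], np.ndarray] | None = None,
) -> TextEmbeddingTable:
    """Encode entity descriptions to a :class:`TextEmbeddingTable`.

    ``backend='trainable'`` returns the bag-of-tokens encoder's state at
    initialization (training happens jointly in the fusion trainer);
    ``backend='pretrained'`` requires ``encode_fn``.
    """
    if backend == "trainable":
        return BagOfTokensEncoder(texts_by_id, dim, seed, min_count).table()
    if backend == "pretrained":
        if encode_fn is None:
            raise ValueError("pretrained backend requires encode_fn")
        return PretrainedAdapter(texts_by_id, dim, seed, encode_fn).table()
    raise ValueError(f"unknown semantic backend {backend!r}")
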