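"""Clustering-based extractive abstract compression.

Downstream pair-similarity scoring accepts at most 512 tokens of document
text, so long abstracts are compressed extractively: each sentence is
embedded as a fixed-dimension vector, the sentence vectors are k-means
clustered into N groups, and sentences nearest their cluster centroids are
selected round-robin until the token budget would be exceeded.  Selected
sentences are emitted in their original order, so the compressed abstract
preserves the writing style and discourse order of the original.

The embedding backend is pluggable (the :class:`Embedder` protocol).  The
shipped backend is a deterministic feature-hashing bag-of-words embedder;
a contextual sentence encoder (e.g. a biomedical BERT) can be dropped in by
implementing the same protocol.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.cluster import KMeans

from ._text import split_sentences, tokenize

__all__ = [
    "Embedder", "HashingEmbedder", "SentenceEmbedding", "ExtractedAbstract",
    "ExtractionConfig", "split_sentences",
    "cluster_sentences", "select_by_centroid", "extract_abstract",
]


@runtime_checkable
class Embedder(Protocol):
    """Sentence embedding backend contract."""

    dimension: int
    deterministic: bool

    def embed(self, sentences: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(sentences), dimension)."""
        ...


class HashingEmbedder:
    """Deterministic feature-hashing bag-of-words sentence embedder.

    Each token is hashed (BLAKE2, stable across processes) to a coordinate
    and a sign; a sentence vector is the L2-normalized signed token-count
    vector.  Sentences sharing vocabulary land near each other, which is all
    k-means needs; no semantics beyond lexical overlap are modelled.
    """

    deterministic = True

    def __init__(self, dimension: int = 32):
        self.dimension = dimension

    def _token_coord(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
        value = int.from_bytes(digest, "big")
        return value % self.dimension, 1.0 if (value >> 60) & 1 else -1.0

    def embed(self, sentences: Sequence[str]) -> np.ndarray:
        vectors = np.zeros((len(sentences), self.dimension))
        for row, sentence in enumerate(sentences):
            for token in tokenize(sentence):
                coord, sign = self._token_coord(token)
                vectors[row, coord] += sign
            norm = np.linalg.norm(vectors[row])
            if norm > 0:
                vectors[row] /= norm
        return vectors


@dataclass(frozen=True)
class SentenceEmbedding:
    sentence_index: int
    text: str
    vector: np.ndarray


@dataclass(frozen=True)
class ExtractedAbstract:
    """A <=budget-token extractive summary with sentence provenance.

    ``selected`` holds (sentence_index, text, cluster_id) triples in original
    abstract order.
    """

    selected: tuple[tuple[int, str, int], ...]
    token_count: int
    n_clusters: int

    @property
    def text(self) -> str:
        return " ".join(text for _, text, _ in self.selected)


@dataclass(frozen=True)
class ExtractionConfig:
    n_clusters: int = 4
    budget: int = 512
    seed: int = 0


def cluster_sentences(embeddings: np.ndarray, n_clusters: int,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """K-means cluster sentence vectors into ``n_clusters`` groups.

    ``n_clusters`` is clamped to the number of sentences.  Returns
    (labels, centroids); deterministic for a fixed seed.
    """
    n = embeddings.shape[0] if embeddings.ndim == 2 else 0
    if n == 0:
        raise ValueError("cannot cluster an empty embedding list")
    k = max(1, min(n_clusters, n))
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(embeddings)
    return labels, km.cluster_centers_


def _token_len(text: str) -> int:
    return len(text.split())


def select_by_centroid(labels: np.ndarray, embeddings: np.ndarray,
                       sentences: Sequence[str], centroids: np.ndarray,
                       budget: int = 512) -> ExtractedAbstract:
    """Pick centroid-nearest sentences round-robin within the token budget.

    Each pass visits clusters in id order and takes, per cluster, the not yet
    selected sentence with the smallest Euclidean distance to the cluster
    centroid (ties broken by sentence position).  Selection stops before the
    first pick that would push the running token count over ``budget``.
    The result lists selected sentences in original abstract order.
    """
    n_clusters = centroids.shape[0]
    # per cluster: sentence indices sorted by (distance to centroid, index)
    queues: list[list[int]] = []
    for cluster in range(n_clusters):
        members = np.flatnonzero(labels == cluster)
        dists = np.linalg.norm(embeddings[members] - centroids[cluster], axis=1)
        order = members[np.lexsort((members, dists))]
        queues.append(list(order))

    chosen: list[int] = []
    total = 0
    done = False
    while not done:
        progressed = False
        for cluster in range(n_clusters):
            if not queues[cluster]:
                continue
            candidate = queues[cluster][0]
            cost = _token_len(sentences[candidate])
            if total + cost > budget:
                done = True
                break
            queues[cluster].pop(0)
            chosen.append(candidate)
            total += cost
            progressed = True
        if not progressed:
            done = True

    chosen.sort()
    selected = tuple((idx, sentences[idx], int(labels[idx])) for idx in chosen)
    return ExtractedAbstract(selected, total, n_clusters)


def extract_abstract(abstract: str, embedder: Embedder,
                     config: ExtractionConfig = ExtractionConfig()
                     ) -> ExtractedAbstract:
    """Split, embed, cluster and select: the full extraction pipeline for one
    abstract.  Deterministic under a deterministic embedder and fixed seed."""
    sentences = split_sentences(abstract)
    if not sentences:
        return ExtractedAbstract((), 0, 0)
    embeddings = embedder.embed(sentences)
    labels, centroids = cluster_sentences(embeddings, config.n_clusters,
                                          config.seed)
    return select_by_centroid(labels, embeddings, sentences, centroids,
                              config.budget)
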