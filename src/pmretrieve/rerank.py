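"""Stage 2: pair-similarity scoring, score fusion, and training-pair export.

The stage-1 candidates (top 1000 by the composite BM25 score) are rescored
by a pair scorer that maps a (query text, document text) pair to a
similarity in [0, 1].  The production backend in the original method is a
fine-tuned biomedical BERT sentence-pair classifier with a sigmoid head;
this package ships a deterministic lexical-overlap scorer implementing the
same :class:`PairScorer` contract, and carries the transformer training
hyperparameters in :class:`TrainingConfig` for an external trainer.

Per topic, each enabled similarity field (abstract and optionally title) is
max–min normalized over the candidate pool and added, with equal weights, to
the stage-1 normalized score; candidates are re-sorted descending to give
the final ranking.

`make_training_pairs` exports labelled sentence pairs for fine-tuning such a
classifier: positives pair a relevant document with its own topic's query,
negatives pair the same document text with a query from a sibling topic that
shares the disease but differs in gene, or shares a gene but differs in
disease — hard negatives differing from the positive in exactly one slot.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

from ._text import tokenize
from .bm25 import ScoredDoc, minmax_normalize
from .corpus import Document, QrelEntry, Topic
from .demographics import (DemographicProfile, demographic_query_tokens,
                           profile_from_text)
from .expansion import HUMAN_ELEMENT, _split_gene_morpheme

__all__ = [
    "PairScorer", "LexicalOverlapScorer", "ConstantScorer",
    "FusionConfig", "TrainingConfig", "TrainingPair",
    "query_text", "document_head", "score_pairs", "fuse_and_rank",
    "make_training_pairs", "write_pairs_tsv", "read_pairs_tsv",
]


@runtime_checkable
class PairScorer(Protocol):
    """Similarity backend contract: score(query, doc) in [0, 1]; inputs are
    truncated to ``max_len`` tokens before scoring."""

    max_len: int
    deterministic: bool

    def score(self, query_text: str, doc_text: str) -> float:
        ...


class LexicalOverlapScorer:
    """Reference similarity backend: the fraction of distinct query tokens
    present in the document text.  Deterministic and bounded in [0, 1]."""

    deterministic = True

    def __init__(self, max_len: int = 512):
        self.max_len = max_len

    def score(self, query_text: str, doc_text: str) -> float:
        q = set(tokenize(query_text))
        if not q:
            return 0.0
        d = set(tokenize(doc_text))
        return len(q & d) / len(q)


class ConstantScorer:
    """Returns a fixed similarity for every pair; rerank neutrality probe."""

    deterministic = True

    def __init__(self, value: float = 0.5, max_len: int = 512):
        if not 0 <= value <= 1:
            raise ValueError("constant similarity must lie in [0, 1]")
        self.value = value
        self.max_len = max_len

    def score(self, query_text: str, doc_text: str) -> float:
        return self.value


@dataclass(frozen=True)
class FusionConfig:
    """Which similarity fields join the fusion, and the candidate depth."""

    use_abstract: bool = True
    use_title: bool = False
    candidate_depth: int = 1000

    def __post_init__(self) -> None:
        if not (self.use_abstract or self.use_title):
            raise ValueError("reranking requires at least one similarity field")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters carried for an external pair-classifier trainer.

    Defaults are the abstract-field settings (the title field conventionally
    uses batch_size 64 and max_len 128).
    """

    epochs: int = 4
    batch_size: int = 32
    max_len: int = 512
    learning_rate: float = 0.0005


def _truncate(text: str, max_len: int) -> str:
    words = text.split()
    return " ".join(words[:max_len]) if len(words) > max_len else text


def query_text(topic: Topic, profile: DemographicProfile | None = None) -> str:
    """Assemble a topic's query text: disease, genes, then demographic
    category/gender tokens, lowercase and space-joined."""
    if profile is None:
        profile = profile_from_text(topic.demographic_raw)
    parts = [topic.disease.lower()]
    parts.extend(gene.lower() for gene in topic.genes)
    parts.extend(demographic_query_tokens(profile))
    return " ".join(" ".join(tokenize(p)) for p in parts if p)


def score_pairs(topic: Topic, candidates: Sequence[ScoredDoc],
                docs_by_pmid: Mapping[str, Document], scorer: PairScorer,
                field: str = "abstract",
                extracted: Mapping[str, str] | None = None,
                profile: DemographicProfile | None = None) -> dict[str, float]:
    """Similarity of each candidate's abstract (or title) to the topic query.

    For the abstract field, ``extracted`` supplies the compressed abstract
    text per pmid (falling back to the raw abstract); both sides are
    truncated to the scorer's token budget.  A scorer failure is re-raised
    naming the offending pmid.
    """
    if field not in ("abstract", "title"):
        raise ValueError(f"unknown similarity field {field!r}")
    query = query_text(topic, profile)
    sims: dict[str, float] = {}
    for cand in candidates:
        doc = docs_by_pmid[cand.pmid]
        if field == "abstract":
            text = (extracted or {}).get(cand.pmid, doc.abstract)
        else:
            text = doc.title
        try:
            value = scorer.score(_truncate(query, scorer.max_len),
                                 _truncate(text, scorer.max_len))
        except Exception as exc:
            raise RuntimeError(f"pair scorer failed on pmid {cand.pmid}") from exc
        if not 0 <= value <= 1:
            raise ValueError(
                f"pair scorer returned {value} outside [0, 1] for pmid {cand.pmid}")
        sims[cand.pmid] = value
    return sims


def fuse_and_rank(candidates: Sequence[ScoredDoc],
                  sims_abstract: Mapping[str, float] | None = None,
                  sims_title: Mapping[str, float] | None = None,
                  config: FusionConfig = FusionConfig()) -> list[ScoredDoc]:
    """Add normalized similarities to the stage-1 normalized score and
    re-rank.

    Each enabled field's similarities are max–min normalized over the
    candidate pool before addition (equal weights).  Sorting is descending by
    fused score with ties broken by ascending PMID; ranks are reassigned
    1..k.
    """
    pool = list(candidates)
    if not pool:
        return []
    for cand in pool:
        cand.fused_score = cand.norm_score
    if config.use_abstract:
        if sims_abstract is None:
            raise ValueError("abstract similarities required by fusion config")
        norm = minmax_normalize([sims_abstract[c.pmid] for c in pool])
        for cand, value in zip(pool, norm):
            cand.sim_abstract = sims_abstract[cand.pmid]
            cand.fused_score += value
    if config.use_title:
        if sims_title is None:
            raise ValueError("title similarities required by fusion config")
        norm = minmax_normalize([sims_title[c.pmid] for c in pool])
        for cand, value in zip(pool, norm):
            cand.sim_title = sims_title[cand.pmid]
            cand.fused_score += value
    pool.sort(key=lambda c: (-c.fused_score, c.pmid))
    for rank, cand in enumerate(pool, start=1):
        cand.rank = rank
    return pool


# ---------------------------------------------------------------------------
# training-pair generation

@dataclass(frozen=True)
class TrainingPair:
    pmid: str
    doc_text: str
    query_text: str
    topic_id: str
    label: int


def document_head(topic: Topic, profile: DemographicProfile) -> str:
    """The extracted head prepended to a relevant document's summary:
    gene morphemes, the "human" element, the age category (with "adult" for
    the adult-range categories) and gender, lowercased."""
    parts: list[str] = []
    for gene in topic.genes:
        parts.extend(tokenize(gene))
    parts.append(HUMAN_ELEMENT)
    if profile.age_category not in ("", "Unknown"):
        parts.extend(tokenize(profile.age_category))
        if profile.age_category in ("Young", "Middle age", "Aged", "Aged 80"):
            parts.append("adult")
    if profile.gender not in ("", "Unknown"):
        parts.append(profile.gender.lower())
    return " ".join(parts)


def _gene_names(topic: Topic) -> set[str]:
    names = set()
    for gene in topic.genes:
        pieces = _split_gene_morpheme(gene)
        if pieces:
            names.add(pieces[0].lower())
    return names


def _siblings(topic: Topic, topics: Sequence[Topic]) -> list[Topic]:
    """Topics differing from ``topic`` in exactly one slot: same disease with
    different genes, or a shared gene with a different disease."""
    out = []
    for other in topics:
        if other.topic_id == topic.topic_id:
            continue
        same_disease = other.disease.lower() == topic.disease.lower()
        shared_gene = bool(_gene_names(other) & _gene_names(topic))
        same_genes = _gene_names(other) == _gene_names(topic)
        if same_disease and not same_genes:
            out.append(other)          # same disease, different gene(s)
        elif shared_gene and not same_disease:
            out.append(other)          # same gene, different disease
    return out


def make_training_pairs(topics: Sequence[Topic], qrels: Iterable[QrelEntry],
                        docs_by_pmid: Mapping[str, Document],
                        extracted: Mapping[str, str] | None = None,
                        relevance_threshold: int = 1) -> list[TrainingPair]:
    """Generate labelled (document, query) pairs for similarity training.

    For every relevant (grade >= threshold) document of a topic, one positive
    pair is emitted against the topic's own query, and one negative pair per
    sibling topic (same disease/different gene or same gene/different
    disease) against the sibling's query.  The document text is the
    disease/gene/demographic head followed by the (possibly compressed)
    abstract.  A topic with no siblings yields only positives.
    """
    topics_by_id = {t.topic_id: t for t in topics}
    pairs: list[TrainingPair] = []
    for entry in qrels:
        if entry.grade < relevance_threshold:
            continue
        topic = topics_by_id.get(entry.topic_id)
        doc = docs_by_pmid.get(entry.pmid)
        if topic is None or doc is None:
            continue
        profile = demographic_profile_for_pairs(doc, topic)
        summary = (extracted or {}).get(entry.pmid, doc.abstract)
        doc_text = f"{document_head(topic, profile)} {summary}".strip()
        pairs.append(TrainingPair(entry.pmid, doc_text,
                                  query_text(topic, profile),
                                  topic.topic_id, 1))
        for sibling in _siblings(topic, topics):
            pairs.append(TrainingPair(entry.pmid, doc_text,
                                      query_text(sibling),
                                      sibling.topic_id, 0))
    return pairs


def demographic_profile_for_pairs(doc: Document, topic: Topic) -> DemographicProfile:
    """Prefer the document's own demographic evidence; fall back to the
    topic's stated demographic when the document carries none."""
    profile = profile_from_text(f"{doc.title} {doc.abstract}", "abstract_regex")
    if profile.age_category == "Unknown" and profile.gender == "Unknown":
        return profile_from_text(topic.demographic_raw)
    return profile


_TSV_HEADER = ("pmid", "document", "query", "topic", "label")


def write_pairs_tsv(pairs: Sequence[TrainingPair], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_TSV_HEADER)
        for pair in pairs:
            writer.writerow([pair.pmid, pair.doc_text, pair.query_text,
                             pair.topic_id, pair.label])


def read_pairs_tsv(path: str | Path) -> list[TrainingPair]:
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if tuple(header) != _TSV_HEADER:
            raise ValueError(f"unexpected pairs TSV header {header!r}")
        return [TrainingPair(row[0], row[1], row[2], row[3], int(row[4]))
                for row in reader]
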