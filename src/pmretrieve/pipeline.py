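"""End-to-end two-stage retrieval.

Stage 1: query expansion (synonyms + the "human" element + demographic
category/gender morphemes), then the improved BM25 composite score over the
whole collection, keeping the top-k candidates.  Stage 2: clustering-based
abstract compression to the pair scorer's token budget, pair-similarity
scoring of (query, abstract) and optionally (query, title), max–min
normalization and equal-weight fusion with the stage-1 score, and a final
descending sort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .bm25 import Index, ScoredDoc, ScoringParams, stage1_retrieve
from .corpus import Document, RunEntry, Topic
from .demographics import demographic_query_tokens, profile_from_text
from .expansion import ExpansionTable, expand_topic
from .extraction import Embedder, ExtractionConfig, HashingEmbedder, extract_abstract
from .rerank import FusionConfig, LexicalOverlapScorer, PairScorer, \
    fuse_and_rank, score_pairs

__all__ = ["PipelineConfig", "prepare_topic", "retrieve_stage1",
           "rerank_candidates", "retrieve", "run_entries"]


@dataclass
class PipelineConfig:
    params: ScoringParams = field(default_factory=ScoringParams)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    run_tag: str = "pmretrieve"


def prepare_topic(topic: Topic, table: ExpansionTable | None = None) -> Topic:
    """Expand a topic in place: synonym lookups, the "human" element, and the
    demographic category/gender tokens as additional query morphemes."""
    expand_topic(topic, table)
    profile = profile_from_text(topic.demographic_raw)
    existing = {t.lower() for t in topic.expansion_terms}
    for token in demographic_query_tokens(profile):
        if token not in existing:
            existing.add(token)
            topic.expansion_terms.append(token)
    return topic


def retrieve_stage1(topic: Topic, docs: Sequence[Document], index: Index,
                    config: PipelineConfig | None = None) -> list[ScoredDoc]:
    config = config or PipelineConfig()
    return stage1_retrieve(topic, docs, index, config.params,
                           config.fusion.candidate_depth)


def rerank_candidates(topic: Topic, candidates: Sequence[ScoredDoc],
                      docs_by_pmid: Mapping[str, Document],
                      scorer: PairScorer,
                      embedder: Embedder | None = None,
                      config: PipelineConfig | None = None) -> list[ScoredDoc]:
    """Stage 2 for one topic's candidate list."""
    config = config or PipelineConfig()
    embedder = embedder or HashingEmbedder()
    profile = profile_from_text(topic.demographic_raw)
    sims_abstract = sims_title = None
    if config.fusion.use_abstract:
        extracted = {}
        for cand in candidates:
            doc = docs_by_pmid[cand.pmid]
            if len(doc.abstract.split()) > config.extraction.budget:
                extracted[cand.pmid] = extract_abstract(
                    doc.abstract, embedder, config.extraction).text
        sims_abstract = score_pairs(topic, candidates, docs_by_pmid, scorer,
                                    "abstract", extracted, profile)
    if config.fusion.use_title:
        sims_title = score_pairs(topic, candidates, docs_by_pmid, scorer,
                                 "title", None, profile)
    return fuse_and_rank(candidates, sims_abstract, sims_title, config.fusion)


def retrieve(topics: Sequence[Topic], docs: Sequence[Document], index: Index,
             scorer: PairScorer | None = None,
             table: ExpansionTable | None = None,
             embedder: Embedder | None = None,
             config: PipelineConfig | None = None
             ) -> dict[str, list[ScoredDoc]]:
    """Run the full two-stage pipeline for every topic."""
    config = config or PipelineConfig()
    scorer = scorer or LexicalOverlapScorer()
    docs_by_pmid = {doc.pmid: doc for doc in docs}
    results: dict[str, list[ScoredDoc]] = {}
    for topic in topics:
        prepare_topic(topic, table)
        candidates = retrieve_stage1(topic, docs, index, config)
        results[topic.topic_id] = rerank_candidates(
            topic, candidates, docs_by_pmid, scorer, embedder, config)
    return results


def run_entries(results: Mapping[str, Sequence[ScoredDoc]],
                run_tag: str = "pmretrieve",
                use_fused: bool = True) -> list[RunEntry]:
    """Flatten per-topic scored documents into TREC run entries."""
    entries: list[RunEntry] = []
    for topic_id in sorted(results):
        for cand in sorted(results[topic_id], key=lambda c: c.rank):
            score = cand.fused_score if use_fused else cand.norm_score
            entries.append(RunEntry(topic_id, cand.pmid, cand.rank, score, run_tag))
    return entries
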