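"""Stage-1 scoring: improved BM25 with wordlist and co-word components.

Three scores are computed per (topic, document) pair and summed:

* the abstract score ``AS`` — an Okapi-style BM25 sum over the query
  morphemes' tokens against the document's abstract+title field;
* the wordlist score ``WS`` — a saturated transform of the summed IDFs of
  query tokens found in the document's combined controlled-vocabulary field
  (chemicals + MeSH headings + keywords);
* the co-word score ``CWS`` — the summed IDFs of the topic's genes that
  co-occur with the disease in the document.

The composite ``AS + WS + CWS`` is max–min normalized over the candidate
pool and the top-k (default 1000) documents form the stage-1 candidate list.
IDF is the natural log of (total documents / documents containing the
token); tokens present in no document, or in every document, contribute 0.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._text import tokenize
from .corpus import Document, Topic, build_wordlist

__all__ = [
    "IndexStats", "ScoringParams", "ScoredDoc", "Index",
    "build_index", "idf", "minmax_normalize",
    "abstract_score", "wordlist_score", "coword_score", "stage1_retrieve",
    "topic_morphemes", "gene_token_groups",
]


@dataclass(frozen=True)
class ScoringParams:
    """BM25 adjustment factors.

    ``k1``/``k2`` control term-frequency saturation for the abstract and
    wordlist scores; ``b1``/``b2`` control document-length normalization.
    Defaults are the conventional (1.2, 0.75) pairs.  ``avgdl_override`` /
    ``avgdwl_override`` replace the corpus-derived average abstract length
    and average wordlist length when set.
    """

    k1: float = 1.2
    k2: float = 1.2
    b1: float = 0.75
    b2: float = 0.75
    avgdl_override: float | None = None
    avgdwl_override: float | None = None

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        if not (0 <= self.b1 <= 1 and 0 <= self.b2 <= 1):
            raise ValueError("b1 and b2 must lie in [0, 1]")
        for name in ("avgdl_override", "avgdwl_override"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class IndexStats:
    """Corpus-level counts behind IDF and length normalization."""

    n_docs: int
    df_abstract: dict[str, int]
    df_wordlist: dict[str, int]
    avgdl: float
    avgdwl: float


@dataclass
class ScoredDoc:
    """Per-document score components accumulated along the pipeline."""

    pmid: str
    as_score: float = 0.0
    ws_score: float = 0.0
    cws_score: float = 0.0
    raw_sum: float = 0.0
    norm_score: float = 0.0
    sim_abstract: float | None = None
    sim_title: float | None = None
    fused_score: float = 0.0
    rank: int = 0


@dataclass
class Index:
    """Inverted statistics over a collection: token frequencies per document
    for the abstract+title field and the wordlist field, plus corpus stats."""

    stats: IndexStats
    abstract_tf: dict[str, Counter] = field(default_factory=dict)
    wordlist_tf: dict[str, Counter] = field(default_factory=dict)
    doc_len: dict[str, int] = field(default_factory=dict)
    wordlist_len: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "pmretrieve-index",
            "version": 1,
            "n_docs": self.stats.n_docs,
            "avgdl": self.stats.avgdl,
            "avgdwl": self.stats.avgdwl,
            "df_abstract": self.stats.df_abstract,
            "df_wordlist": self.stats.df_wordlist,
            "abstract_tf": {p: dict(c) for p, c in self.abstract_tf.items()},
            "wordlist_tf": {p: dict(c) for p, c in self.wordlist_tf.items()},
            "doc_len": self.doc_len,
            "wordlist_len": self.wordlist_len,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Index":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "pmretrieve-index":
            raise ValueError(f"{path} is not a pmretrieve index")
        stats = IndexStats(
            n_docs=payload["n_docs"],
            df_abstract=payload["df_abstract"],
            df_wordlist=payload["df_wordlist"],
            avgdl=payload["avgdl"],
            avgdwl=payload["avgdwl"],
        )
        return cls(
            stats=stats,
            abstract_tf={p: Counter(c) for p, c in payload["abstract_tf"].items()},
            wordlist_tf={p: Counter(c) for p, c in payload["wordlist_tf"].items()},
            doc_len=payload["doc_len"],
            wordlist_len=payload["wordlist_len"],
        )


def build_index(docs: Sequence[Document]) -> Index:
    """Tokenize and index a collection.

    The abstract field indexes title + abstract tokens; the wordlist field
    indexes the combined controlled-vocabulary tokens.  Documents with empty
    wordlists count as zero-length in the avgdwl denominator.
    """
    abstract_tf: dict[str, Counter] = {}
    wordlist_tf: dict[str, Counter] = {}
    doc_len: dict[str, int] = {}
    wordlist_len: dict[str, int] = {}
    df_abstract: Counter = Counter()
    df_wordlist: Counter = Counter()
    for doc in docs:
        a_tokens = tokenize(doc.title) + tokenize(doc.abstract)
        w_tokens = list(build_wordlist(doc).terms)
        abstract_tf[doc.pmid] = Counter(a_tokens)
        wordlist_tf[doc.pmid] = Counter(w_tokens)
        doc_len[doc.pmid] = len(a_tokens)
        wordlist_len[doc.pmid] = len(w_tokens)
        df_abstract.update(set(a_tokens))
        df_wordlist.update(set(w_tokens))
    n = len(docs)
    stats = IndexStats(
        n_docs=n,
        df_abstract=dict(df_abstract),
        df_wordlist=dict(df_wordlist),
        avgdl=(sum(doc_len.values()) / n) if n else 0.0,
        avgdwl=(sum(wordlist_len.values()) / n) if n else 0.0,
    )
    return Index(stats, abstract_tf, wordlist_tf, doc_len, wordlist_len)


def idf(token: str, field_name: str, stats: IndexStats) -> float:
    """Natural-log inverse document frequency of ``token`` in the named
    field (``"abstract"`` or ``"wordlist"``).

    Returns 0 for tokens absent from the corpus (they cannot contribute
    evidence) and for tokens present in every document (log 1 = 0).
    """
    if field_name == "abstract":
        df = stats.df_abstract.get(token, 0)
    elif field_name == "wordlist":
        df = stats.df_wordlist.get(token, 0)
    else:
        raise ValueError(f"unknown field {field_name!r}")
    if df <= 0 or df >= stats.n_docs:
        return 0.0
    return math.log(stats.n_docs / df)


def _avgdl(stats: IndexStats, params: ScoringParams) -> float:
    if params.avgdl_override is not None:
        return params.avgdl_override
    return stats.avgdl


def _avgdwl(stats: IndexStats, params: ScoringParams) -> float:
    if params.avgdwl_override is not None:
        return params.avgdwl_override
    return stats.avgdwl


def gene_token_groups(topic: Topic) -> list[list[str]]:
    """Tokenize each gene morpheme, keeping name and variant together as one
    group (e.g. ``"BRAF (V600E)"`` -> ``["braf", "v600e"]``)."""
    return [tokenize(gene) for gene in topic.genes]


def topic_morphemes(topic: Topic) -> list[str]:
    """The flat token list of a topic's query morphemes: disease tokens,
    gene tokens, and expansion-term tokens, deduplicated in first-seen order.

    After query expansion the expansion terms carry the "human" search
    element and the topic's demographic category/gender tokens, so those
    participate here as full-weight morphemes."""
    tokens: list[str] = []
    tokens.extend(tokenize(topic.disease))
    for group in gene_token_groups(topic):
        tokens.extend(group)
    for term in topic.expansion_terms:
        tokens.extend(tokenize(term))
    seen: set[str] = set()
    unique = []
    for token in tokens:
        if token not in seen:
            seen.add(token)
            unique.append(token)
    return unique


def abstract_score(topic: Topic, doc: Document, index: Index,
                   params: ScoringParams = ScoringParams()) -> float:
    """BM25 abstract score: sum over query tokens of
    ``IDF(q) * f (k1+1) / (f + k1 (1 - b1 + b1 dl/avgdl))`` where ``f`` is the
    token's frequency in the document's abstract+title and ``dl`` the field
    length in tokens."""
    stats = index.stats
    tf = index.abstract_tf.get(doc.pmid)
    if tf is None:
        raise KeyError(f"document {doc.pmid} not in index")
    dl = index.doc_len[doc.pmid]
    avgdl = _avgdl(stats, params)
    norm = 1 - params.b1 + (params.b1 * dl / avgdl if avgdl > 0 else 0.0)
    score = 0.0
    for token in topic_morphemes(topic):
        f = tf.get(token, 0)
        if f == 0:
            continue
        score += idf(token, "abstract", stats) * f * (params.k1 + 1) / (
            f + params.k1 * norm)
    return score


def wordlist_score(topic: Topic, doc: Document, index: Index,
                   params: ScoringParams = ScoringParams()) -> float:
    """Wordlist score: ``tfw (k2+1) / (tfw + k2 (1 - b2 + b2 dwl/avgdwl))``
    where ``tfw`` is the sum of wordlist-field IDFs of the query tokens
    present in the document's wordlist.  Zero when no query token occurs."""
    stats = index.stats
    tf = index.wordlist_tf.get(doc.pmid)
    if tf is None:
        raise KeyError(f"document {doc.pmid} not in index")
    tfw = sum(idf(token, "wordlist", stats)
              for token in topic_morphemes(topic) if tf.get(token, 0) > 0)
    if tfw == 0.0:
        return 0.0
    dwl = index.wordlist_len[doc.pmid]
    avgdwl = _avgdwl(stats, params)
    norm = 1 - params.b2 + (params.b2 * dwl / avgdwl if avgdwl > 0 else 0.0)
    return tfw * (params.k2 + 1) / (tfw + params.k2 * norm)


def _disease_tokens(topic: Topic) -> set[str]:
    tokens = set(tokenize(topic.disease))
    for term in topic.disease_expansion_terms:
        tokens.update(tokenize(term))
    return tokens


def coword_score(topic: Topic, doc: Document, index: Index) -> float:
    """Co-word score: summed gene IDFs for genes that co-occur with the
    disease in the document.

    The disease (any of its tokens, or a disease expansion synonym's tokens)
    and the gene must each occur at least once in the union of the document's
    abstract+title tokens and wordlist tokens.  A gene counts as present when
    any of its tokens occurs; it contributes the sum of the IDFs of its
    occurring tokens, taking each token's IDF from the wordlist field when the
    token occurs in the wordlist and from the abstract field otherwise."""
    a_tf = index.abstract_tf.get(doc.pmid)
    w_tf = index.wordlist_tf.get(doc.pmid)
    if a_tf is None or w_tf is None:
        raise KeyError(f"document {doc.pmid} not in index")
    stats = index.stats

    def present(token: str) -> bool:
        return a_tf.get(token, 0) > 0 or w_tf.get(token, 0) > 0

    if not any(present(t) for t in _disease_tokens(topic)):
        return 0.0
    score = 0.0
    for group in gene_token_groups(topic):
        occurring = [t for t in group if present(t)]
        if not occurring:
            continue
        for token in occurring:
            field_name = "wordlist" if w_tf.get(token, 0) > 0 else "abstract"
            score += idf(token, field_name, stats)
    return score


def minmax_normalize(values: Sequence[float]) -> list[float]:
    """Max–min normalization to [0, 1]: ``(x - min) / (max - min)``.

    A constant sequence maps to all zeros; an empty sequence is an error.
    """
    if len(values) == 0:
        raise ValueError("cannot normalize an empty sequence")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    span = hi - lo
    return [(v - lo) / span for v in values]


def stage1_retrieve(topic: Topic, docs: Sequence[Document], index: Index,
                    params: ScoringParams = ScoringParams(),
                    k: int = 1000) -> list[ScoredDoc]:
    """Score every document, keep the top ``k`` by composite score.

    The composite ``raw_sum = AS + WS + CWS`` is sorted descending (ties
    broken by ascending PMID) and the survivors' ``norm_score`` is the max–min
    normalization of ``raw_sum`` over the candidate pool.
    """
    if params.avgdl_override is not None and params.avgdwl_override is not None \
            and params.avgdl_override > params.avgdwl_override:
        warnings.warn(
            "avgdl_override exceeds avgdwl_override; note the conventional "
            "published parameter table labels these two averages inconsistently "
            "— overrides are applied by position (avgdl to abstracts, avgdwl "
            "to wordlists)", stacklevel=2)
    scored = []
    for doc in docs:
        sd = ScoredDoc(pmid=doc.pmid)
        sd.as_score = abstract_score(topic, doc, index, params)
        sd.ws_score = wordlist_score(topic, doc, index, params)
        sd.cws_score = coword_score(topic, doc, index)
        sd.raw_sum = sd.as_score + sd.ws_score + sd.cws_score
        scored.append(sd)
    scored.sort(key=lambda s: (-s.raw_sum, s.pmid))
    scored = scored[:k]
    if scored:
        for sd, norm in zip(scored, minmax_normalize([s.raw_sum for s in scored])):
            sd.norm_score = norm
    for rank, sd in enumerate(scored, start=1):
        sd.rank = rank
    return scored
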