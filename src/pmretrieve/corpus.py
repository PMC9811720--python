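"""Document/topic/qrels/run data model and file formats.

The canonical on-disk collection dialect is JSONL (one document object per
line); a reader for MEDLINE-flavoured PubMed XML covers the six fields the
retrieval pipeline uses (PMID, title, abstract, chemicals, MeSH headings,
keywords).  Topics, qrels and run files use the TREC exchange conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from ._text import tokenize

__all__ = [
    "Document", "Wordlist", "Topic", "QrelEntry", "RunEntry",
    "CollectionError",
    "read_collection", "write_collection_jsonl", "build_wordlist",
    "read_topics", "write_topics", "read_qrels", "write_qrels",
    "read_run", "write_run",
]


class CollectionError(ValueError):
    """Raised for malformed or inconsistent collection/topic/run files."""


@dataclass(frozen=True)
class Document:
    """One bibliographic record.

    Title and abstract are stored verbatim; the controlled-vocabulary lists
    (chemicals, MeSH headings, keywords) may be empty.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    chemicals: tuple[str, ...] = ()
    mesh_headings: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pmid:
            raise CollectionError("Document requires a non-empty pmid")


@dataclass(frozen=True)
class Wordlist:
    """The combined controlled-vocabulary field of one document.

    ``terms`` is the multiset (as a list, order preserved) of normalized
    tokens drawn from chemicals, MeSH headings and keywords; ``dwl`` is the
    total token count.
    """

    terms: tuple[str, ...]

    @property
    def dwl(self) -> int:
        return len(self.terms)


@dataclass
class Topic:
    """One retrieval case: disease, gene morphemes, and demographic text.

    ``expansion_terms`` starts empty and is populated by query expansion;
    ``disease_expansion_terms`` records the subset that expands the disease,
    used by the co-word score's co-occurrence test.
    """

    topic_id: str
    disease: str
    genes: list[str]
    demographic_raw: str = ""
    expansion_terms: list[str] = field(default_factory=list)
    disease_expansion_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise CollectionError(
                f"topic {self.topic_id!r} requires at least one gene morpheme")


@dataclass(frozen=True)
class QrelEntry:
    topic_id: str
    pmid: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade < 0:
            raise CollectionError("relevance grade must be non-negative")


@dataclass(frozen=True)
class RunEntry:
    topic_id: str
    pmid: str
    rank: int
    score: float
    run_tag: str = "pmretrieve"


def build_wordlist(doc: Document) -> Wordlist:
    """Combine chemicals, MeSH headings and keywords into one token multiset.

    Multi-word terms are tokenized into words ("CDK4 Amplification" yields two
    tokens) and duplicates across the three lists are kept, so ``dwl`` is the
    sum of the per-list token counts.
    """
    terms: list[str] = []
    for source in (doc.chemicals, doc.mesh_headings, doc.keywords):
        for term in source:
            terms.extend(tokenize(term))
    return Wordlist(tuple(terms))


# ---------------------------------------------------------------------------
# collection I/O

_JSONL_FIELDS = ("pmid", "title", "abstract", "chemicals", "mesh_headings",
                 "keywords")


def _document_from_mapping(record: dict, index: int) -> Document:
    try:
        return Document(
            pmid=str(record["pmid"]),
            title=record.get("title", "") or "",
            abstract=record.get("abstract", "") or "",
            chemicals=tuple(record.get("chemicals") or ()),
            mesh_headings=tuple(record.get("mesh_headings") or ()),
            keywords=tuple(record.get("keywords") or ()),
        )
    except KeyError as exc:
        raise CollectionError(f"record {index}: missing field {exc}") from exc


def _read_jsonl(path: Path) -> list[Document]:
    docs = []
    with path.open(encoding="utf-8") as handle:
        for index, line in enumerate(handle):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CollectionError(f"record {index}: malformed JSON ({exc})") from exc
            docs.append(_document_from_mapping(record, index))
    return docs


def _text_of(node) -> str:
    return "".join(node.itertext()) if node is not None else ""


def _read_medline_xml(path: Path) -> list[Document]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CollectionError(f"malformed XML: {exc}") from exc
    docs = []
    for index, article in enumerate(tree.iter("PubmedArticle")):
        pmid = _text_of(article.find(".//PMID")).strip()
        if not pmid:
            raise CollectionError(f"record {index}: missing PMID")
        title = _text_of(article.find(".//ArticleTitle"))
        abstract = " ".join(
            _text_of(node) for node in article.findall(".//Abstract/AbstractText"))
        chemicals = [
            _text_of(node)
            for node in article.findall(".//ChemicalList/Chemical/NameOfSubstance")]
        mesh = [
            _text_of(node)
            for node in article.findall(".//MeshHeadingList/MeshHeading/DescriptorName")]
        keywords = [_text_of(node) for node in article.findall(".//KeywordList/Keyword")]
        docs.append(Document(pmid, title, abstract,
                             tuple(chemicals), tuple(mesh), tuple(keywords)))
    return docs


def read_collection(path: str | Path, dialect: str = "jsonl") -> list[Document]:
    """Read a document collection.

    ``dialect`` is ``"jsonl"`` (one object per line with the canonical field
    names) or ``"medline_xml"`` (PubmedArticle records; only the six fields the
    pipeline uses are mapped).  Duplicate PMIDs raise :class:`CollectionError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jsonl":
        docs = _read_jsonl(path)
    elif dialect == "medline_xml":
        docs = _read_medline_xml(path)
    else:
        raise ValueError(f"unknown collection dialect {dialect!r}")
    seen: set[str] = set()
    for doc in docs:
        if doc.pmid in seen:
            raise CollectionError(f"duplicate pmid {doc.pmid!r} in collection")
        seen.add(doc.pmid)
    return docs


def write_collection_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for doc in docs:
            record = {
                "pmid": doc.pmid,
                "title": doc.title,
                "abstract": doc.abstract,
                "chemicals": list(doc.chemicals),
                "mesh_headings": list(doc.mesh_headings),
                "keywords": list(doc.keywords),
            }
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# topics

def read_topics(path: str | Path) -> list[Topic]:
    """Read topics from JSON: a list of objects with topic_id, disease,
    genes, and optional demographic fields."""
    with Path(path).open(encoding="utf-8") as handle:
        raw = json.load(handle)
    topics = []
    seen: set[str] = set()
    for entry in raw:
        topic = Topic(
            topic_id=str(entry["topic_id"]),
            disease=entry["disease"],
            genes=list(entry["genes"]),
            demographic_raw=entry.get("demographic", "") or entry.get("demographic_raw", ""),
            expansion_terms=list(entry.get("expansion_terms", ())),
        )
        if topic.topic_id in seen:
            raise CollectionError(f"duplicate topic_id {topic.topic_id!r}")
        seen.add(topic.topic_id)
        topics.append(topic)
    return topics


def write_topics(topics: Iterable[Topic], path: str | Path) -> None:
    payload = [
        {
            "topic_id": t.topic_id,
            "disease": t.disease,
            "genes": list(t.genes),
            "demographic": t.demographic_raw,
            "expansion_terms": list(t.expansion_terms),
        }
        for t in topics
    ]
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# qrels

def read_qrels(path: str | Path) -> list[QrelEntry]:
    """Parse whitespace-delimited qrels lines ``topic 0 pmid grade``."""
    entries = []
    seen: set[tuple[str, str]] = set()
    with Path(path).open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CollectionError(f"qrels line {lineno}: expected 4 fields")
            topic_id, _, pmid, grade = parts
            key = (topic_id, pmid)
            if key in seen:
                raise CollectionError(
                    f"qrels line {lineno}: duplicate judgment for {key}")
            seen.add(key)
            entries.append(QrelEntry(topic_id, pmid, int(grade)))
    return entries


def write_qrels(entries: Iterable[QrelEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for entry in entries:
            handle.write(f"{entry.topic_id} 0 {entry.pmid} {entry.grade}\n")


# ---------------------------------------------------------------------------
# runs

def _validate_run(entries: Sequence[RunEntry]) -> None:
    by_topic: dict[str, list[RunEntry]] = {}
    for entry in entries:
        by_topic.setdefault(entry.topic_id, []).append(entry)
    for topic_id, rows in by_topic.items():
        ranks = sorted(row.rank for row in rows)
        if ranks != list(range(1, len(rows) + 1)):
            raise CollectionError(
                f"topic {topic_id}: ranks must be 1..{len(rows)} without gaps")
        pmids = [row.pmid for row in rows]
        if len(set(pmids)) != len(pmids):
            raise CollectionError(f"topic {topic_id}: duplicate pmid in run")
        ordered = sorted(rows, key=lambda r: r.rank)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.score > prev.score:
                raise CollectionError(
                    f"topic {topic_id}: scores increase with rank at {cur.pmid}")


def read_run(path: str | Path) -> list[RunEntry]:
    """Parse TREC run lines ``topic Q0 pmid rank score tag`` and validate
    rank contiguity, score monotonicity and pmid uniqueness per topic."""
    entries = []
    with Path(path).open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise CollectionError(f"run line {lineno}: expected 6 fields")
            topic_id, _, pmid, rank, score, tag = parts
            entries.append(RunEntry(topic_id, pmid, int(rank), float(score), tag))
    _validate_run(entries)
    return entries


def write_run(entries: Sequence[RunEntry], path: str | Path) -> None:
    _validate_run(entries)
    with Path(path).open("w", encoding="utf-8") as handle:
        for entry in entries:
            # repr round-trips floats exactly, so read(write(x)) == x
            handle.write(f"{entry.topic_id} Q0 {entry.pmid} {entry.rank} "
                         f"{entry.score!r} {entry.run_tag}\n")
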