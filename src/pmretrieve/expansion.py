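"""Query expansion from a declarative synonym table.

Expansion maps topic morphemes (disease name, gene symbols) to additional
search morphemes via a user-supplied table — a JSON object from normalized
source term to a list of synonyms, standing in for a MeSH-derived synonym
resource.  Expansion always appends the literal "human" search element,
which distinguishes human precision-medicine studies from animal work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import Topic

__all__ = ["ExpansionTable", "expand_topic", "HUMAN_ELEMENT"]

HUMAN_ELEMENT = "human"


def _normalize_key(term: str) -> str:
    return " ".join(term.lower().split())


@dataclass
class ExpansionTable:
    """Source term -> expansion synonyms, with normalized (lowercased,
    whitespace-collapsed) keys and no self-loops."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, list[str]] = {}
        for key, synonyms in self.entries.items():
            nkey = _normalize_key(key)
            kept = [s for s in synonyms if _normalize_key(s) != nkey]
            normalized[nkey] = kept
        self.entries = normalized

    def lookup(self, term: str) -> list[str]:
        return self.entries.get(_normalize_key(term), [])

    @classmethod
    def load(cls, path: str | Path) -> "ExpansionTable":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2) + "\n",
                              encoding="utf-8")


def _split_gene_morpheme(gene: str) -> list[str]:
    """"BRAF (V600E)" -> ["BRAF", "V600E"]: name and variant are separable
    morphemes for lookup purposes."""
    parts = gene.replace("(", " ").replace(")", " ").split()
    out, seen = [], set()
    for part in parts:
        if part.lower() not in seen:
            seen.add(part.lower())
            out.append(part)
    return out


def expand_topic(topic: Topic, table: ExpansionTable | None = None) -> Topic:
    """Populate a topic's expansion terms from the table (in place).

    Looks up the disease and each gene (name and variant separately),
    deduplicates, and appends the "human" element.  Original morphemes are
    never modified, and re-expanding an already expanded topic is a no-op
    (idempotent).
    """
    if table is None:
        table = ExpansionTable()
    disease_expansions = list(table.lookup(topic.disease))
    gene_expansions: list[str] = []
    for gene in topic.genes:
        gene_expansions.extend(table.lookup(gene))
        for piece in _split_gene_morpheme(gene):
            gene_expansions.extend(table.lookup(piece))

    existing = {_normalize_key(t) for t in topic.expansion_terms}
    for term in disease_expansions + gene_expansions + [HUMAN_ELEMENT]:
        if _normalize_key(term) not in existing:
            existing.add(_normalize_key(term))
            topic.expansion_terms.append(term)

    disease_existing = {_normalize_key(t) for t in topic.disease_expansion_terms}
    for term in disease_expansions:
        if _normalize_key(term) not in disease_existing:
            disease_existing.add(_normalize_key(term))
            topic.disease_expansion_terms.append(term)
    return topic
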