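"""Synthetic collections with planted relevance structure.

Every pipeline stage is exercised against generated data: documents whose
abstracts and controlled-vocabulary lists contain a topic's disease and gene
tokens at controllable rates, demographic phrases rendered the way clinical
abstracts state them ("a 38-year-old male"), hard distractors that mention
the disease without the gene (the annotation pattern that motivates the
co-word score), and matching topics, qrels and an expansion table.
Background text is drawn from a closed vocabulary with Zipf-like
frequencies so IDF values are non-degenerate.  Everything is deterministic
under the spec's seed.

This emulates the *structure* of a PubMed-derived collection — field
inventory, planted signal, graded judgments — not its language or scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Document, QrelEntry, Topic
from .expansion import ExpansionTable

__all__ = ["FixtureSpec", "Fixture", "generate_fixture",
           "generate_clustered_abstract"]

_DEFAULT_MIX = {"Middle age": 0.4, "Aged": 0.3, "Young": 0.3}

# representative integer age ranges per adult-ish category (years)
_AGE_RANGES = {
    "Young": (19, 34), "Middle age": (35, 59), "Aged": (60, 79),
    "Aged 80": (80, 95), "Adolescent": (13, 18), "Child": (6, 12),
    "Preschool": (2, 5),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic collection."""

    n_docs: int = 500
    n_topics: int = 5
    n_relevant_per_topic: int = 10
    vocab_size: int = 200
    abstract_length_range: tuple[int, int] = (40, 80)
    wordlist_length_range: tuple[int, int] = (4, 10)
    signal_strength: float = 3.0
    coword_fraction: float = 1.0
    distractor_fraction: float = 0.1
    demographic_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relevant_per_topic * self.n_topics > self.n_docs:
            raise ValueError("not enough documents for the requested relevant sets")
        if not 0 <= self.coword_fraction <= 1:
            raise ValueError("coword_fraction must lie in [0, 1]")
        if not 0 <= self.distractor_fraction <= 1:
            raise ValueError("distractor_fraction must lie in [0, 1]")
        total = sum(self.demographic_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("demographic_mix probabilities must sum to 1")
        for category in self.demographic_mix:
            if category not in _AGE_RANGES:
                raise ValueError(f"unsupported demographic category {category!r}")


@dataclass
class Fixture:
    documents: list[Document]
    topics: list[Topic]
    qrels: list[QrelEntry]
    expansion_table: ExpansionTable
    relevant_pmids: dict[str, list[str]]


def _zipf_vocab(vocab_size: int) -> tuple[list[str], np.ndarray]:
    words = [f"w{i:04d}" for i in range(vocab_size)]
    weights = 1.0 / np.arange(1, vocab_size + 1)
    return words, weights / weights.sum()


def _demographic_phrase(rng: np.random.Generator, category: str,
                        gender: str) -> str:
    lo, hi = _AGE_RANGES[category]
    age = int(rng.integers(lo, hi + 1))
    noun = {"Male": "male", "Female": "female"}[gender]
    return f"{age}-year-old {noun}"


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate (collection, topics, qrels, expansion table).

    Each topic gets a unique disease and a gene with a variant; its relevant
    documents carry both in the abstract at a max(1, Poisson(signal_strength))
    rate and, for a ``coword_fraction`` share, in the MeSH wordlist as well,
    plus a demographic phrase consistent with the topic.  A
    ``distractor_fraction`` share of the remaining documents mentions the
    disease but not the gene ("Missing Gene" pattern) and is judged
    non-relevant (grade 0); planted relevant documents are judged grade 2.
    With ``signal_strength = 0`` no planting happens at all, so relevant and
    irrelevant documents are statistically indistinguishable and retrieval
    falls to the topical base rate.
    """
    rng = np.random.default_rng(spec.seed)
    words, probs = _zipf_vocab(spec.vocab_size)
    categories = sorted(spec.demographic_mix)
    mix = np.array([spec.demographic_mix[c] for c in categories])

    topics: list[Topic] = []
    for t in range(spec.n_topics):
        category = categories[int(rng.choice(len(categories), p=mix))]
        gender = "Male" if rng.random() < 0.5 else "Female"
        topics.append(Topic(
            topic_id=f"T{t + 1}",
            disease=f"malady{t}",
            genes=[f"gen{t}x (v{t}00e)"],
            demographic_raw=_demographic_phrase(rng, category, gender),
        ))

    expansion = ExpansionTable({
        topic.disease: [f"syn{t}"] for t, topic in enumerate(topics)
    })

    # fixed-width pmids keep ascending-pmid tie-breaks stable
    pmids = [f"{100000 + i}" for i in range(spec.n_docs)]

    # assign document roles: per-topic relevant blocks, then distractors
    roles: list[tuple[str, Topic | None]] = [("background", None)] * spec.n_docs
    order = rng.permutation(spec.n_docs)
    cursor = 0
    for topic in topics:
        for _ in range(spec.n_relevant_per_topic):
            roles[order[cursor]] = ("relevant", topic)
            cursor += 1
    n_rest = spec.n_docs - cursor
    n_distract = int(round(spec.distractor_fraction * n_rest))
    for i in range(n_distract):
        topic = topics[int(rng.integers(len(topics)))]
        roles[order[cursor + i]] = ("distractor", topic)

    documents: list[Document] = []
    qrels: list[QrelEntry] = []
    relevant_pmids: dict[str, list[str]] = {t.topic_id: [] for t in topics}
    for pmid, (role, topic) in zip(pmids, roles):
        length = int(rng.integers(*spec.abstract_length_range))
        tokens = list(rng.choice(words, size=length, p=probs))
        wl_length = int(rng.integers(*spec.wordlist_length_range))
        mesh = list(rng.choice(words, size=wl_length, p=probs))
        title_tokens = list(rng.choice(words, size=6, p=probs))

        planted = spec.signal_strength > 0
        if role in ("relevant", "distractor") and planted:
            assert topic is not None
            disease = topic.disease
            n_inject = max(1, rng.poisson(spec.signal_strength))
            for _ in range(n_inject):
                tokens.insert(int(rng.integers(len(tokens) + 1)), disease)
            if role == "relevant":
                gene_tokens = topic.genes[0].replace("(", " ").replace(")", " ").split()
                n_inject = max(1, rng.poisson(spec.signal_strength))
                for _ in range(n_inject):
                    for gt in gene_tokens:
                        tokens.insert(int(rng.integers(len(tokens) + 1)), gt.lower())
                if rng.random() < 0.5:
                    tokens.insert(int(rng.integers(len(tokens) + 1)),
                                  expansion.lookup(disease)[0])
                phrase = topic.demographic_raw
                tokens.append(f"a {phrase} patient presented .")
                if rng.random() < spec.coword_fraction:
                    mesh.extend([disease] + [gt.lower() for gt in gene_tokens])
                mesh.append("Humans")
                title_tokens.insert(0, disease)

        abstract = " ".join(tokens)
        documents.append(Document(
            pmid=pmid,
            title=" ".join(title_tokens),
            abstract=abstract,
            chemicals=(),
            mesh_headings=tuple(mesh),
            keywords=(),
        ))
        if role == "relevant" and topic is not None:
            qrels.append(QrelEntry(topic.topic_id, pmid, 2))
            relevant_pmids[topic.topic_id].append(pmid)
        elif role == "distractor" and topic is not None:
            qrels.append(QrelEntry(topic.topic_id, pmid, 0))

    return Fixture(documents, topics, qrels, expansion, relevant_pmids)


def generate_clustered_abstract(n_groups: int, sentences_per_group: int,
                                seed: int = 0) -> tuple[str, list[int]]:
    """A synthetic abstract of ``n_groups`` topical sentence groups.

    Each group draws from its own disjoint token pool, so a bag-of-words
    embedder separates the groups cleanly; the returned labels give the
    ground-truth group of each sentence for cluster-recovery assertions.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    pools = [[f"g{g}w{j}" for j in range(12)] for g in range(n_groups)]
    sentences, labels = [], []
    for g in range(n_groups):
        for _ in range(sentences_per_group):
            n_tokens = int(rng.integers(6, 10))
            tokens = list(rng.choice(pools[g], size=n_tokens))
            sentences.append(" ".join(tokens).capitalize() + ".")
            labels.append(g)
    order = rng.permutation(len(sentences))
    text = " ".join(sentences[i] for i in order)
    return text, [labels[i] for i in order]
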