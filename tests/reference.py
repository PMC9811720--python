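"""Independent reference implementations used as test oracles.

Literal transcriptions of the scoring formulas and brute-force metric
definitions, written against plain token lists with no inverted index and no
imports from the package under test, so agreement is evidence about the
implementation path, not a tautology.
"""

from __future__ import annotations

import math
import re


def toks(text: str) -> list[str]:
    return re.sub(r"[^\w]+", " ", text.lower()).split()


# ---------------------------------------------------------------------------
# scoring: corpora are lists of (abstract_tokens, wordlist_tokens)

def naive_idf(token: str, field_token_lists: list[list[str]]) -> float:
    n = len(field_token_lists)
    df = sum(1 for tokens in field_token_lists if token in tokens)
    if df == 0 or df == n:
        return 0.0
    return math.log(n / df)


def naive_abstract_score(query_tokens: list[str], doc_index: int,
                         abstracts: list[list[str]],
                         k1: float = 1.2, b1: float = 0.75) -> float:
    doc = abstracts[doc_index]
    dl = len(doc)
    avgdl = sum(len(a) for a in abstracts) / len(abstracts)
    score = 0.0
    for q in query_tokens:
        f = doc.count(q)
        if f == 0:
            continue
        idf = naive_idf(q, abstracts)
        norm = 1 - b1 + (b1 * dl / avgdl if avgdl > 0 else 0.0)
        score += idf * f * (k1 + 1) / (f + k1 * norm)
    return score


def naive_wordlist_score(query_tokens: list[str], doc_index: int,
                         wordlists: list[list[str]],
                         k2: float = 1.2, b2: float = 0.75) -> float:
    doc = wordlists[doc_index]
    tfw = sum(naive_idf(q, wordlists) for q in query_tokens if q in doc)
    if tfw == 0.0:
        return 0.0
    dwl = len(doc)
    avgdwl = sum(len(w) for w in wordlists) / len(wordlists)
    norm = 1 - b2 + (b2 * dwl / avgdwl if avgdwl > 0 else 0.0)
    return tfw * (k2 + 1) / (tfw + k2 * norm)


def naive_coword_score(disease_tokens: list[str],
                       gene_token_groups: list[list[str]], doc_index: int,
                       abstracts: list[list[str]],
                       wordlists: list[list[str]]) -> float:
    union = set(abstracts[doc_index]) | set(wordlists[doc_index])
    if not any(t in union for t in disease_tokens):
        return 0.0
    score = 0.0
    for group in gene_token_groups:
        occurring = [t for t in group if t in union]
        for token in occurring:
            if token in wordlists[doc_index]:
                score += naive_idf(token, wordlists)
            else:
                score += naive_idf(token, abstracts)
    return score


# ---------------------------------------------------------------------------
# metrics: brute-force definitions

def bf_precision_at_k(ranked: list[str], relevant: set[str], k: int) -> float:
    return len([p for p in ranked[:k] if p in relevant]) / k


def bf_r_precision(ranked: list[str], relevant: set[str]) -> float:
    if not relevant:
        return 0.0
    r = len(relevant)
    return len([p for p in ranked[:r] if p in relevant]) / r


def bf_average_precision(ranked: list[str], relevant: set[str]) -> float:
    if not relevant:
        return 0.0
    precisions = []
    for i, pmid in enumerate(ranked):
        if pmid in relevant:
            precisions.append(bf_precision_at_k(ranked, relevant, i + 1))
    return sum(precisions) / len(relevant)


def bf_ndcg(ranked: list[str], grades: dict[str, int]) -> float:
    def dcg(grade_sequence: list[int]) -> float:
        return sum((2 ** g - 1) / math.log2(i + 2)
                   for i, g in enumerate(grade_sequence))

    actual = dcg([grades.get(p, 0) for p in ranked])
    ideal = dcg(sorted((g for g in grades.values() if g > 0), reverse=True))
    return actual / ideal if ideal > 0 else 0.0
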