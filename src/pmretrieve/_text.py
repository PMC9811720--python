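"""Token normalization and sentence splitting shared across modules.

Index tokens are lowercased, punctuation-stripped words; stemming is applied
only where gender words are matched (see :mod:`pmretrieve.demographics`).
"""

from __future__ import annotations

import re

__all__ = ["tokenize", "split_sentences"]

_PUNCT = re.compile(r"[^\w]+", re.UNICODE)

# Dotted/abbreviated forms a sentence boundary must not follow.  Lowercase,
# final period stripped.
_ABBREVIATIONS = {
    "i.e", "e.g", "etc", "vs", "cf", "al", "fig", "figs", "eq", "eqs",
    "dr", "mr", "mrs", "ms", "st", "no", "ca", "approx", "resp",
}

_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def tokenize(text: str) -> list[str]:
    """Normalize free text to index tokens.

    Lowercases, collapses every punctuation run to a single space, and splits
    on whitespace, so ``"38-year-old male"`` becomes
    ``["38", "year", "old", "male"]``.
    """
    if not text:
        return []
    return _PUNCT.sub(" ", text.lower()).split()


def _ends_with_abbreviation(fragment: str) -> bool:
    last = fragment.rsplit(None, 1)[-1] if fragment.split() else fragment
    return last.rstrip(".").lower() in _ABBREVIATIONS


def split_sentences(text: str) -> list[str]:
    """Split an abstract into sentences.

    Rule-based: boundaries are whitespace runs preceded by ``.``, ``!`` or
    ``?``, except after common abbreviations ("i.e.", "e.g.", "et al.", ...).
    The concatenation of the returned sentences reproduces the input modulo
    whitespace; an empty or blank input yields an empty list.
    """
    if not text or not text.strip():
        return []
    pieces: list[str] = []
    start = 0
    for match in _BOUNDARY.finditer(text):
        candidate = text[start:match.start()]
        if _ends_with_abbreviation(candidate):
            continue
        pieces.append(candidate)
        start = match.end()
    tail = text[start:]
    if tail.strip():
        pieces.append(tail.strip())
    return [p.strip() for p in pieces if p.strip()]
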