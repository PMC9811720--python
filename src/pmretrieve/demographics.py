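"""Age and gender extraction and classification.

Patient cases and MEDLINE abstracts describe demographics in free text
("a 38-year-old male", "an 18-month-old infant").  This module extracts a
numeric age via regular expressions, maps it onto the standard age
categories (Newborn through Aged 80), and stem-matches gender words.  When
the abstract carries no demographic text, the document's MeSH check-tags
(Female, Middle Aged, "Aged, 80 and over", ...) act as a fallback.

Age categories partition [0, inf) with half-open intervals [lower, upper),
so a 60-year-old is "Aged", not "Middle age".  "Fetus" and "Adult" are
assigned only from the literal tokens, since a numeric age always has a
finer category than "Adult".
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path

from ._text import tokenize
from .corpus import Document

__all__ = [
    "DemographicProfile", "AGE_CATEGORIES",
    "extract_age", "classify_age", "extract_gender",
    "demographic_profile", "profile_from_text", "demographic_query_tokens",
    "load_mesh_map", "default_mesh_map",
]

AGE_CATEGORIES = (
    "Fetus", "Newborn", "Infant", "Preschool", "Child", "Adolescent",
    "Young", "Middle age", "Aged", "Aged 80", "Adult", "Unknown",
)

# (upper bound in years, category); intervals are [previous upper, upper)
_AGE_INTERVALS = (
    (1 / 12, "Newborn"),
    (2.0, "Infant"),
    (6.0, "Preschool"),
    (13.0, "Child"),
    (19.0, "Adolescent"),
    (35.0, "Young"),
    (60.0, "Middle age"),
    (80.0, "Aged"),
    (float("inf"), "Aged 80"),
)

_AGE_PATTERN = re.compile(
    r"(\d+(?:\.\d+)?)[\s-]*(year|month|week)s?[\s-]*old",
    re.IGNORECASE)

_UNIT_IN_YEARS = {"year": 1.0, "month": 1 / 12, "week": 1 / 52}

_FEMALE_STEMS = {"female", "woman", "girl"}
_MALE_STEMS = {"male", "man", "boy"}


@dataclass(frozen=True)
class DemographicProfile:
    age_years: float | None
    age_category: str
    gender: str
    source: str  # topic_text | abstract_regex | mesh_fallback


def extract_age(text: str) -> float | None:
    """Return the first age expression in ``text`` in years, or None.

    Matches "N-year(s)-old", "N year(s) old", and the month/week variants,
    converting months and weeks to fractional years.
    """
    match = _AGE_PATTERN.search(text or "")
    if match is None:
        return None
    value = float(match.group(1))
    return value * _UNIT_IN_YEARS[match.group(2).lower()]


def classify_age(age_years: float) -> str:
    """Map a numeric age in years onto its category (half-open intervals)."""
    if age_years < 0:
        raise ValueError("age must be non-negative")
    for upper, category in _AGE_INTERVALS:
        if age_years < upper:
            return category
    return "Aged 80"  # unreachable: last interval is unbounded


def _gender_stem(token: str) -> str:
    """Reduce a token to the base form the gender vocabularies use.

    Handles the common inflections (women -> woman, girls -> girl) without a
    full stemmer; only gender words are ever stemmed in this package.
    """
    irregular = {"women": "woman", "men": "man"}
    token = irregular.get(token, token)
    if token.endswith("s") and token[:-1] in (_FEMALE_STEMS | _MALE_STEMS):
        token = token[:-1]
    return token


def extract_gender(text: str) -> str:
    """Stem-match gender words; the first occurrence wins when both genders
    appear.  Returns "Female", "Male" or "Unknown"."""
    for token in tokenize(text or ""):
        stem = _gender_stem(token)
        if stem in _FEMALE_STEMS:
            return "Female"
        if stem in _MALE_STEMS:
            return "Male"
    return "Unknown"


def _classify_text(text: str) -> tuple[float | None, str, str]:
    """(age_years, age_category, gender) from free text alone."""
    age = extract_age(text)
    tokens = set(tokenize(text or ""))
    if age is not None:
        category = classify_age(age)
    elif "fetus" in tokens or "fetal" in tokens:
        category = "Fetus"
    elif "adult" in tokens or "adults" in tokens:
        category = "Adult"
    else:
        category = "Unknown"
    return age, category, extract_gender(text)


def profile_from_text(text: str, source: str = "topic_text") -> DemographicProfile:
    """Build a profile from topic or abstract text only (no MeSH fallback)."""
    age, category, gender = _classify_text(text)
    return DemographicProfile(age, category, gender, source)


def load_mesh_map(path: str | Path) -> dict[str, dict[str, str]]:
    """Load an editable MeSH term -> demographic category table (JSON)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


def default_mesh_map() -> dict[str, dict[str, str]]:
    text = (importlib_resources.files("pmretrieve")
            .joinpath("resources/mesh_map.json").read_text(encoding="utf-8"))
    return json.loads(text)


def demographic_profile(doc: Document,
                        mesh_map: dict[str, dict[str, str]] | None = None
                        ) -> DemographicProfile:
    """Extract the demographic profile of a document.

    Abstract (plus title) regex/stem extraction runs first; fields it cannot
    fill are looked up in the document's MeSH headings via ``mesh_map``.
    Anything still missing is Unknown.
    """
    if mesh_map is None:
        mesh_map = default_mesh_map()
    text = f"{doc.title} {doc.abstract}"
    age, category, gender = _classify_text(text)
    source = "abstract_regex"
    if category == "Unknown" or gender == "Unknown":
        mesh_category, mesh_gender = "Unknown", "Unknown"
        for heading in doc.mesh_headings:
            entry = mesh_map.get(heading)
            if not entry:
                continue
            if "age_category" in entry and mesh_category == "Unknown":
                mesh_category = entry["age_category"]
            if "gender" in entry and mesh_gender == "Unknown":
                mesh_gender = entry["gender"]
        used_mesh = False
        if category == "Unknown" and mesh_category != "Unknown":
            category = mesh_category
            used_mesh = True
        if gender == "Unknown" and mesh_gender != "Unknown":
            gender = mesh_gender
            used_mesh = True
        if used_mesh and age is None and extract_gender(text) == "Unknown":
            source = "mesh_fallback"
    return DemographicProfile(age, category, gender, source)


def demographic_query_tokens(profile: DemographicProfile) -> list[str]:
    """Render a profile as query morphemes (lowercase category and gender
    tokens), e.g. Middle age / Male -> ["middle", "age", "male"]."""
    tokens: list[str] = []
    if profile.age_category not in ("", "Unknown"):
        tokens.extend(tokenize(profile.age_category))
    if profile.gender not in ("", "Unknown"):
        tokens.append(profile.gender.lower())
    return tokens
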