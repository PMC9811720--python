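from __future__ import annotations

import pytest

from pmretrieve.bm25 import build_index
from pmretrieve.corpus import Document, Topic
from pmretrieve.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic collection: 500 docs, 5 topics, 10 relevant
    each, strong planted signal."""
    return generate_fixture(FixtureSpec(seed=123))


@pytest.fixture(scope="session")
def default_index(default_fixture):
    return build_index(default_fixture.documents)


@pytest.fixture()
def toy_corpus():
    """Four equal-length documents; the query token "q" occurs twice in doc
    d1 only, so df=1 and dl=avgdl — the hand-computed scoring setup."""
    filler = "x0 x1 x2 x3 x4 x5 x6 x7".split()
    docs = [
        Document("d1", "", " ".join(["q", "q"] + filler)),
        Document("d2", "", " ".join(filler + ["y0", "y1"])),
        Document("d3", "", " ".join(filler + ["y2", "y3"])),
        Document("d4", "", " ".join(filler + ["y4", "y5"])),
    ]
    return docs


@pytest.fixture()
def topic_q():
    return Topic("t1", disease="q", genes=["absentgene"])
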