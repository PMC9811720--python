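import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmretrieve.bm25 import (IndexStats, ScoringParams, abstract_score,
                             build_index, coword_score, idf, minmax_normalize,
                             stage1_retrieve, wordlist_score)
from pmretrieve.corpus import Document, Topic

from .reference import (naive_abstract_score, naive_coword_score, naive_idf,
                        naive_wordlist_score)

LN4 = math.log(4)


def stats_for(n_docs, df_abstract=None, df_wordlist=None):
    return IndexStats(n_docs, df_abstract or {}, df_wordlist or {}, 10.0, 5.0)


class TestIdf:
    def test_token_in_every_document_scores_zero(self):
        assert idf("t", "abstract", stats_for(4, {"t": 4})) == 0.0

    def test_absent_token_scores_zero(self):
        assert idf("t", "abstract", stats_for(4, {})) == 0.0

    def test_closed_form(self):
        assert idf("t", "abstract", stats_for(4, {"t": 1})) == pytest.approx(LN4)
        assert idf("t", "wordlist", stats_for(8, None, {"t": 2})) == \
            pytest.approx(math.log(4))


class TestAbstractScore:
    def test_no_query_token_in_abstract_scores_zero(self, toy_corpus, topic_q):
        index = build_index(toy_corpus)
        assert abstract_score(topic_q, toy_corpus[1], index) == 0.0

    def test_hand_computed_value(self, toy_corpus, topic_q):
        # df=1 of 4, f=2, dl=avgdl: ln4 * 2*(k1+1)/(2+k1) with k1=1.2
        index = build_index(toy_corpus)
        expected = LN4 * (2 * 2.2) / (2 + 1.2)
        assert abstract_score(topic_q, toy_corpus[0], index) == \
            pytest.approx(1.9061547465398494, abs=1e-12)
        assert expected == pytest.approx(1.9061547465398494)

    def test_saturation_limit_is_idf_times_k1_plus_1(self, topic_q):
        # a term repeated many times contributes at most IDF * (k1 + 1)
        filler = " ".join(f"x{i}" for i in range(10))
        docs = [Document("d1", "", " ".join(["q"] * 500)),
                Document("d2", "", filler), Document("d3", "", filler),
                Document("d4", "", filler)]
        # fix dl/avgdl = 1 via override so only saturation matters
        index = build_index(docs)
        params = ScoringParams(avgdl_override=500.0)
        value = abstract_score(topic_q, docs[0], index, params)
        assert value == pytest.approx(LN4 * 2.2, rel=1e-2)
        assert value < LN4 * 2.2

    def test_b1_zero_removes_length_dependence(self, topic_q):
        short = Document("d1", "", "q alpha")
        padded = Document("d2", "", "q " + " ".join(f"pad{i}" for i in range(50)))
        other = Document("d3", "", "beta gamma")
        index = build_index([short, padded, other])
        params = ScoringParams(b1=0.0)
        assert abstract_score(topic_q, short, index, params) == \
            pytest.approx(abstract_score(topic_q, padded, index, params))


class TestWordlistScore:
    def make_corpus(self):
        # four docs, all wordlists 3 tokens so dwl = avgdwl; "q" in d1 only
        docs = [Document("d1", mesh_headings=("q", "m1", "m2")),
                Document("d2", mesh_headings=("a", "b", "c")),
                Document("d3", mesh_headings=("d", "e", "f")),
                Document("d4", mesh_headings=("g", "h", "i"))]
        return docs, build_index(docs)

    def test_empty_wordlist_scores_zero(self, topic_q):
        docs = [Document("d1", "", "q"), Document("d2", "", "x")]
        index = build_index(docs)
        assert wordlist_score(topic_q, docs[0], index) == 0.0

    def test_hand_computed_value(self, topic_q):
        # tfw = ln4, dwl = avgdwl: ln4*(k2+1)/(ln4+k2) with k2=1.2
        docs, index = self.make_corpus()
        assert wordlist_score(topic_q, docs[0], index) == \
            pytest.approx(1.179234521913873, abs=1e-12)

    def test_monotone_in_tfw(self):
        docs, index = self.make_corpus()
        one = wordlist_score(Topic("t", "q", ["zz"]), docs[0], index)
        two = wordlist_score(Topic("t", "q", ["m1"]), docs[0], index)
        assert two > one > 0


class TestCowordScore:
    def make_corpus(self):
        docs = [
            Document("d1", "", "melanoma story braf v600e appears"),
            Document("d2", "", "melanoma alone no gene here x1"),
            Document("d3", "", "braf without disease mention x2"),
            Document("d4", "", "background words only here x3"),
        ]
        return docs, build_index(docs)

    def test_disease_absent_scores_zero(self):
        docs, index = self.make_corpus()
        topic = Topic("t", "melanoma", ["braf"])
        assert coword_score(topic, docs[2], index) == 0.0
        assert coword_score(topic, docs[3], index) == 0.0

    def test_single_qualifying_gene_contributes_its_idf(self):
        docs, index = self.make_corpus()
        topic = Topic("t", "melanoma", ["v600e"])
        # v600e occurs in 1 of 4 abstracts
        assert coword_score(topic, docs[0], index) == pytest.approx(LN4)

    def test_multiple_genes_sum(self):
        docs, index = self.make_corpus()
        topic = Topic("t", "melanoma", ["v600e", "braf"])
        # df(v600e)=1 -> ln4; df(braf)=2 -> ln2
        assert coword_score(topic, docs[0], index) == \
            pytest.approx(2.0794415416798357, abs=1e-12)

    def test_wordlist_occurrence_uses_wordlist_idf(self):
        docs = [
            Document("d1", "", "melanoma text", mesh_headings=("braf",)),
            Document("d2", "", "braf braf melanoma x"),
            Document("d3", "", "other things", mesh_headings=("braf",)),
            Document("d4", "", "unrelated", mesh_headings=("m",)),
        ]
        index = build_index(docs)
        topic = Topic("t", "melanoma", ["braf"])
        # braf is in d1's wordlist -> wordlist-field df (2 of 4), not abstract df
        assert coword_score(topic, docs[0], index) == pytest.approx(math.log(2))


class TestMinMax:
    def test_forced_endpoints_and_midpoint(self):
        assert minmax_normalize([2, 4, 6]) == [0.0, 0.5, 1.0]

    def test_constant_sequence_maps_to_zero(self):
        assert minmax_normalize([3, 3, 3]) == [0.0, 0.0, 0.0]

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            minmax_normalize([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_output_bounded_with_endpoints_attained(self, values):
        normed = minmax_normalize(values)
        assert all(0.0 <= v <= 1.0 for v in normed)
        if len(set(values)) >= 2:
            assert min(normed) == 0.0 and max(normed) == 1.0


def random_toy_corpus(rng, n_docs=None):
    vocab = [f"t{i}" for i in range(30)]
    n = n_docs or rng.randint(3, 20)
    docs = []
    for i in range(n):
        length = rng.randint(3, 30)
        abstract = " ".join(rng.choice(vocab) for _ in range(length))
        mesh = tuple(rng.choice(vocab) for _ in range(rng.randint(0, 5)))
        docs.append(Document(f"{i:03d}", "", abstract, mesh_headings=mesh))
    disease = rng.choice(vocab)
    genes = [rng.choice(vocab) for _ in range(rng.randint(1, 3))]
    return docs, Topic("t", disease, genes)


class TestOracleEquivalence:
    """The indexed implementation matches a literal formula transcription."""

    def test_scores_match_naive_reimplementation(self):
        rng = random.Random(42)
        for _ in range(10):
            docs, topic = random_toy_corpus(rng)
            index = build_index(docs)
            abstracts = [d.abstract.split() for d in docs]
            wordlists = [list(d.mesh_headings) for d in docs]
            query = list(dict.fromkeys(
                topic.disease.split() + [t for g in topic.genes for t in g.split()]))
            genes = [g.split() for g in topic.genes]
            for i, doc in enumerate(docs):
                assert abstract_score(topic, doc, index) == pytest.approx(
                    naive_abstract_score(query, i, abstracts), abs=1e-9)
                assert wordlist_score(topic, doc, index) == pytest.approx(
                    naive_wordlist_score(query, i, wordlists), abs=1e-9)
                assert coword_score(topic, doc, index) == pytest.approx(
                    naive_coword_score(topic.disease.split(), genes, i,
                                       abstracts, wordlists), abs=1e-9)


class TestStage1:
    def test_k_exceeding_collection_returns_all_ranked(self, toy_corpus, topic_q):
        index = build_index(toy_corpus)
        scored = stage1_retrieve(topic_q, toy_corpus, index, k=1000)
        assert [s.rank for s in scored] == [1, 2, 3, 4]
        assert scored[0].pmid == "d1"

    def test_ties_break_by_ascending_pmid(self):
        docs = [Document("b", "", "x"), Document("a", "", "x"),
                Document("c", "", "y")]
        index = build_index(docs)
        topic = Topic("t", "absent", ["alsoabsent"])
        scored = stage1_retrieve(topic, docs, index)
        assert [s.pmid for s in scored] == ["a", "b", "c"]

    def test_ordering_matches_brute_force(self):
        docs = [Document("1", "", "q q q filler one two"),
                Document("2", "", "q filler three four five"),
                Document("3", "", "filler six seven eight nine")]
        index = build_index(docs)
        topic = Topic("t", "q", ["none"])
        scored = stage1_retrieve(topic, docs, index)
        abstracts = [d.abstract.split() for d in docs]
        naive = sorted(range(3), key=lambda i: (-naive_abstract_score(["q"], i, abstracts),
                                                docs[i].pmid))
        assert [s.pmid for s in scored] == [docs[i].pmid for i in naive]
        # and norm_score spans [0, 1] over the pool
        assert scored[0].norm_score == 1.0 and scored[-1].norm_score == 0.0

    def test_ranking_invariant_under_affine_raw_sum_transform(self, default_fixture,
                                                              default_index):
        topic = default_fixture.topics[0]
        scored = stage1_retrieve(topic, default_fixture.documents,
                                 default_index, k=50)
        rescaled = sorted(scored, key=lambda s: (-(3.0 * s.raw_sum + 7.0), s.pmid))
        assert [s.pmid for s in rescaled] == [s.pmid for s in scored]


def test_scoring_params_validation():
    with pytest.raises(ValueError):
        ScoringParams(k1=-1)
    with pytest.raises(ValueError):
        ScoringParams(b1=1.5)
    with pytest.raises(ValueError):
        ScoringParams(avgdl_override=0.0)
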