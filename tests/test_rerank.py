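import pytest

from pmretrieve.bm25 import ScoredDoc, build_index, stage1_retrieve
from pmretrieve.corpus import Document, QrelEntry, Topic
from pmretrieve.pipeline import prepare_topic, rerank_candidates
from pmretrieve.rerank import (ConstantScorer, FusionConfig,
                               LexicalOverlapScorer, document_head,
                               fuse_and_rank, make_training_pairs, query_text,
                               read_pairs_tsv, score_pairs, write_pairs_tsv)
from pmretrieve.demographics import profile_from_text


def make_candidates(norm_scores):
    cands = []
    for i, norm in enumerate(norm_scores):
        cands.append(ScoredDoc(pmid=f"{100 + i}", norm_score=norm,
                               rank=i + 1))
    return cands


class TestScorePairs:
    def test_constant_scorer_gives_constant_similarities(self):
        topic = Topic("t", "melanoma", ["braf"])
        cands = make_candidates([1.0, 0.5, 0.0])
        docs = {c.pmid: Document(c.pmid, "title", "some abstract")
                for c in cands}
        sims = score_pairs(topic, cands, docs, ConstantScorer(0.5))
        assert sims == {c.pmid: 0.5 for c in cands}

    def test_overlap_scorer_hand_computed(self):
        topic = Topic("t", "melanoma", ["braf"], "64-year-old male")
        # query tokens: melanoma braf aged male -> 4 distinct
        docs = {
            "a": Document("a", "", "melanoma braf and much else"),
            "b": Document("b", "", "melanoma only text here"),
        }
        cands = [ScoredDoc("a"), ScoredDoc("b")]
        sims = score_pairs(topic, cands, docs, LexicalOverlapScorer())
        assert sims["a"] == pytest.approx(2 / 4)
        assert sims["b"] == pytest.approx(1 / 4)

    def test_empty_candidates_empty_map(self):
        topic = Topic("t", "melanoma", ["braf"])
        assert score_pairs(topic, [], {}, ConstantScorer()) == {}

    def test_scorer_failure_names_pmid(self):
        class Broken:
            max_len = 512
            deterministic = True

            def score(self, q, d):
                raise RuntimeError("boom")

        topic = Topic("t", "melanoma", ["braf"])
        cands = [ScoredDoc("777")]
        docs = {"777": Document("777", "", "text")}
        with pytest.raises(RuntimeError, match="777"):
            score_pairs(topic, cands, docs, Broken())


class TestFuseAndRank:
    def test_constant_similarities_preserve_stage1_order(self):
        cands = make_candidates([1.0, 0.7, 0.3, 0.0])
        order_before = [c.pmid for c in cands]
        sims = {c.pmid: 0.5 for c in cands}
        fused = fuse_and_rank(cands, sims)
        assert [c.pmid for c in fused] == order_before
        assert [c.rank for c in fused] == [1, 2, 3, 4]

    def test_cancellation_yields_pmid_order(self):
        # sim = 1 - norm_score: after normalization the fused scores tie,
        # so the final order is ascending pmid
        cands = make_candidates([1.0, 0.7, 0.3, 0.0])
        sims = {c.pmid: 1.0 - c.norm_score for c in cands}
        fused = fuse_and_rank(cands, sims)
        assert [c.pmid for c in fused] == sorted(c.pmid for c in cands)
        assert len({c.fused_score for c in fused}) == 1

    def test_four_doc_hand_arithmetic_with_both_fields(self):
        cands = make_candidates([1.0, 0.8, 0.4, 0.0])
        sims_a = {"100": 0.2, "101": 0.9, "102": 0.3, "103": 0.6}
        sims_t = {"100": 0.5, "101": 0.1, "102": 0.9, "103": 0.7}
        fused = fuse_and_rank(cands, sims_a, sims_t,
                              FusionConfig(use_abstract=True, use_title=True))
        # minmax(sims_a): 0.0, 1.0, 1/7, 4/7 ; minmax(sims_t): 0.5, 0.0, 1.0, 0.75
        expected = {"100": 1.0 + 0.0 + 0.5,
                    "101": 0.8 + 1.0 + 0.0,
                    "102": 0.4 + 1 / 7 + 1.0,
                    "103": 0.0 + 4 / 7 + 0.75}
        for cand in fused:
            assert cand.fused_score == pytest.approx(expected[cand.pmid])
        # 1.8 > 0.4 + 1/7 + 1.0 > 1.5 > 0 + 4/7 + 0.75
        assert [c.pmid for c in fused] == ["101", "102", "100", "103"]

    def test_fused_score_bounded_by_one_plus_enabled_fields(self):
        cands = make_candidates([0.9, 0.5, 0.1])
        sims = {c.pmid: 0.3 * i for i, c in enumerate(cands)}
        fused = fuse_and_rank(cands, sims)
        assert all(c.fused_score <= 2.0 + 1e-12 for c in fused)

    def test_missing_required_similarities_is_an_error(self):
        with pytest.raises(ValueError):
            fuse_and_rank(make_candidates([1.0]), None)


class TestRerankNeutrality:
    def test_constant_scorer_reproduces_stage1_on_fixture(self, default_fixture,
                                                          default_index):
        topic = prepare_topic(default_fixture.topics[0],
                              default_fixture.expansion_table)
        stage1 = stage1_retrieve(topic, default_fixture.documents,
                                 default_index, k=100)
        stage1_order = [c.pmid for c in stage1]
        docs = {d.pmid: d for d in default_fixture.documents}
        reranked = rerank_candidates(topic, stage1, docs, ConstantScorer(0.5))
        assert [c.pmid for c in reranked] == stage1_order


class TestTrainingPairs:
    def make_inputs(self):
        # mirrors the sibling structure: same disease/different gene and
        # same gene/different disease
        topics = [
            Topic("2017-1", "Liposarcoma", ["CDK4 Amplification"],
                  "38-year-old male"),
            Topic("2017-2", "Liposarcoma", ["MDM2 Amplification"],
                  "29-year-old male"),
            Topic("2018-1", "Melanoma", ["BRAF (V600E)"], "64-year-old male"),
            Topic("2018-2", "Colon cancer", ["BRAF (V600E)"],
                  "50-year-old female"),
        ]
        doc = Document("10101594", "CDK4 in liposarcoma",
                       "A 38-year-old adult male with cdk4 amplification.")
        qrels = [QrelEntry("2017-1", "10101594", 2)]
        return topics, qrels, {doc.pmid: doc}

    def test_positive_pair_matches_head_plus_summary_structure(self):
        topics, qrels, docs = self.make_inputs()
        pairs = make_training_pairs(topics, qrels, docs)
        positives = [p for p in pairs if p.label == 1]
        assert len(positives) == 1
        pos = positives[0]
        assert pos.pmid == "10101594" and pos.topic_id == "2017-1"
        assert pos.doc_text.startswith(
            "cdk4 amplification human middle age adult male")
        assert pos.query_text == "liposarcoma cdk4 amplification middle age male"

    def test_negative_from_sibling_differs_in_exactly_one_slot(self):
        topics, qrels, docs = self.make_inputs()
        pairs = make_training_pairs(topics, qrels, docs)
        negatives = [p for p in pairs if p.label == 0]
        assert len(negatives) == 1  # only 2017-2 shares the disease
        neg = negatives[0]
        assert neg.topic_id == "2017-2"
        assert neg.doc_text == [p for p in pairs if p.label == 1][0].doc_text
        assert "mdm2" in neg.query_text and "liposarcoma" in neg.query_text

    def test_topic_without_sibling_yields_only_positives(self):
        topics = [Topic("t1", "Unique disease", ["GENEX"], "40-year-old male")]
        doc = Document("1", "", "A 40-year-old male with genex.")
        pairs = make_training_pairs(topics, [QrelEntry("t1", "1", 2)],
                                    {"1": doc})
        assert all(p.label == 1 for p in pairs) and len(pairs) == 1

    def test_tsv_roundtrip(self, tmp_path):
        topics, qrels, docs = self.make_inputs()
        pairs = make_training_pairs(topics, qrels, docs)
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv(pairs, path)
        assert read_pairs_tsv(path) == pairs


def test_query_text_assembly_order():
    topic = Topic("2017-1", "Liposarcoma", ["CDK4 Amplification"],
                  "38-year-old male")
    assert query_text(topic) == "liposarcoma cdk4 amplification middle age male"


def test_document_head_includes_human_element():
    topic = Topic("t", "Liposarcoma", ["CDK4 Amplification"])
    profile = profile_from_text("38-year-old male")
    assert document_head(topic, profile) == \
        "cdk4 amplification human middle age adult male"
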