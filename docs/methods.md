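# Methods

## The retrieval model

A query is a patient case: a disease, one or more gene morphemes (a gene
symbol plus an optional variant, "BRAF (V600E)"), and a demographic
description. Retrieval is two-stage. Stage 1 scores every document with a
BM25 variant extended beyond the abstract: the *wordlist* score rewards
query terms appearing in the document's controlled vocabulary (chemical
list ∪ MeSH headings ∪ keywords), and the *co-word* score rewards
disease–gene co-occurrence, which separates on-topic articles from ones
that discuss the disease without the queried gene. Stage 2 rescoring uses a
sentence-pair similarity model over the (query, abstract) and optionally
(query, title) pairs, each abstract first compressed to the model's
512-token input budget by extractive summarization.

### Stage-1 scoring in detail

For query morphemes q₁…qₙ and document d:

- `AS(Q,d) = Σᵢ IDF_abs(qᵢ) · fᵢ(k₁+1) / (fᵢ + k₁(1 − b₁ + b₁·dl/avgdl))`
- `WS(Q,d) = tfw(k₂+1) / (tfw + k₂(1 − b₂ + b₂·dwl/avgdwl))`,
  `tfw = Σ {IDF_wl(qᵢ) : qᵢ in d's wordlist}`
- `CWS(Q,d) = Σᵢ IDF(gᵢ, d)` over genes satisfying the co-occurrence
  condition with the disease.

`IDF = ln(N/df)` with natural log (the base scales all scores uniformly and
cannot change a ranking). Degenerate document frequencies contribute zero:
`df = 0` (no evidence available) and `df = N` (ln 1 = 0). Query morphemes
are lowercased word tokens; a multi-word morpheme ("CDK4 Amplification")
scores per constituent token. The abstract field is title + abstract.

Three points are genuinely underdetermined in the method's published form
and are resolved here as package design choices:

1. **Co-occurrence field (union vs conjunction).** The disease and the gene
   must each occur at least once in the *union* of abstract+title tokens
   and wordlist tokens. The union reading was chosen because many MEDLINE
   records have sparse or empty keyword/chemical lists, and a conjunctive
   reading would zero the co-word score for them even when the abstract
   states the co-occurrence plainly.
2. **Which IDF for the gene in CWS.** A gene token occurring in the
   wordlist uses the wordlist-field df (controlled vocabulary is the
   higher-precision evidence); otherwise the abstract-field df. A
   multi-token gene counts as present when any of its tokens occurs and
   contributes the summed IDF of its occurring tokens, so a matched variant
   (rare, high IDF) counts for more than a matched symbol alone.
3. **Where expansion terms act.** Expansion synonyms are full-weight query
   morphemes in AS and WS, and disease synonyms also satisfy the disease
   side of the co-occurrence condition. Restricting them to CWS only would
   make expansion nearly inert on documents with empty wordlists.

The composite `x = AS + WS + CWS` is normalized per topic by
`x_norm = (x − min X)/(max X − min X)` over the candidate pool; a constant
pool maps to all zeros (any constant works — fusion adds a second
normalized score, so only differences matter). Ranking ties break by
ascending PMID so runs are reproducible byte-for-byte.

**Parameters.** `k₁ = k₂ = 1.2`, `b₁ = b₂ = 0.75` (dimensionless;
conventional BM25 settings — the published method used the same values and
delegated tuning to an external optimizer, which is out of scope here).
`avgdl`/`avgdwl` are computed from the indexed corpus; overrides exist for
reproducing a fixed configuration (the conventional published table lists
85 for the average abstract length and 13 for the average wordlist length,
with its two remark strings apparently swapped; overrides are applied by
position, and a warning notes the inconsistency when both are set in that
pattern). Candidate depth k = 1000.

### Demographics

Age is extracted with regular expressions over "N-year(s)-old",
"N month(s) old" and week variants (months/weeks converted to fractional
years), then classified into the standard categories: Newborn [0, 1/12),
Infant [1/12, 2), Preschool [2, 6), Child [6, 13), Adolescent [13, 19),
Young [19, 35), Middle age [35, 60), Aged [60, 80), Aged 80 [80, ∞) years.
The published category table shares its interval endpoints; half-open
intervals resolve every age to exactly one category deterministically
(60 → Aged). "Fetus" and "Adult" are assigned only from the literal tokens,
Adult only when no numeric age is present, since a numeric age always has a
finer category. Gender words (female/woman/girl, male/man/boy) are matched
at token level after a minimal inflection normalization (women → woman,
plural -s); only gender words are ever stemmed. When the abstract carries
no demographic text, the document's MeSH check-tags are consulted through
an editable JSON table (`resources/mesh_map.json`). The demographic enters
*scoring* as extra query morphemes — the category and gender tokens are
appended to the topic's expansion terms — because the published method
describes extraction and classification but not the scoring hook; appending
morphemes mirrors the head format of its training samples ("… human
middle-aged adult male") and keeps demographic mismatch a soft (score)
rather than hard (filter) signal.

### Query expansion

A declarative JSON table (term → synonyms) stands in for a MeSH-derived
synonym resource: tests and users control expansion exactly, and a
MeSH-derived table can be plugged in without code changes. Expansion looks
up the disease and each gene (name and variant separately), deduplicates,
never removes original morphemes, is idempotent, and always appends the
"human" search element that distinguishes human studies from animal work.

### Abstract extraction

Sentences are split rule-based (boundaries after `.!?`, guarded against
common abbreviations), embedded, k-means clustered into N groups, and
selected round-robin: each pass visits clusters in id order and takes the
unselected sentence nearest (Euclidean) its cluster centroid, stopping
before the first pick that would exceed the token budget; output preserves
original sentence order. Round-robin multi-pass filling is a design choice
— one-per-cluster can underfill a 512-token budget badly, and round-robin
fills it while keeping cluster coverage balanced. Tokens are
whitespace-delimited words (the downstream scorer budget is token-based).
Defaults: N = 4 (the method leaves N to the implementer; 4 covers the
background/methods/results/conclusion structure typical of structured
abstracts), budget = 512, k-means with k-means++ seeding, 10 restarts, 300
iterations, fixed seed — all deterministic. N is clamped to the sentence
count. The shipped embedder is a deterministic feature-hashing bag-of-words
encoder (D = 32, BLAKE2-hashed tokens, L2-normalized); it satisfies the
same `Embedder` protocol as a contextual sentence encoder (D = 768) and
separates topically distinct sentence groups by lexical overlap, which is
sufficient for clustering-based selection. Abstracts at or under the budget
pass through unchanged.

### Similarity reranking and training pairs

The pair scorer contract is `score(query_text, doc_text) → [0, 1]` with
inputs truncated to a per-field token budget (512 abstract / 128 title).
The shipped `LexicalOverlapScorer` returns the fraction of distinct query
tokens present in the document text; `ConstantScorer` exists to verify
rerank neutrality (constant similarity must reproduce the stage-1 ranking
exactly — it does, because adding a constant to every fused score is
order-preserving). Similarities are max–min normalized over each topic's
candidate pool before fusion, putting them on the stage-1 score's scale;
fusion weights are equal (1, 1, 1). The query text is
"disease genes demographic-category gender", lowercased.

Training pairs for an external pair-classifier trainer: a positive pairs a
relevant document (head + summary, where the head is "gene-tokens human
age-category [adult] gender") with its own topic's query; negatives reuse
the same document text against a sibling topic's query, where a sibling
shares the disease but differs in gene, or shares a gene but differs in
disease — so every negative differs from its positive in exactly one slot.
The transformer hyperparameters (4 epochs, batch 32/64, max length 512/128,
learning rate 5e-4 for abstract/title) are carried in `TrainingConfig` for
that trainer; fine-tuning itself is outside this package's test surface.

### Evaluation

Unjudged documents are non-relevant (the trec_eval convention); binary
metrics binarize at grade ≥ 1 (judgment scales here are 0/1/2); NDCG uses
exponential gain `2^grade − 1`, `log2(rank+1)` discount, full run depth;
means are macro-averages over topics; the PR curve samples the nine cutoffs
5–1000. The NDCG gain variant is stated because published numbers computed
with linear gain would not be comparable.

## The synthetic data

`generate_fixture` builds collections whose relevance is *planted*: a
relevant document receives its topic's disease and gene tokens
max(1, Poisson(signal_strength)) times in the abstract, the pair in its
MeSH wordlist with probability `coword_fraction`, a demographic phrase
rendered as clinical text ("a 38-year-old male patient presented"), a
"Humans" check-tag, and the disease in the title; hard distractors receive
the disease but not the gene (the "missing gene" annotation pattern that
motivates the co-word score) and are judged grade 0. Background text draws
from a closed Zipf-weighted vocabulary so document frequencies — and hence
IDF values — are non-degenerate. Defaults: 500 documents, 5 topics, 10
relevant per topic, signal strength 3, coword fraction 1, 10 % distractors
— small enough that the whole pipeline runs in seconds, large enough that
score distributions are not degenerate. With signal strength 0 no planting
occurs at all, so retrieval falls to the topical base rate — the negative
control.

What passing on this fixture shows: the scoring formulas, co-occurrence
logic, demographic handling, extraction budget discipline, fusion algebra
and metric computations are correct, and the pipeline's stages compose
deterministically. What it does not show: retrieval quality on real
biomedical language (synonymy, polysemy, hedging), realistic score
calibration at 10⁷-document scale, or the value a fine-tuned contextual
pair scorer adds over lexical overlap — the perfect metric values on the
strong-signal fixture are a property of the construction, not a performance
claim.

## Known limitations

- The MEDLINE XML reader maps only the six fields the pipeline uses; it is
  not a general MEDLINE DTD parser.
- Age *ranges* ("aged 40–50 years") resolve to their first number; the
  category of a range spanning a boundary is therefore the lower bound's.
- The expansion table is flat: no ontology traversal, no broader/narrower
  direction control.
- The similarity stage's quality ceiling is the backend's; the shipped
  lexical backend is a correctness and neutrality reference, not a
  semantic matcher.
- Index persistence is plain JSON, adequate for tens of thousands of
  documents, not millions.
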