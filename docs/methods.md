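# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `conceptlink`. It is the package's own account of its
design; every empirical statement here is computed by the test suite or
by `scripts/acceptance.py`.

## Corpus model

A *concept corpus* is the set of publication records retrieved by one
broad concept query (e.g. `stroke[MeSH]`). Concept membership is pure
retrieval provenance: a record retrieved by several queries keeps a
multi-membership `concepts` set rather than being duplicated. Corpus
summaries therefore report both the arithmetic sum of per-concept counts
(the convention used when per-concept components are published) and the
deduplicated union of PMIDs.

Record parsing makes three decisions that PubMed's format leaves open:

* **Human-study flag** — presence of the MeSH descriptor "Humans"
  (case-insensitive exact descriptor match). This is the standard
  machine-readable marker for human studies.
* **English-abstract flag** — an abstract is present *and* the record's
  language list contains `eng`; records with an abstract but no language
  metadata are treated as English (and logged), because language tagging
  is inconsistent in older MEDLINE eras.
* **Year precedence** — `PubDate/Year`, else the first 4-digit token of
  `MedlineDate`, else `ArticleDate/Year`; unknown otherwise. Years
  outside [1800, next year] are treated as unknown.

## Normalization and matching

Vocabulary and matcher share one normalizer: NFKC, lowercase, tokens are
alphanumeric runs with internal hyphens kept, everything else a
separator. Characters whose NFKC expansion introduces punctuation
("½" → "1⁄2") have the punctuation stripped so normalization is a fixed
point (property-tested).

Topic matching is deterministic exact phrase matching over a token trie
of the vocabulary's accepted surfaces:

* a topic matches if its token sequence occurs contiguously in the
  normalized title or abstract, or equals a whole normalized index term;
* **longest-match-wins** per starting token: "skill learning" suppresses
  "skill" at that position, but "skill" still matches elsewhere;
* the only morphology is a bare-plural allowance on the final token
  ("synapse" also matches "synapses"), because expert seed lists mix
  number forms; a plural variant never shadows another term's exact
  surface;
* a topic counts once per record (document frequency), though every
  match event is retained for mention-count analyses.

Fuzzy matching, stemming, NER, and negation handling are deliberately
out of scope: publication-count scores demand reproducible matching, and
the synthetic-corpus tests rely on the matcher recovering planted
frequencies *exactly*. One consequence worth noting: strict
anti-monotonicity under vocabulary removal does not hold in general —
removing a longer phrase can unsuppress a contained shorter term at the
same position. This is inherent to longest-match-wins.

## Vocabulary lifecycle

The vocabulary is versioned and append-only for expert terms. Cells in
the seed table listing alternatives ("networks/systems",
"complex, complexity") split into separate terms sharing the cell's
concept hint; duplicate surfaces merge their hints.

Index-term enrichment adds any normalized author keyword / MeSH
descriptor occurring in at least `min_doc_count` distinct records
(default 5, to suppress idiosyncratic author keywords).

Synonym expansion proposes, for each accepted term, up to `k = 10`
embedding neighbours with cosine ≥ 0.6. Multi-word terms are queried
through their **head token, taken to be the final token** (the usual
English noun-phrase head); neighbour tokens must co-occur with every
remaining token of the phrase in at least one document, and the proposed
surface is the phrase with its head replaced. Candidates are sorted by
similarity descending, then lexicographically, so candidate lists are
deterministic. **No proposal enters the vocabulary without an explicit
accept decision**; rejections are kept in an audit log, and the
review-gate is what keeps the inevitable junk neighbours of
template-locked phrases out of the matcher.

## Word embeddings

Vectors are obtained by factorising a positive pointwise-mutual-
information (PPMI) co-occurrence matrix with truncated SVD. Counting
uses a symmetric window of 5 tokens over the concatenation of each
record's title, abstract, and index terms; context-distribution
smoothing (`α = 0.75`) damps function-word similarity; vectors are
`U·√Σ` rows, unit-normalized, with dimension `min(100, |V|−1)`. Tokens
below `min_count = 5` corpus occurrences receive no vector.

This count-based formulation captures the same distributional signal as
sampled predict-style embeddings (tokens used in interchangeable
contexts get nearly parallel vectors) while being exactly reproducible:
counts are deterministic and the SVD solver is seeded. On the acceptance
corpus (3 × 1,000 records), a synonym pair planted in 100 matched
context frames scores cosine ≈ 0.99 and is proposed at the defaults,
while a disjoint-context control pair scores ≈ 0.26 and is not.

## Link groups and scores

For each (topic, concept) the engine counts distinct PMIDs. A topic's
link group is the **maximal** set of concepts where its count reaches
`min_count` (default 1); a theme in the three-way group is therefore not
also listed pairwise, and raising the threshold can only shrink groups
(tested). A theme's publication count deduplicates PMIDs shared between
the concepts of its group. Scores are within-group proportions
(`count / Σ counts`), summing to 1 per group, ordered score-descending
with lexicographic tie-break. The packaged case-study theme table stores
*printed* counts and *printed* scores separately — the published scores
deviate slightly from within-group proportions of the published counts
(e.g. 113/199 = 0.568 vs a printed 0.562), and the original
normalization is not recoverable — so tests and the acceptance script
compare counts and tallies, never recomputed scores against printed
ones.

Against a brute-force enumeration over all (topic, concept, pmid)
triples, `build_link_map` agrees exactly on randomized corpora of ≤ 20
records (both in the unit suite and the acceptance suite).

## Temporal analysis

A topic's share in year *y* is its fraction of all topic mentions that
year × 100, so shares within a year sum to 100%. "Mention" defaults to
*records mentioning the topic* (consistent with presence-only
extraction); a `mode="mentions"` flag counts individual match events
instead, for corpora where within-record frequency matters. The
alternative normalization (within-topic across years) was considered
and rejected as the default because within-year shares directly support
"what was the field discussing in year y" comparisons.

Emergence is the first year with a nonzero share. Era link maps
partition records by inclusive year ranges; the default eras (1975–1990,
1997–2003, 2012–2018) reproduce the case study's periods, and gap-year
records are dropped rather than assigned to a nearest era. Overlapping
eras are rejected before any stage runs.

## Article ranking

The published case study does not define its article "weighting"; the
implementation here is a **reconstruction**: an article's weight is the
sum of normalized scores of the full-intersection themes present in its
topic set. Two alternatives ship behind the `strategy` option
(`theme_count`, `count_sum`). Selection takes the top N by weight;
presentation within the selection is year descending (most recent
first), then weight, then PMID. Exact membership of the published
30-article shortlist is not reproducible without the original database
snapshot; the packaged shortlist table is used for tally checks only.

## Synthetic corpora

The generator emulates: per-concept record counts, per-(topic, concept)
mention probabilities, concept overlap (a record joins the cyclically
next concept with probability `overlap_rate` and samples topics from the
per-topic maximum of its member concepts' probabilities), a publication-
year distribution, and synonym pairs planted in matched context frames
(≥ 50 frames per pair enforced; control pairs get member-specific,
disjoint frames). Records are serialized as PubMed-XML-shaped documents
and parsed back through the regular reader, so the pipeline exercises
the same code paths as on real data.

Abstracts are template text, not natural language — exact ground truth
beats realism for verification. The spec validator rejects
configurations that would break ground-truth exactness: topics nesting
one another (including plural forms) or sharing tokens with the filler
templates. What passing tests therefore show is that the *machinery* is
exact and deterministic on corpora whose statistical structure is known;
they do not show robustness to real-world phenomena the generator omits
(spelling variation, hyphenation drift, non-English abstracts mislabeled
as English, topic phrases split across clauses, MEDLINE field
idiosyncrasies).

## Determinism and numerical notes

Every stage is deterministic given the config seed: corpus generation
uses a seeded `random.Random`, embedding counts are exact, the SVD is
seeded, candidate and theme orderings have total tie-breaks, and all
writers emit sorted rows with fixed float formatting (scores to 9
decimals). Two pipeline runs with the same config and seed produce
byte-identical theme tables and graph exports (tested). Neighbour
ranking rounds cosines to 12 decimals before tie-breaking so floating-
point jitter cannot reorder equal-similarity tokens.

Problem sizes used in the checked runs — 3 concepts × 1,000 records for
parameter recovery, ≤ 20-record corpora for oracle equivalence, 120–360
records for temporal recovery — were chosen as the smallest corpora at
which every planted statistic is comfortably estimable; all scale
linearly if enlarged.

## Known limitations

* The fetch subcommand (NCBI E-utilities) is a thin convenience and is
  not exercised by the test suite.
* MeSH tree expansion of query headings is out of scope: records arrive
  already tagged with their concept query.
* Printed normalized scores in the packaged case-study table are not
  reproducible from printed counts (see above); the package's own score
  definition is the documented within-group proportion.
* Phrase embeddings are out of scope; multi-word synonym proposal works
  through the head token and document co-occurrence, which favours
  head-substitution candidates.
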