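# conceptlink

Dictionary-based topic extraction and weighted concept-link maps for
biomedical literature corpora.

## The problem

Scoping a research field that sits at the intersection of several large
literatures — the motivating case study is the intersection of
**neuroplasticity**, **stroke recovery**, and **learning** in stroke
rehabilitation — is infeasible by hand: broad PubMed queries for each
concept return hundreds of thousands of records. `conceptlink`
implements an automatic text-processing engine for this task:

1. **Corpus assembly** — parse PubMed XML / MEDLINE `.nbib` records
   (title, abstract, index terms, year), keep which concept query
   retrieved each record as provenance, and filter to human studies with
   English abstracts.
2. **Controlled vocabulary** — start from an expert seed list of topic
   terms, enrich it with author keywords / MeSH descriptors used in
   enough records, and expand it with embedding-proposed synonyms that a
   human reviewer accepts or rejects. Only reviewed terms ever become
   matchable.
3. **Topic extraction** — exact normalized phrase matching of vocabulary
   terms in each record's title, abstract, and index terms
   (longest-match-wins; a bare-plural allowance; no stemming or fuzzy
   matching, by design, so results are exactly reproducible).
4. **Concept-link map** — each topic is assigned to its maximal *link
   group*: the set of concepts in which its document count reaches a
   threshold. With three concepts this yields unique themes, pairwise
   links, and the full three-way intersection. A theme's weight is its
   publication count normalized within its link group
   (`score = count / Σ counts in group`), and the result exports as a
   weighted bipartite graph (GraphML or node-link JSON).
5. **Temporal analysis** — per-year topic shares (within a year, shares
   sum to 100%), topic emergence years, and per-era link maps over
   configurable year ranges (defaults: early 1975–1990, emerging
   1997–2003, recent 2012–2018).
6. **Article ranking** — articles are weighted by the sum of the
   normalized scores of the full-intersection themes they mention, and
   the top-N shortlist is presented most recent first.

A synthetic-corpus generator (`conceptlink.synthetic`) plants topic
frequencies, concept overlaps, publication years, and synonym contexts
with exact ground truth, so the entire pipeline is testable offline.

## Worked example

`examples/concept_map.py` generates a three-concept synthetic corpus in
which "motor imagery" is planted in all three concepts, "spatial
neglect" in two, and "gait speed" in one, then extracts topics and
builds the link map:

```
link group [learning|neuroplasticity|stroke recovery]
  motor imagery    score 1.000 (291 publications)
link group [neuroplasticity|stroke recovery]
  spatial neglect  score 1.000 (105 publications)
link group [stroke recovery]
  gait speed       score 1.000 (106 publications)
GraphML export: 2312 bytes, 6 concept-topic edges
```

Each theme lands in exactly the link group it was planted in; the
publication counts are distinct-PMID document counts (deduplicated
across concepts within a group), and each group's scores sum to 1.

The other examples cover parsing/filtering (`parse_and_filter.py`),
vocabulary building with synonym review (`build_vocabulary.py` — the
planted pair consolidation→reconsolidation is proposed at cosine 0.99
and accepted), temporal trends (`temporal_trends.py`), and ranking
(`rank_articles.py` — an article mentioning the case study's "Cognition"
and "Brain" themes weighs 0.279 + 0.141 = 0.420).

There is also a thin CLI: `conceptlink run config.yaml` executes the
whole pipeline from a validated YAML config and writes a run manifest
(seed, config hash, per-stage counts) alongside the exports;
subcommands `parse`, `filter`, `extract`, `map`, and the
network-dependent `fetch` expose individual stages.

## Packaged case-study tables

The package ships the expert seed vocabulary, the intersection-theme
table (counts and normalized scores as printed in the case study), and
the 30-article shortlist for the neuroplasticity / stroke recovery /
learning study as CSV fixtures, loadable via `load_seed_vocabulary()`,
`load_reference_theme_table()`, and `load_reference_top_articles()`.

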