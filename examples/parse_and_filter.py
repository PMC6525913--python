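"""Parse PubMed-XML records, filter to human studies with English
abstracts, and summarize the per-concept corpora.

Builds a small synthetic three-concept corpus, round-trips it through the
XML reader, and prints the counts a literature scoping run starts from.
"""

from conceptlink import (CorpusSpec, generate_corpus, filter_records,
                         ConceptCorpus, summarize_corpora)

spec = CorpusSpec(
    concepts=["neuroplasticity", "stroke recovery", "learning"],
    n_records_per_concept={"neuroplasticity": 30, "stroke recovery": 60,
                           "learning": 90},
    topic_frequency={("motor imagery", "learning"): 0.4},
    overlap_rate=0.1,
    seed=1)
corpora, _ = generate_corpus(spec)

filtered = [ConceptCorpus(c.concept,
                          filter_records(c.records, require_human=True,
                                         require_english_abstract=True),
                          c.search_date)
            for c in corpora]
summary = summarize_corpora(filtered)

for concept, n in summary.per_concept_counts.items():
    print(f"{concept:>16}: {n} records after filtering")
print(f"simple sum:    {summary.simple_sum}")
print(f"deduped union: {summary.deduped_union}")
print("(the difference is records retrieved by more than one concept query)")
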