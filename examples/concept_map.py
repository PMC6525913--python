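"""Extract topics per concept corpus and build the weighted concept-link
map: unique themes, pairwise links, and the full three-way intersection.
"""

from conceptlink import (CorpusSpec, Vocabulary, VocabularyTerm,
                         build_link_map, export_graph,
                         extract_corpus_topics, generate_corpus)
from conceptlink.linkmap import group_key

spec = CorpusSpec(
    concepts=["neuroplasticity", "stroke recovery", "learning"],
    n_records_per_concept={c: 200 for c in
                           ("neuroplasticity", "stroke recovery", "learning")},
    topic_frequency={
        ("motor imagery", "neuroplasticity"): 0.5,
        ("motor imagery", "stroke recovery"): 0.4,
        ("motor imagery", "learning"): 0.4,
        ("gait speed", "stroke recovery"): 0.5,
        ("spatial neglect", "stroke recovery"): 0.3,
        ("spatial neglect", "neuroplasticity"): 0.3,
    },
    seed=3)
corpora, _ = generate_corpus(spec)

vocab = Vocabulary().add_terms(
    [VocabularyTerm(t, "expert", frozenset(), True) for t in spec.topics()])
assignments = {c.concept: extract_corpus_topics(c, vocab) for c in corpora}

cmap = build_link_map(assignments, min_count=1)
for key, themes in sorted(cmap.groups().items(), key=lambda kv: -len(kv[0])):
    print(f"link group [{key}]")
    for t in themes:
        print(f"  {t.topic:<16} score {t.normalized_score:.3f} "
              f"({t.publication_count} publications)")
print("(scores are within-group proportions of publication counts; the")
print(" full three-way group contains the themes intersecting all concepts)")

graphml = export_graph(cmap, "graphml")
print(f"GraphML export: {len(graphml)} bytes, "
      f"{sum(len(t.link_group) for t in cmap.themes)} concept-topic edges")
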