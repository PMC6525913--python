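"""Track topic usage over time: per-year shares, emergence years, and
per-era concept-link maps.
"""

from conceptlink import (CorpusSpec, EraDefinition, Vocabulary,
                         VocabularyTerm, era_link_maps,
                         extract_corpus_topics, generate_corpus,
                         topic_emergence, topic_year_distribution)

spec = CorpusSpec(
    concepts=["neuroplasticity", "stroke recovery", "learning"],
    n_records_per_concept={c: 150 for c in
                           ("neuroplasticity", "stroke recovery", "learning")},
    topic_frequency={
        ("motor imagery", c): 0.4
        for c in ("neuroplasticity", "stroke recovery", "learning")
    } | {("gait speed", "stroke recovery"): 0.5},
    year_distribution={1980: 1.0, 2000: 1.0, 2015: 2.0},
    seed=4)
corpora, _ = generate_corpus(spec)
vocab = Vocabulary().add_terms(
    [VocabularyTerm(t, "expert", frozenset(), True) for t in spec.topics()])

assignments = {c.concept: extract_corpus_topics(c, vocab) for c in corpora}
records = [r for c in corpora for r in c.records]
flat = [a for asg in assignments.values() for a in asg]

series = topic_year_distribution(flat, records, (1975, 2018))
for s in series:
    shares = ", ".join(f"{y}: {p:.1f}%" for y, p in
                       sorted(s.per_year_percent.items()))
    print(f"{s.topic:<14} {shares}")
print("(within each year the topic shares sum to 100%)")

print("emergence years:", topic_emergence(series))

maps = era_link_maps(assignments, records,
                     [EraDefinition("early", 1975, 1990),
                      EraDefinition("recent", 2012, 2018)])
for era, cmap in maps.items():
    full = [t.topic for t in cmap.full_intersection()]
    print(f"{era}: {len(cmap.themes)} themes, three-way links: {full}")
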