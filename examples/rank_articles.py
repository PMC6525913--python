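"""Rank articles by their intersection-theme weight and print the
shortlist, most recent first.

Uses the packaged intersection-theme table for the neuroplasticity /
stroke recovery / learning case study as the weighting source: an
article's weight is the sum of the normalized scores of the three-way
themes found in its topic set.
"""

from conceptlink import (article_weights, load_reference_theme_table,
                         load_reference_top_articles, top_articles)
from conceptlink.extraction import Match, TopicAssignment

cmap = load_reference_theme_table()
print(f"reference map: {len(cmap.full_intersection())} three-way themes")

# toy extracted topic sets for five articles
topic_sets = {
    "a1": ({"Cognition", "Brain"}, 2016),
    "a2": ({"Motor learning", "Movement"}, 2018),
    "a3": ({"Cognition", "Stimulation", "BDNF"}, 2014),
    "a4": ({"Synaptic plasticity"}, 2017),     # pairwise theme only
    "a5": (set(), 2015),
}
assignments = []
for pmid, (topics, _) in topic_sets.items():
    a = TopicAssignment(pmid)
    for t in topics:
        a.topics.add(t)
        a.matches.append(Match(t, "abstract", 0, 1))
    assignments.append(a)
years = {pmid: year for pmid, (_, year) in topic_sets.items()}

weights = article_weights(assignments, cmap, years)
for w in top_articles(weights, 3):
    themes = ", ".join(sorted(w.matched_themes)) or "-"
    print(f"  {w.pmid} ({w.year}) weight {w.weight:.3f}  [{themes}]")
print("(weight sums the normalized scores of matched three-way themes;")
print(" articles matching only pairwise themes weigh 0)")

articles = load_reference_top_articles()
reviews = sum(1 for a in articles if a.type == "Review")
trials = sum(1 for a in articles if a.type == "Controlled trial")
print(f"packaged case-study shortlist: {len(articles)} articles "
      f"({reviews} reviews, {trials} controlled trials)")
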