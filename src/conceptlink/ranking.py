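"""Article ranking by intersection-theme weight.

An article's weight is the sum of normalized scores of the full-
intersection themes present in its topic set, so articles touching many
heavy intersection themes rise to the top.  This weighting is a
reconstruction — the original engine's formula was not published — and
two alternatives (theme count; per-concept-count weighted sum) are
available behind the ``strategy`` option.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

from .extraction import TopicAssignment
from .linkmap import ConceptLinkMap

STRATEGIES = ("score_sum", "theme_count", "count_sum")


@dataclass(frozen=True)
class ArticleWeight:
    """One article's intersection weight and the themes that produced it."""

    pmid: str
    weight: float
    matched_themes: frozenset[str]
    year: int | None = None


def article_weights(assignments: list[TopicAssignment],
                    cmap: ConceptLinkMap,
                    years: Mapping[str, int | None] | None = None,
                    strategy: str = "score_sum") -> list[ArticleWeight]:
    """Weight each article by its full-intersection theme content.

    strategy:
        ``score_sum`` (default) sums the normalized scores of matched
        full-intersection themes; ``theme_count`` counts them;
        ``count_sum`` sums their publication counts.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    full = cmap.full_intersection()
    if not full:
        raise ValueError("link map has no full-intersection themes")
    value = {
        "score_sum": {t.topic: t.normalized_score for t in full},
        "theme_count": {t.topic: 1.0 for t in full},
        "count_sum": {t.topic: float(t.publication_count) for t in full},
    }[strategy]
    years = years or {}
    out = []
    for a in assignments:
        matched = frozenset(t for t in a.topics if t in value)
        out.append(ArticleWeight(
            a.pmid, sum(value[t] for t in matched), matched,
            years.get(a.pmid)))
    return out


def top_articles(weights: list[ArticleWeight], n: int) -> list[ArticleWeight]:
    """Select the ``n`` heaviest articles; present most recent first.

    Selection is by weight descending (ties by PMID for stability);
    presentation within the selected set is year descending, then weight
    descending, then PMID.  Asking for more than available returns all.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(weights):
        import logging

        logging.getLogger(__name__).info(
            "requested top %d but only %d articles available", n, len(weights))
    chosen = sorted(weights, key=lambda w: (-w.weight, w.pmid))[:n]
    chosen.sort(key=lambda w: (-(w.year if w.year is not None else -1),
                               -w.weight, w.pmid))
    return chosen


def write_shortlist_csv(weights: list[ArticleWeight],
                        path: Union[str, Path],
                        titles: Mapping[str, str] | None = None) -> None:
    titles = titles or {}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "pmid", "year", "title", "weight",
                    "matched_themes"])
        for rank, aw in enumerate(weights, 1):
            w.writerow([rank, aw.pmid, aw.year if aw.year is not None else "",
                        titles.get(aw.pmid, ""), f"{aw.weight:.9f}",
                        ";".join(sorted(aw.matched_themes))])


@dataclass(frozen=True)
class ReferenceArticle:
    """An entry of the packaged top-article shortlist fixture."""

    author: str
    year: int
    title: str
    journal: str
    type: str


def load_reference_top_articles() -> list[ReferenceArticle]:
    """The packaged 30-article shortlist from the stroke-rehabilitation
    case study (author, year, title, journal, study type)."""
    ref = resources.files("conceptlink.data") / "top_articles.csv"
    with resources.as_file(ref) as p, open(p, newline="",
                                           encoding="utf-8") as fh:
        return [ReferenceArticle(row["author"], int(row["year"]), row["title"],
                                 row["journal"], row["type"])
                for row in csv.DictReader(fh)]
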