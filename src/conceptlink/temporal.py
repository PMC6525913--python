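"""Time-based topic analysis: per-year topic distributions, emergence
years, and per-era concept-link maps.

For each year, a topic's share is its fraction of all topic mentions that
year (so shares within a year sum to 100%).  By default a "mention" is a
record mentioning the topic at least once, consistent with presence-only
extraction; ``mode="mentions"`` counts every match event instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .extraction import TopicAssignment
from .linkmap import ConceptLinkMap, build_link_map
from .records import PublicationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EraDefinition:
    """A named, inclusive year range used to partition the corpus."""

    name: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(f"era {self.name!r}: start after end")

    def __contains__(self, year: int | None) -> bool:
        return year is not None and self.start_year <= year <= self.end_year


#: The three periods used in the stroke-rehabilitation case study.
DEFAULT_ERAS = (
    EraDefinition("early", 1975, 1990),
    EraDefinition("emerging", 1997, 2003),
    EraDefinition("recent", 2012, 2018),
)


@dataclass
class TopicTimeSeries:
    """Per-year usage percentages for one topic, plus its emergence year
    (first year with any mention)."""

    topic: str
    per_year_percent: dict[int, float] = field(default_factory=dict)
    emergence_year: int | None = None


def _check_eras(eras: Iterable[EraDefinition]) -> list[EraDefinition]:
    eras = list(eras)
    spans = sorted(eras, key=lambda e: e.start_year)
    for a, b in zip(spans, spans[1:]):
        if b.start_year <= a.end_year:
            raise ValueError(f"eras {a.name!r} and {b.name!r} overlap")
    return eras


def topic_year_distribution(assignments: list[TopicAssignment],
                            records: Iterable[PublicationRecord],
                            year_range: tuple[int, int],
                            mode: str = "records",
                            ) -> list[TopicTimeSeries]:
    """Within-year topic percentages over ``year_range`` (inclusive).

    ``mode="records"`` counts records mentioning a topic; ``"mentions"``
    counts individual match events.  Records with unknown year are
    excluded (their number is logged).  Years with no mentions get no
    entries rather than 0/0.
    """
    start, end = year_range
    if end < start:
        raise ValueError(f"year_range end {end} before start {start}")
    if mode not in ("records", "mentions"):
        raise ValueError("mode must be 'records' or 'mentions'")
    year_of = {r.pmid: r.year for r in records}
    unknown = sum(1 for y in year_of.values() if y is None)
    if unknown:
        logger.info("%d record(s) with unknown year excluded from the "
                    "time analysis", unknown)

    # per-year per-topic tallies
    tallies: dict[int, dict[str, int]] = {}
    for a in assignments:
        year = year_of.get(a.pmid)
        if year is None or not (start <= year <= end):
            continue
        per_topic = tallies.setdefault(year, {})
        if mode == "records":
            for topic in a.topics:
                per_topic[topic] = per_topic.get(topic, 0) + 1
        else:
            for m in a.matches:
                per_topic[m.topic] = per_topic.get(m.topic, 0) + 1

    topics = sorted({t for per in tallies.values() for t in per})
    series = []
    for topic in topics:
        per_year: dict[int, float] = {}
        emergence = None
        for year in sorted(tallies):
            total = sum(tallies[year].values())
            count = tallies[year].get(topic, 0)
            per_year[year] = 100.0 * count / total
            if count and emergence is None:
                emergence = year
        series.append(TopicTimeSeries(topic, per_year, emergence))
    return series


def topic_emergence(series: list[TopicTimeSeries]) -> dict[str, int | None]:
    """First year with a nonzero share, per topic."""
    out: dict[str, int | None] = {}
    for s in series:
        nonzero = [y for y, p in s.per_year_percent.items() if p > 0]
        out[s.topic] = min(nonzero) if nonzero else None
    return out


def era_link_maps(assignments_by_concept: Mapping[str, list[TopicAssignment]],
                  records: Iterable[PublicationRecord],
                  eras: Iterable[EraDefinition] = DEFAULT_ERAS,
                  min_count: int = 1) -> dict[str, ConceptLinkMap]:
    """One concept-link map per era, over the records published in it.

    Records outside every era (including unknown years) are dropped; era
    bounds are inclusive.  Overlapping eras are rejected up front.
    """
    eras = _check_eras(eras)
    year_of = {r.pmid: r.year for r in records}
    out: dict[str, ConceptLinkMap] = {}
    for era in eras:
        restricted = {
            concept: [a for a in assignments
                      if year_of.get(a.pmid) in era]
            for concept, assignments in assignments_by_concept.items()
        }
        out[era.name] = build_link_map(restricted, min_count=min_count)
    return out


def write_time_series_csv(series: list[TopicTimeSeries], path) -> None:
    """CSV of (topic, year, percent), percent to 6 decimals."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["topic", "year", "percent"])
        for s in sorted(series, key=lambda s: s.topic):
            for year in sorted(s.per_year_percent):
                w.writerow([s.topic, year, f"{s.per_year_percent[year]:.6f}"])
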