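"""Weighted concept-link maps.

Topics extracted per concept corpus are classified into *link groups*: a
topic's group is the maximal set of concepts in which its document count
reaches ``min_count``.  With three concepts this yields unique themes
(one concept), pairwise links, and the full three-way intersection.  A
theme's weight is its publication count normalized within its link group,
giving the relative importance of each theme on a link.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx

from .extraction import TopicAssignment

GROUP_SEP = "|"


def group_key(concepts: Iterable[str]) -> str:
    return GROUP_SEP.join(sorted(concepts))


@dataclass(frozen=True)
class ThemeLink:
    """One theme: a topic, the concepts it links, and its weight."""

    topic: str
    link_group: frozenset[str]
    publication_count: int
    normalized_score: float = 0.0

    def __post_init__(self) -> None:
        if not self.link_group:
            raise ValueError("theme requires a non-empty link group")
        if self.publication_count <= 0:
            raise ValueError("emitted themes must have publication_count > 0")


class TopicConceptCounts:
    """Mapping (topic, concept) -> document count, backed by PMID sets so
    cross-concept publication counts can be deduplicated."""

    def __init__(self) -> None:
        self._pmids: dict[tuple[str, str], set[str]] = {}

    def add(self, topic: str, concept: str, pmid: str) -> None:
        self._pmids.setdefault((topic, concept), set()).add(pmid)

    def __getitem__(self, key: tuple[str, str]) -> int:
        return len(self._pmids[key])

    def get(self, key: tuple[str, str], default: int = 0) -> int:
        s = self._pmids.get(key)
        return len(s) if s is not None else default

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._pmids

    def __len__(self) -> int:
        return len(self._pmids)

    def items(self):
        for key in sorted(self._pmids):
            yield key, len(self._pmids[key])

    def topics(self) -> list[str]:
        return sorted({t for t, _ in self._pmids})

    def pmids(self, topic: str, concept: str) -> set[str]:
        return set(self._pmids.get((topic, concept), set()))


@dataclass
class ConceptLinkMap:
    """The weighted graph: concept nodes, theme links, and the threshold
    used to drop weak connections."""

    concepts: list[str]
    themes: list[ThemeLink]
    min_count_threshold: int = 1
    counts: TopicConceptCounts | None = field(default=None, repr=False)

    def themes_in_group(self, concepts: Iterable[str]) -> list[ThemeLink]:
        want = frozenset(concepts)
        return [t for t in self.themes if t.link_group == want]

    def full_intersection(self) -> list[ThemeLink]:
        return self.themes_in_group(self.concepts)

    def groups(self) -> dict[str, list[ThemeLink]]:
        out: dict[str, list[ThemeLink]] = {}
        for t in self.themes:
            out.setdefault(group_key(t.link_group), []).append(t)
        return out


# ---------------------------------------------------------------------------

def theme_counts(assignments_by_concept: Mapping[str, list[TopicAssignment]],
                 ) -> TopicConceptCounts:
    """Per-(topic, concept) distinct-PMID document counts."""
    counts = TopicConceptCounts()
    for concept, assignments in assignments_by_concept.items():
        for a in assignments:
            for topic in a.topics:
                counts.add(topic, concept, a.pmid)
    return counts


def classify_link_groups(counts: TopicConceptCounts,
                         min_count: int = 1) -> list[ThemeLink]:
    """Assign each topic to its maximal link group (unscored themes).

    A topic joins every concept where its document count reaches
    ``min_count``; topics reaching it nowhere are dropped.  The theme's
    publication count deduplicates PMIDs shared between concept corpora.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    themes = []
    for topic in counts.topics():
        group = frozenset(
            concept for (t, concept) in counts._pmids
            if t == topic and counts[(t, concept)] >= min_count)
        if not group:
            continue
        pmids: set[str] = set()
        for concept in group:
            pmids |= counts.pmids(topic, concept)
        themes.append(ThemeLink(topic, group, len(pmids)))
    return themes


def normalize_scores(themes: list[ThemeLink]) -> list[ThemeLink]:
    """Score themes of one link group as within-group count proportions.

    Scores sum to 1; output sorted by score descending, ties broken by
    topic.  An empty group is an error (nothing to normalize against).
    """
    if not themes:
        raise ValueError("cannot normalize an empty link group")
    groups = {t.link_group for t in themes}
    if len(groups) != 1:
        raise ValueError("normalize_scores expects a single link group")
    total = sum(t.publication_count for t in themes)
    scored = [replace(t, normalized_score=t.publication_count / total)
              for t in themes]
    scored.sort(key=lambda t: (-t.normalized_score, t.topic))
    return scored


def build_link_map(assignments_by_concept: Mapping[str, list[TopicAssignment]],
                   min_count: int = 1,
                   top_n_per_group: int | None = None) -> ConceptLinkMap:
    """Full pipeline: count -> classify -> normalize per link group.

    ``top_n_per_group`` optionally keeps only the strongest themes of each
    group (filtering happens before normalization so kept scores still sum
    to 1 within the group).
    """
    concepts = sorted(assignments_by_concept)
    if len(concepts) < 2:
        raise ValueError("a link map needs at least 2 concepts")
    counts = theme_counts(assignments_by_concept)
    unscored = classify_link_groups(counts, min_count)
    by_group: dict[frozenset[str], list[ThemeLink]] = {}
    for t in unscored:
        by_group.setdefault(t.link_group, []).append(t)
    themes: list[ThemeLink] = []
    for group in sorted(by_group, key=lambda g: (len(g), group_key(g))):
        members = by_group[group]
        if top_n_per_group is not None:
            members.sort(key=lambda t: (-t.publication_count, t.topic))
            members = members[:top_n_per_group]
        themes.extend(normalize_scores(members))
    themes.sort(key=lambda t: (-t.normalized_score, t.topic,
                               group_key(t.link_group)))
    return ConceptLinkMap(concepts, themes, min_count, counts)


# ---------------------------------------------------------------------------
# Theme table (CSV)

def write_theme_table(cmap: ConceptLinkMap, path: Union[str, Path]) -> None:
    """CSV of (link_group, topic, publication_count, normalized_score),
    scores printed to 9 decimals; deterministic row order."""
    rows = sorted(cmap.themes,
                  key=lambda t: (len(t.link_group), group_key(t.link_group),
                                 -t.normalized_score, t.topic))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["link_group", "topic", "publication_count",
                    "normalized_score"])
        for t in rows:
            w.writerow([group_key(t.link_group), t.topic,
                        t.publication_count, f"{t.normalized_score:.9f}"])


def read_theme_table(path: Union[str, Path]) -> list[ThemeLink]:
    themes = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            themes.append(ThemeLink(
                row["topic"],
                frozenset(row["link_group"].split(GROUP_SEP)),
                int(row["publication_count"]),
                float(row["normalized_score"])))
    return themes


def load_reference_theme_table() -> ConceptLinkMap:
    """The packaged intersection-theme table for the neuroplasticity /
    stroke recovery / learning case study.

    Publication counts and normalized scores are stored as printed in the
    source table; the scores are *not* recomputed from the counts (the
    printed weights differ slightly from within-group proportions).
    """
    ref = resources.files("conceptlink.data") / "intersection_themes.csv"
    with resources.as_file(ref) as p:
        themes = read_theme_table(p)
    concepts = sorted({c for t in themes for c in t.link_group})
    return ConceptLinkMap(concepts, themes, min_count_threshold=1)


# ---------------------------------------------------------------------------
# Graph export / import

_FORMATS = ("graphml", "json")


def to_networkx(cmap: ConceptLinkMap) -> nx.Graph:
    g = nx.Graph()
    for concept in cmap.concepts:
        g.add_node(concept, kind="concept")
    for t in sorted(cmap.themes, key=lambda t: t.topic):
        node = f"topic:{t.topic}"
        g.add_node(node, kind="topic", topic=t.topic,
                   link_group=group_key(t.link_group),
                   publication_count=t.publication_count,
                   normalized_score=t.normalized_score)
        for concept in sorted(t.link_group):
            weight = (cmap.counts.get((t.topic, concept), 0)
                      if cmap.counts is not None else t.publication_count)
            g.add_edge(concept, node, weight=int(weight))
    return g


def export_graph(cmap: ConceptLinkMap, format: str = "json") -> str:
    """Serialize the map as GraphML or a node-link JSON document.

    Edge weights are per-concept document counts; theme attributes ride on
    the topic nodes.  JSON output is canonically ordered so identical maps
    serialize byte-identically.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; supported: "
                         f"{', '.join(_FORMATS)}")
    g = to_networkx(cmap)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(g)) + "\n"
    payload = nx.node_link_data(g, edges="links")
    payload["nodes"].sort(key=lambda n: str(n["id"]))
    payload["links"].sort(key=lambda e: (str(e["source"]), str(e["target"])))
    payload["min_count_threshold"] = cmap.min_count_threshold
    payload["concepts"] = list(cmap.concepts)
    return json.dumps(payload, sort_keys=True, indent=1, ensure_ascii=False)


class _EdgeCounts:
    """Read-only (topic, concept) -> count view rebuilt from graph edges
    (PMID sets are not serialized, so imports keep counts only)."""

    def __init__(self, counts: dict[tuple[str, str], int]):
        self._counts = counts

    def get(self, key: tuple[str, str], default: int = 0) -> int:
        return self._counts.get(key, default)


def import_graph(data: str, format: str = "json") -> ConceptLinkMap:
    """Rebuild a ConceptLinkMap from an exported graph (lossless for the
    theme structure; per-concept edge weights are retained as counts only
    in the graph, not re-expanded to PMID sets)."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; supported: "
                         f"{', '.join(_FORMATS)}")
    if format == "graphml":
        g = nx.parse_graphml(data)
        min_count = 1
        concepts = sorted(n for n, d in g.nodes(data=True)
                          if d.get("kind") == "concept")
    else:
        payload = json.loads(data)
        g = nx.node_link_graph(payload, edges="links")
        min_count = int(payload.get("min_count_threshold", 1))
        concepts = list(payload.get("concepts", []))
    themes = []
    edge_counts: dict[tuple[str, str], int] = {}
    for node, d in g.nodes(data=True):
        if d.get("kind") != "topic":
            continue
        themes.append(ThemeLink(
            d["topic"], frozenset(d["link_group"].split(GROUP_SEP)),
            int(d["publication_count"]), float(d["normalized_score"])))
        for concept in g.neighbors(node):
            edge_counts[(d["topic"], concept)] = int(
                g.edges[node, concept].get("weight", 0))
    themes.sort(key=lambda t: (-t.normalized_score, t.topic,
                               group_key(t.link_group)))
    return ConceptLinkMap(concepts, themes, min_count,
                          counts=_EdgeCounts(edge_counts))
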