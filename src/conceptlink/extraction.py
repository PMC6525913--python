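"""Dictionary-based topic extraction.

Vocabulary surfaces are matched as contiguous normalized token sequences
in the title and abstract, or as whole normalized index terms.  Matching
is exact (no stemming or fuzziness) apart from a bare-plural allowance on
the final token ("synapse" also matches "synapses").  When two surfaces
match at the same starting token the longer one wins; the shorter surface
still matches at other positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .normalize import Token, normalize_text, phrase_tokens
from .vocabulary import Vocabulary

FIELDS = ("title", "abstract", "index_terms")


class Match(NamedTuple):
    """One match event: which topic, in which field, where.

    For title/abstract, ``start``/``end`` are character offsets into the
    original field text; for index terms they give the term's position in
    the record's sorted index-term list (start == end).
    """

    topic: str
    field: str
    start: int
    end: int


@dataclass
class TopicAssignment:
    """Per-record set of matched topics with their match events."""

    pmid: str
    topics: set[str] = field(default_factory=set)
    matches: list[Match] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"pmid": self.pmid, "topics": sorted(self.topics),
                "matches": [list(m) for m in self.matches]}


class PhraseMatcher:
    """Token-trie matcher over a vocabulary's accepted surfaces."""

    _END = "\x00"

    def __init__(self, surfaces: Iterable[str]):
        self._root: dict = {}
        exact: list[tuple[tuple[str, ...], str]] = []
        for surface in surfaces:
            tokens = tuple(surface.split())
            if tokens:
                exact.append((tokens, surface))
        for tokens, surface in exact:
            self._insert(tokens, surface, overwrite=True)
        # plural variants never shadow an exact surface of another term
        for tokens, surface in exact:
            plural = tokens[:-1] + (tokens[-1] + "s",)
            self._insert(plural, surface, overwrite=False)

    def _insert(self, tokens: tuple[str, ...], surface: str,
                overwrite: bool) -> None:
        node = self._root
        for tok in tokens:
            node = node.setdefault(tok, {})
        if overwrite or self._END not in node:
            node[self._END] = surface

    def match_tokens(self, tokens: list[Token]) -> list[tuple[str, int, int]]:
        """Longest-match-wins scan; returns (surface, start_tok, end_tok)."""
        out = []
        n = len(tokens)
        for i in range(n):
            node = self._root
            best: tuple[str, int] | None = None
            j = i
            while j < n and tokens[j].text in node:
                node = node[tokens[j].text]
                j += 1
                if self._END in node:
                    best = (node[self._END], j)
            if best is not None:
                out.append((best[0], i, best[1]))
        return out

    def match_exact(self, phrase: str) -> str | None:
        """Surface matched by the whole phrase (index-term matching)."""
        node = self._root
        for tok in phrase_tokens(phrase):
            if tok not in node:
                return None
            node = node[tok]
        return node.get(self._END)


def build_matcher(vocab: Vocabulary) -> PhraseMatcher:
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    return PhraseMatcher(vocab.accepted_surfaces())


def extract_topics(record, vocab: Vocabulary | PhraseMatcher,
                   ) -> TopicAssignment:
    """Match vocabulary topics in one record's title, abstract and index
    terms.  A topic appears once in ``topics`` however often it matches;
    every match event is kept in ``matches``."""
    matcher = vocab if isinstance(vocab, PhraseMatcher) else build_matcher(vocab)
    assignment = TopicAssignment(record.pmid)
    for fieldname in ("title", "abstract"):
        text = getattr(record, fieldname)
        tokens = normalize_text(text)
        for surface, ti, tj in matcher.match_tokens(tokens):
            assignment.matches.append(
                Match(surface, fieldname, tokens[ti].start, tokens[tj - 1].end))
            assignment.topics.add(surface)
    for idx, term in enumerate(sorted(record.index_terms)):
        surface = matcher.match_exact(term)
        if surface is not None:
            assignment.matches.append(Match(surface, "index_terms", idx, idx))
            assignment.topics.add(surface)
    return assignment


def extract_corpus_topics(corpus, vocab: Vocabulary) -> list[TopicAssignment]:
    """One assignment per record, in corpus order."""
    if len(corpus.records) == 0:
        return []
    matcher = build_matcher(vocab)
    return [extract_topics(rec, matcher) for rec in corpus.records]


def topic_index(assignments: Iterable[TopicAssignment]) -> dict[str, set[str]]:
    """Aggregate topic -> set of PMIDs mentioning it."""
    index: dict[str, set[str]] = {}
    for a in assignments:
        for topic in a.topics:
            index.setdefault(topic, set()).add(a.pmid)
    return index
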