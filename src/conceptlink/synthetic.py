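"""Synthetic publication corpora with planted, exactly-known structure.

The generator emits PubMed-XML-shaped documents (parsed back through the
regular reader, so the whole pipeline sees them as real data) in which
every topic mention, concept membership, publication year, and synonym
context is planted by construction and recorded in a ``GroundTruth``
object.  Abstracts are template text rather than natural language: exact
bookkeeping beats realism when the goal is to verify that extraction,
link-map construction, temporal analysis and ranking recover precisely
what was planted.

To keep the ground truth exactly predictive of the matcher's output, the
spec is validated so that no planted topic is a contiguous token
subsequence of another (including bare-plural forms) and no topic token
appears in the filler templates.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union
from xml.sax.saxutils import escape

from .normalize import phrase_tokens
from .records import ConceptCorpus, PublicationRecord, parse_pubmed_xml

# Filler sentence fragments; deliberately free of plausible topic words.
_FILLER_SENTENCES = (
    "Data were gathered over consecutive assessment intervals.",
    "Baseline values were recorded before the first session.",
    "Follow-up measurements continued for several weeks.",
    "The protocol was approved by the institutional board.",
)

_TOPIC_SENTENCE = "This investigation considers {} in a clinical cohort."
_TITLE_TEMPLATE = "A study of {} in rehabilitation research"
_TITLE_EMPTY = "An observational report from rehabilitation research"

#: Shared context frames for planting synonym pairs ("{}" is the slot).
DEFAULT_FRAMES = (
    "the {} of recent traces was measured after overnight rest",
    "patients showed gradual {} following repeated practice sessions",
    "the observed {} depended on the spacing of practice",
    "interference disrupted {} when applied during the retention interval",
    "pharmacological agents modulated {} in a dose dependent manner",
    "sleep appeared to promote {} across all follow-up intervals",
    "the rate of {} varied between younger and older participants",
    "electrophysiological markers tracked {} throughout the retention test",
    "the {} process continued for several hours after practice ended",
    "boosting {} required reactivation before the final assessment",
)


@dataclass
class CorpusSpec:
    """Declarative description of a synthetic multi-concept corpus.

    topic_frequency maps ``(topic, concept)`` to the per-record
    probability that a record of that concept mentions the topic.
    ``overlap_rate`` is the probability that a record is additionally
    assigned to one other (cyclically next) concept, with the union of
    both concepts' topic profiles (per-topic maximum probability).
    ``synonym_pairs`` are planted in shared context frames;
    ``control_pairs`` get disjoint frames each, so only the former should
    be proposed as synonyms.
    """

    concepts: list[str]
    n_records_per_concept: dict[str, int]
    topic_frequency: dict[tuple[str, str], float]
    synonym_pairs: list[tuple[str, str]] = field(default_factory=list)
    control_pairs: list[tuple[str, str]] = field(default_factory=list)
    year_distribution: dict[int, float] = field(
        default_factory=lambda: {y: 1.0 for y in range(1995, 2019)})
    overlap_rate: float = 0.0
    frames_per_pair: int = 100
    pmid_prefix: str = ""
    seed: int = 0

    def topics(self) -> list[str]:
        return sorted({t for t, _ in self.topic_frequency})

    def validate(self) -> None:
        if not self.concepts:
            raise ValueError("concepts: need at least one concept label")
        for c in self.concepts:
            if self.n_records_per_concept.get(c, 0) < 0:
                raise ValueError(f"n_records_per_concept[{c!r}]: negative")
        for (topic, concept), p in self.topic_frequency.items():
            if concept not in self.concepts:
                raise ValueError(
                    f"topic_frequency: unknown concept {concept!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"topic_frequency[({topic!r}, {concept!r})]: {p} "
                    "outside [0, 1]")
        if not self.year_distribution:
            raise ValueError("year_distribution: empty")
        if any(w < 0 for w in self.year_distribution.values()):
            raise ValueError("year_distribution: negative weight")
        if not any(w > 0 for w in self.year_distribution.values()):
            raise ValueError("year_distribution: all weights zero")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise ValueError(f"overlap_rate: {self.overlap_rate} outside [0, 1]")
        if (self.synonym_pairs or self.control_pairs) \
                and self.frames_per_pair < 50:
            raise ValueError("frames_per_pair: need >= 50 frames per pair")
        # ground-truth exactness: topics must not nest or collide with fillers
        token_seqs = {t: phrase_tokens(t) for t in self.topics()}
        filler_tokens = set()
        templates = _FILLER_SENTENCES + (_TOPIC_SENTENCE, _TITLE_TEMPLATE,
                                         _TITLE_EMPTY)
        if self.synonym_pairs or self.control_pairs:
            templates = templates + DEFAULT_FRAMES
        for s in templates:
            filler_tokens |= set(phrase_tokens(s.replace("{}", "")))
        for topic, seq in token_seqs.items():
            if not seq:
                raise ValueError(f"topic {topic!r} normalizes to nothing")
            if set(seq) & filler_tokens:
                raise ValueError(
                    f"topic {topic!r} shares tokens with filler templates")
            for other, oseq in token_seqs.items():
                if topic == other:
                    continue
                for variant in (oseq, oseq[:-1] + (oseq[-1] + "s",)):
                    if _contains(variant, seq) or _contains(seq, variant):
                        raise ValueError(
                            f"topics {topic!r} and {other!r} nest; ground "
                            "truth would not be exact")


def _contains(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(haystack[i:i + n] == needle
               for i in range(len(haystack) - n + 1))


@dataclass
class GroundTruth:
    """Exact bookkeeping of everything the generator planted."""

    per_record_topics: dict[str, set[str]]
    concept_membership: dict[str, set[str]]
    record_years: dict[str, int]
    per_concept_counts: dict[str, int]

    def doc_frequency(self, topic: str, concept: str) -> int:
        return sum(1 for pmid, topics in self.per_record_topics.items()
                   if topic in topics
                   and concept in self.concept_membership[pmid])

    def first_mention_year(self, topic: str) -> int | None:
        years = [self.record_years[pmid]
                 for pmid, topics in self.per_record_topics.items()
                 if topic in topics]
        return min(years) if years else None

    def to_json(self) -> str:
        return json.dumps({
            "per_record_topics": {k: sorted(v) for k, v
                                  in sorted(self.per_record_topics.items())},
            "concept_membership": {k: sorted(v) for k, v
                                   in sorted(self.concept_membership.items())},
            "record_years": dict(sorted(self.record_years.items())),
            "per_concept_counts": dict(sorted(self.per_concept_counts.items())),
        }, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        return cls({k: set(v) for k, v in d["per_record_topics"].items()},
                   {k: set(v) for k, v in d["concept_membership"].items()},
                   {k: int(v) for k, v in d["record_years"].items()},
                   d["per_concept_counts"])


def plant_synonym_sentences(pairs: list[tuple[str, str]],
                            context_templates: tuple[str, ...] = DEFAULT_FRAMES,
                            n_frames: int = 100,
                            ) -> list[tuple[str, str]]:
    """Sentences placing both members of each pair in identical frames.

    Returns ``(slot_word, sentence)`` tuples: for every frame instance one
    sentence per pair member, so both members see the same context
    distribution.  Requires at least 50 frames per pair.
    """
    if pairs and n_frames < 50:
        raise ValueError("need >= 50 context frames per pair")
    out = []
    for term, synonym in pairs:
        if term == synonym:
            raise ValueError("synonym pair members must differ")
        for i in range(n_frames):
            frame = context_templates[i % len(context_templates)]
            out.append((term, frame.format(term)))
            out.append((synonym, frame.format(synonym)))
    return out


def _control_sentences(pairs: list[tuple[str, str]], n_frames: int,
                       ) -> list[tuple[str, str]]:
    """Disjoint-context sentences: each pair member gets its own frames
    built from member-specific filler tokens, so the two members never
    share contexts."""
    out = []
    for pi, (a, b) in enumerate(pairs):
        for mi, word in enumerate((a, b)):
            stem = f"ctxw{pi}{mi}"
            frames = [
                f"{stem}alpha procedures involved {{}} under {stem}beta conditions",
                f"repeated {stem}gamma trials produced {{}} in the {stem}delta arm",
                f"the {stem}epsilon cohort exhibited {{}} at {stem}zeta visits",
            ]
            for i in range(n_frames):
                out.append((word, frames[i % len(frames)].format(word)))
    return out


def generate_corpus(spec: CorpusSpec,
                    ) -> tuple[list[ConceptCorpus], GroundTruth]:
    """Generate concept corpora plus their exact ground truth.

    Records are serialized to PubMed XML and parsed back through the
    regular reader, so field handling is exercised identically to real
    data.  Identical specs (including seed) give identical corpora.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    years = sorted(spec.year_distribution)
    weights = [spec.year_distribution[y] for y in years]

    per_record_topics: dict[str, set[str]] = {}
    membership: dict[str, set[str]] = {}
    record_years: dict[str, int] = {}
    raw: dict[str, PublicationRecord] = {}
    corpus_pmids: dict[str, list[str]] = {c: [] for c in spec.concepts}

    serial = 0
    for ci, concept in enumerate(spec.concepts):
        for _ in range(spec.n_records_per_concept.get(concept, 0)):
            serial += 1
            pmid = f"{spec.pmid_prefix}{90000000 + serial}"
            concepts = {concept}
            if len(spec.concepts) > 1 and rng.random() < spec.overlap_rate:
                concepts.add(spec.concepts[(ci + 1) % len(spec.concepts)])
            # per-topic mention probability: max over member concepts
            mentioned = []
            for topic in spec.topics():
                p = max(spec.topic_frequency.get((topic, c), 0.0)
                        for c in concepts)
                if rng.random() < p:
                    mentioned.append(topic)
            year = rng.choices(years, weights=weights)[0]

            sentences = [_TOPIC_SENTENCE.format(t) for t in mentioned]
            sentences.append(
                _FILLER_SENTENCES[rng.randrange(len(_FILLER_SENTENCES))])
            title = (_TITLE_TEMPLATE.format(mentioned[0]) if mentioned
                     else _TITLE_EMPTY)
            index_terms = {t for t in mentioned if rng.random() < 0.5}

            rec = PublicationRecord(
                pmid=pmid, title=title, abstract=" ".join(sentences),
                index_terms=index_terms, year=year,
                has_english_abstract=True, is_human_study=True,
                concepts=set(concepts))
            raw[pmid] = rec
            per_record_topics[pmid] = set(mentioned)
            membership[pmid] = set(concepts)
            record_years[pmid] = year
            for c in concepts:
                corpus_pmids[c].append(pmid)

    # plant synonym / control contexts in round-robin records
    extra = plant_synonym_sentences(spec.synonym_pairs,
                                    n_frames=spec.frames_per_pair)
    extra += _control_sentences(spec.control_pairs, spec.frames_per_pair)
    all_pmids = sorted(raw)
    if extra and not all_pmids:
        raise ValueError("cannot plant synonym contexts in an empty corpus")
    topic_set = set(spec.topics())
    for i, (word, sentence) in enumerate(extra):
        pmid = all_pmids[i % len(all_pmids)]
        raw[pmid].abstract += " " + sentence.capitalize() + "."
        if word in topic_set:
            per_record_topics[pmid].add(word)

    corpora = []
    for concept in spec.concepts:
        xml = records_to_pubmed_xml([raw[p] for p in corpus_pmids[concept]])
        corpora.append(ConceptCorpus(
            concept, parse_pubmed_xml(xml, concept)))
    truth = GroundTruth(per_record_topics, membership, record_years,
                        {c: len(corpus_pmids[c]) for c in spec.concepts})
    return corpora, truth


# ---------------------------------------------------------------------------
# PubMed XML writing

_ARTICLE_TEMPLATE = """  <PubmedArticle>
    <MedlineCitation>
      <PMID>{pmid}</PMID>
      <Article>
        <Journal>
          <JournalIssue>
            <PubDate>
              <Year>{year}</Year>
            </PubDate>
          </JournalIssue>
          <Title>Synthetic Corpus Reports</Title>
        </Journal>
        <ArticleTitle>{title}</ArticleTitle>
{abstract}        <Language>eng</Language>
      </Article>
{mesh}{keywords}    </MedlineCitation>
  </PubmedArticle>
"""


def records_to_pubmed_xml(records: list[PublicationRecord]) -> str:
    """Serialize records as a ``PubmedArticleSet`` document (synthetic:
    only the fields the reader consumes are populated)."""
    parts = ['<?xml version="1.0" encoding="UTF-8"?>\n<PubmedArticleSet>\n']
    for rec in records:
        abstract = ""
        if rec.abstract:
            abstract = ("        <Abstract>\n          <AbstractText>"
                        f"{escape(rec.abstract)}</AbstractText>\n"
                        "        </Abstract>\n")
        mesh_terms = sorted(rec.index_terms)
        if rec.is_human_study:
            mesh_terms = ["Humans"] + mesh_terms
        mesh = ""
        if mesh_terms:
            rows = "".join(
                "        <MeshHeading>\n          <DescriptorName>"
                f"{escape(m)}</DescriptorName>\n        </MeshHeading>\n"
                for m in mesh_terms)
            mesh = f"      <MeshHeadingList>\n{rows}      </MeshHeadingList>\n"
        keywords = ""
        return_parts = _ARTICLE_TEMPLATE.format(
            pmid=escape(rec.pmid), year=rec.year or 2000,
            title=escape(rec.title), abstract=abstract, mesh=mesh,
            keywords=keywords)
        parts.append(return_parts)
    parts.append("</PubmedArticleSet>\n")
    return "".join(parts)


def write_pubmed_xml(records: list[PublicationRecord],
                     path: Union[str, Path]) -> None:
    Path(path).write_text(records_to_pubmed_xml(records), encoding="utf-8")
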