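"""Publication records: PubMed XML / MEDLINE parsing, filtering, summaries.

A *concept corpus* is the set of records retrieved by one concept query
(e.g. ``stroke[MeSH]``); concept membership is provenance, carried on each
record in its ``concepts`` set.  A record retrieved by several queries is
stored once per corpus but keeps multi-membership rather than being
duplicated.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from lxml import etree

logger = logging.getLogger(__name__)

YEAR_MIN = 1800


def _year_max() -> int:
    return _dt.date.today().year + 1


@dataclass
class PublicationRecord:
    """One publication: identity, searchable text, flags and provenance.

    ``index_terms`` is the union of assigned MeSH descriptor names and
    author-supplied keywords.  ``year`` is ``None`` when no usable date
    was found.  ``concepts`` records which concept queries retrieved the
    article.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    index_terms: set[str] = field(default_factory=set)
    year: int | None = None
    has_english_abstract: bool = False
    is_human_study: bool = False
    concepts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("record requires a non-empty pmid")
        if self.year is not None and not (YEAR_MIN <= self.year <= _year_max()):
            raise ValueError(f"year {self.year} outside [{YEAR_MIN}, {_year_max()}]")

    def to_json_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract": self.abstract,
            "index_terms": sorted(self.index_terms),
            "year": self.year,
            "has_english_abstract": self.has_english_abstract,
            "is_human_study": self.is_human_study,
            "concepts": sorted(self.concepts),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PublicationRecord":
        return cls(
            pmid=d["pmid"],
            title=d.get("title", ""),
            abstract=d.get("abstract", ""),
            index_terms=set(d.get("index_terms", ())),
            year=d.get("year"),
            has_english_abstract=bool(d.get("has_english_abstract", False)),
            is_human_study=bool(d.get("is_human_study", False)),
            concepts=set(d.get("concepts", ())),
        )


@dataclass
class ConceptCorpus:
    """Records retrieved by one concept query, plus the search date stamp."""

    concept: str
    records: list[PublicationRecord]
    search_date: _dt.date = field(default_factory=_dt.date.today)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise ValueError(
                    f"duplicate pmid {rec.pmid!r} in corpus {self.concept!r}"
                )
            seen.add(rec.pmid)
            rec.concepts.add(self.concept)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CorpusSummary:
    """Per-concept record counts, their arithmetic sum, and the deduplicated
    union of PMIDs across corpora.

    Records retrieved by more than one concept query inflate ``simple_sum``
    relative to ``deduped_union``; both are reported because published
    per-concept component counts typically sum without deduplication.
    """

    per_concept_counts: dict[str, int]
    simple_sum: int
    deduped_union: int

    @classmethod
    def from_counts(cls, per_concept_counts: dict[str, int],
                    deduped_union: int | None = None) -> "CorpusSummary":
        total = sum(per_concept_counts.values())
        return cls(dict(per_concept_counts), total,
                   total if deduped_union is None else deduped_union)


# ---------------------------------------------------------------------------
# PubMed XML

_HUMANS = "humans"


def _text(el) -> str:
    return "".join(el.itertext()) if el is not None else ""


def _extract_year(article_el) -> int | None:
    """PubDate Year > MedlineDate first 4-digit token > ArticleDate year."""
    y = article_el.findtext(".//Journal/JournalIssue/PubDate/Year")
    if y and y.strip().isdigit():
        year = int(y.strip())
        if YEAR_MIN <= year <= _year_max():
            return year
    md = article_el.findtext(".//Journal/JournalIssue/PubDate/MedlineDate")
    if md:
        m = re.search(r"\b(\d{4})\b", md)
        if m:
            year = int(m.group(1))
            if YEAR_MIN <= year <= _year_max():
                return year
    y = article_el.findtext(".//ArticleDate/Year")
    if y and y.strip().isdigit():
        year = int(y.strip())
        if YEAR_MIN <= year <= _year_max():
            return year
    return None


def parse_pubmed_xml(source: Union[str, Path, IO[bytes]],
                     concept: str) -> list[PublicationRecord]:
    """Parse a ``PubmedArticleSet`` document into publication records.

    Parameters
    ----------
    source:
        Path, file object, or XML string/bytes.
    concept:
        Concept label stamped on every record (retrieval provenance).

    Each ``PubmedArticle`` yields one record.  Articles without a PMID are
    skipped with a logged warning.  Malformed XML raises
    ``lxml.etree.XMLSyntaxError``, which carries the line/column position.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    elif hasattr(source, "read"):
        root = etree.parse(source).getroot()
    else:
        root = etree.parse(str(source)).getroot()

    records: list[PublicationRecord] = []
    skipped = 0
    for art in root.iter("PubmedArticle"):
        citation = art.find("MedlineCitation")
        if citation is None:
            skipped += 1
            continue
        pmid = (citation.findtext("PMID") or "").strip()
        if not pmid:
            skipped += 1
            continue
        article = citation.find("Article")
        title = _text(article.find("ArticleTitle")) if article is not None else ""
        abstract_el = article.find("Abstract") if article is not None else None
        abstract = " ".join(
            _text(t).strip()
            for t in (abstract_el.findall("AbstractText") if abstract_el is not None else [])
        ).strip()
        languages = [
            (lang.text or "").strip().lower()
            for lang in (article.findall("Language") if article is not None else [])
        ]
        # Abstract plus "eng" language marker; records with an abstract but
        # no language metadata are treated as English (tagging is patchy in
        # older MEDLINE eras) and logged.
        if abstract:
            if languages:
                has_eng = "eng" in languages
            else:
                has_eng = True
                logger.debug("pmid %s: abstract without language metadata, "
                             "treated as English", pmid)
        else:
            has_eng = False

        mesh = {
            (d.text or "").strip()
            for d in citation.findall(".//MeshHeading/DescriptorName")
            if (d.text or "").strip()
        }
        keywords = {
            _text(k).strip()
            for k in citation.findall(".//KeywordList/Keyword")
            if _text(k).strip()
        }
        records.append(PublicationRecord(
            pmid=pmid,
            title=title.strip(),
            abstract=abstract,
            index_terms=mesh | keywords,
            year=_extract_year(article) if article is not None else None,
            has_english_abstract=has_eng,
            is_human_study=any(m.lower() == _HUMANS for m in mesh),
            concepts={concept},
        ))
    if skipped:
        logger.warning("skipped %d article(s) lacking a PMID", skipped)
    return records


# ---------------------------------------------------------------------------
# MEDLINE .nbib (secondary reader)

_NBIB_TAG = re.compile(r"^([A-Z]{2,4})\s*- (.*)$")


def parse_nbib(source: Union[str, Path, IO[str]],
               concept: str) -> list[PublicationRecord]:
    """Parse MEDLINE ``.nbib`` formatted records (PMID/TI/AB/MH/OT/DP/LA)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)

    records: list[PublicationRecord] = []
    fields: dict[str, list[str]] = {}
    key: str | None = None

    def flush() -> None:
        nonlocal fields
        if not fields:
            return
        pmid = fields.get("PMID", [""])[0].strip()
        if not pmid:
            logger.warning("skipped .nbib record lacking a PMID")
            fields = {}
            return
        abstract = " ".join(fields.get("AB", [])).strip()
        langs = [v.strip().lower() for v in fields.get("LA", [])]
        mesh = {re.sub(r"[*]", "", v).split("/")[0].strip()
                for v in fields.get("MH", [])}
        mesh.discard("")
        keywords = {v.strip() for v in fields.get("OT", [])} - {""}
        year = None
        for v in fields.get("DP", []):
            m = re.search(r"\b(\d{4})\b", v)
            if m and YEAR_MIN <= int(m.group(1)) <= _year_max():
                year = int(m.group(1))
                break
        records.append(PublicationRecord(
            pmid=pmid,
            title=" ".join(fields.get("TI", [])).strip(),
            abstract=abstract,
            index_terms=mesh | keywords,
            year=year,
            has_english_abstract=bool(abstract) and ("eng" in langs or not langs),
            is_human_study=any(m.lower() == _HUMANS for m in mesh),
            concepts={concept},
        ))
        fields = {}

    for line in text.splitlines():
        if not line.strip():
            flush()
            key = None
            continue
        m = _NBIB_TAG.match(line)
        if m:
            key = m.group(1)
            fields.setdefault(key, []).append(m.group(2))
        elif line.startswith("      ") and key is not None:
            fields[key][-1] += " " + line.strip()
    flush()
    return records


# ---------------------------------------------------------------------------
# Filtering and summaries

def filter_records(records: Iterable[PublicationRecord],
                   require_human: bool = True,
                   require_english_abstract: bool = True,
                   ) -> list[PublicationRecord]:
    """Return records passing all enabled predicates, order preserved.

    Pure: the input records are not modified.
    """
    out = []
    for rec in records:
        if require_human and not rec.is_human_study:
            continue
        if require_english_abstract and not rec.has_english_abstract:
            continue
        out.append(rec)
    return out


def summarize_corpora(corpora: list[ConceptCorpus]) -> CorpusSummary:
    """Count records per concept, their simple sum, and distinct PMIDs."""
    if not corpora:
        raise ValueError("at least one corpus required")
    per: dict[str, int] = {}
    union: set[str] = set()
    for corpus in corpora:
        seen: set[str] = set()
        for rec in corpus.records:
            if rec.pmid in seen:
                raise ValueError(
                    f"duplicate pmid {rec.pmid!r} in corpus {corpus.concept!r}")
            seen.add(rec.pmid)
        per[corpus.concept] = per.get(corpus.concept, 0) + len(corpus.records)
        union |= seen
    return CorpusSummary(per, sum(per.values()), len(union))


# ---------------------------------------------------------------------------
# Internal record store: one JSON object per line, UTF-8

def write_records_jsonl(records: Iterable[PublicationRecord],
                        path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict(), ensure_ascii=False,
                                sort_keys=True) + "\n")


def read_records_jsonl(path: Union[str, Path]) -> Iterator[PublicationRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                yield PublicationRecord.from_json_dict(json.loads(line))
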