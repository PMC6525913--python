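"""Controlled topic vocabulary: expert seeds, index-term enrichment, and
embedding-proposed synonyms gated by manual review.

The vocabulary is versioned and append-only with respect to expert terms:
enrichment and review may add terms but never remove a seed.  Terms carry
an ``origin`` label (``expert`` / ``index_term`` / ``embedding``) so the
provenance of every matchable topic is auditable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

from .normalize import normalize_phrase

ORIGINS = ("expert", "index_term", "embedding")

# "networks/systems" and "complex, complexity" style cells list alternatives
_ALT_SPLIT = re.compile(r"[/,]")


@dataclass(frozen=True)
class VocabularyTerm:
    """A single topic term: normalized surface, provenance, review state."""

    surface: str
    origin: str
    concept_hints: frozenset[str] = frozenset()
    accepted: bool = True

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty vocabulary surface")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class Vocabulary:
    """Versioned set of topic terms keyed by normalized surface."""

    terms: dict[str, VocabularyTerm] = field(default_factory=dict)
    version: int = 0
    audit_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __contains__(self, phrase: str) -> bool:
        return normalize_phrase(phrase) in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, phrase: str) -> VocabularyTerm | None:
        return self.terms.get(normalize_phrase(phrase))

    def accepted_surfaces(self) -> list[str]:
        """Surfaces matchable by the extraction engine (review-gated)."""
        return sorted(s for s, t in self.terms.items() if t.accepted)

    def expert_surfaces(self) -> set[str]:
        return {s for s, t in self.terms.items() if t.origin == "expert"}

    def _with_terms(self, new_terms: dict[str, VocabularyTerm],
                    audit: Iterable[tuple[str, str, str]] = ()) -> "Vocabulary":
        return Vocabulary(new_terms, self.version + 1,
                          self.audit_log + list(audit))

    def add_terms(self, terms: Iterable[VocabularyTerm]) -> "Vocabulary":
        """New vocabulary with ``terms`` added; existing surfaces keep their
        entry but gain any new concept hints.  Bumps the version."""
        merged = dict(self.terms)
        for term in terms:
            surface = normalize_phrase(term.surface)
            term = replace(term, surface=surface)
            if surface in merged:
                old = merged[surface]
                merged[surface] = replace(
                    old, concept_hints=old.concept_hints | term.concept_hints)
            else:
                merged[surface] = term
        return self._with_terms(merged)

    # -- persistence --------------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["surface", "origin", "concept_hints", "accepted",
                        "version"])
            for surface in sorted(self.terms):
                t = self.terms[surface]
                w.writerow([t.surface, t.origin,
                            "|".join(sorted(t.concept_hints)),
                            int(t.accepted), self.version])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Vocabulary":
        terms: dict[str, VocabularyTerm] = {}
        version = 0
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                hints = frozenset(h for h in row["concept_hints"].split("|") if h)
                terms[row["surface"]] = VocabularyTerm(
                    row["surface"], row["origin"], hints,
                    bool(int(row["accepted"])))
                version = int(row["version"])
        return cls(terms, version)


@dataclass(frozen=True)
class SynonymCandidate:
    """An embedding-proposed synonym awaiting manual review."""

    seed_surface: str
    candidate_surface: str
    similarity: float

    def __post_init__(self) -> None:
        if self.candidate_surface == self.seed_surface:
            raise ValueError("candidate equals seed surface")


# ---------------------------------------------------------------------------
# Seed vocabulary

def _split_alternatives(cell: str) -> list[str]:
    parts = [p.strip() for p in _ALT_SPLIT.split(cell)]
    return [p for p in parts if p]


def load_seed_vocabulary(seed_table: Union[str, Path, None] = None) -> Vocabulary:
    """Load the expert seed list into a version-1 vocabulary.

    ``seed_table`` is a CSV with columns ``concept,term``; ``None`` loads
    the packaged expert list for the neuroplasticity / stroke recovery /
    learning case study.  Cells listing alternatives separated by slashes
    or commas ("networks/systems") become separate terms, each hinted with
    the cell's concept column.
    """
    if seed_table is None:
        ref = resources.files("conceptlink.data") / "seed_vocabulary.csv"
        with resources.as_file(ref) as p:
            return load_seed_vocabulary(p)
    rows: list[tuple[str, str]] = []
    with open(seed_table, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"concept", "term"} <= set(
                reader.fieldnames):
            raise ValueError("seed table requires 'concept' and 'term' columns")
        for row in reader:
            if row["term"] and row["term"].strip():
                rows.append((row["concept"].strip(), row["term"]))
    if not rows:
        raise ValueError("seed table is empty")
    terms = [
        VocabularyTerm(normalize_phrase(alt), "expert",
                       frozenset({concept}), accepted=True)
        for concept, cell in rows
        for alt in _split_alternatives(cell)
    ]
    return Vocabulary().add_terms(terms)


# ---------------------------------------------------------------------------
# Index-term enrichment

def enrich_from_index_terms(vocab: Vocabulary, corpora: Iterable,
                            min_doc_count: int = 5) -> Vocabulary:
    """Add author keywords / MeSH descriptors used in at least
    ``min_doc_count`` records as accepted ``index_term`` entries.

    Document counts are over distinct PMIDs across all corpora.  Terms
    already in the vocabulary are left untouched.  The version is bumped
    even when nothing qualifies, recording that enrichment ran.
    """
    if min_doc_count < 1:
        raise ValueError("min_doc_count must be >= 1")
    docs_per_term: dict[str, set[str]] = {}
    for corpus in corpora:
        for rec in corpus.records:
            for raw in rec.index_terms:
                surface = normalize_phrase(raw)
                if surface:
                    docs_per_term.setdefault(surface, set()).add(rec.pmid)
    new = [
        VocabularyTerm(surface, "index_term", frozenset(), accepted=True)
        for surface, pmids in sorted(docs_per_term.items())
        if len(pmids) >= min_doc_count and surface not in vocab.terms
    ]
    return vocab.add_terms(new)


# ---------------------------------------------------------------------------
# Embedding-based synonym proposal and review

def propose_synonyms(model, vocab: Vocabulary, k: int = 10,
                     min_similarity: float = 0.6) -> list[SynonymCandidate]:
    """Propose up to ``k`` nearest-neighbour synonyms per accepted term.

    Single-token terms are queried directly.  A multi-word term is queried
    through its head (final) token; neighbour tokens must co-occur with
    every remaining token of the phrase in at least one document, and the
    candidate surface is the phrase with its head replaced.  Candidates
    already in the vocabulary are dropped.  Output is sorted by similarity
    descending, then candidate surface, then seed surface.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[SynonymCandidate] = []
    for surface in vocab.accepted_surfaces():
        tokens = surface.split()
        head, rest = tokens[-1], tokens[:-1]
        if head not in model:
            continue
        if any(tok not in model for tok in rest):
            continue
        for neighbor, sim in model.most_similar(head, k):
            if sim < min_similarity:
                continue
            if rest and not all(model.cooccurs_in_document(neighbor, tok)
                                for tok in rest):
                continue
            candidate = " ".join(rest + [neighbor])
            if candidate in vocab.terms or candidate == surface:
                continue
            out.append(SynonymCandidate(surface, candidate, float(sim)))
    out.sort(key=lambda c: (-c.similarity, c.candidate_surface, c.seed_surface))
    return out


def apply_review(vocab: Vocabulary, candidates: list[SynonymCandidate],
                 decisions: Mapping[str, str]) -> Vocabulary:
    """Apply accept/reject decisions to proposed synonyms.

    Accepted candidates enter the vocabulary with origin ``embedding`` and
    ``accepted=True``; rejections are recorded in the audit log; undecided
    candidates are ignored.  A decision naming an unproposed candidate is
    an error.
    """
    known = {c.candidate_surface: c for c in candidates}
    unknown = set(decisions) - set(known)
    if unknown:
        raise ValueError(f"decisions for unproposed candidates: {sorted(unknown)}")
    added: dict[str, VocabularyTerm] = {}
    audit: list[tuple[str, str, str]] = []
    for surface, verdict in sorted(decisions.items()):
        if verdict not in ("accept", "reject"):
            raise ValueError(f"decision must be accept|reject, got {verdict!r}")
        audit.append((surface, known[surface].seed_surface, verdict))
        if verdict == "accept":
            added[surface] = VocabularyTerm(surface, "embedding", frozenset(),
                                            accepted=True)
    merged = dict(vocab.terms)
    for surface, term in added.items():
        merged.setdefault(surface, term)
    return Vocabulary(merged, vocab.version + 1, vocab.audit_log + audit)
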