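"""Pipeline orchestration: validated run configuration, stage chaining,
and reproducible run manifests.

``run_pipeline`` executes parse -> filter -> vocabulary (seed / enrich /
embed / review) -> extract -> link map -> temporal -> rank, writing every
export plus a manifest recording the package version, seed, config hash
and per-stage counts.  Deterministic stages re-run bit-identically from
the same config and seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import extraction, linkmap, ranking, temporal, vocabulary
from .embedding import EmbeddingConfig, train_embedding
from .records import (ConceptCorpus, filter_records, parse_nbib,
                      parse_pubmed_xml, summarize_corpora)
from .synthetic import CorpusSpec, generate_corpus


class FilterConfig(BaseModel):
    require_human: bool = True
    require_english_abstract: bool = True


class VocabularyConfig(BaseModel):
    seed_table: Optional[str] = None      # None -> packaged expert list
    use_synthetic_topics: bool = False    # planted topics as expert seeds
    min_doc_count: int = Field(5, ge=1)


class EmbeddingParams(BaseModel):
    enabled: bool = True
    vector_size: int = Field(100, ge=1)
    window: int = Field(5, ge=1)
    min_count: int = Field(5, ge=1)


class SynonymConfig(BaseModel):
    k: int = Field(10, ge=1)
    min_similarity: float = Field(0.6, ge=-1.0, le=1.0)
    decisions: Optional[str] = None       # CSV candidate,decision


class MapConfig(BaseModel):
    min_count: int = Field(1, ge=1)
    top_n_per_group: Optional[int] = Field(None, ge=1)


class EraConfig(BaseModel):
    name: str
    start_year: int
    end_year: int

    @model_validator(mode="after")
    def _ordered(self):
        if self.start_year > self.end_year:
            raise ValueError(f"era {self.name!r}: start_year after end_year")
        return self


class RankConfig(BaseModel):
    top_n: int = Field(30, ge=1)
    strategy: str = "score_sum"

    @field_validator("strategy")
    @classmethod
    def _known(cls, v):
        if v not in ranking.STRATEGIES:
            raise ValueError(f"strategy must be one of {ranking.STRATEGIES}")
        return v


class SyntheticConfig(BaseModel):
    n_records_per_concept: dict[str, int]
    topic_frequency: dict[str, dict[str, float]]  # concept -> topic -> p
    year_distribution: dict[int, float] = Field(
        default_factory=lambda: {y: 1.0 for y in range(1995, 2019)})
    overlap_rate: float = Field(0.0, ge=0.0, le=1.0)
    synonym_pairs: list[tuple[str, str]] = Field(default_factory=list)
    control_pairs: list[tuple[str, str]] = Field(default_factory=list)
    frames_per_pair: int = 100


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    concepts: list[str]
    inputs: dict[str, str] = Field(default_factory=dict)  # concept -> path
    synthetic: Optional[SyntheticConfig] = None
    filters: FilterConfig = Field(default_factory=FilterConfig)
    vocabulary: VocabularyConfig = Field(default_factory=VocabularyConfig)
    embedding: EmbeddingParams = Field(default_factory=EmbeddingParams)
    synonyms: SynonymConfig = Field(default_factory=SynonymConfig)
    map: MapConfig = Field(default_factory=MapConfig)
    eras: list[EraConfig] = Field(default_factory=lambda: [
        EraConfig(name=e.name, start_year=e.start_year, end_year=e.end_year)
        for e in temporal.DEFAULT_ERAS])
    year_range: tuple[int, int] = (1975, 2018)
    rank: RankConfig = Field(default_factory=RankConfig)
    seed: int = 0
    output_dir: str = "conceptlink_out"

    @model_validator(mode="after")
    def _check(self):
        if len(self.concepts) < 2:
            raise ValueError("need at least 2 concepts")
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("duplicate concept labels")
        if self.synthetic is None and set(self.inputs) != set(self.concepts):
            raise ValueError("inputs must cover every concept (or provide "
                             "a synthetic corpus spec)")
        spans = sorted(self.eras, key=lambda e: e.start_year)
        for a, b in zip(spans, spans[1:]):
            if b.start_year <= a.end_year:
                raise ValueError(f"eras {a.name!r} and {b.name!r} overlap")
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("year_range end before start")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_corpora(config: RunConfig) -> list[ConceptCorpus]:
    if config.synthetic is not None:
        syn = config.synthetic
        spec = CorpusSpec(
            concepts=list(config.concepts),
            n_records_per_concept=dict(syn.n_records_per_concept),
            topic_frequency={(t, c): p
                             for c, topics in syn.topic_frequency.items()
                             for t, p in topics.items()},
            synonym_pairs=[tuple(p) for p in syn.synonym_pairs],
            control_pairs=[tuple(p) for p in syn.control_pairs],
            year_distribution=dict(syn.year_distribution),
            overlap_rate=syn.overlap_rate,
            frames_per_pair=syn.frames_per_pair,
            seed=config.seed)
        corpora, _ = generate_corpus(spec)
        return corpora
    corpora = []
    for concept in config.concepts:
        path = Path(config.inputs[concept])
        if path.suffix.lower() == ".nbib":
            records = parse_nbib(path, concept)
        else:
            records = parse_pubmed_xml(path, concept)
        corpora.append(ConceptCorpus(concept, records))
    return corpora


def _read_decisions(path) -> dict[str, str]:
    with open(path, newline="", encoding="utf-8") as fh:
        return {row["candidate"]: row["decision"]
                for row in csv.DictReader(fh)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - context for operators
                raise StageError(name, exc) from exc
        return deco

    corpora = stage("parse")(lambda: _load_corpora(config))
    manifest["stages"]["parse"] = {
        c.concept: len(c.records) for c in corpora}

    def _filter():
        return [ConceptCorpus(c.concept, filter_records(
            c.records, config.filters.require_human,
            config.filters.require_english_abstract), c.search_date)
            for c in corpora]
    corpora = stage("filter")(_filter)
    summary = summarize_corpora(corpora)
    manifest["stages"]["filter"] = {
        "per_concept": summary.per_concept_counts,
        "simple_sum": summary.simple_sum,
        "deduped_union": summary.deduped_union,
    }

    def _vocab():
        if config.vocabulary.use_synthetic_topics:
            if config.synthetic is None:
                raise ValueError("use_synthetic_topics requires a synthetic "
                                 "corpus spec")
            terms = [
                vocabulary.VocabularyTerm(
                    vocabulary.normalize_phrase(t), "expert",
                    frozenset({c}), True)
                for c, topics in config.synthetic.topic_frequency.items()
                for t in topics]
            vocab = vocabulary.Vocabulary().add_terms(terms)
        else:
            vocab = vocabulary.load_seed_vocabulary(
                config.vocabulary.seed_table)
        vocab = vocabulary.enrich_from_index_terms(
            vocab, corpora, config.vocabulary.min_doc_count)
        candidates = []
        if config.embedding.enabled:
            model = train_embedding(corpora, EmbeddingConfig(
                vector_size=config.embedding.vector_size,
                window=config.embedding.window,
                min_count=config.embedding.min_count,
                seed=config.seed))
            candidates = vocabulary.propose_synonyms(
                model, vocab, config.synonyms.k,
                config.synonyms.min_similarity)
            if config.synonyms.decisions:
                vocab = vocabulary.apply_review(
                    vocab, candidates,
                    _read_decisions(config.synonyms.decisions))
        return vocab, candidates

    vocab, candidates = stage("vocabulary")(_vocab)
    vocab.to_csv(out_dir / "vocabulary.csv")
    manifest["outputs"].append("vocabulary.csv")
    manifest["stages"]["vocabulary"] = {
        "terms": len(vocab), "version": vocab.version,
        "synonym_candidates": len(candidates)}

    def _extract():
        return {c.concept: extraction.extract_corpus_topics(c, vocab)
                for c in corpora}
    assignments = stage("extract")(_extract)
    manifest["stages"]["extract"] = {
        concept: sum(1 for a in asg if a.topics)
        for concept, asg in assignments.items()}

    cmap = stage("map")(lambda: linkmap.build_link_map(
        assignments, config.map.min_count, config.map.top_n_per_group))
    linkmap.write_theme_table(cmap, out_dir / "themes.csv")
    (out_dir / "concept_map.graphml").write_text(
        linkmap.export_graph(cmap, "graphml"), encoding="utf-8")
    (out_dir / "concept_map.json").write_text(
        linkmap.export_graph(cmap, "json"), encoding="utf-8")
    manifest["outputs"] += ["themes.csv", "concept_map.graphml",
                            "concept_map.json"]
    manifest["stages"]["map"] = {
        "themes": len(cmap.themes),
        "full_intersection": len(cmap.full_intersection())}

    all_records = [r for c in corpora for r in c.records]
    all_assignments = []
    seen: set[str] = set()
    for asg in assignments.values():
        for a in asg:
            if a.pmid not in seen:
                seen.add(a.pmid)
                all_assignments.append(a)

    def _temporal():
        series = temporal.topic_year_distribution(
            all_assignments, all_records, config.year_range)
        eras = [temporal.EraDefinition(e.name, e.start_year, e.end_year)
                for e in config.eras]
        era_maps = temporal.era_link_maps(assignments, all_records, eras,
                                          config.map.min_count)
        return series, era_maps
    series, era_maps = stage("temporal")(_temporal)
    temporal.write_time_series_csv(series, out_dir / "topic_years.csv")
    manifest["outputs"].append("topic_years.csv")
    for name, emap in era_maps.items():
        fname = f"themes_{name}.csv"
        linkmap.write_theme_table(emap, out_dir / fname)
        manifest["outputs"].append(fname)
    manifest["stages"]["temporal"] = {
        "topics": len(series),
        "eras": {name: len(m.themes) for name, m in era_maps.items()}}

    def _rank():
        years = {r.pmid: r.year for r in all_records}
        weights = ranking.article_weights(all_assignments, cmap, years,
                                          config.rank.strategy)
        return ranking.top_articles(weights, config.rank.top_n)
    try:
        shortlist = _rank()
    except ValueError:
        shortlist = []  # no full-intersection theme in this corpus
    titles = {r.pmid: r.title for r in all_records}
    ranking.write_shortlist_csv(shortlist, out_dir / "top_articles.csv",
                                titles)
    manifest["outputs"].append("top_articles.csv")
    manifest["stages"]["rank"] = {"selected": len(shortlist)}

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1), encoding="utf-8")
    return manifest


def _version() -> str:
    try:
        return _pkg_version("conceptlink")
    except PackageNotFoundError:
        return "unknown"
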