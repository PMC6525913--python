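import pytest
from lxml import etree

from conceptlink import (ConceptCorpus, filter_records, parse_nbib,
                         parse_pubmed_xml, read_records_jsonl,
                         summarize_corpora, write_records_jsonl)

from conftest import make_record


class TestParsePubmedXml:
    def test_empty_article_set(self):
        assert parse_pubmed_xml(
            "<PubmedArticleSet></PubmedArticleSet>", "c") == []

    def test_three_article_fixture_flags(self, three_article_xml):
        records = parse_pubmed_xml(three_article_xml, "stroke recovery")
        assert [r.pmid for r in records] == ["1001", "1002", "1003"]
        by = {r.pmid: r for r in records}
        assert by["1001"].has_english_abstract and by["1001"].is_human_study
        assert not by["1002"].has_english_abstract  # no abstract element
        assert by["1002"].abstract == ""
        assert by["1002"].is_human_study
        assert by["1003"].has_english_abstract
        assert not by["1003"].is_human_study  # no Humans descriptor
        assert all(r.concepts == {"stroke recovery"} for r in records)

    def test_index_terms_are_set_union_of_mesh_and_keywords(
            self, three_article_xml):
        rec = parse_pubmed_xml(three_article_xml, "c")[0]
        # 2 MeSH + 2 keywords, one keyword ("stroke") differing only by case
        # from a descriptor is kept as a distinct raw string
        assert rec.index_terms == {"Humans", "Stroke", "stroke",
                                   "Neuronal Plasticity"}

    def test_year_precedence_medlinedate(self, three_article_xml):
        by = {r.pmid: r for r in parse_pubmed_xml(three_article_xml, "c")}
        assert by["1001"].year == 2015
        assert by["1002"].year == 1999  # first 4-digit token of MedlineDate

    def test_article_without_pmid_skipped(self):
        xml = """<PubmedArticleSet><PubmedArticle><MedlineCitation>
          <Article><ArticleTitle>No id</ArticleTitle></Article>
          </MedlineCitation></PubmedArticle></PubmedArticleSet>"""
        assert parse_pubmed_xml(xml, "c") == []

    def test_malformed_xml_reports_position(self):
        with pytest.raises(etree.XMLSyntaxError) as err:
            parse_pubmed_xml("<PubmedArticleSet><broken", "c")
        assert err.value.lineno is not None


class TestParseNbib:
    NBIB = """PMID- 2001
TI  - Motor learning and gait speed
      after stroke
AB  - Practice improved gait speed in the cohort.
MH  - Humans
MH  - Stroke/rehabilitation*
OT  - motor learning
DP  - 2016 Mar
LA  - eng

PMID- 2002
TI  - An animal study
AB  - Observations in rodents.
MH  - Rats
DP  - 1998
LA  - eng
"""

    def test_fields_and_continuation(self):
        records = parse_nbib(self.NBIB, "learning")
        assert len(records) == 2
        first = records[0]
        assert first.pmid == "2001"
        assert first.title == "Motor learning and gait speed after stroke"
        assert first.year == 2016
        assert first.is_human_study
        # MH descriptor part only (subheading and asterisk stripped)
        assert "Stroke" in first.index_terms
        assert "motor learning" in first.index_terms
        assert not records[1].is_human_study


class TestFilterRecords:
    def test_no_predicates_is_identity(self):
        records = [make_record(1, human=False, english=False)]
        assert filter_records(records, False, False) == records

    def test_hand_counted_survivors(self):
        records = [
            make_record(1, human=True, english=True),
            make_record(2, human=True, english=False),
            make_record(3, human=False, english=True),
            make_record(4, human=True, english=True),
            make_record(5, human=False, english=False),
        ]
        kept = filter_records(records, True, True)
        assert [r.pmid for r in kept] == ["1", "4"]

    def test_all_filtered_out(self):
        records = [make_record(i, human=False) for i in range(3)]
        assert filter_records(records, require_human=True,
                              require_english_abstract=False) == []

    def test_idempotent_and_pure(self):
        records = [make_record(i, human=i % 2 == 0) for i in range(6)]
        before = list(records)
        once = filter_records(records, True, False)
        assert filter_records(once, True, False) == once
        assert records == before


class TestSummarizeCorpora:
    def test_single_corpus(self):
        corpus = ConceptCorpus("c", [make_record(i) for i in range(10)])
        s = summarize_corpora([corpus])
        assert s.simple_sum == s.deduped_union == 10

    def test_shared_pmids_dedup(self):
        shared = [make_record(i, concepts=("a",)) for i in (1, 2, 3)]
        a = ConceptCorpus("a", shared + [make_record(4), make_record(5)])
        b = ConceptCorpus(
            "b", [make_record(i, concepts=("b",)) for i in (1, 2, 3, 6)])
        s = summarize_corpora([a, b])
        assert s.simple_sum == 9
        assert s.deduped_union == 6

    def test_duplicate_pmid_within_corpus_rejected(self):
        with pytest.raises(ValueError, match="duplicate pmid"):
            ConceptCorpus("c", [make_record(1), make_record(1)])

    def test_requires_at_least_one_corpus(self):
        with pytest.raises(ValueError):
            summarize_corpora([])


def test_jsonl_round_trip(tmp_path, three_article_xml):
    records = parse_pubmed_xml(three_article_xml, "c")
    path = tmp_path / "records.jsonl"
    write_records_jsonl(records, path)
    back = list(read_records_jsonl(path))
    assert back == records
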