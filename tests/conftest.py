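import pytest

from conceptlink import (ConceptCorpus, CorpusSpec, PublicationRecord,
                         TopicAssignment, Vocabulary, VocabularyTerm)

THREE_ARTICLE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1001</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2015</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>Motor learning after stroke</ArticleTitle>
        <Abstract><AbstractText>Motor learning improves skill after training.</AbstractText></Abstract>
        <Language>eng</Language>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Humans</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Stroke</DescriptorName></MeshHeading>
      </MeshHeadingList>
      <KeywordList><Keyword>stroke</Keyword><Keyword>Neuronal Plasticity</Keyword></KeywordList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1002</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><MedlineDate>1999 Jan-Feb</MedlineDate></PubDate></JournalIssue></Journal>
        <ArticleTitle>A study without an abstract</ArticleTitle>
        <Language>eng</Language>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Humans</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1003</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2010</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>Synaptic consolidation in rodents</ArticleTitle>
        <Abstract><AbstractText>Consolidation was observed in rodent synapses.</AbstractText></Abstract>
        <Language>eng</Language>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Rats</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


def make_record(pmid, title="", abstract="", index_terms=(), year=2000,
                human=True, english=True, concepts=("c1",)):
    return PublicationRecord(
        pmid=str(pmid), title=title, abstract=abstract,
        index_terms=set(index_terms), year=year,
        has_english_abstract=english, is_human_study=human,
        concepts=set(concepts))


def vocab_of(*surfaces):
    return Vocabulary().add_terms(
        [VocabularyTerm(s, "expert", frozenset(), True) for s in surfaces])


def assignment(pmid, *topics):
    from conceptlink.extraction import Match

    a = TopicAssignment(str(pmid))
    for t in topics:
        a.topics.add(t)
        a.matches.append(Match(t, "abstract", 0, 1))
    return a


@pytest.fixture
def three_article_xml():
    return THREE_ARTICLE_XML


@pytest.fixture
def toy_assignments():
    """Concept A mentions {x, y}, B mentions {y}, C mentions {y, z}."""
    return {
        "A": [assignment("a1", "x", "y")],
        "B": [assignment("b1", "y")],
        "C": [assignment("c1", "y", "z")],
    }


@pytest.fixture
def small_spec():
    return CorpusSpec(
        concepts=["alpha", "beta", "gamma"],
        n_records_per_concept={"alpha": 8, "beta": 7, "gamma": 6},
        topic_frequency={
            ("motor imagery", "alpha"): 0.7,
            ("gait speed", "beta"): 0.6,
            ("spatial neglect", "gamma"): 0.6,
            ("consolidation", "alpha"): 0.4,
            ("consolidation", "beta"): 0.4,
            ("consolidation", "gamma"): 0.4,
        },
        year_distribution={1999: 1.0, 2015: 1.0},
        seed=11)


@pytest.fixture
def corpus_pair():
    recs1 = [make_record(i, abstract="motor imagery practice") for i in (1, 2, 3)]
    recs2 = [make_record(i, abstract="gait speed recovery") for i in (4, 5)]
    return [ConceptCorpus("c1", recs1), ConceptCorpus("c2", recs2)]
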