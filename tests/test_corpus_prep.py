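"""Corpus preparation: parsing, relevance filtering, concept replacement,
tokenization."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kce.corpus_prep import (
    ArticleRecord,
    ConceptAnnotation,
    CorpusPrepError,
    apply_concept_annotations,
    concept_token,
    lemmatize,
    parse_annotations,
    parse_articles,
    preprocess_text,
    read_corpus,
    select_relevant,
    write_corpus,
)
from kce.corpus_prep import TokenDocument


def art(pmid="1", year=2000, mesh=(), keywords=(), title="T", abstract="A"):
    return ArticleRecord(pmid, year, frozenset(mesh), frozenset(keywords), title, abstract)


# -- parse_articles ---------------------------------------------------------

class TestParseArticles:
    def test_empty_source_gives_empty_list(self):
        assert parse_articles("") == []

    def test_earliest_year_is_recorded(self):
        recs = parse_articles("9\t2001;1999\tD000001\t\tTitle\tBody\n")
        assert recs[0].year == 1999

    def test_three_row_table_matches_hand_parse(self):
        tsv = (
            "1\t1995\tD009369;D011494\tkw one;kw two\tFirst title\tFirst abstract\n"
            "2\t2003\t\t\tSecond title\t\n"
            "3\t2010;2008\tD002289\tNSCLC\tThird title\tThird abstract\n"
        )
        recs = parse_articles(tsv)
        assert len(recs) == 3
        assert recs[0] == art(
            "1", 1995, {"D009369", "D011494"}, {"kw one", "kw two"},
            "First title", "First abstract",
        )
        assert recs[1].abstract == ""  # missing abstract is not an error
        assert recs[2] == art("3", 2008, {"D002289"}, {"NSCLC"}, "Third title", "Third abstract")

    def test_xml_dialect_round_trip(self):
        xml = """<PubmedArticleSet>
          <PubmedArticle>
            <PMID>42</PMID>
            <DateCompleted><Year>2005</Year></DateCompleted>
            <PubDate><Year>2002</Year></PubDate>
            <ArticleTitle>An XML title</ArticleTitle>
            <Abstract><AbstractText>Some text.</AbstractText></Abstract>
            <MeshHeadingList>
              <MeshHeading><DescriptorName UI="D009369">Neoplasms</DescriptorName></MeshHeading>
            </MeshHeadingList>
            <KeywordList><Keyword>kinase</Keyword></KeywordList>
          </PubmedArticle>
        </PubmedArticleSet>"""
        (rec,) = parse_articles(xml)
        assert rec.pmid == "42"
        assert rec.year == 2002  # earliest among the dated fields
        assert rec.mesh_ids == {"D009369"}
        assert rec.keywords == {"kinase"}
        assert rec.abstract == "Some text."

    def test_malformed_row_names_the_field(self):
        with pytest.raises(CorpusPrepError, match="year"):
            parse_articles("7\tnot-a-year\t\t\tT\tA\n")


# -- select_relevant --------------------------------------------------------

class TestSelectRelevant:
    def test_child_descriptor_selects(self, toy_hierarchy):
        a = art(mesh={"D002289"})  # grandchild of Neoplasms
        assert select_relevant([a], {"D009369"}, toy_hierarchy) == [a]

    def test_empty_abstract_excludes_despite_matching_descriptor(self, toy_hierarchy):
        a = art(mesh={"D009369"}, abstract="")
        assert select_relevant([a], {"D009369"}, toy_hierarchy) == []

    def test_no_mesh_no_keywords_excludes(self, toy_hierarchy):
        a = art(mesh=set(), keywords=set())
        assert select_relevant([a], {"D009369"}, toy_hierarchy) == []

    def test_keyword_matches_synonym_case_insensitively(self, toy_hierarchy):
        a = art(keywords={"nsclc"})  # synonym of a descendant descriptor
        assert select_relevant([a], {"D009369"}, toy_hierarchy) == [a]

    def test_unknown_search_descriptor_is_an_error(self, toy_hierarchy):
        with pytest.raises(CorpusPrepError):
            select_relevant([], {"D999999"}, toy_hierarchy)

    def test_monotone_in_search_set(self, toy_hierarchy):
        articles = [
            art("1", mesh={"D002289"}),
            art("2", mesh={"D011494"}),
            art("3", mesh={"D051096"}),
            art("4", keywords={"tumors"}),
        ]
        small = select_relevant(articles, {"D009369"}, toy_hierarchy)
        large = select_relevant(articles, {"D009369", "D011494", "D051096"}, toy_hierarchy)
        assert set(a.pmid for a in small) <= set(a.pmid for a in large)
        assert [a.pmid for a in large] == ["1", "2", "3", "4"]  # order preserved


# -- apply_concept_annotations ----------------------------------------------

class TestConceptReplacement:
    def test_disease_span_becomes_mesh_token(self):
        a = art(title="Study", abstract="non-small-cell lung carcinoma patients")
        # offsets into "Study non-small-cell lung carcinoma patients"
        ann = ConceptAnnotation("1", 6, 35, "disease", "MESH:D002289")
        out = apply_concept_annotations(a, [ann])
        assert out == "Study meshd002289 patients"

    def test_human_species_annotation_is_skipped(self):
        a = art(title="A", abstract="patient cohort")
        ann = ConceptAnnotation("1", 2, 9, "species", "9606")
        assert apply_concept_annotations(a, [ann]) == "A patient cohort"

    def test_nonhuman_species_is_replaced(self):
        a = art(title="A", abstract="mouse model")
        ann = ConceptAnnotation("1", 2, 7, "species", "10090")
        assert apply_concept_annotations(a, [ann]) == "A taxon10090 model"

    def test_empty_annotation_list_is_identity(self):
        a = art()
        assert apply_concept_annotations(a, []) == a.annotated_text

    def test_out_of_range_offset_names_pmid(self):
        a = art(pmid="77", title="T", abstract="x")
        ann = ConceptAnnotation("77", 0, 99, "gene", "1956")
        with pytest.raises(CorpusPrepError, match="77"):
            apply_concept_annotations(a, [ann])

    def test_overlap_keeps_longest_span(self):
        a = art(title="T", abstract="lung carcinoma")
        # "lung" inside "lung carcinoma": the longer disease span wins
        short = ConceptAnnotation("1", 2, 6, "disease", "D008168")
        long = ConceptAnnotation("1", 2, 16, "disease", "D008175")
        assert apply_concept_annotations(a, [short, long]) == "T meshd008175"

    def test_characters_outside_spans_are_preserved(self):
        a = art(title="Alpha beta", abstract="gamma EGFR delta")
        ann = ConceptAnnotation("1", 17, 21, "gene", "1956")
        out = apply_concept_annotations(a, [ann])
        assert out == "Alpha beta gamma ncbigene1956 delta"
        # everything except the span is untouched
        assert out[:17] == a.annotated_text[:17]
        assert out.endswith(" delta")

    @pytest.mark.parametrize(
        "category,concept_id,expected",
        [
            ("disease", "MESH:D002289", "meshd002289"),
            ("gene", "1956", "ncbigene1956"),
            ("species", "10090", "taxon10090"),
            ("cellline", "CVCL_0023", "cvcl0023"),
            ("snp", "rs334", "rs334"),
        ],
    )
    def test_concept_token_dialect(self, category, concept_id, expected):
        assert concept_token(category, concept_id) == expected


# -- preprocess_text --------------------------------------------------------

class TestPreprocess:
    def test_acronym_retained_stopword_removed(self, stoplist):
        # ALL (acute lymphocytic leukemia) survives; "all"/"All" do not
        toks = preprocess_text("ALL all All remission", stoplist)
        assert toks == ["all", "remission"]

    def test_comparative_lemmatized(self, stoplist):
        assert preprocess_text("higher doses", stoplist) == ["high", "dose"]

    def test_empty_text(self, stoplist):
        assert preprocess_text("", stoplist) == []

    def test_hyphen_splits_compounds(self, stoplist):
        assert preprocess_text("non-small-cell", stoplist) == ["non", "small", "cell"]

    def test_single_letters_removed(self, stoplist):
        assert preprocess_text("a B c vitamin K", stoplist) == ["vitamin"]

    def test_no_punctuation_stopwords_or_uppercase_in_output(self, stoplist):
        text = "The patient's EGFR-mutant tumors (n=12) responded; P<0.05!"
        toks = preprocess_text(text, stoplist)
        for tok in toks:
            assert not set(tok) & set(string.punctuation)
            assert tok == tok.lower()
            assert len(tok) > 1

    @given(
        text=st.text(
            alphabet=string.ascii_lowercase + string.digits + " .,;-()",
            max_size=200,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_punctuation_stop_lowercase_stages_are_a_fixed_point(self, text, stoplist):
        # over lowercase input (no acronym/stop-word collisions) re-running
        # the normalization on its own output changes nothing
        once = preprocess_text(text, stoplist)
        twice = preprocess_text(" ".join(once), stoplist)
        assert once == twice

    @pytest.mark.parametrize(
        "inflected,base",
        [("studies", "study"), ("tumors", "tumor"), ("analyses", "analysis"),
         ("mice", "mouse"), ("higher", "high"), ("branches", "branch")],
    )
    def test_lemmatizer_pairs(self, inflected, base):
        assert lemmatize(inflected) == base


# -- annotation parsing and corpus round trip --------------------------------

def test_parse_annotations_and_validation():
    anns = parse_annotations("1\t0\t4\tgene\t1956\n1\t5\t9\tdisease\tD002289\n")
    assert len(anns) == 2 and anns[0].category == "gene"
    with pytest.raises(CorpusPrepError):
        parse_annotations("1\t9\t4\tgene\t1956\n")  # start >= end


def test_corpus_round_trip(tmp_path):
    docs = [TokenDocument("1", ("alpha", "beta")), TokenDocument("2", ("meshd002289",))]
    path = tmp_path / "corpus.gz"
    write_corpus(docs, path)
    assert read_corpus(path) == docs
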