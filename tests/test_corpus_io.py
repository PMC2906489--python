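"""Corpus reading/writing: GENIA-like XML, plain abstracts, evidence
tables and network exports."""

import logging

import pytest
from lxml import etree

from ppidict.corpus_io import (
    CorpusFormatError,
    read_evidence_table,
    read_genia_xml,
    read_plain_abstracts,
    split_sentences,
    write_evidence_table,
    write_genia_xml,
    write_network,
)
from ppidict.model import InteractionEvidence
from ppidict.network import build_network

from conftest import annotate, corpus_of

GENIA_SAMPLE = """<?xml version="1.0"?>
<set>
  <article>
    <articleinfo><bibliomisc>MEDLINE:90000001</bibliomisc></articleinfo>
    <title>t1</title>
    <abstract>
      <sentence><cons sem="G#protein_molecule">IL-2</cons> binds <cons sem="G#protein_molecule">IL-2R</cons> .</sentence>
    </abstract>
  </article>
  <article>
    <articleinfo><bibliomisc>MEDLINE:90000002</bibliomisc></articleinfo>
    <title>t2</title>
    <abstract>
      <sentence>the <cons sem="G#protein_complex"><cons sem="G#protein_molecule">p50</cons>/<cons sem="G#protein_molecule">p65</cons> heterodimer</cons> was purified .</sentence>
    </abstract>
  </article>
  <article>
    <articleinfo><bibliomisc>MEDLINE:90000003</bibliomisc></articleinfo>
    <title>t3</title>
    <abstract>
      <sentence><cons sem="G#protein_family_or_group">NF-kappa B</cons> activity and <cons sem="G#DNA_domain_or_region">kappa B sites</cons> .</sentence>
      <sentence>no annotations here .</sentence>
    </abstract>
  </article>
</set>
"""


@pytest.fixture
def genia_file(tmp_path):
    p = tmp_path / "mini.xml"
    p.write_text(GENIA_SAMPLE, encoding="utf-8")
    return p


class TestReadGeniaXml:
    def test_documents_and_mention_counts(self, genia_file):
        corpus = read_genia_xml(genia_file)
        assert len(corpus.documents) == 3
        # 2 + 2 (innermost of the nested complex) + 1 (DNA span skipped)
        assert corpus.n_mentions() == 5

    def test_annotated_sentence_classes(self, genia_file):
        corpus = read_genia_xml(genia_file)
        sent = corpus.documents[0].sentences[0]
        assert sent.text == "IL-2 binds IL-2R ."
        assert [m.surface for m in sent.mentions] == ["IL-2", "IL-2R"]
        assert {m.semantic_class for m in sent.mentions} == {
            "protein_molecule"}

    def test_innermost_nesting_rule(self, genia_file):
        corpus = read_genia_xml(genia_file)
        sent = corpus.documents[1].sentences[0]
        assert [m.surface for m in sent.mentions] == ["p50", "p65"]

    def test_surface_equals_text_slice_everywhere(self, genia_file):
        corpus = read_genia_xml(genia_file)
        for _, sent in corpus.iter_sentences():
            for m in sent.mentions:
                assert sent.text[m.start:m.end] == m.surface

    def test_empty_but_valid_corpus(self, tmp_path):
        p = tmp_path / "empty.xml"
        p.write_text("<set></set>", encoding="utf-8")
        assert len(read_genia_xml(p).documents) == 0

    def test_malformed_xml_names_line(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<set>\n<article>\n</set>", encoding="utf-8")
        with pytest.raises(CorpusFormatError, match="line"):
            read_genia_xml(p)

    def test_unknown_dialect_rejected(self, tmp_path):
        p = tmp_path / "foreign.xml"
        p.write_text("<experiment><run/></experiment>", encoding="utf-8")
        with pytest.raises(CorpusFormatError, match="unsupported"):
            read_genia_xml(p)

    def test_insensitive_to_attribute_order_and_whitespace(self, tmp_path):
        a = tmp_path / "a.xml"
        b = tmp_path / "b.xml"
        a.write_text(
            '<set><article><articleinfo><bibliomisc>MEDLINE:1</bibliomisc>'
            '</articleinfo><title>t</title><abstract>'
            '<sentence><cons sem="G#protein_molecule" lex="il2">IL-2</cons>'
            ' binds .</sentence></abstract></article></set>')
        b.write_text(
            '<set>\n\n  <article>\n<articleinfo><bibliomisc>MEDLINE:1'
            '</bibliomisc></articleinfo>\n<title>t</title>\n<abstract>'
            '<sentence><cons lex="il2" sem="G#protein_molecule">IL-2</cons>'
            ' binds .</sentence></abstract>\n</article>\n</set>')
        ca, cb = read_genia_xml(a), read_genia_xml(b)
        sa, sb = ca.documents[0].sentences[0], cb.documents[0].sentences[0]
        assert sa.text == sb.text and sa.mentions == sb.mentions

    def test_write_read_round_trip(self, tmp_path):
        corpus = corpus_of(
            ("X1", [annotate("ABC-1 binds the XYZ-2 receptor .",
                             ["ABC-1", ("XYZ-2", "protein_family_or_group")])]))
        out = tmp_path / "rt.xml"
        write_genia_xml(corpus, out)
        back = read_genia_xml(out)
        assert back.documents[0].doc_id == "X1"
        s0, s1 = corpus.documents[0].sentences[0], back.documents[0].sentences[0]
        assert s0.text == s1.text and s0.mentions == s1.mentions


class TestPlainAbstracts:
    def test_two_records(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("D1\tTitle one\tA binds B. C was measured.\n"
                     "D2\tTitle two\tNothing here.\n", encoding="utf-8")
        corpus = read_plain_abstracts(p)
        assert [d.doc_id for d in corpus.documents] == ["D1", "D2"]
        assert [s.text for s in corpus.documents[0].sentences] == [
            "A binds B.", "C was measured."]

    def test_sentence_split_rule(self):
        assert split_sentences("A binds B. C was measured.") == [
            "A binds B.", "C was measured."]
        # lower-case continuation is not a boundary
        assert split_sentences("binding of p50. to p65 was seen") == [
            "binding of p50. to p65 was seen"]
        # a digit does open a sentence
        assert split_sentences("See text. 5 units were used.") == [
            "See text.", "5 units were used."]

    def test_empty_abstract_warns(self, tmp_path, caplog):
        p = tmp_path / "a.tsv"
        p.write_text("D1\tTitle\t\n", encoding="utf-8")
        with caplog.at_level(logging.WARNING):
            corpus = read_plain_abstracts(p)
        assert corpus.documents[0].sentences == []
        assert any("empty abstract" in r.message for r in caplog.records)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("D1\tTitle\tabstract text\nD2\tonly-two-cols\n")
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_plain_abstracts(p)


def _ev(a, b, doc, idx=0, kw="bind", pid="BND-4", text="x binds y ."):
    return InteractionEvidence(
        protein_a=min(a, b), protein_b=max(a, b), keyword=kw, pattern_id=pid,
        doc_id=doc, sentence_index=idx, sentence_text=text)


class TestEvidenceTable:
    def test_rows_and_header(self, tmp_path):
        p = tmp_path / "ev.tsv"
        write_evidence_table([_ev("a", "b", "D1"), _ev("a", "c", "D1"),
                              _ev("b", "c", "D2")], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4 and lines[0].startswith("protein_a\t")

    def test_empty_table(self, tmp_path):
        p = tmp_path / "ev.tsv"
        write_evidence_table([], p)
        assert len(p.read_text().splitlines()) == 1

    def test_round_trip_identity(self, tmp_path):
        evs = [_ev("a", "b", "D2", 3), _ev("q", "z", "D1", 0, kw="interact",
                                           pid="INT-1", text="q interacts z .")]
        p = tmp_path / "ev.tsv"
        write_evidence_table(evs, p)
        back = read_evidence_table(p)
        key = lambda e: e.key() + (e.sentence_text,)
        assert sorted(key(e) for e in evs) == [key(e) for e in back]


class TestWriteNetwork:
    def _net(self):
        return build_network([_ev("a", "b", "D1"), _ev("b", "c", "D2")])

    def test_sif_lines(self, tmp_path):
        p = tmp_path / "n.sif"
        write_network(self._net(), p, "sif")
        assert p.read_text().splitlines() == ["a pp b", "b pp c"]

    @pytest.mark.parametrize("fmt", ["sif", "graphml", "mitab"])
    def test_empty_network_valid(self, tmp_path, fmt):
        p = tmp_path / f"empty.{fmt}"
        write_network(build_network([]), p, fmt)
        if fmt == "graphml":
            etree.parse(str(p))  # well-formed XML
        else:
            assert p.read_text() == ""

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="sif"):
            write_network(self._net(), tmp_path / "x", "dot")

    def test_graphml_independent_reparse(self, tmp_path):
        """An independent XML reader sees identical node and edge sets."""
        net = self._net()
        p = tmp_path / "n.graphml"
        write_network(net, p, "graphml")
        tree = etree.parse(str(p))
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        nodes = {e.get("id") for e in tree.findall(".//g:node", ns)}
        edges = {tuple(sorted((e.get("source"), e.get("target"))))
                 for e in tree.findall(".//g:edge", ns)}
        assert nodes == {n for n, _ in net.sorted_nodes()}
        assert edges == set(net.sorted_edges())

    def test_mitab_has_15_columns(self, tmp_path):
        p = tmp_path / "n.mitab"
        write_network(self._net(), p, "mitab")
        for line in p.read_text().splitlines():
            assert len(line.split("\t")) == 15
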