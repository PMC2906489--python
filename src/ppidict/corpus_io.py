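"""Corpus input/output.

Reads two corpus dialects into the document model:

* a documented GENIA-like XML subset — ``<article>`` elements carrying a
  ``<bibliomisc>`` accession, a ``<title>`` and an ``<abstract>`` whose
  ``<sentence>`` elements contain (possibly nested) ``<cons>``
  constituents with a ``sem`` attribute naming a GENIA semantic class
  (an optional ``G#`` prefix is accepted);
* plain tab-separated abstract records (id, title, abstract), the
  MEDLINE-download shape, which arrive without entity annotations.

Writes interaction evidence as TSV and networks as SIF, GraphML or
minimal PSI-MI TAB 2.5 (MITAB).

When protein-typed constituents nest, the innermost protein-typed span
is indexed as the mention: inner spans name specific molecules while
outer spans are usually coordinations.  Anything that is not the
supported XML dialect is rejected loudly rather than half-parsed.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Union

from lxml import etree

from .model import (
    PROTEIN_SEMANTIC_CLASSES,
    UNKNOWN_CLASS,
    Corpus,
    Document,
    InteractionEvidence,
    ProteinMention,
    Sentence,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

EVIDENCE_COLUMNS = ("protein_a", "protein_b", "keyword", "pattern_id",
                    "doc_id", "sentence_index", "sentence_text")

NETWORK_FORMATS = ("sif", "graphml", "mitab")


class CorpusFormatError(ValueError):
    """Raised for malformed or unsupported corpus input."""


# ---------------------------------------------------------------------------
# GENIA-like XML


def _sem_class(raw: Optional[str]) -> Optional[str]:
    """Map a ``sem`` attribute to a semantic class, or None if not protein."""
    if raw is None:
        return None
    label = raw.strip()
    if label.startswith("G#"):
        label = label[2:]
    if not label.startswith("protein"):
        return None
    return label if label in PROTEIN_SEMANTIC_CLASSES else UNKNOWN_CLASS


def _parse_sentence(elem: etree._Element, index: int) -> Sentence:
    parts: list[str] = []
    length = 0
    mentions: list[ProteinMention] = []

    def walk(e: etree._Element) -> bool:
        """Append e's content; return True if a protein constituent is inside."""
        nonlocal length
        protein_below = False
        start = length
        if e.text:
            parts.append(e.text)
            length += len(e.text)
        for child in e:
            if walk(child):
                protein_below = True
            if child.tail:
                parts.append(child.tail)
                length += len(child.tail)
        cls = _sem_class(e.get("sem")) if e.tag == "cons" else None
        if cls is not None and not protein_below:
            mentions.append(_mention_placeholder(start, length, cls))
            return True
        return cls is not None or protein_below

    def _mention_placeholder(start: int, end: int, cls: str):
        return (start, end, cls)

    for child in elem:
        walk(child)
        if child.tail:
            parts.append(child.tail)
            length += len(child.tail)
    # walk() above only visits children; account for the element's own text.
    text_head = elem.text or ""
    text = text_head + "".join(parts)
    offset = len(text_head)
    built = [ProteinMention.from_span(text, s + offset, e + offset, cls)
             for (s, e, cls) in mentions]
    return Sentence(text=text, mentions=built, index=index)


def read_genia_xml(path: PathLike) -> Corpus:
    """Read a GENIA-like XML corpus file.

    Raises :class:`CorpusFormatError` for malformed XML (naming the
    line) and for well-formed files that are not the supported dialect
    (no ``<sentence>`` elements).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    articles = root.findall(".//article")
    if root.tag == "article":
        articles = [root]
    if not root.findall(".//sentence") and articles:
        raise CorpusFormatError(
            f"unsupported corpus dialect in {path}: no <sentence> elements "
            f"found")
    if not articles:
        if root.tag in ("set", "corpus") and len(root) == 0:
            return Corpus(documents=[])
        raise CorpusFormatError(
            f"unsupported corpus dialect in {path}: no <article> elements "
            f"found")
    documents: list[Document] = []
    for n, art in enumerate(articles):
        bib = art.find(".//bibliomisc")
        doc_id = (bib.text or "").strip() if bib is not None else art.get("id", "")
        if doc_id.startswith("MEDLINE:"):
            doc_id = doc_id[len("MEDLINE:"):]
        if not doc_id:
            raise CorpusFormatError(
                f"article #{n + 1} in {path} has no identifier "
                f"(<bibliomisc> or id attribute)")
        title_el = art.find("title")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        scope = art.find("abstract")
        sent_parent = scope if scope is not None else art
        sentences = [
            _parse_sentence(s, i)
            for i, s in enumerate(sent_parent.findall(".//sentence"))
        ]
        documents.append(Document(doc_id=doc_id, title=title,
                                  sentences=sentences))
    return Corpus(documents=documents)


def _escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


def _sentence_xml(sent: Sentence) -> str:
    """Serialize a sentence with its mentions as nested <cons> markup."""
    out: list[str] = []
    pos = 0
    for m in sorted(sent.mentions, key=lambda m: m.start):
        out.append(_escape(sent.text[pos:m.start]))
        out.append(f'<cons sem="G#{m.semantic_class}">'
                   f"{_escape(m.surface)}</cons>")
        pos = m.end
    out.append(_escape(sent.text[pos:]))
    return "".join(out)


def write_genia_xml(corpus: Corpus, path: PathLike) -> None:
    """Write a corpus in the GENIA-like XML dialect read_genia_xml accepts."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<set>"]
    for doc in corpus.documents:
        lines.append("  <article>")
        lines.append(f"    <articleinfo><bibliomisc>MEDLINE:{_escape(doc.doc_id)}"
                     f"</bibliomisc></articleinfo>")
        lines.append(f"    <title>{_escape(doc.title)}</title>")
        lines.append("    <abstract>")
        for sent in doc.sentences:
            lines.append(f"      <sentence>{_sentence_xml(sent)}</sentence>")
        lines.append("    </abstract>")
        lines.append("  </article>")
    lines.append("</set>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# plain abstracts

# A sentence ends at ". ", "? " or "! " followed by an uppercase letter
# or digit.  No abbreviation list: deterministic and adequate for
# abstracts; a documented limitation for e.g. "E. coli".
_SENT_SPLIT_RE = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    text = text.strip()
    if not text:
        return []
    return [s for s in _SENT_SPLIT_RE.split(text) if s]


def read_plain_abstracts(path: PathLike) -> Corpus:
    """Read tab-separated (id, title, abstract) records, one per line.

    Sentences are split heuristically; mentions are left empty and are
    filled later by dictionary tagging.
    """
    path = Path(path)
    documents: list[Document] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusFormatError(
                    f"{path}, line {lineno}: expected 3 tab-separated "
                    f"columns (id, title, abstract), got {len(parts)}")
            doc_id, title, abstract = parts
            sentences = [Sentence(text=s, index=i)
                         for i, s in enumerate(split_sentences(abstract))]
            if not sentences:
                logger.warning("document %s (line %d) has an empty abstract",
                               doc_id, lineno)
            documents.append(Document(doc_id=doc_id.strip(), title=title,
                                      sentences=sentences))
    return Corpus(documents=documents)


# ---------------------------------------------------------------------------
# evidence tables


def write_evidence_table(evidences: Iterable[InteractionEvidence],
                         path: PathLike) -> None:
    """Write evidence as TSV with a fixed column set and deterministic order."""
    rows = sorted(evidences, key=lambda e: e.key())
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for e in rows:
            writer.writerow([e.protein_a, e.protein_b, e.keyword,
                             e.pattern_id, e.doc_id, e.sentence_index,
                             e.sentence_text])


def read_evidence_table(path: PathLike) -> list[InteractionEvidence]:
    """Read back a TSV evidence table (semantic classes are not persisted)."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != EVIDENCE_COLUMNS:
            raise CorpusFormatError(
                f"{path}: not an evidence table (unexpected header)")
        out = []
        for row in reader:
            if len(row) != len(EVIDENCE_COLUMNS):
                raise CorpusFormatError(
                    f"{path}: row with {len(row)} columns")
            a, b, kw, pid, doc_id, idx, text = row
            out.append(InteractionEvidence(
                protein_a=a, protein_b=b, keyword=kw, pattern_id=pid,
                doc_id=doc_id, sentence_index=int(idx), sentence_text=text))
    return out


# ---------------------------------------------------------------------------
# network export


def write_network(network, path: PathLike, format: str = "sif") -> None:
    """Write a PPI network as SIF, GraphML or minimal MITAB 2.5.

    ``network`` is a :class:`ppidict.network.PPINetwork`; only its
    public accessors are used.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; supported: "
            + ", ".join(NETWORK_FORMATS))
    path = Path(path)
    if fmt == "sif":
        lines = [f"{a} pp {b}" for a, b in network.sorted_edges()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""),
                        encoding="utf-8")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        for name, cls in network.sorted_nodes():
            g.add_node(name, semantic_class=cls)
        for a, b in network.sorted_edges():
            g.add_edge(a, b,
                       evidence_count=network.evidence_count(a, b),
                       literature_count=network.literature_count(a, b),
                       keywords=",".join(sorted(network.edge_keywords(a, b))))
        nx.write_graphml(g, str(path), named_key_ids=True)
    else:  # mitab
        with path.open("w", encoding="utf-8", newline="") as fh:
            for a, b in network.sorted_edges():
                row = [a, b] + ["-"] * 13
                fh.write("\t".join(row) + "\n")
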