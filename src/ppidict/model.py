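"""Core domain model: documents, sentences, protein mentions, evidence.

All character offsets are 0-based, half-open, counted in Unicode code
points, so ``sentence.text[m.start:m.end] == m.surface`` always holds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

#: GENIA ontology labels accepted as protein semantic classes.  Any
#: other label (or a missing one) maps to the sentinel ``"unknown"``.
PROTEIN_SEMANTIC_CLASSES = frozenset(
    {
        "protein_molecule",
        "protein_family_or_group",
        "protein_complex",
        "protein_subunit",
        "protein_substructure",
        "protein_domain_or_region",
    }
)

UNKNOWN_CLASS = "unknown"

_WS_RE = re.compile(r"\s+")
# Flanking punctuation stripped during normalization.  Hyphens are kept:
# they are part of many protein names (IL-2) and never flank them.
_FLANK_PUNCT = ".,;:!?()[]{}<>\"'`/\\"


def normalize_name(surface: str) -> str:
    """Normalize a protein surface form to its canonical dictionary key.

    Case-folds, collapses internal whitespace to single spaces and strips
    flanking punctuation.  No synonym or database-identifier mapping is
    attempted; two strings denote the same protein iff they normalize
    identically.
    """
    s = _WS_RE.sub(" ", surface.casefold().strip())
    return s.strip(_FLANK_PUNCT + " ")


@dataclass(frozen=True)
class ProteinMention:
    """An annotated protein entity span within one sentence."""

    start: int
    end: int
    surface: str
    normalized: str
    semantic_class: str = UNKNOWN_CLASS

    @classmethod
    def from_span(cls, text: str, start: int, end: int,
                  semantic_class: str = UNKNOWN_CLASS) -> "ProteinMention":
        surface = text[start:end]
        cleaned = (semantic_class if semantic_class in PROTEIN_SEMANTIC_CLASSES
                   else UNKNOWN_CLASS)
        return cls(start=start, end=end, surface=surface,
                   normalized=normalize_name(surface), semantic_class=cleaned)


@dataclass
class Sentence:
    """One sentence of an abstract with its protein mentions."""

    text: str
    mentions: list[ProteinMention] = field(default_factory=list)
    index: int = 0

    def __post_init__(self) -> None:
        for m in self.mentions:
            if not (0 <= m.start <= m.end <= len(self.text)):
                raise ValueError(
                    f"mention span [{m.start}, {m.end}) outside sentence of "
                    f"length {len(self.text)}")
            if self.text[m.start:m.end] != m.surface:
                raise ValueError(
                    f"mention surface {m.surface!r} does not equal the "
                    f"sentence slice {self.text[m.start:m.end]!r}")
        self.mentions.sort(key=lambda m: (m.start, m.end))


@dataclass
class Document:
    """An abstract: identifier, title, ordered sentences."""

    doc_id: str
    title: str = ""
    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        for i, s in enumerate(self.sentences):
            s.index = i


@dataclass
class Corpus:
    """A collection of documents with unique identifiers."""

    documents: list[Document] = field(default_factory=list)
    lexicon_hint: Optional[set[str]] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise ValueError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def iter_sentences(self) -> Iterator[tuple[str, Sentence]]:
        for doc in self.documents:
            for sent in doc.sentences:
                yield doc.doc_id, sent

    def n_mentions(self) -> int:
        return sum(len(s.mentions) for _, s in self.iter_sentences())


@dataclass(frozen=True)
class InteractionEvidence:
    """One extracted interaction: a protein pair asserted by one sentence.

    ``protein_a``/``protein_b`` hold the canonical (normalized) names with
    ``protein_a <= protein_b`` lexicographically; the pair is undirected.
    For patterns whose surface form is directional (activate, regulate)
    the ``agent`` field records which of the two filled the agent slot.
    """

    protein_a: str
    protein_b: str
    keyword: str
    pattern_id: str
    doc_id: str
    sentence_index: int
    sentence_text: str
    semantic_class_a: str = UNKNOWN_CLASS
    semantic_class_b: str = UNKNOWN_CLASS
    agent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError("self-interaction evidence is not allowed")
        if self.protein_a > self.protein_b:
            raise ValueError("protein_a must sort before protein_b")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))

    def key(self) -> tuple:
        """Identity used for deduplication and deterministic ordering."""
        return (self.doc_id, self.sentence_index, self.protein_a,
                self.protein_b, self.keyword, self.pattern_id)


def make_evidence(a: ProteinMention, b: ProteinMention, *, keyword: str,
                  pattern_id: str, doc_id: str, sentence: Sentence,
                  directional: bool = False) -> InteractionEvidence:
    """Build a canonical evidence record from two mentions (a = agent slot)."""
    pa, pb = a, b
    if pa.normalized > pb.normalized:
        pa, pb = pb, pa
    return InteractionEvidence(
        protein_a=pa.normalized,
        protein_b=pb.normalized,
        keyword=keyword,
        pattern_id=pattern_id,
        doc_id=doc_id,
        sentence_index=sentence.index,
        sentence_text=sentence.text,
        semantic_class_a=pa.semantic_class,
        semantic_class_b=pb.semantic_class,
        agent=a.normalized if directional else None,
    )
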