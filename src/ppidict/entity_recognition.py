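"""Dictionary-based protein name recognition and query authentication.

A lexicon of known protein names is compiled from an annotated corpus
(or loaded from a plain-text file) and applied to raw sentences by
longest-match, left-to-right, case-insensitive matching at token
boundaries.  A token boundary is a transition to or from the character
class letters+digits+hyphen, so names such as "NF-kappa B" and "IL-2R"
match as units and "IL-2" never fires inside "IL-2R".

Part-of-speech tagging and machine-learned NER are out of scope: the
lexicon is a desk-scale surrogate for an external statistical tagger.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .model import (
    UNKNOWN_CLASS,
    Corpus,
    ProteinMention,
    Sentence,
    normalize_name,
)

# Name tokens: maximal runs of letters, digits and internal hyphens.
_NAME_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


def name_tokens(text: str) -> list[tuple[int, int, str]]:
    """(start, end, lowercased token) for every name token in ``text``."""
    return [(m.start(), m.end(), m.group(0).lower())
            for m in _NAME_TOKEN_RE.finditer(text)]


class LexiconError(ValueError):
    pass


@dataclass
class ProteinLexicon:
    """Known protein names with their majority semantic class."""

    entries: set[str] = field(default_factory=set)
    class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not e for e in self.entries):
            raise LexiconError("lexicon entries must be non-empty")
        unknown = set(self.class_map) - self.entries
        if unknown:
            raise LexiconError(
                f"class_map keys missing from entries: {sorted(unknown)[:3]}")
        # token sequences per entry, for multi-token dictionary matching
        self._token_index: dict[str, list[tuple[str, ...]]] = defaultdict(list)
        self._max_tokens = 0
        for entry in self.entries:
            toks = tuple(t for _, _, t in name_tokens(entry))
            if toks:
                self._token_index[toks[0]].append(toks)
                self._max_tokens = max(self._max_tokens, len(toks))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries

    def semantic_class(self, name: str) -> str:
        return self.class_map.get(normalize_name(name), UNKNOWN_CLASS)


def build_lexicon(corpus: Corpus) -> ProteinLexicon:
    """Compile the lexicon from every annotated mention in ``corpus``.

    The semantic class of an entry is the majority class over all of its
    mentions, ties broken lexicographically.
    """
    votes: dict[str, Counter] = defaultdict(Counter)
    for _, sent in corpus.iter_sentences():
        for m in sent.mentions:
            if m.normalized:
                votes[m.normalized][m.semantic_class] += 1
    if not votes:
        raise LexiconError("cannot build lexicon from unannotated corpus")
    class_map = {}
    for name, counter in votes.items():
        top = max(counter.values())
        class_map[name] = min(c for c, n in counter.items() if n == top)
    return ProteinLexicon(entries=set(votes), class_map=class_map)


def load_lexicon(path: Union[str, Path]) -> ProteinLexicon:
    """Load a lexicon file: one name per line, optional tab-separated
    semantic class, ``#`` comments."""
    entries: set[str] = set()
    class_map: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, _, cls = line.partition("\t")
        norm = normalize_name(name)
        if not norm:
            continue
        entries.add(norm)
        if cls.strip():
            class_map[norm] = cls.strip()
    if not entries:
        raise LexiconError(f"lexicon file {path} contains no entries")
    return ProteinLexicon(entries=entries, class_map=class_map)


def tag_proteins(sentence: Sentence, lexicon: ProteinLexicon) -> Sentence:
    """Return a copy of ``sentence`` with dictionary-matched mentions.

    Longest match wins; between equal-length overlapping candidates the
    leftmost wins; matched spans are consumed so no returned mention is
    a strict sub-span of another.  Idempotent: existing annotations are
    replaced by the dictionary matching result.
    """
    if not lexicon.entries:
        raise LexiconError("cannot tag with an empty lexicon")
    toks = name_tokens(sentence.text)
    mentions: list[ProteinMention] = []
    i = 0
    while i < len(toks):
        first = toks[i][2]
        best_len = 0
        candidates = lexicon._token_index.get(first, ())
        for cand in candidates:
            k = len(cand)
            if k <= best_len or i + k > len(toks):
                continue
            window = tuple(t for _, _, t in toks[i:i + k])
            if window != cand:
                continue
            # the span must normalize to the entry (guards punctuation
            # between tokens: "IL-2 , R" must not match "il-2 r")
            span_text = sentence.text[toks[i][0]:toks[i + k - 1][1]]
            if normalize_name(span_text) in lexicon.entries:
                best_len = k
        if best_len:
            start = toks[i][0]
            end = toks[i + best_len - 1][1]
            norm = normalize_name(sentence.text[start:end])
            mentions.append(ProteinMention(
                start=start, end=end, surface=sentence.text[start:end],
                normalized=norm,
                semantic_class=lexicon.class_map.get(norm, UNKNOWN_CLASS)))
            i += best_len
        else:
            i += 1
    return Sentence(text=sentence.text, mentions=mentions,
                    index=sentence.index)


def tag_corpus(corpus: Corpus, lexicon: ProteinLexicon) -> Corpus:
    """Apply :func:`tag_proteins` to every sentence of a corpus."""
    docs = []
    for doc in corpus.documents:
        tagged = [tag_proteins(s, lexicon) for s in doc.sentences]
        docs.append(type(doc)(doc_id=doc.doc_id, title=doc.title,
                              sentences=tagged))
    return Corpus(documents=docs, lexicon_hint=corpus.lexicon_hint)


def authenticate_query(name: str,
                       lexicon: ProteinLexicon) -> tuple[bool, Optional[str]]:
    """Check whether ``name`` is a known protein name.

    Returns ``(accepted, canonical_name)``; the canonical (normalized)
    form is what downstream querying uses.
    """
    if not name or not name.strip():
        raise ValueError("empty query")
    norm = normalize_name(name)
    if norm in lexicon.entries:
        return True, norm
    return False, None
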