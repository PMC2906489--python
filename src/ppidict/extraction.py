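"""Sentence selection and pattern matching — the extraction core.

Two stages mirror the tool's article-parser / full-sentence-parser
split:

1. :func:`select_sentences` keeps the sentences that contain the query
   protein *and* at least one interaction keyword variant (token
   bounded, case-insensitive).
2. :func:`match_patterns` aligns each selected sentence against the
   22-template inventory and emits one
   :class:`~ppidict.model.InteractionEvidence` per (protein pair,
   keyword, pattern) found.

Matching model
--------------

A sentence is converted to a sequence of items: protein *groups* and
plain lowercased tokens.  Runs of protein mentions linked by commas
and/or "and" are collapsed into a single coordinated group, so
"A, B and C interact" exposes one group {A, B, C}; slot elements fill
from any group member and coordinated-pair elements expand to every
unordered pair inside one group ("A, B and C interact" yields
{A,B}, {A,C}, {B,C}).

Between consecutive template elements up to ``filler_window`` (default
3) intervening tokens are tolerated, provided none of them is a protein
or a keyword variant — this lets "the IL-2 / IL-2R alpha complex" match
the separator template while keeping anchors local.  The ellipsis
element allows an unbounded gap.

Negation is deliberately not modelled: "A does not interact with B"
matches like its affirmative form.  This is a documented property of
the keyword-dictionary approach, measurable with the negation probes in
:mod:`ppidict.synthetic_corpus`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .entity_recognition import ProteinLexicon, build_lexicon, name_tokens
from .model import (
    Corpus,
    InteractionEvidence,
    ProteinMention,
    Sentence,
    make_evidence,
)
from .patterns import (
    ALL_KEYWORD_FORMS,
    Coord,
    Ellipsis_,
    PatternTemplate,
    Slot,
    TokenSet,
    default_patterns,
    keyword_variants,
)

DEFAULT_FILLER_WINDOW = 3

# Words or single punctuation marks (hyphens internal to alphanumeric
# runs stay inside their word, so "IL-2" is one token but the free
# hyphen of "A - B" is its own).
_ITEM_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

_COORDINATORS = {",", "and"}


class QueryError(ValueError):
    """Raised when a query protein was not authenticated against the corpus."""


@dataclass(frozen=True)
class _Group:
    """A maximal run of coordinated protein mentions (possibly one)."""

    members: tuple[ProteinMention, ...]


_Item = Union[_Group, str]


def sentence_contains_keyword(sentence: Sentence) -> bool:
    return any(t in ALL_KEYWORD_FORMS for _, _, t in
               name_tokens(sentence.text))


def _sentence_items(sentence: Sentence,
                    filler_window: int = DEFAULT_FILLER_WINDOW
                    ) -> list[_Item]:
    mentions = sorted(sentence.mentions, key=lambda m: (m.start, -m.end))
    flat: list[Union[ProteinMention, str]] = []
    pos = 0
    last_end = -1
    for m in mentions:
        if m.start < last_end:  # overlapping annotation; keep the first
            continue
        flat.extend(t.lower() for t in
                    _ITEM_TOKEN_RE.findall(sentence.text[pos:m.start]))
        flat.append(m)
        pos = last_end = m.end
    flat.extend(t.lower() for t in
                _ITEM_TOKEN_RE.findall(sentence.text[pos:]))
    # Collapse coordination runs: P ((,|and|, and) filler* P)+ .  Up to
    # filler_window non-coordinator filler tokens may sit between the
    # coordinator and the next protein ("A and the novel B").
    items: list[_Item] = []
    i = 0
    while i < len(flat):
        it = flat[i]
        if not isinstance(it, ProteinMention):
            items.append(it)
            i += 1
            continue
        members = [it]
        j = i + 1
        while True:
            k = j
            if k < len(flat) and flat[k] == ",":
                k += 1
            if k < len(flat) and flat[k] == "and":
                k += 1
            if k == j:  # no coordinator
                break
            skipped = 0
            while (k < len(flat) and skipped < filler_window
                   and isinstance(flat[k], str)
                   and _is_filler(flat[k])
                   and flat[k] not in _COORDINATORS):
                k += 1
                skipped += 1
            if k >= len(flat) or not isinstance(flat[k], ProteinMention):
                break
            members.append(flat[k])
            j = k + 1
        items.append(_Group(members=tuple(members)))
        i = j
    return items


def _is_filler(item: _Item) -> bool:
    return isinstance(item, str) and item not in ALL_KEYWORD_FORMS


def _element_matches(el, item: _Item) -> bool:
    if isinstance(el, Slot):
        return isinstance(item, _Group)
    if isinstance(el, Coord):
        return isinstance(item, _Group) and len(item.members) >= 2
    if isinstance(el, TokenSet):
        return isinstance(item, str) and item in el.forms
    raise TypeError(el)


def _match_branch(items: Sequence[_Item], elements: Sequence,
                  window: int) -> list[dict]:
    """All alignments of ``elements`` against ``items``.

    Returns one binding dict per alignment, mapping slot names (or
    "coord") to the matched group.
    """
    results: list[dict] = []

    def rec(ei: int, pos: int, unbounded: bool, bindings: dict) -> None:
        if ei == len(elements):
            results.append(dict(bindings))
            return
        el = elements[ei]
        if isinstance(el, Ellipsis_):
            rec(ei + 1, pos, True, bindings)
            return
        if pos < 0:  # first concrete element: anchor anywhere
            starts = range(len(items))
        elif unbounded:
            starts = range(pos + 1, len(items))
        else:
            starts = []
            for q in range(pos + 1, min(len(items), pos + 2 + window)):
                if all(_is_filler(items[g]) for g in range(pos + 1, q)):
                    starts.append(q)
                else:
                    break
        for q in starts:
            if not _element_matches(el, items[q]):
                continue
            key = el.name if isinstance(el, Slot) else (
                "coord" if isinstance(el, Coord) else None)
            if key is not None:
                bindings[key] = items[q]
            rec(ei + 1, q, False, bindings)
            if key is not None:
                del bindings[key]

    rec(0, -1, False, {})
    return results


def _pairs_from_binding(binding: dict) -> list[tuple[ProteinMention,
                                                     ProteinMention]]:
    if "coord" in binding:
        group: _Group = binding["coord"]
        return [(a, b) for a, b in itertools.combinations(group.members, 2)
                if a.normalized != b.normalized]
    ga: _Group = binding["A"]
    gb: _Group = binding["B"]
    return [(a, b) for a in ga.members for b in gb.members
            if a.normalized != b.normalized]


def match_patterns(sentence: Sentence, *, doc_id: str = "",
                   patterns: Optional[Sequence[PatternTemplate]] = None,
                   filler_window: int = DEFAULT_FILLER_WINDOW,
                   ) -> list[InteractionEvidence]:
    """Match one tagged sentence against the template inventory.

    Every template instantiation with two distinct protein mentions
    yields one evidence; duplicates collapse to one evidence per
    (unordered pair, keyword, pattern).  Results are deterministically
    ordered.
    """
    if patterns is None:
        patterns = default_patterns()
    if not sentence.mentions:
        return []
    items = _sentence_items(sentence, filler_window)
    seen: dict[tuple, InteractionEvidence] = {}
    for pat in patterns:
        for branch in pat.branches:
            for binding in _match_branch(items, branch, filler_window):
                for a, b in _pairs_from_binding(binding):
                    ev = make_evidence(
                        a, b, keyword=pat.keyword, pattern_id=pat.pattern_id,
                        doc_id=doc_id, sentence=sentence,
                        directional=pat.directional)
                    seen.setdefault(ev.key(), ev)
    return sorted(seen.values(), key=lambda e: e.key())


def select_sentences(corpus: Corpus, query: str, *,
                     lexicon: Optional[ProteinLexicon] = None,
                     ) -> list[tuple[str, Sentence]]:
    """Sentences that mention the (canonical) query protein and a keyword.

    ``query`` must be the canonical name produced by
    :func:`ppidict.entity_recognition.authenticate_query`; an
    unauthenticated query raises :class:`QueryError`.
    """
    if lexicon is None:
        lexicon = build_lexicon(corpus)
    if query not in lexicon.entries:
        raise QueryError(
            f"query {query!r} is not an authenticated protein name; run "
            f"authenticate_query against the corpus lexicon first")
    out = []
    for doc_id, sent in corpus.iter_sentences():
        if any(m.normalized == query for m in sent.mentions) \
                and sentence_contains_keyword(sent):
            out.append((doc_id, sent))
    return out


def extract_ppi(corpus: Corpus, query: str, *,
                lexicon: Optional[ProteinLexicon] = None,
                patterns: Optional[Sequence[PatternTemplate]] = None,
                filler_window: int = DEFAULT_FILLER_WINDOW,
                ) -> list[InteractionEvidence]:
    """Full query pipeline: select sentences, match patterns, keep the
    evidences that involve the query protein.  Deterministic order."""
    evidences: list[InteractionEvidence] = []
    for doc_id, sent in select_sentences(corpus, query, lexicon=lexicon):
        for ev in match_patterns(sent, doc_id=doc_id, patterns=patterns,
                                 filler_window=filler_window):
            if query in (ev.protein_a, ev.protein_b):
                evidences.append(ev)
    return sorted(set(evidences), key=lambda e: e.key())


def extract_all(corpus: Corpus, *,
                patterns: Optional[Sequence[PatternTemplate]] = None,
                filler_window: int = DEFAULT_FILLER_WINDOW,
                ) -> list[InteractionEvidence]:
    """Corpus-wide extraction over every keyword-bearing sentence
    (no query filter); used for evaluation against a gold standard."""
    evidences: list[InteractionEvidence] = []
    for doc_id, sent in corpus.iter_sentences():
        if not sent.mentions or not sentence_contains_keyword(sent):
            continue
        evidences.extend(match_patterns(sent, doc_id=doc_id,
                                        patterns=patterns,
                                        filler_window=filler_window))
    return sorted(set(evidences), key=lambda e: e.key())


def count_keyword_tokens(sentence: Sentence, lemma: str) -> int:
    """Token occurrences of any variant of ``lemma`` in one sentence."""
    variants = keyword_variants(lemma)
    return sum(1 for _, _, t in name_tokens(sentence.text) if t in variants)
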