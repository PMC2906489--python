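"""Seeded generator of GENIA-like corpora with planted interactions.

Emulates the structure an annotated abstract collection exposes to the
pipeline: documents of annotated sentences where a configurable
fraction of sentences are verbatim instantiations of the 22 interaction
templates (these carry the gold pairs), a fraction contain an
interaction keyword but no extractable pair (keyword distractors, at
most one protein mention), and the rest are keyword-free distractors.
Protein names are sampled in GENIA style (alphanumeric stems with
hyphens and Greek-letter tokens, "IL-2"-like) to exercise tokenization.
Filler tokens come from a fixed stop-word list disjoint from the
keyword dictionary, so distractors can never accidentally instantiate a
template.

What this does *not* emulate: paraphrase, anaphora, negation scope
(except via the dedicated probe generator), nested coordination or the
long noun compounds of real abstracts — pipeline behaviour on real text
is not certified by tests built on this generator.

All randomness flows from one seed; the same config produces
byte-identical corpus and gold files.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .corpus_io import write_genia_xml
from .entity_recognition import name_tokens
from .evaluation import GoldStandard, write_gold_standard
from .model import Corpus, Document, ProteinMention, Sentence
from .patterns import (
    ALL_KEYWORD_FORMS,
    FORM_TABLE,
    KEYWORD_VARIANTS,
    PatternTemplate,
    default_patterns,
)

# Filler vocabulary: never a keyword variant, a coordinator or a
# template literal, so fillers cannot complete a pattern.
STOPWORDS = (
    "the", "a", "an", "this", "novel", "putative", "human", "murine",
    "cellular", "nuclear", "specific", "recombinant", "endogenous",
    "purified", "highly", "conserved", "truncated", "mutant",
)
_PLAIN_WORDS = (
    "was", "is", "were", "expression", "levels", "cells", "treatment",
    "observed", "measured", "detected", "samples", "patients", "analysis",
    "in", "by", "after", "during", "upon", "strongly", "significantly",
)
_GREEK = ("alpha", "beta", "gamma", "delta", "kappa")
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: literal tokens appearing in templates; excluded from distractor text
TEMPLATE_LITERALS = frozenset(
    {"with", "of", "to", "between", "among", "and", "each", "other",
     "contains", "contain", "contained", "containing", "-", "/", ","})


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generation parameters; the defaults define the study conditions."""

    n_documents: int = 200
    sentences_per_document: tuple[int, int] = (3, 6)
    n_proteins: int = 60
    planted_fraction: float = 0.5
    keyword_distractor_fraction: float = 0.25
    keyword_free_fraction: float = 0.25
    class_weights: dict[str, float] = field(default_factory=lambda: {
        "protein_molecule": 0.6,
        "protein_family_or_group": 0.25,
        "protein_complex": 0.15,
    })
    max_slot_fillers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.planted_fraction + self.keyword_distractor_fraction
                 + self.keyword_free_fraction)
        if abs(total - 1.0) > 1e-9:
            raise SyntheticError("sentence-category fractions must sum to 1")
        if self.n_proteins < 2:
            raise SyntheticError("protein inventory needs at least 2 names")
        lo, hi = self.sentences_per_document
        if not (1 <= lo <= hi):
            raise SyntheticError("invalid sentences_per_document range")


def sample_protein_inventory(rng: random.Random, n: int,
                             class_weights: dict[str, float]
                             ) -> list[tuple[str, str]]:
    """Sample ``n`` distinct GENIA-style (name, semantic_class) pairs.

    No name's token sequence is a prefix of another's, so dictionary
    tagging of generated text recovers exactly the planted spans.
    """
    classes = list(class_weights)
    weights = [class_weights[c] for c in classes]
    names: list[str] = []
    token_seqs: list[tuple[str, ...]] = []
    attempts = 0
    while len(names) < n:
        attempts += 1
        if attempts > 200 * n:
            raise SyntheticError("could not sample a distinct inventory")
        stem = "".join(rng.choice(_LETTERS)
                       for _ in range(rng.randint(2, 4)))
        style = rng.random()
        if style < 0.4:
            name = f"{stem}-{rng.randint(1, 99)}"
        elif style < 0.7:
            name = f"{stem}{rng.randint(1, 9)}"
        else:
            name = f"{stem}-{rng.randint(1, 9)} {rng.choice(_GREEK)}"
        toks = tuple(t for _, _, t in name_tokens(name.lower()))
        if any(toks == s[:len(toks)] or s == toks[:len(s)]
               for s in token_seqs):
            continue
        token_seqs.append(toks)
        names.append(name)
    return [(name, rng.choices(classes, weights)[0]) for name in names]


def _assemble(tokens: Sequence[Union[str, tuple[str, str]]]) -> Sentence:
    """Join tokens into a sentence; tuples are (protein surface, class)."""
    parts: list[str] = []
    mentions: list[ProteinMention] = []
    pos = 0
    for tok in tokens:
        if parts:
            parts.append(" ")
            pos += 1
        if isinstance(tok, tuple):
            surface, cls = tok
            mentions.append((pos, pos + len(surface), cls))  # type: ignore
            parts.append(surface)
            pos += len(surface)
        else:
            parts.append(tok)
            pos += len(tok)
    text = "".join(parts)
    built = [ProteinMention.from_span(text, s, e, cls)
             for (s, e, cls) in mentions]  # type: ignore
    return Sentence(text=text, mentions=built)


def instantiate_template(rng: random.Random, pattern: PatternTemplate,
                         a: tuple[str, str], b: tuple[str, str], *,
                         max_slot_fillers: int = 2) -> Sentence:
    """A verbatim instantiation of one template with proteins a and b.

    Slot positions may receive up to ``max_slot_fillers`` stop-word
    fillers; the ellipsis expands to 4-6 fillers so that only the
    ellipsis template itself bridges the gap.
    """
    out: list[Union[str, tuple[str, str]]] = []
    for tok in pattern.template.split():
        if tok == "A":
            if max_slot_fillers and rng.random() < 0.5:
                out.extend(rng.choices(STOPWORDS,
                                       k=rng.randint(1, max_slot_fillers)))
            out.append(a)
        elif tok == "B":
            if max_slot_fillers and rng.random() < 0.5:
                out.extend(rng.choices(STOPWORDS,
                                       k=rng.randint(1, max_slot_fillers)))
            out.append(b)
        elif tok == "...":
            out.extend(rng.choices(STOPWORDS, k=rng.randint(4, 6)))
        elif tok.startswith("(") and "|" in tok:
            out.append(rng.choice(tok[1:-1].split("|")))
        elif tok in FORM_TABLE:
            out.append(rng.choice(sorted(FORM_TABLE[tok])))
        else:
            out.append(tok)
    out.append(".")
    return _assemble(out)


def _distractor_words(rng: random.Random, k: int) -> list[str]:
    pool = STOPWORDS + _PLAIN_WORDS
    return [rng.choice(pool) for _ in range(k)]


def keyword_distractor_sentence(rng: random.Random,
                                inventory: Sequence[tuple[str, str]]
                                ) -> Sentence:
    """A keyword-bearing sentence with at most one protein: never yields
    evidence (two distinct protein slots are required)."""
    lemma = rng.choice(list(KEYWORD_VARIANTS))
    variant = rng.choice(sorted(KEYWORD_VARIANTS[lemma]))
    toks: list[Union[str, tuple[str, str]]] = []
    if rng.random() < 0.7:
        toks.append(rng.choice(list(inventory)))
    toks.extend(_distractor_words(rng, rng.randint(1, 3)))
    toks.append(variant)
    toks.extend(_distractor_words(rng, rng.randint(1, 4)))
    toks.append(".")
    return _assemble(toks)


def keyword_free_sentence(rng: random.Random,
                          inventory: Sequence[tuple[str, str]]) -> Sentence:
    """A sentence with no interaction keyword (0-2 protein mentions)."""
    toks: list[Union[str, tuple[str, str]]] = []
    n_prot = rng.randint(0, 2)
    toks.extend(_distractor_words(rng, rng.randint(2, 4)))
    for _ in range(n_prot):
        toks.append(rng.choice(list(inventory)))
        toks.extend(_distractor_words(rng, rng.randint(1, 3)))
    toks.append(".")
    return _assemble(toks)


def build_corpus(config: SyntheticConfig) -> tuple[Corpus, GoldStandard]:
    """Generate the corpus and its gold standard in memory."""
    rng = random.Random(config.seed)
    patterns = default_patterns()
    inventory = sample_protein_inventory(rng, config.n_proteins,
                                         config.class_weights)
    documents: list[Document] = []
    gold_rows: list[tuple[str, str, str]] = []
    lo, hi = config.sentences_per_document
    for d in range(config.n_documents):
        doc_id = f"{90000000 + d}"
        sentences: list[Sentence] = []
        for _ in range(rng.randint(lo, hi)):
            roll = rng.random()
            if roll < config.planted_fraction:
                pat = rng.choice(patterns)
                a, b = rng.sample(inventory, 2)
                sentences.append(instantiate_template(
                    rng, pat, a, b,
                    max_slot_fillers=config.max_slot_fillers))
                gold_rows.append((doc_id, a[0], b[0]))
            elif roll < (config.planted_fraction
                         + config.keyword_distractor_fraction):
                sentences.append(keyword_distractor_sentence(rng, inventory))
            else:
                sentences.append(keyword_free_sentence(rng, inventory))
        documents.append(Document(
            doc_id=doc_id, title=f"Synthetic abstract {d + 1}",
            sentences=sentences))
    gold = GoldStandard.from_tuples(gold_rows)
    return Corpus(documents=documents), gold


def generate_corpus(config: SyntheticConfig,
                    xml_path: Union[str, Path],
                    gold_path: Union[str, Path]
                    ) -> tuple[Corpus, GoldStandard]:
    """Generate and write the corpus (GENIA-like XML) and gold (TSV)."""
    corpus, gold = build_corpus(config)
    write_genia_xml(corpus, xml_path)
    write_gold_standard(gold, gold_path)
    return corpus, gold


def generate_negation_probes(n_probes: int = 20, seed: int = 0, *,
                             inventory: Optional[Sequence[tuple[str, str]]]
                             = None) -> Corpus:
    """Probe sentences of the form "A does not interact with B".

    The keyword-dictionary matcher has no negation component, so every
    probe is extracted as if affirmative; probes are absent from any
    gold standard and therefore *measure* the false-positive behaviour
    of negation-blind matching.
    """
    rng = random.Random(seed)
    if inventory is None:
        inventory = sample_protein_inventory(
            rng, max(8, n_probes // 2),
            {"protein_molecule": 1.0})
    frames = (
        ("does not", "interact", "with"),
        ("did not", "associate", "with"),
        ("does not", "bind", None),
        ("does not", "activate", None),
        ("did not", "regulate", None),
    )
    documents = []
    for i in range(n_probes):
        neg, lemma, link = frames[i % len(frames)]
        a, b = rng.sample(list(inventory), 2)
        toks: list[Union[str, tuple[str, str]]] = [a]
        toks.extend(neg.split())
        toks.append(rng.choice(sorted(FORM_TABLE[lemma])))
        if link:
            toks.append(link)
        toks.append(b)
        toks.append(".")
        documents.append(Document(
            doc_id=f"NEG{i + 1:04d}", title="Negation probe",
            sentences=[_assemble(toks)]))
    return Corpus(documents=documents)


def generate_random_sentences(n_sentences: int, seed: int, *,
                              n_proteins: int = 12,
                              planted_fraction: float = 0.5
                              ) -> list[Sentence]:
    """Adversarial random sentences for matcher cross-validation.

    Half are template instantiations mutated by random token insertion
    or deletion; half are token soup over the full template vocabulary
    (keyword variants, literals, separators, coordinators, stop words,
    1-4 protein mentions) — dense in near-matches and coordinations.
    """
    rng = random.Random(seed)
    inventory = sample_protein_inventory(rng, n_proteins,
                                         {"protein_molecule": 0.7,
                                          "protein_family_or_group": 0.3})
    patterns = default_patterns()
    literal_pool = sorted(TEMPLATE_LITERALS) + sorted(ALL_KEYWORD_FORMS)
    sentences = []
    for _ in range(n_sentences):
        if rng.random() < planted_fraction:
            pat = rng.choice(patterns)
            a, b = rng.sample(inventory, 2)
            base = instantiate_template(rng, pat, a, b)
            toks = _resplit(base)
            # mutate: random insertion and/or deletion
            if rng.random() < 0.5 and len(toks) > 3:
                del toks[rng.randrange(len(toks))]
            if rng.random() < 0.6:
                toks.insert(rng.randrange(len(toks) + 1),
                            rng.choice(literal_pool))
            sentences.append(_assemble(toks))
        else:
            toks = []
            for _ in range(rng.randint(5, 14)):
                r = rng.random()
                if r < 0.3:
                    toks.append(rng.choice(list(inventory)))
                elif r < 0.6:
                    toks.append(rng.choice(literal_pool))
                else:
                    toks.append(rng.choice(STOPWORDS + _PLAIN_WORDS))
            toks.append(".")
            sentences.append(_assemble(toks))
    return sentences


def _resplit(sentence: Sentence) -> list[Union[str, tuple[str, str]]]:
    """Decompose an assembled sentence back into generator tokens."""
    toks: list[Union[str, tuple[str, str]]] = []
    pos = 0
    for m in sentence.mentions:
        toks.extend(sentence.text[pos:m.start].split())
        toks.append((m.surface, m.semantic_class))
        pos = m.end
    toks.extend(sentence.text[pos:].split())
    return toks
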