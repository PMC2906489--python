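"""Recall / precision / F evaluation against a hand-annotated gold
standard, and the keyword frequency statistics behind the dictionary.

Definitions (standard for relation extraction): with TP the number of
interactions extracted correctly, TP+FN the number of interactions in
the dataset and TP+FP the number of interactions retrieved,

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F         = 2 * precision * recall / (precision + recall)

Degenerate denominators yield 0 by convention and are flagged on the
result.  The default comparison scope is pair-level per document
(an extracted pair counts as correct only in a document whose gold
annotation lists it); corpus-level micro-averaging is the aggregate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, Union

from .extraction import count_keyword_tokens
from .model import Corpus, InteractionEvidence, normalize_name
from .patterns import keyword_variants

PAIR_SCOPE = "pair"
PAIR_DOC_SCOPE = "pair+doc"


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f: float
    degenerate: bool = False
    scope: str = PAIR_DOC_SCOPE

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn,
                "recall": self.recall, "precision": self.precision,
                "F": self.f, "degenerate": self.degenerate,
                "scope": self.scope}


@dataclass
class GoldStandard:
    """Hand-annotated true interaction pairs with document provenance."""

    pairs: set[tuple[str, frozenset[str]]] = field(default_factory=set)

    @classmethod
    def from_tuples(cls, rows: Iterable[tuple[str, str, str]]
                    ) -> "GoldStandard":
        pairs = set()
        for doc_id, a, b in rows:
            na, nb = normalize_name(a), normalize_name(b)
            if na and nb and na != nb:
                pairs.add((doc_id, frozenset((na, nb))))
        return cls(pairs=pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def doc_pairs(self) -> set[tuple[str, frozenset[str]]]:
        return set(self.pairs)

    def pair_set(self) -> set[frozenset[str]]:
        return {p for _, p in self.pairs}


def read_gold_standard(path: Union[str, Path]) -> GoldStandard:
    """TSV gold file: doc_id, protein_a, protein_b (``#`` comments)."""
    rows = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}, line {lineno}: expected 3 columns, got "
                    f"{len(parts)}")
            rows.append(tuple(parts))
    gold = GoldStandard.from_tuples(rows)
    if not gold.pairs:
        raise ValueError(f"empty gold standard: {path}")
    return gold


def write_gold_standard(gold: GoldStandard, path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for doc_id, pair in sorted(gold.pairs,
                                   key=lambda r: (r[0], sorted(r[1]))):
            a, b = sorted(pair)
            writer.writerow([doc_id, a, b])


def precision_recall_f(tp: int, fp: int, fn: int, *,
                       scope: str = PAIR_DOC_SCOPE) -> EvalResult:
    """Exact-fraction recall/precision/F from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fn > 0:
        recall = Fraction(tp, tp + fn)
    else:
        recall, degenerate = Fraction(0), True
    if tp + fp > 0:
        precision = Fraction(tp, tp + fp)
    else:
        precision, degenerate = Fraction(0), True
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = Fraction(0)
        degenerate = degenerate or tp + fp + fn > 0
    return EvalResult(tp=tp, fp=fp, fn=fn, recall=float(recall),
                      precision=float(precision), f=float(f),
                      degenerate=degenerate, scope=scope)


def evaluate_extraction(predicted: Sequence[InteractionEvidence],
                        gold: GoldStandard,
                        scope: str = PAIR_DOC_SCOPE) -> EvalResult:
    """Compare extracted evidence with the gold standard.

    ``scope`` is ``"pair+doc"`` (default: a pair must be predicted in a
    document whose gold lists it) or ``"pair"`` (document-blind).
    """
    if scope == PAIR_DOC_SCOPE:
        pred = {(e.doc_id, e.pair) for e in predicted}
        ref = gold.doc_pairs()
    elif scope == PAIR_SCOPE:
        pred = {e.pair for e in predicted}
        ref = gold.pair_set()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    return precision_recall_f(tp, fp, fn, scope=scope)


def keyword_frequency(corpus: Corpus, lemma: str) -> int:
    """Token occurrences of any variant of ``lemma`` over all sentences."""
    keyword_variants(lemma)  # validates the lemma
    return sum(count_keyword_tokens(sent, lemma)
               for _, sent in corpus.iter_sentences())


def keyword_pr(corpus: Corpus, gold: GoldStandard,
               lemma: str) -> tuple[float, float]:
    """Per-keyword (recall, precision) against the gold standard.

    Operationalization (declared, since several readings are possible):
    a sentence "contains a gold interaction" when both proteins of some
    gold pair of its document are mentioned in it.  Then

    * precision = fraction of keyword-containing sentences that contain
      a gold interaction;
    * recall = fraction of gold pairs for which some sentence of their
      document mentions both proteins and a variant of the keyword.

    Degenerate denominators yield 0.0.
    """
    variants = keyword_variants(lemma)
    gold_by_doc: dict[str, list[frozenset[str]]] = {}
    for doc_id, pair in gold.pairs:
        gold_by_doc.setdefault(doc_id, []).append(pair)

    kw_sentences = 0
    kw_sentences_with_gold = 0
    covered_pairs: set[tuple[str, frozenset[str]]] = set()
    for doc_id, sent in corpus.iter_sentences():
        has_kw = count_keyword_tokens(sent, lemma) > 0
        if not has_kw:
            continue
        kw_sentences += 1
        names = {m.normalized for m in sent.mentions}
        hit = False
        for pair in gold_by_doc.get(doc_id, ()):
            if pair <= names:
                hit = True
                covered_pairs.add((doc_id, pair))
        if hit:
            kw_sentences_with_gold += 1
    recall = len(covered_pairs) / len(gold.pairs) if gold.pairs else 0.0
    precision = (kw_sentences_with_gold / kw_sentences
                 if kw_sentences else 0.0)
    return recall, precision


def keyword_table(corpus: Corpus, gold=None) -> list[dict]:
    """Per-keyword frequency (and recall/precision when gold supplied),
    one row per lemma of the dictionary."""
    from .patterns import KEYWORD_LEMMAS

    rows = []
    for i, lemma in enumerate(KEYWORD_LEMMAS, start=1):
        row = {"id": i, "keyword": lemma,
               "frequency": keyword_frequency(corpus, lemma)}
        if gold is not None:
            r, p = keyword_pr(corpus, gold, lemma)
            row["recall_pct"] = round(100.0 * r, 1)
            row["precision_pct"] = round(100.0 * p, 1)
        rows.append(row)
    return rows
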