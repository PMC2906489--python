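"""The interaction keyword dictionary and surface-pattern templates.

Six interaction lemmas (interact, associate, bind, complex, activate,
regulate) anchor a fixed inventory of 22 surface templates with two
protein slots A and B.  Templates are shipped as a plain TSV data file so
the inventory is inspectable and extensible; each row compiles to one or
more element sequences (alternations expanded) that the matcher in
:mod:`ppidict.extraction` aligns against tokenized sentences.

Compiled element vocabulary:

* ``Slot("A")`` / ``Slot("B")`` — a protein slot (fills from a mention,
  or from any member of a coordinated mention group);
* ``Coord()`` — a coordinated group "A and B" collapsed into a single
  element; fills with every unordered pair inside one coordination run;
* ``TokenSet(forms)`` — one token drawn from a closed set (a keyword
  inflection set, a literal word, or a separator character);
* ``Ellipsis_()`` — an unbounded gap (the "complex ... contains" row).

A written keyword form expands to the inflections appropriate for the
position it occupies: verbal templates use verbal forms only, nominal
templates ("Binding of A to B") the nominal form only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

#: lemma -> every accepted surface variant (used for sentence selection
#: and word-frequency statistics; token-bounded, case-insensitive).
KEYWORD_VARIANTS: dict[str, frozenset[str]] = {
    "interact": frozenset(
        {"interact", "interacts", "interacted", "interacting",
         "interaction", "interactions"}),
    "associate": frozenset(
        {"associate", "associates", "associated", "association"}),
    "bind": frozenset({"bind", "binds", "bound", "binding"}),
    "complex": frozenset({"complex", "complexes", "complexed"}),
    "activate": frozenset({"activate", "activates", "activated"}),
    "regulate": frozenset({"regulate", "regulates", "regulated"}),
}

KEYWORD_LEMMAS = tuple(KEYWORD_VARIANTS)

ALL_KEYWORD_FORMS: frozenset[str] = frozenset(
    itertools.chain.from_iterable(KEYWORD_VARIANTS.values()))

# Written template word -> the token forms it stands for.  Verbal and
# nominal inflections are kept apart so that e.g. "interaction of A with
# B" does not also license "A interaction with B".
FORM_TABLE: dict[str, frozenset[str]] = {
    "interact": frozenset({"interact", "interacts", "interacted",
                           "interacting"}),
    "interaction": frozenset({"interaction", "interactions"}),
    "associate": frozenset({"associate", "associates", "associated"}),
    "associated": frozenset({"associated"}),
    "association": frozenset({"association"}),
    "bind": frozenset({"bind", "binds", "bound"}),
    "binding": frozenset({"binding"}),
    "complex": frozenset({"complex", "complexes", "complexed"}),
    "activate": frozenset({"activate", "activates", "activated"}),
    "regulate": frozenset({"regulate", "regulates", "regulated"}),
}


def keyword_variants(lemma: str) -> frozenset[str]:
    """Return every surface variant of one of the six interaction lemmas."""
    try:
        return KEYWORD_VARIANTS[lemma]
    except KeyError:
        raise ValueError(
            f"unknown keyword lemma {lemma!r}; the dictionary covers: "
            + ", ".join(KEYWORD_LEMMAS)) from None


# ---------------------------------------------------------------------------
# compiled template elements


@dataclass(frozen=True)
class Slot:
    name: str  # "A" or "B"


@dataclass(frozen=True)
class Coord:
    """A coordinated pair of slots ("A and B") collapsed to one element."""


@dataclass(frozen=True)
class TokenSet:
    forms: frozenset[str]


@dataclass(frozen=True)
class Ellipsis_:
    """Unbounded gap between the surrounding elements."""


Element = Union[Slot, Coord, TokenSet, Ellipsis_]


@dataclass(frozen=True)
class PatternTemplate:
    """One row of the pattern inventory."""

    pattern_id: str
    keyword: str
    directional: bool
    template: str
    branches: tuple[tuple[Element, ...], ...]


class PatternError(ValueError):
    pass


def _expand_alternations(tokens: list[str]) -> Iterable[list[str]]:
    """Yield every concrete token sequence of a template expression."""
    options: list[list[str]] = []
    for tok in tokens:
        if tok.startswith("(") and tok.endswith(")") and "|" in tok:
            options.append(tok[1:-1].split("|"))
        else:
            options.append([tok])
    for combo in itertools.product(*options):
        yield list(combo)


def _compile_branch(tokens: list[str], pattern_id: str) -> tuple[Element, ...]:
    elements: list[Element] = []
    for tok in tokens:
        if tok in ("A", "B"):
            elements.append(Slot(tok))
        elif tok == "...":
            elements.append(Ellipsis_())
        elif tok in FORM_TABLE:
            elements.append(TokenSet(FORM_TABLE[tok]))
        else:
            elements.append(TokenSet(frozenset({tok.lower()})))
    # Coordination rewrite: a literal "and" directly linking the two
    # slots means the slots form one coordinated group in the sentence.
    for i in range(len(elements) - 2):
        a, mid, b = elements[i:i + 3]
        if (isinstance(a, Slot) and isinstance(b, Slot)
                and isinstance(mid, TokenSet) and mid.forms == {"and"}):
            elements[i:i + 3] = [Coord()]
            break
    slots = sum(isinstance(e, (Slot,)) for e in elements)
    coords = sum(isinstance(e, Coord) for e in elements)
    if not ((slots == 2 and coords == 0) or (slots == 0 and coords == 1)):
        raise PatternError(
            f"pattern {pattern_id}: template must contain slots A and B "
            f"exactly once")
    return tuple(elements)


def compile_template(pattern_id: str, keyword: str, directional: bool,
                     template: str) -> PatternTemplate:
    tokens = template.split()
    if "A" not in tokens or "B" not in tokens:
        raise PatternError(
            f"pattern {pattern_id}: template must mention both A and B")
    if keyword not in KEYWORD_VARIANTS:
        raise PatternError(
            f"pattern {pattern_id}: unknown keyword {keyword!r}")
    branches = tuple(_compile_branch(list(b), pattern_id)
                     for b in _expand_alternations(tokens))
    return PatternTemplate(pattern_id=pattern_id, keyword=keyword,
                           directional=directional, template=template,
                           branches=branches)


def load_patterns(path: Optional[Union[str, Path]] = None) -> list[PatternTemplate]:
    """Load the pattern inventory from ``path`` or the packaged default."""
    if path is None:
        text = (resources.files("ppidict") / "data" / "patterns.tsv").read_text(
            encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    patterns: list[PatternTemplate] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise PatternError(
                f"pattern file line {lineno}: expected 4 tab-separated "
                f"fields, got {len(parts)}")
        pattern_id, keyword, directional, template = parts
        if pattern_id in seen:
            raise PatternError(
                f"pattern file line {lineno}: duplicate id {pattern_id}")
        seen.add(pattern_id)
        patterns.append(compile_template(
            pattern_id, keyword, directional.strip().lower() in
            ("yes", "true", "1"), template))
    if not patterns:
        raise PatternError("pattern file contains no templates")
    return patterns


_DEFAULT: Optional[list[PatternTemplate]] = None


def default_patterns() -> list[PatternTemplate]:
    """The packaged 22-template inventory (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_patterns()
    return _DEFAULT
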