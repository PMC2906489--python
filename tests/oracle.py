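"""Independent reference implementations used to cross-check the package.

* :func:`brute_force_matches` — a naive regex-based template enumerator:
  every template branch is compiled to a regular expression over a
  space-joined token string in which each coordination run of protein
  mentions is replaced by a placeholder symbol, and every ordered
  mention pair is tried exhaustively.  It shares the declared matching
  rules (token boundaries, 3-token filler window, coordination
  expansion) but none of the production matcher's code path.
* :class:`UnionFind` — connected components by union by size, to check
  the traversal-based topology computation.
"""

from __future__ import annotations

import re

from ppidict.model import Sentence
from ppidict.patterns import (
    ALL_KEYWORD_FORMS,
    FORM_TABLE,
    PatternTemplate,
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9-]+|[^\sA-Za-z0-9]")

_KW_ALT = "|".join(sorted(re.escape(k) for k in ALL_KEYWORD_FORMS))
# a filler token: not a run placeholder, not a keyword variant
_FILLER = rf"(?!R\d+ )(?!(?:{_KW_ALT}) )\S+"


def _tokens(sentence: Sentence) -> list[tuple[str, object]]:
    """("P", mention) / ("T", lowercased text) tokens, left to right."""
    out: list[tuple[str, object]] = []
    pos = 0
    for m in sorted(sentence.mentions, key=lambda m: m.start):
        for t in _TOKEN_RE.findall(sentence.text[pos:m.start]):
            out.append(("T", t.lower()))
        out.append(("P", m))
        pos = m.end
    for t in _TOKEN_RE.findall(sentence.text[pos:]):
        out.append(("T", t.lower()))
    return out


def _coordination_runs(tokens, window: int) -> list[list[int]]:
    """Maximal runs of protein tokens linked by ','/'and' plus up to
    ``window`` filler tokens after each coordinator."""
    runs: list[list[int]] = []
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i][0] != "P":
            i += 1
            continue
        run = [i]
        j = i + 1
        while True:
            k = j
            saw = False
            if k < n and tokens[k] == ("T", ","):
                k, saw = k + 1, True
            if k < n and tokens[k] == ("T", "and"):
                k, saw = k + 1, True
            if not saw:
                break
            skipped = 0
            while (k < n and skipped < window and tokens[k][0] == "T"
                   and tokens[k][1] not in ALL_KEYWORD_FORMS
                   and tokens[k][1] not in (",", "and")):
                k += 1
                skipped += 1
            if k >= n or tokens[k][0] != "P":
                break
            run.append(k)
            j = k + 1
        runs.append(run)
        i = j
    return runs


def _branch_specs(template: str):
    """Expand a raw template expression into naive branch token lists."""
    slots: list[list[str]] = []
    for tok in template.split():
        if tok.startswith("(") and tok.endswith(")") and "|" in tok:
            slots.append(tok[1:-1].split("|"))
        else:
            slots.append([tok])
    def expand(i):
        if i == len(slots):
            yield []
            return
        for choice in slots[i]:
            for rest in expand(i + 1):
                yield [choice] + rest
    yield from expand(0)


def _coordinated(branch: list[str]) -> bool:
    for i in range(len(branch) - 2):
        if branch[i] == "A" and branch[i + 1] == "and" and branch[i + 2] == "B":
            return True
    return False


def _piece(tok: str, run_symbol_a: str, run_symbol_b: str) -> str:
    if tok == "A":
        return re.escape(run_symbol_a) + " "
    if tok == "B":
        return re.escape(run_symbol_b) + " "
    if tok == "...":
        return r"(?:\S+ )*"
    forms = FORM_TABLE.get(tok, frozenset({tok.lower()}))
    return "(?:" + "|".join(sorted(re.escape(f) for f in forms)) + ") "


def _branch_regex(branch: list[str], sym_a: str, sym_b: str,
                  window: int) -> str:
    gap = rf"(?:{_FILLER} ){{0,{window}}}"
    pieces = []
    for tok in branch:
        if tok == "...":
            pieces.append(None)  # unbounded gap marker
        else:
            pieces.append(_piece(tok, sym_a, sym_b))
    out = []
    pending_unbounded = False
    for p in pieces:
        if p is None:
            pending_unbounded = True
            continue
        if out:
            out.append(r"(?:\S+ )*" if pending_unbounded else gap)
        out.append(p)
        pending_unbounded = False
    return "(?:^| )" + "".join(out)


def brute_force_matches(sentence: Sentence,
                        patterns: list[PatternTemplate],
                        window: int = 3) -> set[tuple]:
    """All (frozenset pair, keyword, pattern_id) triples in a sentence."""
    tokens = _tokens(sentence)
    runs = _coordination_runs(tokens, window)
    run_of = {}
    for ri, run in enumerate(runs):
        for ti in run:
            run_of[ti] = ri
    # render the token string with each run replaced by one symbol
    symbols: list[str] = []
    covered_until = -1
    for ti, (kind, val) in enumerate(tokens):
        if ti <= covered_until:
            continue
        if kind == "P":
            ri = run_of[ti]
            symbols.append(f"R{ri}")
            covered_until = runs[ri][-1]
        else:
            symbols.append(val)
    seq = " ".join(symbols) + " "

    mentions = [(ti, tok[1]) for ti, tok in enumerate(tokens)
                if tok[0] == "P"]
    found: set[tuple] = set()
    for pat in patterns:
        for branch in _branch_specs(pat.template):
            coord = _coordinated(branch)
            # replace the A-and-B core by a single A for coordinated reads
            if coord:
                b2 = []
                skip = 0
                for i, tok in enumerate(branch):
                    if skip:
                        skip -= 1
                        continue
                    if (tok == "A" and i + 2 < len(branch)
                            and branch[i + 1] == "and"
                            and branch[i + 2] == "B"):
                        b2.append("A")
                        skip = 2
                    else:
                        b2.append(tok)
                branch = b2
            for ti, ma in mentions:
                for tj, mb in mentions:
                    if ti == tj or ma.normalized == mb.normalized:
                        continue
                    ra, rb = run_of[ti], run_of[tj]
                    if coord:
                        if ra != rb or tj < ti:
                            continue
                        rx = _branch_regex(branch, f"R{ra}", "", window)
                    else:
                        if ra == rb:
                            continue
                        rx = _branch_regex(branch, f"R{ra}", f"R{rb}", window)
                    if re.search(rx, seq):
                        found.add((frozenset((ma.normalized, mb.normalized)),
                                   pat.keyword, pat.pattern_id))
    return found


class UnionFind:
    """Union by size with path compression."""

    def __init__(self) -> None:
        self.parent: dict = {}
        self.size: dict = {}

    def add(self, x) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.size[x] = 1

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        self.add(a)
        self.add(b)
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def n_components(self) -> int:
        return sum(1 for x in self.parent if self.find(x) == x)
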