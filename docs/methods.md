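# Methods

This note documents the models, rules and numerical choices behind
`ppidict`, the assumptions they rest on, and what the test suite does
and does not establish.

## The extraction model

`ppidict` implements dictionary-pattern relation extraction: an
interaction is asserted when a single sentence realizes one of a fixed
inventory of surface templates with two distinct protein mentions in
its slots. There is no syntactic parsing, no learned model, no
anaphora, and no cross-sentence inference; the unit of evidence is the
sentence. The design trades recall on paraphrase for complete
transparency — every extracted edge can be traced to a sentence, a
keyword and a template id.

### Keyword dictionary

Six interaction lemmas anchor the inventory — *interact, associate,
bind, complex, activate, regulate* — each with a closed set of surface
variants used for sentence selection and frequency statistics:

| lemma     | variants |
|-----------|----------|
| interact  | interact, interacts, interacted, interacting, interaction, interactions |
| associate | associate, associates, associated, association |
| bind      | bind, binds, bound, binding |
| complex   | complex, complexes, complexed |
| activate  | activate, activates, activated |
| regulate  | regulate, regulates, regulated |

Keyword hits are token-bounded and case-insensitive: *binding* counts,
*DNA-binding* does not (the hyphenated compound is one token).

### Template inventory

The 22 templates live in `src/ppidict/data/patterns.tsv`, one per line,
so the inventory is inspectable and replaceable (`--patterns`). A
template is a token sequence over two protein slots `A`/`B`, keyword
forms, literal tokens, alternation groups (`(with|and)`), a separator
class (`(-|/)`) and an ellipsis (`...`). Within each template the
written keyword form expands only to the inflections appropriate to its
position — verbal templates (`A interact with B`) accept verbal forms,
nominal templates (`Binding of A to B`) the nominal form — so
"interaction" never licenses the verbal frame. Two of the printed
source rows are elliptical; they are implemented here as the
*between/among A and B* and *complex … contains A and B* readings, a
declared interpretation rather than an attested form, and the
between/among alternation is carried as two separate pattern ids so
each surface reading is independently testable.

### Matching rules

The matcher aligns compiled templates against a tokenized sentence
(words with internal hyphens, single punctuation marks, and protein
mentions as atomic items). The rules that matter:

* **Filler window** (default 3, configurable): up to three intervening
  tokens are tolerated between consecutive template elements, provided
  none is a protein or a keyword variant. Bare-literal adjacency would
  match almost nothing in prose ("the IL-2 / IL-2R alpha **complex**"
  needs the window); a wider window would admit unrelated clauses.
* **Coordination**: maximal runs of mentions linked by commas/"and"
  (with up to the filler window of stop tokens after each coordinator)
  collapse into one group. A slot fills from any group member; the
  coordinated-pair element (`A and B …`) expands to every unordered
  pair within one group, so "A, B and C interact" yields all three
  pairs. This maximizes recall consistent with the template meaning;
  it over-extracts when a coordination mixes interactors with
  non-interactors.
* **Deduplication**: one evidence per (unordered pair, keyword,
  pattern id) per sentence; repeated keyword occurrences are matched
  independently and then collapsed. Distinct templates may co-fire on
  the same pair (e.g. `A complex with B` necessarily also satisfies
  `A complex B`, since *with* is a legal filler); no precedence rule is
  imposed — the records agree on the pair and differ only in pattern id.
* **Self-pairs** (identical normalized names) are discarded.
* **Direction**: *activate*/*regulate* are directional on the surface;
  the agent slot is kept on the evidence record, but the network is
  undirected — a directed network is a possible extension, not a
  current feature.
* **Negation is not modelled.** "A does not interact with B" matches
  the affirmative template (the negation words are ordinary fillers).
  This is intrinsic to the method; `generate_negation_probes` exists to
  measure the resulting false-positive rate, and the acceptance script
  reports it (100% of probes match, by construction of the approach).

### Names, lexicon, tagging

Protein identity is the normalized surface string: case-folded,
whitespace-collapsed, flanking punctuation stripped. No synonym or
database-identifier mapping is attempted, so "IL-2" and "interleukin-2"
are different proteins here. For un-annotated text a dictionary tagger
(longest match, left-to-right, token-bounded, leftmost wins on ties)
applies a lexicon compiled from an annotated corpus — the majority
semantic class per name, ties broken lexicographically. A statistical
POS-based tagger would generalize beyond the lexicon; that is an
external-tool concern deliberately out of scope.

When GENIA-style annotations nest, the innermost protein-typed span is
the mention: inner spans name specific molecules, outer spans are
usually coordinations or complexes. This is a package choice; corpora
that annotate differently will shift mention boundaries.

## Evaluation

Recall TP/(TP+FN), precision TP/(TP+FP) and balanced F (harmonic mean)
are computed in exact fraction arithmetic before conversion to float;
degenerate denominators give 0 and set a flag. The default comparison
scope is pair-level per document — an extracted pair counts as correct
only in a document whose gold annotation lists it — with a
document-blind `pair` scope available. Per-keyword recall/precision
against a gold standard uses a declared operationalization (a sentence
"contains" a gold interaction when it mentions both proteins of a gold
pair of its document), since several readings are defensible.

## The synthetic corpus

The generator is the package's study instrument, not a test fixture:
its defaults define the conditions under which every end-to-end claim
is measured — 200 documents of 3–6 sentences, a 60-name protein
inventory in GENIA-like styles ("QTR-7", "NF2", "TRB-2 alpha") with
semantic classes drawn 60/25/15 from molecule / family-or-group /
complex, and a 50/25/25 sentence mix:

* **planted** — a verbatim instantiation of a uniformly sampled
  template with a sampled protein pair, up to 2 stop-word fillers at
  each slot (inside the matcher's window of 3) and 4–6 fillers for the
  ellipsis (outside it, so only the ellipsis template bridges); each
  contributes one gold pair with document provenance;
* **keyword distractor** — contains a keyword variant but at most one
  protein mention, so it can never fill two slots;
* **keyword-free distractor** — 0–2 mentions, no keyword, hence never
  selected.

Filler vocabulary is disjoint from the keyword variants, and no
inventory name's token sequence is a prefix of another's, so dictionary
tagging recovers exactly the planted spans. Under these conditions the
predicted pair set equals the gold set — recall and precision 1.0 —
and that is what the acceptance checks assert, with precision compared
against the value predicted analytically from the composition (no
non-planted sentence can contribute a pair) rather than against an
aspiration. What passing these tests shows is that the matcher
implements its declared rules exactly; it does **not** certify
performance on real abstracts, whose paraphrase, negation scope,
nested coordination and long noun compounds the generator deliberately
does not imitate.

`generate_random_sentences` is the adversarial counterpart used for
cross-validation: half mutated template instantiations (random token
insertions/deletions), half token soup over the full template
vocabulary with 1–4 mentions, dense in near-matches and coordinations.
The production matcher is required to agree exactly with an
independently written brute-force enumerator (regex over a
run-collapsed token string, every ordered mention pair tried) on 1,000
such sentences.

## Numerical and formatting choices

* Offsets are 0-based, half-open, in Unicode code points; a mention's
  surface always equals its text slice, asserted at construction.
* All orderings are deterministic: evidences sort by (document,
  sentence, pair, keyword, pattern); networks are insertion-order
  independent; generated files are byte-identical for a fixed seed.
* Sentence splitting for plain-text abstracts is a single rule —
  terminator (.?!) + space + uppercase/digit — with no abbreviation
  list; adequate for abstracts, and wrong on e.g. "E. coli", which is
  accepted as a documented limitation.
* Node semantic class under conflicting annotations is the majority
  vote, ties lexicographic.
* Circular extraction defaults to one hop and keeps a visited set, so
  cyclic corpora terminate; hop-2 networks always contain hop-1
  networks.
* Exports: SIF (`A pp B`), GraphML with node class and edge
  evidence/literature counts, and minimal 15-column MITAB with names in
  columns 1–2. GraphML is written via networkx and verified against an
  independent XML re-parse.

## Known limitations

Lexical matching cannot see negation, speculation or paraphrase;
precision on real text is bounded by the first two, recall by the
third. Protein identity is string-based; species and synonym
resolution must happen upstream or downstream. The XML dialect is a
documented GENIA-like subset — anything else is rejected loudly rather
than half-parsed. Interactions spanning sentences are invisible.
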