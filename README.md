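# ppidict

Keyword-dictionary pattern matching for protein–protein interaction
(PPI) extraction from annotated biomedical abstracts.

Most experimentally supported protein interactions are still reported
only as free text. `ppidict` is a small, fully deterministic text-mining
pipeline for pulling those assertions out of abstract collections: given
a corpus and a query protein name, it finds every sentence that mentions
the query together with an interaction keyword, matches those sentences
against a fixed inventory of surface patterns, and aggregates the
matches into an undirected, evidence-backed interaction network. It is
aimed at people building PPI datasets or benchmarking relation-extraction
systems who want a transparent, inspectable baseline rather than a
trained model.

## Method

The extractor is a four-stage pipeline:

1. **Authentication** — the query string is checked against a protein
   lexicon compiled from the corpus annotations (or loaded from a file);
   names are normalized by case-folding, whitespace collapsing and
   flanking-punctuation stripping.
2. **Sentence selection** — keep sentences containing the query protein
   *and* at least one variant of the six interaction keywords
   *interact, associate, bind, complex, activate, regulate*.
3. **Pattern matching** — align each selected sentence against 22
   two-slot surface templates (e.g. `A interact with B`,
   `Binding of A to B`, `A (-|/) B complex`), with a bounded filler
   window, coordination expansion (`A, B and C interact` ⇒ all three
   pairs) and per-(pair, keyword, pattern) deduplication.
4. **Network aggregation** — one node per protein (with its GENIA
   semantic class), one edge per interacting pair; each edge carries its
   evidence sentences and a *literature count* (distinct supporting
   documents) as a reliability proxy. Topology is reported as node,
   edge and connected-component counts, and "circular extraction"
   re-queries newly found partners to grow the network hop by hop.

Extraction quality against a gold standard **G** of annotated pairs is
scored with the standard relation-extraction metrics. With TP the pairs
extracted correctly, TP+FN = |G| and TP+FP the pairs retrieved:

    recall R = TP / (TP + FN),  precision P = TP / (TP + FP),
    F = 2PR / (P + R)

Because the approach is purely lexical it is negation-blind by design
("A does not interact with B" still matches); the package ships a probe
generator that *measures* this false-positive mode instead of hiding it.

## Worked example

Generate a seeded synthetic corpus with planted interactions, then
query one of its proteins:

```bash
$ ppidict simulate --out-corpus demo.xml --out-gold demo_gold.tsv \
      --n-documents 12 --seed 4
wrote 12 documents (79 mentions) and 31 gold pairs [seed 4]

$ ppidict query --corpus demo.xml --query "jd-8 beta" --hops 2 --out-dir out
5 evidences; network: 6 nodes, 5 edges, 1 components

$ ppidict eval --corpus demo.xml --gold demo_gold.tsv
TP=31 FP=0 FN=0  recall=1.000 precision=1.000 F=1.000 [pair+doc]
```

The 5 evidences are 5 matched sentences; with `--hops 2` the three
partners found for `jd-8 beta` in hop one were themselves re-queried,
growing the map to 6 proteins in one connected component
(`out/network.sif` lists the 5 edges as `A pp B` lines, each backed by
one document in `report.json`'s literature counts).

The `query` run writes `out/evidence.tsv` (one row per matched
sentence: pair, keyword, pattern id, document, sentence), network
exports (`network.sif`, `network.graphml`, optionally MITAB) and
`report.json` with the topology, per-class partner counts for the query
and the per-edge literature counts. `eval` reports recall 1.0 here
because every planted template instantiation in the synthetic corpus is
recovered, and precision 1.0 because the distractor sentences cannot
form a protein pair — on real prose precision is limited by
negation-blindness and coordination over-expansion (see
`docs/methods.md`).

`ppidict stats` prints the per-keyword frequency table (and per-keyword
recall/precision when a gold file is supplied); `ppidict convert` turns
an evidence table into any of the network formats.

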