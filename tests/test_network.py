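"""Network aggregation, topology, statistics and circular extraction."""

import random

import pytest

from ppidict.model import InteractionEvidence
from ppidict.network import (
    NetworkError,
    build_network,
    circular_extract,
    literature_count,
    semantic_class_count,
    semantic_class_profile,
    topology,
)
from ppidict.patterns import default_patterns
from ppidict.synthetic_corpus import instantiate_template, sample_protein_inventory

from conftest import corpus_of
from oracle import UnionFind


def ev(a, b, doc, pid="BND-4", kw="bind", idx=0, cls_a="protein_molecule",
       cls_b="protein_molecule"):
    if a > b:
        a, b = b, a
        cls_a, cls_b = cls_b, cls_a
    return InteractionEvidence(
        protein_a=a, protein_b=b, keyword=kw, pattern_id=pid, doc_id=doc,
        sentence_index=idx, sentence_text=f"{a} binds {b} .",
        semantic_class_a=cls_a, semantic_class_b=cls_b)


class TestBuildNetwork:
    def test_counts_and_literature(self):
        net = build_network([ev("a", "b", "doc1"), ev("a", "b", "doc2"),
                             ev("b", "c", "doc1")])
        assert (net.n_nodes, net.n_edges) == (3, 2)
        assert literature_count(net, "a", "b") == 2
        assert literature_count(net, "b", "c") == 1

    def test_empty(self):
        net = build_network([])
        assert (net.n_nodes, net.n_edges) == (0, 0)

    def test_two_patterns_one_document_count_once(self):
        net = build_network([ev("a", "b", "doc1", pid="BND-4"),
                             ev("a", "b", "doc1", pid="BND-2")])
        assert net.n_edges == 1
        assert literature_count(net, "a", "b") == 1
        assert net.evidence_count("a", "b") == 2

    def test_permutation_invariance(self):
        evs = [ev("a", "b", "d1"), ev("b", "c", "d2"), ev("c", "d", "d3"),
               ev("a", "d", "d1", pid="INT-1", kw="interact")]
        n1 = build_network(evs)
        n2 = build_network(list(reversed(evs)))
        assert n1.sorted_nodes() == n2.sorted_nodes()
        assert n1.sorted_edges() == n2.sorted_edges()
        for a, b in n1.sorted_edges():
            assert n1.literature_count(a, b) == n2.literature_count(a, b)

    def test_edge_symmetry(self):
        net = build_network([ev("a", "b", "d1")])
        assert net.edge_evidences("a", "b") == net.edge_evidences("b", "a")


class TestTopology:
    def test_forced_component_structure(self):
        net = build_network([ev("a", "b", "d"), ev("b", "c", "d"),
                             ev("d", "e", "d")])
        topo = topology(net)
        assert (topo.n_nodes, topo.n_edges, topo.n_components) == (5, 3, 2)
        assert topo.components["a"] == topo.components["c"]
        assert topo.components["a"] != topo.components["d"]

    def test_empty_network(self):
        topo = topology(build_network([]))
        assert (topo.n_nodes, topo.n_edges, topo.n_components) == (0, 0, 0)

    def test_component_count_matches_union_find_oracle(self):
        rng = random.Random(77)
        for _ in range(60):
            n = rng.randint(2, 25)
            pairs = []  # self-pairs cannot be built; skip them
            for _ in range(rng.randint(1, 40)):
                i, j = rng.randrange(n), rng.randrange(n)
                if i != j:
                    pairs.append((f"p{i}", f"p{j}"))
            net = build_network([ev(a, b, f"d{k % 7}")
                                 for k, (a, b) in enumerate(pairs)])
            uf = UnionFind()
            for a, b in pairs:
                uf.union(min(a, b), max(a, b))
            topo = topology(net)
            assert topo.n_components == uf.n_components()
            # component sizes partition the node set
            assert len(topo.components) == topo.n_nodes


class TestSemanticClassCounts:
    def _net(self):
        return build_network([
            ev("q", "a", "d1", cls_a="protein_molecule",
               cls_b="protein_molecule"),
            ev("q", "b", "d1", cls_a="protein_molecule",
               cls_b="protein_molecule"),
            ev("q", "c", "d2", cls_a="protein_molecule",
               cls_b="protein_family_or_group"),
        ])

    def test_counts_by_class(self):
        net = self._net()
        assert semantic_class_count(net, "q", "protein_molecule") == 2
        assert semantic_class_count(net, "q", "protein_family_or_group") == 1

    def test_class_without_neighbors(self):
        assert semantic_class_count(self._net(), "q", "protein_complex") == 0

    def test_profile_partitions_degree(self):
        rng = random.Random(3)
        for _ in range(20):
            classes = ["protein_molecule", "protein_family_or_group",
                       "protein_complex"]
            evs = [ev("q", f"n{i}", f"d{i % 3}",
                      cls_b=rng.choice(classes))
                   for i in range(rng.randint(1, 12))]
            net = build_network(evs)
            profile = semantic_class_profile(net, "q")
            assert sum(profile.values()) == net.graph.degree("q")

    def test_unknown_query_raises(self):
        with pytest.raises(NetworkError, match="no extracted"):
            semantic_class_count(self._net(), "zz", "protein_molecule")


class TestLiteratureCount:
    def test_absent_edge_is_an_error_not_zero(self):
        net = build_network([ev("a", "b", "d1")])
        with pytest.raises(NetworkError, match="no edge"):
            literature_count(net, "a", "zz")

    def test_monotone_under_corpus_extension(self):
        evs = [ev("a", "b", "d1")]
        before = literature_count(build_network(evs), "a", "b")
        evs.append(ev("a", "b", "d2"))
        after = literature_count(build_network(evs), "a", "b")
        assert after >= before


def _chain_corpus():
    """A-B asserted in doc1, B-C in doc2."""
    rng = random.Random(0)
    pats = default_patterns()
    int1 = next(p for p in pats if p.pattern_id == "INT-1")
    a = ("AAX-1", "protein_molecule")
    b = ("BBX-2", "protein_molecule")
    c = ("CCX-3", "protein_molecule")
    return corpus_of(
        ("doc1", [instantiate_template(rng, int1, a, b,
                                       max_slot_fillers=0)]),
        ("doc2", [instantiate_template(rng, int1, b, c,
                                       max_slot_fillers=0)]),
    )


class TestCircularExtract:
    def test_hop_semantics_on_chain(self):
        corpus = _chain_corpus()
        one = circular_extract(corpus, "aax-1", hops=1)
        assert one.sorted_edges() == [("aax-1", "bbx-2")]
        two = circular_extract(corpus, "aax-1", hops=2)
        assert two.sorted_edges() == [("aax-1", "bbx-2"),
                                      ("bbx-2", "ccx-3")]

    def test_monotone_in_hops(self):
        corpus = _chain_corpus()
        one = circular_extract(corpus, "aax-1", hops=1)
        two = circular_extract(corpus, "aax-1", hops=2)
        assert set(dict(one.sorted_nodes())) <= set(dict(two.sorted_nodes()))
        assert set(one.sorted_edges()) <= set(two.sorted_edges())

    def test_terminates_on_cycles(self):
        rng = random.Random(0)
        pats = default_patterns()
        int1 = next(p for p in pats if p.pattern_id == "INT-1")
        a = ("AAX-1", "protein_molecule")
        b = ("BBX-2", "protein_molecule")
        corpus = corpus_of(
            ("doc1", [instantiate_template(rng, int1, a, b,
                                           max_slot_fillers=0)]),
            ("doc2", [instantiate_template(rng, int1, b, a,
                                           max_slot_fillers=0)]),
        )
        net = circular_extract(corpus, "aax-1", hops=10)
        assert net.sorted_edges() == [("aax-1", "bbx-2")]
        assert literature_count(net, "aax-1", "bbx-2") == 2

    def test_invalid_hops(self):
        with pytest.raises(ValueError):
            circular_extract(_chain_corpus(), "aax-1", hops=0)
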