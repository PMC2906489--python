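"""PPI network aggregation, topology and circular extraction.

Evidence records aggregate into an undirected graph: one node per
canonical protein name, one edge per unordered pair.  Each edge carries
its evidence list, the set of keywords seen and a *literature count* —
the number of distinct documents supporting the edge, the reliability
proxy reported alongside each interaction (the more articles assert a
pair, the higher the confidence).  Agent/target slots of directional
patterns live only in the evidence records; the graph is undirected.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .entity_recognition import ProteinLexicon, build_lexicon
from .model import UNKNOWN_CLASS, Corpus, InteractionEvidence
from .extraction import extract_ppi


class NetworkError(ValueError):
    pass


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    n_components: int
    components: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"n_nodes": self.n_nodes, "n_edges": self.n_edges,
                "n_components": self.n_components}


class PPINetwork:
    """Undirected protein interaction network built from evidence."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction ------------------------------------------------------

    def add_evidence(self, ev: InteractionEvidence) -> None:
        for name, cls in ((ev.protein_a, ev.semantic_class_a),
                          (ev.protein_b, ev.semantic_class_b)):
            if name not in self.graph:
                self.graph.add_node(name, class_votes=Counter())
            self.graph.nodes[name]["class_votes"][cls] += 1
        a, b = ev.protein_a, ev.protein_b
        if not self.graph.has_edge(a, b):
            self.graph.add_edge(a, b, evidences=[], doc_ids=set(),
                                keywords=set())
        data = self.graph.edges[a, b]
        if ev not in data["evidences"]:
            data["evidences"].append(ev)
            data["doc_ids"].add(ev.doc_id)
            data["keywords"].add(ev.keyword)

    # -- accessors ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, name: str) -> str:
        """Majority semantic class of a node, ties broken lexicographically."""
        votes: Counter = self.graph.nodes[name]["class_votes"]
        if not votes:
            return UNKNOWN_CLASS
        top = max(votes.values())
        return min(c for c, n in votes.items() if n == top)

    def sorted_nodes(self) -> list[tuple[str, str]]:
        return [(n, self.node_class(n)) for n in sorted(self.graph.nodes)]

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def neighbors(self, name: str) -> list[str]:
        return sorted(self.graph.neighbors(name))

    def edge_evidences(self, a: str, b: str) -> list[InteractionEvidence]:
        self._require_edge(a, b)
        return list(self.graph.edges[a, b]["evidences"])

    def edge_keywords(self, a: str, b: str) -> set[str]:
        self._require_edge(a, b)
        return set(self.graph.edges[a, b]["keywords"])

    def evidence_count(self, a: str, b: str) -> int:
        self._require_edge(a, b)
        return len(self.graph.edges[a, b]["evidences"])

    def literature_count(self, a: str, b: str) -> int:
        self._require_edge(a, b)
        return len(self.graph.edges[a, b]["doc_ids"])

    def _require_edge(self, a: str, b: str) -> None:
        if not self.graph.has_edge(a, b):
            raise NetworkError(f"no edge between {a!r} and {b!r}")


def build_network(evidences: Iterable[InteractionEvidence]) -> PPINetwork:
    """Aggregate evidence into a network (insertion-order independent)."""
    net = PPINetwork()
    for ev in sorted(set(evidences), key=lambda e: e.key()):
        net.add_evidence(ev)
    return net


def topology(network: PPINetwork) -> NetworkTopology:
    """Node/edge/connected-component counts and component membership."""
    comps = list(nx.connected_components(network.graph))
    comps.sort(key=lambda c: sorted(c)[0])
    membership = {name: i for i, comp in enumerate(comps)
                  for name in comp}
    return NetworkTopology(
        n_nodes=network.n_nodes, n_edges=network.n_edges,
        n_components=len(comps), components=membership)


def semantic_class_count(network: PPINetwork, query: str,
                         semantic_class: str) -> int:
    """How many interaction partners of ``query`` belong to a class."""
    if query not in network:
        raise NetworkError(
            f"query {query!r} has no extracted interactions")
    return sum(1 for n in network.graph.neighbors(query)
               if network.node_class(n) == semantic_class)


def semantic_class_profile(network: PPINetwork, query: str) -> dict[str, int]:
    """Per-class partner counts; values sum to the query's degree."""
    if query not in network:
        raise NetworkError(
            f"query {query!r} has no extracted interactions")
    counts: Counter = Counter(network.node_class(n)
                              for n in network.graph.neighbors(query))
    return dict(sorted(counts.items()))


def literature_count(network: PPINetwork, a: str, b: str) -> int:
    """Distinct documents supporting the a-b edge (always >= 1)."""
    return network.literature_count(a, b)


def circular_extract(corpus: Corpus, seed_query: str, hops: int = 1, *,
                     lexicon: Optional[ProteinLexicon] = None,
                     patterns=None) -> PPINetwork:
    """Breadth-first network growth: query the seed, then every newly
    discovered partner, up to ``hops`` expansion rounds."""
    if hops < 1:
        raise ValueError("hops must be >= 1")
    if lexicon is None:
        lexicon = build_lexicon(corpus)
    visited: set[str] = set()
    frontier = [seed_query]
    evidences: set[InteractionEvidence] = set()
    for _ in range(hops):
        next_frontier: list[str] = []
        for name in frontier:
            if name in visited:
                continue
            visited.add(name)
            for ev in extract_ppi(corpus, name, lexicon=lexicon,
                                  patterns=patterns):
                evidences.add(ev)
                partner = (ev.protein_b if ev.protein_a == name
                           else ev.protein_a)
                if partner not in visited:
                    next_frontier.append(partner)
        if not next_frontier:
            break
        frontier = sorted(set(next_frontier))
    return build_network(evidences)
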