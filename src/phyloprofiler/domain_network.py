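"""Directed domain-adjacency networks with expansion and pattern search.

Each node is a Pfam accession; a directed edge ``A -> B`` records that B
immediately follows A (N-terminal to C-terminal) in at least one protein's
architecture.  Direction is meaningful: ``A -> B`` and ``B -> A`` are
distinct adjacencies, and a tandem pair of identical domains produces a
self-loop.  Edges carry a weight (number of adjacent occurrences) and
provenance (the proteins realizing them), so the proteins behind any edge
can always be recovered from an export.

Exploration mirrors an interactive session: neighbors discovered by
expanding a node against a species proteome enter the graph as ``transient``
additions; committing a neighbor makes it ``committed`` so it can seed
further expansion; pattern search merges matching proteins' full
architectures into the graph.  Nodes built from the seed protein set are
``core``.  No operation ever removes a node or an edge.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from .arch_compare import Architecture, is_subsequence

__all__ = [
    "NodeAttrs",
    "EdgeAttrs",
    "DomainGraph",
    "PatternQuery",
    "build_adjacency_graph",
    "highlight_architecture",
    "expand_neighbors",
    "commit_neighbor",
    "search_pattern",
]

NODE_STATUSES = ("core", "transient", "committed")


@dataclasses.dataclass
class NodeAttrs:
    count: int = 0  # total occurrences across contributing architectures
    status: str = "core"


@dataclasses.dataclass
class EdgeAttrs:
    weight: int = 0
    provenance: set[str] = dataclasses.field(default_factory=set)


@dataclasses.dataclass(frozen=True)
class PatternQuery:
    """An ordered domain pattern (repeats allowed), optionally species-scoped."""

    domains: tuple[str, ...]
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.domains) < 1:
            raise ValueError("pattern query must contain at least one domain")


@dataclasses.dataclass
class DomainGraph:
    """Directed multigraph summary of domain adjacencies with provenance."""

    nodes: dict[str, NodeAttrs] = dataclasses.field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeAttrs] = dataclasses.field(default_factory=dict)
    seed_proteins: list[str] = dataclasses.field(default_factory=list)
    architectures: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)

    # -- mutation helpers -------------------------------------------------
    def _add_architecture(self, arch: Architecture, status: str) -> None:
        self.seed_proteins.append(arch.protein_id)
        self.architectures[arch.protein_id] = tuple(arch.domains)
        for acc in arch.domains:
            node = self.nodes.setdefault(acc, NodeAttrs(count=0, status=status))
            node.count += 1
        for src, dst in zip(arch.domains, arch.domains[1:]):
            edge = self.edges.setdefault((src, dst), EdgeAttrs())
            edge.weight += 1
            edge.provenance.add(arch.protein_id)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": {
                acc: {"count": a.count, "status": a.status}
                for acc, a in sorted(self.nodes.items())
            },
            "edges": [
                {
                    "source": src,
                    "target": dst,
                    "weight": e.weight,
                    "provenance": sorted(e.provenance),
                }
                for (src, dst), e in sorted(self.edges.items())
            ],
            "seed_proteins": list(self.seed_proteins),
            "architectures": {
                pid: list(domains) for pid, domains in sorted(self.architectures.items())
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "DomainGraph":
        g = cls()
        for acc, attrs in payload["nodes"].items():
            status = attrs["status"]
            if status not in NODE_STATUSES:
                raise ValueError(f"node {acc!r}: unknown status {status!r}")
            g.nodes[acc] = NodeAttrs(count=int(attrs["count"]), status=status)
        for e in payload["edges"]:
            src, dst = e["source"], e["target"]
            if src not in g.nodes or dst not in g.nodes:
                raise ValueError(f"edge {src}->{dst} references unknown node")
            g.edges[(src, dst)] = EdgeAttrs(
                weight=int(e["weight"]), provenance=set(e["provenance"])
            )
        g.seed_proteins = list(payload["seed_proteins"])
        g.architectures = {
            pid: tuple(domains)
            for pid, domains in payload.get("architectures", {}).items()
        }
        return g


def build_adjacency_graph(architectures: Iterable[Architecture]) -> DomainGraph:
    """Build the core adjacency graph from a set of seed architectures."""
    g = DomainGraph()
    for arch in architectures:
        g._add_architecture(arch, status="core")
    return g


def highlight_architecture(
    graph: DomainGraph, protein_id: str
) -> tuple[set[str], set[tuple[str, str]]]:
    """The exact node and directed-edge subsets traversed by one protein."""
    if protein_id not in graph.architectures:
        raise KeyError(f"protein {protein_id!r} did not contribute to this graph")
    domains = graph.architectures[protein_id]
    return set(domains), set(zip(domains, domains[1:]))


def expand_neighbors(
    graph: DomainGraph,
    domain: str,
    proteome: Sequence[Architecture],
) -> set[tuple[str, str, frozenset[str]]]:
    """Find all domains adjacent to ``domain`` across a species proteome.

    Returns ``(neighbor accession, direction, supporting protein ids)``
    triples, direction being ``upstream`` (neighbor precedes the domain) or
    ``downstream`` (neighbor follows it).  The discovered neighbors and their
    adjacency edges are recorded in the graph as ``transient``; core nodes
    and edges are never modified.
    """
    if domain not in graph.nodes:
        raise KeyError(f"domain {domain!r} is not a node of this graph")
    support: dict[tuple[str, str], set[str]] = {}
    occurrences: dict[tuple[str, str], int] = {}
    for arch in proteome:
        for prev_acc, acc in zip(arch.domains, arch.domains[1:]):
            if acc == domain:
                key = (prev_acc, "upstream")
                support.setdefault(key, set()).add(arch.protein_id)
                occurrences[key] = occurrences.get(key, 0) + 1
            if prev_acc == domain:
                key = (acc, "downstream")
                support.setdefault(key, set()).add(arch.protein_id)
                occurrences[key] = occurrences.get(key, 0) + 1
    result = {
        (acc, direction, frozenset(pids))
        for (acc, direction), pids in support.items()
    }
    # Record discoveries as transient overlay; idempotent under re-expansion
    # (weights only ever grow toward the proteome-wide occurrence count).
    for (acc, direction), pids in sorted(
        support.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        if acc not in graph.nodes:
            graph.nodes[acc] = NodeAttrs(count=0, status="transient")
        src, dst = (acc, domain) if direction == "upstream" else (domain, acc)
        edge = graph.edges.setdefault((src, dst), EdgeAttrs())
        edge.provenance |= pids
        edge.weight = max(edge.weight, occurrences[(acc, direction)])
    return result


def commit_neighbor(graph: DomainGraph, neighbor: str) -> DomainGraph:
    """Promote a transient neighbor to a permanent (committed) node so it can
    seed further expansion.  Only the node's status changes."""
    if neighbor not in graph.nodes:
        raise KeyError(f"domain {neighbor!r} is not a node of this graph")
    if graph.nodes[neighbor].status != "transient":
        raise ValueError(
            f"domain {neighbor!r} is {graph.nodes[neighbor].status}, not transient"
        )
    graph.nodes[neighbor].status = "committed"
    return graph


def search_pattern(
    query: PatternQuery | Sequence[str],
    proteome: Sequence[Architecture],
    graph: DomainGraph | None = None,
    contiguous: bool = False,
) -> list[str]:
    """Proteins whose architecture contains the query pattern in N->C order.

    Matching is subsequence containment — the pattern need not be contiguous,
    so query ``[A, B, C]`` matches architecture ``[A, D, B, C]`` — unless
    ``contiguous`` is set.  When a graph is supplied, matched proteins' full
    architectures are merged into it (new nodes enter as ``committed``).
    Results are sorted by protein id.
    """
    pattern = tuple(query.domains if isinstance(query, PatternQuery) else query)
    if not pattern:
        raise ValueError("empty pattern")
    matched: list[Architecture] = []
    for arch in proteome:
        ok = (
            _contains_contiguous(pattern, arch.domains)
            if contiguous
            else is_subsequence(pattern, arch.domains)
        )
        if ok:
            matched.append(arch)
    matched.sort(key=lambda a: a.protein_id)
    if graph is not None:
        for arch in matched:
            if arch.protein_id in graph.architectures:
                continue  # already contributing; merging again would double-count
            graph._add_architecture(arch, status="committed")
    return [a.protein_id for a in matched]


def _contains_contiguous(pattern: tuple[str, ...], domains: tuple[str, ...]) -> bool:
    n = len(pattern)
    return any(domains[i : i + n] == pattern for i in range(len(domains) - n + 1))
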