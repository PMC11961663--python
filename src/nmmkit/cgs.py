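"""Coreference-based graph search (CGS).

Coreference edges from the knowledge base's relation collection are
compiled into a Coreference Primary Term Graph (CPTG): a directed
acyclic graph whose nodes are terms (surface strings or NMM-ID keys)
and whose sinks — nodes with no outgoing edge — are the *Primary
Terms*.  Resolving a term means collecting every sink reachable from
it; a well-curated graph yields exactly one, but the resolver returns
the full set so curation errors surface instead of being masked.

The module also provides dictionary-based entity extraction: a
left-to-right, longest-match scan of free text against the graph's
surface forms, yielding non-overlapping matches annotated with their
resolved primary terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import CycleError
from .knowledgebase import RelationEdge

__all__ = ["CptgGraph", "EntityMatch", "build_cptg", "resolve_primary",
           "extract_entities"]


@dataclass(frozen=True)
class EntityMatch:
    """A dictionary match in free text: half-open span, surface, primaries."""

    start: int
    end: int
    surface: str
    primary_terms: tuple[str, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CptgGraph:
    """Compiled coreference primary term graph."""

    graph: nx.DiGraph
    sinks: frozenset[str] = field(init=False)
    _surfaces_by_length: list[int] = field(init=False)
    _surface_set: frozenset[str] = field(init=False)

    def __post_init__(self):
        self.sinks = frozenset(
            n for n in self.graph.nodes if self.graph.out_degree(n) == 0
        )
        self._surface_set = frozenset(self.graph.nodes)
        self._surfaces_by_length = sorted(
            {len(s) for s in self._surface_set}, reverse=True
        )

    @property
    def nodes(self) -> frozenset[str]:
        return self._surface_set


def build_cptg(edges: Iterable[RelationEdge]) -> CptgGraph:
    """Compile relation edges into a CPTG; verifies acyclicity at build time.

    Raises :class:`CycleError` carrying one offending cycle if the edge
    set is not a DAG.
    """
    g = nx.DiGraph()
    for edge in edges:
        g.add_edge(edge.source_term, edge.target_term)
    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _v in nx.find_cycle(g)]
        raise CycleError(
            f"coreference edges contain a cycle: {' -> '.join(cycle + cycle[:1])}",
            cycle=cycle,
        )
    return CptgGraph(graph=g)


def resolve_primary(cptg: CptgGraph, term: str) -> set[str]:
    """All Primary Terms (sinks) reachable from ``term``.

    A sink resolves to itself; an unknown term yields the empty set.
    """
    if term not in cptg.graph:
        return set()
    if term in cptg.sinks:
        return {term}
    reachable = nx.descendants(cptg.graph, term)
    return {n for n in reachable if n in cptg.sinks}


def extract_entities(cptg: CptgGraph, text: str) -> list[EntityMatch]:
    """Longest-match, leftmost-first dictionary extraction.

    Scans left to right; at each position the longest surface form in
    the graph that matches wins and its span is consumed, so matches
    never overlap and come out sorted by start offset.
    """
    matches: list[EntityMatch] = []
    n = len(text)
    i = 0
    lengths = cptg._surfaces_by_length
    while i < n:
        hit = None
        for length in lengths:
            if i + length > n:
                continue
            candidate = text[i:i + length]
            if candidate in cptg._surface_set:
                hit = candidate
                break
        if hit is None:
            i += 1
            continue
        matches.append(
            EntityMatch(
                start=i,
                end=i + len(hit),
                surface=hit,
                primary_terms=tuple(sorted(resolve_primary(cptg, hit))),
            )
        )
        i += len(hit)
    return matches
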