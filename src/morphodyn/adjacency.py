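"""Spatial adjacency graphs and iterative neighbor expansion.

Spatial tracks list pairs of objects at the same time point (physical
neighbors or any other same-time relation); dictionary tracks attach a
quantitative value to each pair, typically the contact area between two
touching objects.  Both build the same undirected per-time graph.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Set, Tuple

import networkx as nx

from .core import MorphoFormatError, ObjectKey
from .info_io import InfoTrack, LinkedValue, SpatialLink

__all__ = ["AdjacencyGraph", "build_adjacency", "expand_neighbors"]


class AdjacencyGraph:
    """Undirected graph over object keys; edges never cross time points.

    Edge weights, when present, are contact areas (squared dataset length
    units) and must be positive.  Weighted and unweighted edges may
    coexist: an unweighted edge has no ``weight`` attribute, not weight 0.
    """

    def __init__(self):
        self.g = nx.Graph()

    def add_edge(self, a: ObjectKey, b: ObjectKey,
                 weight: Optional[float] = None, strict: bool = True) -> None:
        if a.t != b.t:
            raise MorphoFormatError(
                f"adjacency edge {a} -- {b} crosses time points")
        if a == b:
            raise MorphoFormatError(f"self-adjacency on {a}")
        if weight is not None and not weight > 0:
            raise MorphoFormatError(
                f"contact weight for {a} -- {b} must be > 0, got {weight}")
        if self.g.has_edge(a, b):
            existing = self.g.edges[a, b].get("weight")
            if weight is not None and existing is not None \
                    and existing != weight and strict:
                raise MorphoFormatError(
                    f"conflicting weights for edge {a} -- {b}: "
                    f"{existing} vs {weight}")
            if weight is not None:
                self.g.edges[a, b]["weight"] = weight
            return
        if weight is None:
            self.g.add_edge(a, b)
        else:
            self.g.add_edge(a, b, weight=weight)

    @property
    def nodes(self) -> Set[ObjectKey]:
        return set(self.g.nodes)

    @property
    def edges(self) -> Set[Tuple[ObjectKey, ObjectKey]]:
        return {tuple(sorted(e)) for e in self.g.edges}

    def neighbors(self, key: ObjectKey) -> Set[ObjectKey]:
        return set(self.g.neighbors(key))

    def weight(self, a: ObjectKey, b: ObjectKey) -> Optional[float]:
        return self.g.edges[a, b].get("weight")

    def at_time(self, t: int) -> "AdjacencyGraph":
        sub = AdjacencyGraph()
        sub.g = self.g.subgraph([n for n in self.g if n.t == t]).copy()
        return sub


def build_adjacency(track: InfoTrack, strict: bool = True) -> AdjacencyGraph:
    """Build an adjacency graph from a spatial or dictionary track.

    Symmetric duplicates (``A:B`` and ``B:A``) collapse to one undirected
    edge; for dictionary tracks, conflicting duplicate weights are an error
    in strict mode (last wins otherwise).
    """
    if track.info_type not in ("space", "dict"):
        raise MorphoFormatError(
            f"adjacency requires a 'space' or 'dict' track, got "
            f"{track.info_type!r}")
    ag = AdjacencyGraph()
    for e in track.entries:
        if isinstance(e, SpatialLink):
            ag.add_edge(e.a, e.b, strict=strict)
        elif isinstance(e, LinkedValue):
            if e.source.t != e.target.t:
                raise MorphoFormatError(
                    f"dictionary adjacency edge {e.source} -- {e.target} "
                    "crosses time points")
            ag.add_edge(e.source, e.target, weight=e.value, strict=strict)
    return ag


def expand_neighbors(
    graph: AdjacencyGraph,
    seeds: Iterable[ObjectKey],
    iterations: int,
) -> Set[ObjectKey]:
    """Breadth-first closure of radius ``iterations`` around the seeds.

    Radius 0 returns the seeds unchanged; each iteration adds all physical
    neighbors of the current selection, mirroring repeated neighbor
    selection in a browser.  Monotone in ``iterations`` with the connected
    component as fixed point.
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    current = set(seeds)
    for _ in range(iterations):
        frontier = set()
        for n in current:
            if n in graph.g:
                frontier |= set(graph.g.neighbors(n))
        new = current | frontier
        if new == current:
            break
        current = new
    return current
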