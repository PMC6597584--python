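"""Temporal lineage graphs: divisions, fusions, tracking, selection propagation.

Temporal tracks encode "OTP2 originates from OTP1 at a previous time
point".  A division of OTP1 into OTP2 and OTP3 appears as the two edges
OTP1->OTP2 and OTP1->OTP3; a fusion of OTP1 and OTP2 into OTP3 as
OTP1->OTP3 and OTP2->OTP3.  The lineage graph is therefore a DAG ordered
by time, in which out-degree >= 2 marks a division and in-degree >= 2 a
fusion target.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx

from .core import MorphoFormatError, ObjectKey
from .info_io import InfoTrack, SelectionLabel, TemporalLink

__all__ = [
    "LineageGraph",
    "build_lineage",
    "propagate_selection",
    "export_lineage_edgelist",
    "export_lineage_newick",
]

EVENT_NONE = "none"
EVENT_DIVISION = "division"
EVENT_FUSION = "fusion-target"
EVENT_APPEARANCE = "appearance"
EVENT_DISAPPEARANCE = "disappearance"


class LineageGraph:
    """Directed, time-ordered graph of object keys.

    Thin wrapper around a :class:`networkx.DiGraph` adding event
    classification and time-aware queries.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.g = graph if graph is not None else nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, key: ObjectKey) -> None:
        self.g.add_node(key)

    def add_edge(self, source: ObjectKey, target: ObjectKey) -> None:
        if source.t >= target.t:
            raise MorphoFormatError(
                f"lineage edge {source} -> {target} must advance in time")
        if target.t - source.t > 1:
            warnings.warn(
                f"lineage edge {source} -> {target} skips "
                f"{target.t - source.t - 1} time point(s)", stacklevel=2)
        if self.g.has_edge(source, target):
            warnings.warn(f"duplicate lineage edge {source} -> {target}; "
                          "deduplicated", stacklevel=2)
            return
        self.g.add_edge(source, target)

    # -- structure --------------------------------------------------------
    @property
    def nodes(self) -> Set[ObjectKey]:
        return set(self.g.nodes)

    @property
    def edges(self) -> Set[Tuple[ObjectKey, ObjectKey]]:
        return set(self.g.edges)

    def children(self, key: ObjectKey) -> Set[ObjectKey]:
        return set(self.g.successors(key))

    def parents(self, key: ObjectKey) -> Set[ObjectKey]:
        return set(self.g.predecessors(key))

    @property
    def t_min(self) -> int:
        return min(k.t for k in self.g.nodes)

    @property
    def t_max(self) -> int:
        return max(k.t for k in self.g.nodes)

    # -- events -----------------------------------------------------------
    def events(self) -> Dict[ObjectKey, str]:
        """Classify every node.

        division: out-degree >= 2; fusion-target: in-degree >= 2;
        appearance: no parent although earlier time points exist;
        disappearance: no child although later time points exist.  A node
        can be both a division and a fusion target; division takes
        precedence in the single-label map, with fusions always retrievable
        via :meth:`fusion_targets`.
        """
        if not self.g:
            return {}
        t0, t1 = self.t_min, self.t_max
        out: Dict[ObjectKey, str] = {}
        for n in self.g.nodes:
            if self.g.out_degree(n) >= 2:
                out[n] = EVENT_DIVISION
            elif self.g.in_degree(n) >= 2:
                out[n] = EVENT_FUSION
            elif self.g.in_degree(n) == 0 and n.t > t0:
                out[n] = EVENT_APPEARANCE
            elif self.g.out_degree(n) == 0 and n.t < t1:
                out[n] = EVENT_DISAPPEARANCE
            else:
                out[n] = EVENT_NONE
        return out

    def divisions(self) -> Set[ObjectKey]:
        return {n for n in self.g.nodes if self.g.out_degree(n) >= 2}

    def fusion_targets(self) -> Set[ObjectKey]:
        return {n for n in self.g.nodes if self.g.in_degree(n) >= 2}

    # -- reachability -----------------------------------------------------
    def _check_seeds(self, seeds: Iterable[ObjectKey]) -> Set[ObjectKey]:
        seeds = set(seeds)
        unknown = seeds - self.nodes
        if unknown:
            raise KeyError(
                f"unknown seed key(s): {', '.join(str(k) for k in sorted(unknown))}")
        return seeds

    def descendants(self, seeds: Iterable[ObjectKey]) -> Set[ObjectKey]:
        """Forward reachability closure, including the seeds."""
        seeds = self._check_seeds(seeds)
        out = set(seeds)
        for s in seeds:
            out |= nx.descendants(self.g, s)
        return out

    def ancestors(self, seeds: Iterable[ObjectKey]) -> Set[ObjectKey]:
        """Backward reachability closure, including the seeds."""
        seeds = self._check_seeds(seeds)
        out = set(seeds)
        for s in seeds:
            out |= nx.ancestors(self.g, s)
        return out

    def identity_chains(self) -> List[List[ObjectKey]]:
        """Maximal chains of one-to-one temporal succession.

        A chain is a maximal path along edges whose source has out-degree 1
        and whose target has in-degree 1 — i.e. the same physical object
        tracked between events.  Every node belongs to exactly one chain
        (possibly a singleton).
        """
        def chain_edge(u, v) -> bool:
            return self.g.out_degree(u) == 1 and self.g.in_degree(v) == 1

        chains = []
        visited: Set[ObjectKey] = set()
        for n in sorted(self.g.nodes):
            if n in visited:
                continue
            # rewind to the start of n's chain
            start = n
            while True:
                preds = list(self.g.predecessors(start))
                if len(preds) == 1 and chain_edge(preds[0], start) \
                        and preds[0] not in visited:
                    start = preds[0]
                else:
                    break
            chain = [start]
            visited.add(start)
            cur = start
            while True:
                succs = list(self.g.successors(cur))
                if len(succs) == 1 and chain_edge(cur, succs[0]):
                    cur = succs[0]
                    chain.append(cur)
                    visited.add(cur)
                else:
                    break
            chains.append(chain)
        return chains


def build_lineage(track: InfoTrack) -> LineageGraph:
    """Build the lineage graph from a temporal information track."""
    if track.info_type != "time":
        raise MorphoFormatError(
            f"lineage requires a 'time' track, got {track.info_type!r}")
    lg = LineageGraph()
    for e in track.entries:
        assert isinstance(e, TemporalLink)
        lg.add_node(e.source)
        lg.add_node(e.target)
        lg.add_edge(e.source, e.target)
    return lg


def propagate_selection(
    graph: LineageGraph,
    selection: InfoTrack,
    direction: str = "forward",
) -> InfoTrack:
    """Propagate color-selection labels along the lineage.

    Every node reachable from a labeled node in the chosen direction
    (``forward``, ``backward`` or ``both``) receives that label.  Where
    conflicting labels meet (e.g. at a fusion target), the smallest label
    wins, deterministically, and a warning lists the conflict.  ``both``
    iterates forward then backward passes to a fixed point.
    """
    if selection.info_type != "selection":
        raise MorphoFormatError(
            f"expected a 'selection' track, got {selection.info_type!r}")
    if direction not in ("forward", "backward", "both"):
        raise ValueError(f"direction must be forward/backward/both, got {direction!r}")

    labels: Dict[ObjectKey, int] = {}
    for e in selection.entries:
        if e.key not in graph.nodes:
            raise KeyError(f"selection key {e.key} not in lineage graph")
        labels[e.key] = min(labels.get(e.key, e.label), e.label)

    def sweep(forward: bool) -> bool:
        changed = False
        order = nx.topological_sort(graph.g)
        nodes = list(order) if forward else list(reversed(list(order)))
        for n in nodes:
            neigh = graph.parents(n) if forward else graph.children(n)
            incoming = sorted({labels[p] for p in neigh if p in labels})
            if not incoming:
                continue
            if len(incoming) > 1:
                warnings.warn(
                    f"conflicting selection labels {incoming} meet at {n}; "
                    f"keeping {incoming[0]}", stacklevel=3)
            candidate = incoming[0]
            if n in labels:
                if candidate < labels[n] and n not in original:
                    labels[n] = candidate
                    changed = True
            else:
                labels[n] = candidate
                changed = True
        return changed

    original = {e.key for e in selection.entries}
    if direction == "forward":
        sweep(forward=True)
    elif direction == "backward":
        sweep(forward=False)
    else:
        while True:
            c1 = sweep(forward=True)
            c2 = sweep(forward=False)
            if not (c1 or c2):
                break

    entries = [SelectionLabel(key=k, label=v) for k, v in sorted(labels.items())]
    return InfoTrack(name=f"{selection.name}.propagated", info_type="selection",
                     entries=entries)


def export_lineage_edgelist(graph: LineageGraph) -> str:
    """Deterministic TSV edge list: ``source<TAB>target<TAB>event(source)``."""
    ev = graph.events()
    lines = []
    for s, t in sorted(graph.edges):
        lines.append(f"{s}\t{t}\t{ev[s]}")
    return "\n".join(lines) + ("\n" if lines else "")


def export_lineage_newick(graph: LineageGraph) -> str:
    """Export a fusion-free lineage forest as Newick, node names ``t.id.ch``.

    Fusions make the graph a DAG rather than a forest, so requesting Newick
    on a graph with fusion targets is an error.
    """
    if graph.fusion_targets():
        raise MorphoFormatError(
            "lineage contains fusion events; Newick export requires a tree")

    def name(k: ObjectKey) -> str:
        return f"{k.t}.{k.id}.{k.ch}"

    def subtree(n: ObjectKey) -> str:
        kids = sorted(graph.children(n))
        if not kids:
            return name(n)
        return "(" + ",".join(subtree(c) for c in kids) + ")" + name(n)

    roots = sorted(n for n in graph.nodes if graph.g.in_degree(n) == 0)
    return "".join(subtree(r) + ";\n" for r in roots)
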