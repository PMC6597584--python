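"""Gene-expression catalogs and set operations on expression patterns.

A genetic track maps objects to an expression level of one gene — either
boolean (0/1, on/off) or quantitative — with the gene name carried by the
track name (by convention, the name of the information file).  A
:class:`GeneCatalog` gathers several genes and supports the usual
pattern-algebra queries: which objects express a gene, the overlap and
union of several genes' patterns, and the gene list of a picked object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

from .core import MorphoFormatError, ObjectKey
from .info_io import GeneticLevel, InfoTrack, SelectionLabel

__all__ = ["GeneCatalog"]


@dataclass
class GeneCatalog:
    """A collection of genetic tracks, one per gene.

    ``threshold`` defines "expressed": level strictly greater than the
    threshold.  The default 0 makes boolean 0/1 tracks behave as on/off.
    """

    tracks: Dict[str, InfoTrack] = field(default_factory=dict)
    threshold: float = 0.0

    def add(self, track: InfoTrack) -> None:
        if track.info_type != "genetic":
            raise MorphoFormatError(
                f"gene catalog accepts 'genetic' tracks only, got "
                f"{track.info_type!r}")
        if track.name in self.tracks:
            raise MorphoFormatError(f"duplicate gene name {track.name!r}")
        self.tracks[track.name] = track

    @property
    def genes(self) -> List[str]:
        return sorted(self.tracks)

    def _track(self, gene: str) -> InfoTrack:
        if gene not in self.tracks:
            raise KeyError(f"unknown gene {gene!r}")
        return self.tracks[gene]

    def expressed_set(self, gene: str) -> Set[ObjectKey]:
        """Objects whose expression level exceeds the threshold."""
        return {e.key for e in self._track(gene).entries
                if e.level > self.threshold}

    def expressing_count(self, gene: str) -> int:
        """Total number of objects expressing the gene."""
        return len(self.expressed_set(gene))

    def overlap(self, genes: Sequence[str]) -> Set[ObjectKey]:
        """Intersection of the expression patterns of two or more genes."""
        if len(genes) < 2:
            raise ValueError("overlap requires at least two genes")
        sets = [self.expressed_set(g) for g in genes]
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out

    def union(self, genes: Sequence[str]) -> Set[ObjectKey]:
        """Union of the expression patterns of two or more genes."""
        if len(genes) < 2:
            raise ValueError("union requires at least two genes")
        out: Set[ObjectKey] = set()
        for g in genes:
            out |= self.expressed_set(g)
        return out

    def genes_of(self, key: ObjectKey) -> List[str]:
        """Sorted list of genes expressed by a picked object."""
        return [g for g in self.genes if key in self.expressed_set(g)]

    def expression_selection(self, gene_a: str, gene_b: str) -> InfoTrack:
        """Three-way selection track for a gene pair.

        Objects expressing only the first gene get label 1, only the
        second label 2, and the overlap label 3 (disjoint classes; the
        green/red/blue rendering is the viewer's concern).
        """
        a = self.expressed_set(gene_a)
        b = self.expressed_set(gene_b)
        entries = []
        for k in sorted(a | b):
            if k in a and k in b:
                label = 3
            elif k in a:
                label = 1
            else:
                label = 2
            entries.append(SelectionLabel(key=k, label=label))
        return InfoTrack(name=f"{gene_a}_vs_{gene_b}", info_type="selection",
                         entries=entries)
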