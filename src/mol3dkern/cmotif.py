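"""Chain-motif (c-motif) graphs.

A c-motif is a set of four consecutive atoms on a simple path of the
molecular graph (a directed 3-hop path).  The c-motif graph ``C = (Vc, Ec)``
has one node per motif, carrying the 13-entry feature of
:mod:`mol3dkern.hopfeatures`, and an edge between two motifs whenever they
share at least one atom.  The chain-motif graph kernel is the GraphHopper
kernel evaluated on these derived graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hopfeatures import CMotifFeature, cmotif_feature, enumerate_khop_paths
from .molio import MoleculeGraph

__all__ = ["CMotifGraph", "build_cmotif_graph"]


@dataclass
class CMotifGraph:
    """Graph over the 3-hop paths (chain motifs) of one molecule.

    Motifs are ordered lexicographically by their atom-id tuple; edges are
    unordered index pairs of motifs sharing >= 1 atom.
    """

    motifs: list[tuple[int, ...]]
    features: list[CMotifFeature]
    edges: list[tuple[int, int]]
    source: str = ""

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_motifs)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        for lst in nbrs:
            lst.sort()
        return nbrs


def build_cmotif_graph(
    g: MoleculeGraph, dedupe_reversed: bool = False
) -> CMotifGraph:
    """Build the c-motif graph of a molecule.

    One motif node per directed 3-hop path (both directions kept unless
    ``dedupe_reversed``); a molecule without 3-hop paths yields an empty
    graph.  The shared-atom test is literal nonempty intersection of the two
    4-atom sets, found through an atom -> motif inverted index.
    """
    paths = enumerate_khop_paths(g, hops=3, dedupe_reversed=dedupe_reversed)
    features = [cmotif_feature(g, p) for p in paths]
    by_atom: dict[int, list[int]] = {}
    for idx, p in enumerate(paths):
        for atom in p:
            by_atom.setdefault(atom, []).append(idx)
    edge_set: set[tuple[int, int]] = set()
    for members in by_atom.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                edge_set.add((members[a], members[b]))
    return CMotifGraph(paths, features, sorted(edge_set), source=g.name)
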