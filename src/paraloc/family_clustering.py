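"""Gene-family construction by stringent double linkage.

Three proteins A, B, C cluster together only when all three pairwise
filtered links exist, i.e. double-linkage clusters are the maximal
cliques of the filtered pair graph (an edge in no larger clique is a
2-member cluster).  Because a protein can sit in several maximal
cliques, overlapping clusters are then merged by single linkage into
"superclusters" until each protein belongs to exactly one family.

A gene-conversion guard removes genes with more than ``max_matches``
(default 5) identifying matches — pair-graph degree computed on the
original graph, single pass — since conversion between members of large
families resets apparent divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from paraloc.pair_detection import ProteinPair

log = logging.getLogger(__name__)


@dataclass
class PairGraph:
    """Undirected graph of proteins linked by filtered reciprocal pairs."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[ProteinPair], require_reciprocal: bool = True
    ) -> "PairGraph":
        g = nx.Graph()
        for p in pairs:
            if require_reciprocal and not p.passed_reciprocal:
                continue
            a, b = sorted(p.ids)
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(graph=g)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PairGraph":
        g = nx.Graph()
        for a, b in edges:
            if a != b:
                g.add_edge(a, b)
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, node: str) -> int:
        return self.graph.degree[node]


@dataclass(frozen=True)
class GeneFamily:
    """A cluster of >= 2 proteins; ``kind`` records whether it came
    straight from double linkage or from a supercluster merge."""

    members: frozenset[str]
    kind: str = "double_linkage"  # or "supercluster"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a gene family needs at least 2 members")
        if self.kind not in ("double_linkage", "supercluster"):
            raise ValueError(f"unknown family kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.members)


def double_linkage_clusters(
    g: PairGraph, max_family_size: int = 2000
) -> set[GeneFamily]:
    """Maximal cliques of the pair graph as clusters (Bron-Kerbosch with
    pivoting via networkx).  Every edge lies in some maximal clique, so
    edges outside any triangle emerge as 2-member clusters.  A protein
    may appear in several clusters at this stage."""
    families: set[GeneFamily] = set()
    for clique in nx.find_cliques(g.graph):
        if len(clique) < 2:
            continue
        if len(clique) > max_family_size:
            log.warning(
                "clique of size %d capped at max_family_size=%d",
                len(clique),
                max_family_size,
            )
            clique = sorted(clique)[:max_family_size]
        families.add(GeneFamily(members=frozenset(clique)))
    return families


def merge_superclusters(clusters: set[GeneFamily]) -> set[GeneFamily]:
    """Single-linkage merge of clusters sharing any member, iterated to a
    fixpoint, so the result partitions the member set.  Families produced
    by a merge are tagged ``supercluster``; untouched ones keep their
    ``double_linkage`` kind."""
    overlap = nx.Graph()
    clusters = list(clusters)
    overlap.add_nodes_from(range(len(clusters)))
    owner: dict[str, int] = {}
    for i, fam in enumerate(clusters):
        for m in fam.members:
            if m in owner:
                overlap.add_edge(owner[m], i)
            owner[m] = i
    # owner maps each member to *one* cluster containing it; chained
    # overlaps still connect because every later cluster links to the
    # previous owner, and connected components give the transitive merge.
    merged: set[GeneFamily] = set()
    for comp in nx.connected_components(overlap):
        comp = sorted(comp)
        members = frozenset().union(*(clusters[i].members for i in comp))
        if len(comp) == 1:
            merged.add(GeneFamily(members=members, kind=clusters[comp[0]].kind))
        else:
            merged.add(GeneFamily(members=members, kind="supercluster"))
    return merged


def build_families(g: PairGraph) -> set[GeneFamily]:
    """Double linkage followed by supercluster merging."""
    return merge_superclusters(double_linkage_clusters(g))


def gene_conversion_filter(g: PairGraph, max_matches: int = 5) -> PairGraph:
    """Remove every protein with more than ``max_matches`` identifying
    matches (pair-graph degree on the ORIGINAL graph, single pass) along
    with its incident edges; returns the induced subgraph."""
    keep = [n for n in g.graph.nodes if g.graph.degree[n] <= max_matches]
    return PairGraph(graph=g.graph.subgraph(keep).copy())


def duplication_proportion(families: Iterable[GeneFamily], total_genes: int) -> float:
    """Fraction of the genome in a duplicate family: distinct family
    members over total genes."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    members: set[str] = set()
    for fam in families:
        members |= fam.members
    if len(members) > total_genes:
        raise ValueError("more family members than total genes")
    return len(members) / total_genes


def family_count(families: Iterable[GeneFamily]) -> int:
    return sum(1 for _ in families)


def write_families_tsv(path, families: Iterable[GeneFamily]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("family_id\tkind\tmembers\n")
        fams = sorted(families, key=lambda f: sorted(f.members))
        for i, fam in enumerate(fams, 1):
            out.write(f"F{i:05d}\t{fam.kind}\t{','.join(sorted(fam.members))}\n")
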