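"""Pangenome graph: gene-family nodes linked by genomic contiguity.

Two families are linked if some genome carries members of both as direct
neighbors on a contig.  Each edge records how often the adjacency occurs
per genome; its weight is the total adjacency count divided by the number
of genomes, so an adjacency conserved everywhere has weight 1 and
repeated paralogous adjacencies can push a weight above 1.  Because the
graph is a union over genomes, an assembly gap in one genome does not
remove a link supported by the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .genome import Genome

__all__ = ["PangenomeGraph", "build_graph", "mrf_edges"]


@dataclass
class PangenomeGraph:
    """Weighted family-contiguity graph over ``n_genomes`` genomes.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are
    family ids (attribute ``gene_count``: number of member genes seen) and
    whose edges carry ``count`` (total adjacency occurrences,
    countNeighboringGenes summed over genomes), ``genomes`` (per-genome
    occurrence counts) and ``weight`` = count / n_genomes.  Self-loops
    mark adjacent paralogs of a single family.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    n_genomes: int = 0

    @property
    def families(self) -> list[str]:
        return list(self.graph.nodes)

    def total_adjacency_count(self) -> int:
        return sum(d["count"] for _, _, d in self.graph.edges(data=True))

    def degree_no_self(self, node) -> int:
        """Number of distinct neighbors, excluding the node itself."""
        return sum(1 for nbr in self.graph.adj[node] if nbr != node)

    def subset_genomes(self, genome_ids: Sequence[str]) -> "PangenomeGraph":
        """Induced graph keeping only adjacencies observed in a genome subset.

        Edge counts are restricted to the subset and weights recomputed
        with the subset size as N; edges unsupported within the subset are
        dropped, as are nodes with no remaining gene occurrences.
        """
        keep = set(genome_ids)
        n = len(keep)
        out = nx.Graph()
        for u, v, d in self.graph.edges(data=True):
            per = {g: c for g, c in d["genomes"].items() if g in keep}
            if not per:
                continue
            count = sum(per.values())
            out.add_edge(u, v, count=count, genomes=per, weight=count / n)
        for node, d in self.graph.nodes(data=True):
            if node in out:
                out.nodes[node].update(d)
        return PangenomeGraph(out, n)


def build_graph(genomes: Sequence[Genome], n_genomes: int | None = None) -> PangenomeGraph:
    """Build the contiguity graph from ordered, family-annotated genomes.

    Consecutive genes on a contig contribute one adjacency between their
    families (plus the last→first closure on circular contigs).  Strand is
    ignored: neighborhood is positional.
    """
    if n_genomes is None:
        n_genomes = len(genomes)
    g = nx.Graph()
    for genome in genomes:
        for contig in genome.contigs:
            fams = [gene.family_id for gene in contig.genes]
            for fam in fams:
                if fam not in g:
                    g.add_node(fam, gene_count=0)
                g.nodes[fam]["gene_count"] += 1
            pairs = list(zip(fams, fams[1:]))
            if contig.circular and len(fams) > 1:
                pairs.append((fams[-1], fams[0]))
            for a, b in pairs:
                if g.has_edge(a, b):
                    d = g.edges[a, b]
                    d["count"] += 1
                    d["genomes"][genome.genome_id] = d["genomes"].get(genome.genome_id, 0) + 1
                else:
                    g.add_edge(a, b, count=1, genomes={genome.genome_id: 1})
    for _, _, d in g.edges(data=True):
        d["weight"] = d["count"] / n_genomes
    return PangenomeGraph(g, n_genomes)


def mrf_edges(
    pangraph: PangenomeGraph, max_degree: int = 10
) -> list[tuple[str, str, float]]:
    """Edges eligible for MRF smoothing: ``(u, v, weight)`` triples.

    Hub families — degree above ``max_degree`` in the full graph — are
    excluded from smoothing entirely (every incident edge is dropped), as
    are self-loops.  Excluded families still receive partition labels;
    they just take no part in the spatial prior.
    """
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    ok = {n for n in pangraph.graph.nodes if pangraph.degree_no_self(n) <= max_degree}
    return [
        (u, v, d["weight"])
        for u, v, d in pangraph.graph.edges(data=True)
        if u != v and u in ok and v in ok
    ]
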