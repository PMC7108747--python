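"""Readers and writers for the standard interchange formats.

Matrices travel as Rtab (families × genomes 0/1 TSV, first column the
family id) or CSV (same plus a partition column); graphs as GEXF 1.2 or
JSON.  All writers are deterministic: fixed orderings, no timestamps.
"""

from __future__ import annotations

import json
import os
import re

import networkx as nx
import numpy as np
import pandas as pd

from .genome import Genome
from .graph import PangenomeGraph
from .matrix import PAMatrix
from .partition import PARTITION_COLORS, Partitioning

__all__ = [
    "write_matrix",
    "read_rtab",
    "write_graph",
    "read_graph",
    "write_gff3",
    "write_family_map",
    "write_truth",
    "read_distance_matrix",
]


# ---------------------------------------------------------------- matrices


def write_matrix(
    pa: PAMatrix, partitioning: Partitioning | None, path, format: str = "Rtab"
) -> None:
    """Write the P/A matrix as Rtab, or CSV with a partition column."""
    fmt = format.lower()
    if fmt == "rtab":
        df = pd.DataFrame(pa.X, index=pa.family_ids, columns=pa.genome_ids)
        df.index.name = "Gene"
        df.to_csv(path, sep="\t")
    elif fmt == "csv":
        df = pd.DataFrame(pa.X, index=pa.family_ids, columns=pa.genome_ids)
        df.index.name = "Gene"
        if partitioning is not None:
            lab = partitioning.as_dict()
            df.insert(0, "partition", [lab[f] for f in pa.family_ids])
        df.to_csv(path)
    else:
        raise ValueError(f"unknown matrix format {format!r} (use Rtab or CSV)")


def read_rtab(path) -> PAMatrix:
    """Read a families × genomes 0/1 Rtab (or CSV with a partition column)."""
    sep = "\t" if str(path).lower().endswith((".rtab", ".tsv", ".tab")) else None
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if "partition" in df.columns:
        df = df.drop(columns=["partition"])
    return PAMatrix(
        df.to_numpy(dtype=np.int8), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


# ------------------------------------------------------------------ graphs


def _serializable_graph(
    pangraph: PangenomeGraph, partitioning: Partitioning | None
) -> nx.Graph:
    lab = partitioning.as_dict() if partitioning is not None else {}
    g = nx.Graph(n_genomes=pangraph.n_genomes)
    for node in sorted(pangraph.graph.nodes):
        d = pangraph.graph.nodes[node]
        part = lab.get(node, "")
        attrs = {"gene_count": int(d.get("gene_count", 0)), "partition": part}
        if part in PARTITION_COLORS:
            r, gg, b = PARTITION_COLORS[part]
            attrs["viz"] = {"color": {"r": r, "g": gg, "b": b}}
        g.add_node(node, **attrs)
    for u, v in sorted(map(lambda e: tuple(sorted(e)), pangraph.graph.edges)):
        d = pangraph.graph.edges[u, v]
        genomes = ",".join(f"{gid}:{c}" for gid, c in sorted(d["genomes"].items()))
        g.add_edge(u, v, weight=float(d["weight"]), count=int(d["count"]), genomes=genomes)
    return g


def write_graph(
    pangraph: PangenomeGraph,
    partitioning: Partitioning | None,
    path,
    format: str = "GEXF",
) -> None:
    """Write the partitioned graph as GEXF 1.2 or JSON.

    Node attributes: partition, gene_count (plus the conventional
    orange/green/blue partition colors as GEXF viz attributes).  Edge
    attributes: weight, adjacency count, per-genome counts.
    """
    fmt = format.lower()
    g = _serializable_graph(pangraph, partitioning)
    if fmt == "gexf":
        lines = "\n".join(nx.generate_gexf(g, version="1.2draft"))
        # networkx stamps the file with the current date; pin it for
        # byte-reproducible output
        lines = re.sub(r'lastmodifieddate="[^"]*"', 'lastmodifieddate="1970-01-01"', lines)
        with open(path, "w") as fh:
            fh.write(lines + "\n")
    elif fmt == "json":
        payload = {
            "n_genomes": pangraph.n_genomes,
            "nodes": [
                {"id": n, **{k: v for k, v in d.items() if k != "viz"}}
                for n, d in sorted(g.nodes(data=True))
            ],
            "edges": [
                {"source": u, "target": v, **d}
                for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown graph format {format!r} (use GEXF or JSON)")


def _parse_genomes_attr(s: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in s.split(","):
        if item:
            gid, c = item.rsplit(":", 1)
            out[gid] = int(c)
    return out


def read_graph(path, format: str | None = None) -> tuple[PangenomeGraph, dict[str, str]]:
    """Read a graph written by :func:`write_graph`.

    Returns the graph and the family → partition mapping (empty strings
    if the graph was written unpartitioned).
    """
    fmt = (format or os.path.splitext(str(path))[1].lstrip(".")).lower()
    g = nx.Graph()
    partitions: dict[str, str] = {}
    if fmt == "gexf":
        raw = nx.read_gexf(path)
        n_genomes = 0
        for n, d in raw.nodes(data=True):
            g.add_node(n, gene_count=int(d.get("gene_count", 0)))
            partitions[n] = d.get("partition", "")
        for u, v, d in raw.edges(data=True):
            genomes = _parse_genomes_attr(d.get("genomes", ""))
            count = int(d.get("count", sum(genomes.values())))
            g.add_edge(u, v, count=count, genomes=genomes, weight=float(d["weight"]))
            if d["weight"] > 0:
                n_genomes = round(count / d["weight"])
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        n_genomes = payload["n_genomes"]
        for nd in payload["nodes"]:
            g.add_node(nd["id"], gene_count=nd.get("gene_count", 0))
            partitions[nd["id"]] = nd.get("partition", "")
        for ed in payload["edges"]:
            g.add_edge(
                ed["source"],
                ed["target"],
                count=ed["count"],
                genomes=_parse_genomes_attr(ed["genomes"]),
                weight=ed["weight"],
            )
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return PangenomeGraph(g, n_genomes), partitions


# --------------------------------------------------------- genome artifacts


def write_gff3(genome: Genome, path) -> None:
    """Write a genome's gene coordinates as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in genome.contigs:
            if contig.genes:
                end = max(g.end for g in contig.genes)
                fh.write(f"##sequence-region {contig.contig_id} 1 {end}\n")
            for g in contig.genes:
                attrs = f"ID={g.gene_id}"
                if contig.circular:
                    attrs += ";Is_circular=true"
                fh.write(
                    f"{contig.contig_id}\tpangem\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
                )


def write_family_map(genomes: list[Genome], path) -> None:
    """Write the gene → family 2-column TSV for a genome collection."""
    with open(path, "w") as fh:
        for genome in genomes:
            for gene in genome.genes:
                fh.write(f"{gene.gene_id}\t{gene.family_id}\n")


def write_truth(truth, path) -> None:
    """Write the synthetic ground truth (family, label, component) TSV."""
    with open(path, "w") as fh:
        fh.write("family_id\ttrue_label\tcomponent\n")
        for fam, lab, comp in zip(truth.family_ids, truth.labels_true, truth.components_true):
            fh.write(f"{fam}\t{lab}\t{comp}\n")


def read_distance_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a square genome-distance TSV with id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column ids differ")
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
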