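"""Genome and gene data model, plus GFF3 ingestion.

A :class:`Genome` is an ordered collection of contigs; each contig is an
ordered list of :class:`Gene` records sorted by start coordinate.  Gene
order within contigs is the only positional information the downstream
graph construction uses — coordinates are kept 1-based inclusive as in
GFF3 but never interpreted beyond ordering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

__all__ = ["Gene", "Contig", "Genome", "read_gff3", "read_family_map"]


@dataclass(frozen=True)
class Gene:
    """A single annotated gene with its family assignment."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    family_id: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")


@dataclass
class Contig:
    """An ordered run of genes on one replicon or assembly fragment.

    ``circular=True`` adds the last→first adjacency when building the
    contiguity graph; assemblies default to linear.
    """

    contig_id: str
    genes: list[Gene] = field(default_factory=list)
    circular: bool = False

    def sort(self) -> None:
        # stable order: start, then end, then gene_id
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))


@dataclass
class Genome:
    genome_id: str
    contigs: list[Contig] = field(default_factory=list)

    @property
    def genes(self) -> list[Gene]:
        return [g for c in self.contigs for g in c.genes]

    def validate(self) -> None:
        seen: set[str] = set()
        for contig in self.contigs:
            starts = [g.start for g in contig.genes]
            if starts != sorted(starts):
                raise ValueError(
                    f"genome {self.genome_id}, contig {contig.contig_id}: genes not ordered by start"
                )
            for g in contig.genes:
                if g.gene_id in seen:
                    raise ValueError(
                        f"genome {self.genome_id}: duplicate gene_id {g.gene_id!r}"
                    )
                seen.add(g.gene_id)


def read_family_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column TSV (gene_id TAB family_id) into a dict."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


_GENE_TYPES = ("CDS", "tRNA", "rRNA", "tmRNA", "ncRNA")


def read_gff3(
    paths: Mapping[str, str | os.PathLike] | Sequence[str | os.PathLike],
    family_map: Mapping[str, str] | str | os.PathLike,
    feature_types: Iterable[str] = _GENE_TYPES,
) -> list[Genome]:
    """Read one GFF3 file per genome into ordered :class:`Genome` objects.

    Parameters
    ----------
    paths
        Either a mapping ``genome_id -> gff3 path`` or a sequence of paths
        (genome ids are then taken from the file stem).
    family_map
        ``gene_id -> family_id`` mapping, or the path of a 2-column TSV.
    feature_types
        GFF3 feature types retained (CDS plus RNA genes by default).

    Every retained feature must have a family assignment; unmapped gene ids
    raise a ``ValueError`` listing the offenders.
    """
    if not isinstance(family_map, Mapping):
        family_map = read_family_map(family_map)
    if isinstance(paths, Mapping):
        items = list(paths.items())
    else:
        items = [(Path(p).stem.replace(".gff", ""), p) for p in paths]

    wanted = set(feature_types)
    genomes: list[Genome] = []
    for genome_id, path in items:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
        )
        contigs: dict[str, Contig] = {}
        missing: list[str] = []
        seen_ids: set[str] = set()
        for feat in db.all_features():
            if feat.featuretype not in wanted:
                continue
            gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
                "locus_tag", [None]
            )[0]
            if gene_id is None:
                raise ValueError(f"{path}: {feat.featuretype} at {feat.seqid}:{feat.start} lacks an ID")
            if gene_id in seen_ids:
                raise ValueError(f"genome {genome_id}: duplicate gene_id {gene_id!r}")
            seen_ids.add(gene_id)
            fam = family_map.get(gene_id)
            if fam is None:
                missing.append(gene_id)
                continue
            circular = feat.attributes.get("Is_circular", ["false"])[0].lower() == "true"
            contig = contigs.setdefault(feat.seqid, Contig(feat.seqid))
            if circular:
                contig.circular = True
            contig.genes.append(
                Gene(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    family_id=fam,
                )
            )
        if missing:
            raise ValueError(
                f"genome {genome_id}: {len(missing)} gene(s) without family mapping: "
                + ", ".join(sorted(missing)[:10])
            )
        genome = Genome(genome_id, sorted(contigs.values(), key=lambda c: c.contig_id))
        for contig in genome.contigs:
            contig.sort()
        genome.validate()
        genomes.append(genome)
    return genomes
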