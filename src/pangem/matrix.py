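"""Binary presence/absence matrix of gene families across genomes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import Genome

__all__ = ["PAMatrix", "build_pa_matrix"]


@dataclass
class PAMatrix:
    """F×N binary matrix X with x_ij = 1 iff family i occurs in genome j.

    Rows are gene families, columns genomes.  Presence means "at least one
    member of the family", so paralogs do not inflate entries.  Every row
    has at least one 1 (a family that occurs nowhere is not a family).
    """

    X: np.ndarray
    family_ids: list[str]
    genome_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.int8))
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (families × genomes)")
        if self.X.shape != (len(self.family_ids), len(self.genome_ids)):
            raise ValueError(
                f"shape {self.X.shape} inconsistent with {len(self.family_ids)} families "
                f"× {len(self.genome_ids)} genomes"
            )
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X entries must be 0 or 1")
        if (self.X.sum(axis=1) < 1).any():
            empty = [self.family_ids[i] for i in np.flatnonzero(self.X.sum(axis=1) < 1)]
            raise ValueError(f"families with zero presence: {empty[:10]}")

    @property
    def n_families(self) -> int:
        return self.X.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.X.shape[1]

    def family_index(self, family_id: str) -> int:
        try:
            return self.family_ids.index(family_id)
        except ValueError:
            raise KeyError(family_id) from None

    def presence_frequency(self) -> np.ndarray:
        """Fraction of genomes each family is present in (length F)."""
        return self.X.mean(axis=1)

    def subset_genomes(self, genome_ids: Sequence[str]) -> "PAMatrix":
        """Restrict to a genome subset, dropping families absent from it."""
        col = [self.genome_ids.index(g) for g in genome_ids]
        sub = self.X[:, col]
        keep = sub.sum(axis=1) >= 1
        return PAMatrix(
            sub[keep], [f for f, k in zip(self.family_ids, keep) if k], list(genome_ids)
        )


def build_pa_matrix(genomes: Sequence[Genome]) -> PAMatrix:
    """Build the P/A matrix from annotated genomes.

    Families are ordered by first appearance across the genome sequence;
    genomes keep their input order.
    """
    if not genomes:
        raise ValueError("at least one genome is required")
    family_ids: list[str] = []
    fam_idx: dict[str, int] = {}
    genome_ids = [g.genome_id for g in genomes]
    rows: list[set[int]] = [set() for _ in genomes]
    for j, genome in enumerate(genomes):
        for gene in genome.genes:
            i = fam_idx.get(gene.family_id)
            if i is None:
                i = fam_idx[gene.family_id] = len(family_ids)
                family_ids.append(gene.family_id)
            rows[j].add(i)
    if not family_ids:
        raise ValueError("no gene families found in the input genomes")
    X = np.zeros((len(family_ids), len(genomes)), dtype=np.int8)
    for j, present in enumerate(rows):
        X[list(present), j] = 1
    return PAMatrix(X, family_ids, genome_ids)
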