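"""Descriptive statistics on a partitioned pangenome graph."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .graph import PangenomeGraph
from .matrix import PAMatrix
from .partition import CLOUD, PERSISTENT, SHELL, Partitioning
from .rarefaction import soft_core_min_presence

__all__ = [
    "partition_degree_stats",
    "shell_jaccard_distances",
    "shell_structure_correlation",
    "summary_table",
    "mash_distance_to_ani_percent",
]


def mash_distance_to_ani_percent(mash_distance: float) -> float:
    """Approximate Average Nucleotide Identity (%) for a Mash distance.

    Mash distance approximates 1 − ANI, so the customary conspecific
    cutoff of 0.06 corresponds to a 94% ANI species boundary.
    """
    if not 0 <= mash_distance <= 1:
        raise ValueError("Mash distance must lie in [0, 1]")
    return 100.0 * (1.0 - mash_distance)


def partition_degree_stats(
    pangraph: PangenomeGraph, partitioning: Partitioning
) -> pd.DataFrame:
    """Per-partition connectivity census.

    For each label, the subgraph induced on same-label families is
    examined: mean degree inside it, number of connected components,
    largest-component size and singleton count.  The mean degree toward
    other partitions is reported alongside for transparency.
    """
    import networkx as nx

    lab = partitioning.as_dict()
    g = pangraph.graph
    rows = []
    for label in (PERSISTENT, SHELL, CLOUD):
        nodes = [n for n in g.nodes if lab.get(n) == label]
        if not nodes:
            rows.append((label, 0, np.nan, np.nan, 0, 0, 0))
            continue
        sub = g.subgraph(nodes)
        degs = [d for _, d in sub.degree()]
        cross = [
            sum(1 for nbr in g.adj[n] if nbr != n and lab.get(nbr) != label) for n in nodes
        ]
        comps = list(nx.connected_components(sub))
        rows.append(
            (
                label,
                len(nodes),
                float(np.mean(degs)),
                float(np.mean(cross)),
                len(comps),
                max(len(c) for c in comps),
                sum(1 for c in comps if len(c) == 1),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "partition",
            "n_families",
            "mean_intra_degree",
            "mean_cross_degree",
            "n_components",
            "largest_component",
            "n_singletons",
        ],
    )


def shell_jaccard_distances(pa: PAMatrix, partitioning: Partitioning) -> np.ndarray:
    """N×N Jaccard distance matrix between genomes on shell-family P/A."""
    shell_rows = [
        pa.family_index(f)
        for f, l in zip(partitioning.family_ids, partitioning.labels)
        if str(l) == SHELL and f in set(pa.family_ids)
    ]
    if not shell_rows:
        raise ValueError("no shell families: shell structure is undefined")
    profiles = pa.X[shell_rows].T.astype(bool)  # genomes × shell families
    return squareform(pdist(profiles, metric="jaccard"))


def shell_structure_correlation(
    pa: PAMatrix, partitioning: Partitioning, genome_distances: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of shell-P/A Jaccard vs genomic distances.

    ``genome_distances`` is a symmetric N×N matrix (e.g. Mash/ANI-based,
    supplied by the user) in the genome order of ``pa``.  Returns
    (rho, p-value) over the strict upper triangles.
    """
    D = np.asarray(genome_distances, dtype=float)
    n = pa.n_genomes
    if D.shape != (n, n):
        raise ValueError(f"distance matrix must be {n}×{n}")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 genomes")
    J = shell_jaccard_distances(pa, partitioning)
    iu = np.triu_indices(n, k=1)
    rho, p = spearmanr(J[iu], D[iu])
    return float(rho), float(p)


def summary_table(
    partitioning: Partitioning, pa: PAMatrix, soft_threshold: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome partition counts plus a pangenome-level summary.

    Returns ``(per_genome, overview)``: the first has one row per genome
    with its count of present persistent/shell/cloud families and total;
    the second the family totals per partition, medians and IQRs of the
    per-genome counts, and the soft-core size.
    """
    lab_by_fam = dict(zip(partitioning.family_ids, map(str, partitioning.labels)))
    labels = np.array([lab_by_fam[f] for f in pa.family_ids], dtype=object)
    per_rows = []
    for j, gid in enumerate(pa.genome_ids):
        present = pa.X[:, j] == 1
        per_rows.append(
            (
                gid,
                int((present & (labels == PERSISTENT)).sum()),
                int((present & (labels == SHELL)).sum()),
                int((present & (labels == CLOUD)).sum()),
                int(present.sum()),
            )
        )
    per_genome = pd.DataFrame(
        per_rows, columns=["genome_id", PERSISTENT, SHELL, CLOUD, "total"]
    )

    presence = pa.X.sum(axis=1)
    soft_min = soft_core_min_presence(pa.n_genomes, soft_threshold)
    over_rows = []
    for label in (PERSISTENT, SHELL, CLOUD):
        col = per_genome[label]
        over_rows.append(
            (
                label,
                int((labels == label).sum()),
                float(col.median()),
                float(col.quantile(0.75) - col.quantile(0.25)),
            )
        )
    overview = pd.DataFrame(
        over_rows, columns=["partition", "n_families", "median_per_genome", "iqr_per_genome"]
    )
    overview.attrs["soft_core_size"] = int((presence >= soft_min).sum())
    overview.attrs["pangenome_size"] = pa.n_families
    return per_genome, overview
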