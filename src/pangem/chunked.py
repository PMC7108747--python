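"""Chunked partitioning with consensus voting, for large genome sets.

NEM scales poorly past a few hundred genomes, so genomes are shuffled
into chunks (≥500 advised), each chunk is partitioned independently
(P/A columns and graph weights restricted to the chunk, weights
renormalized by the chunk size), and each family's label is decided by
absolute majority over the samplings in which it was present.  Families
without an absolute majority trigger further sampling rounds; any still
undecided after ``max_rounds`` fall back to shell, the convention for
uncertain families.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .graph import PangenomeGraph
from .matrix import PAMatrix
from .nem import MRFConfig, run_nem
from .partition import CLOUD, PERSISTENT, SHELL, Partitioning

__all__ = ["ChunkVote", "make_chunks", "partition_chunked"]


@dataclass
class ChunkVote:
    """Voting record of one family across chunk partitionings."""

    family_id: str
    votes: Counter = field(default_factory=Counter)
    samplings_present: int = 0

    def add(self, label: str) -> None:
        self.votes[label] += 1
        self.samplings_present += 1

    @property
    def decided(self) -> bool:
        """Absolute majority: a unique modal label holding at least half
        of the samplings where the family was present."""
        if not self.votes:
            return False
        top = self.votes.most_common()
        best_count = top[0][1]
        if sum(1 for _, c in top if c == best_count) > 1:
            return False
        return best_count >= 0.5 * self.samplings_present

    @property
    def label(self) -> str | None:
        return self.votes.most_common(1)[0][0] if self.decided else None


def make_chunks(
    genome_ids: list[str],
    chunk_size: int = 500,
    rng: np.random.Generator | int | None = None,
    merge_small: bool = True,
) -> list[list[str]]:
    """Randomly split genomes into chunks of ``chunk_size``.

    A trailing chunk smaller than half the chunk size is merged into its
    predecessor (set ``merge_small=False`` to keep it separate).  With
    N ≤ chunk_size the single chunk is the full genome set.
    """
    if chunk_size < 2:
        raise ValueError("chunk_size must be >= 2")
    rng = np.random.default_rng(rng)
    ids = list(genome_ids)
    if len(ids) <= chunk_size:
        return [ids]
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    chunks = [shuffled[i : i + chunk_size] for i in range(0, len(shuffled), chunk_size)]
    if merge_small and len(chunks) > 1 and len(chunks[-1]) < chunk_size / 2:
        chunks[-2].extend(chunks.pop())
    return chunks


def _vote_component(label: str, K: int) -> int:
    if label == PERSISTENT:
        return 1
    if label == CLOUD:
        return K
    return 2 if K >= 3 else K


def partition_chunked(
    pa: PAMatrix,
    graph: PangenomeGraph | None,
    K: int,
    config: MRFConfig | None = None,
    chunk_size: int = 500,
    max_rounds: int = 10,
    seed: int | None = None,
    return_votes: bool = False,
):
    """Partition a large genome set chunk-wise and aggregate by majority.

    K is fixed in advance (select it on the full data or one chunk).
    When the genome count does not exceed ``chunk_size`` this is exactly
    the non-chunked NEM pipeline.
    """
    config = config or MRFConfig()
    if pa.n_genomes <= chunk_size:
        _, _, part = run_nem(pa, graph, K, config)
        return (part, {}) if return_votes else part

    rng = np.random.default_rng(seed)
    votes = {f: ChunkVote(f) for f in pa.family_ids}
    for _ in range(max_rounds):
        for chunk in make_chunks(pa.genome_ids, chunk_size, rng):
            sub = pa.subset_genomes(chunk)
            sub_graph = graph.subset_genomes(chunk) if graph is not None else None
            _, _, part = run_nem(sub, sub_graph, K, config)
            for fam, lab in zip(part.family_ids, part.labels):
                votes[fam].add(str(lab))
        if all(v.decided for v in votes.values()):
            break

    undecided = [f for f, v in votes.items() if not v.decided]
    if undecided:
        warnings.warn(
            f"{len(undecided)} family(ies) undecided after {max_rounds} rounds; "
            "assigned to shell",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = np.array(
        [votes[f].label if votes[f].decided else SHELL for f in pa.family_ids],
        dtype=object,
    )
    components = np.array([_vote_component(str(l), K) for l in labels])
    # posterior stand-in: vote fractions spread over the class-representative columns
    T = np.zeros((pa.n_families, K))
    for i, f in enumerate(pa.family_ids):
        v = votes[f]
        denom = max(v.samplings_present, 1)
        for lab, c in v.votes.items():
            T[i, _vote_component(lab, K) - 1] += c / denom
    part = Partitioning(
        family_ids=list(pa.family_ids),
        K=K,
        labels=labels,
        components=components,
        posteriors=T,
        decided=np.array([votes[f].decided for f in pa.family_ids], dtype=bool),
    )
    return (part, votes) if return_votes else part
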